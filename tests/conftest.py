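import random

import pytest

from salt.index import IndexBundle
from salt.reference_model import GenomeSequence, SnpPanel, SnpRecord


def make_genome(length: int, seed: int, name: str = "c1") -> GenomeSequence:
    rng = random.Random(seed)
    return GenomeSequence(name, "".join(rng.choice("ACGT") for _ in range(length)))


def make_panel(genome: GenomeSequence, positions, n_alts=1, seed: int = 0) -> SnpPanel:
    rng = random.Random(seed)
    records = []
    for i, pos in enumerate(positions):
        ref = genome.seq[pos]
        others = [b for b in "ACGT" if b != ref]
        alts = tuple(sorted(rng.sample(others, n_alts)))
        records.append(SnpRecord(genome.name, pos, ref, alts, f"s{i}"))
    return SnpPanel(records)


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    return make_genome(400, seed=11)


@pytest.fixture(scope="session")
def toy_panel(toy_genome) -> SnpPanel:
    return make_panel(toy_genome, [50, 120, 121, 300], seed=5)


@pytest.fixture(scope="session")
def toy_bundle(toy_genome, toy_panel) -> IndexBundle:
    return IndexBundle([toy_genome], toy_panel, k=21)


@pytest.fixture(scope="session")
def empty_panel_bundle(toy_genome) -> IndexBundle:
    return IndexBundle([toy_genome], SnpPanel([]), k=21)


def apply_alts(genome: GenomeSequence, panel: SnpPanel, positions) -> str:
    """Donor sequence carrying the first ALT allele at the given panel sites."""
    seq = list(genome.seq)
    for pos in positions:
        rec = panel.get(genome.name, pos)
        seq[pos] = rec.alt_alleles[0]
    return "".join(seq)
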