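# Methods

This note documents the model implemented by `salt`, the choices made where
the design was genuinely open, and what the bundled simulator does and does
not emulate.

## The augmented reference and its two indexes

A reference genome plus a SNP panel defines a set of haplotype sequences:
at every panel site the donor may carry the reference allele or one of up
to three alternative alleles.  `salt` represents this set with two
structures.

*The Gray-encoded reference* assigns each position a 4-bit allele mask
(bit order A,C,G,T, most- to least-significant; N is `0000` and never
matches).  Off-panel positions are one-hot; panel positions carry the union
of reference and alternative allele bits.  The name "Gray code" is kept for
continuity with the literature on bit-packed allele encodings, but the
scheme is a plain one-hot/bitmask encoding: position *i* of the target and
position *j* of the query match iff the bitwise AND of their masks is
nonzero.  (A literal reading of "mask & mask = 1" would make only T match
T; the AND-nonzero interpretation is the only one consistent with the
encoding's worked examples and with the IUPAC-bitmask precedent.)

*The alternative reference (ALT-REF)* makes SNP-crossing seeds findable by
exact search.  For each panel SNP at *p*, every haplotype over the window
`[p-k, p+k]` (clipped at contig ends) formed by choosing one allele at each
panel site in the window is emitted, except the all-reference combination,
which the primary index already covers.  Windows are joined with `#`, each
window followed by one `#` (the text ends in `#`).  Duplicate
(anchor, string) pairs arising from adjacent sites are emitted once.
Enumeration is capped at 256 combinations per site: sites are incorporated
nearest-the-centre first and the remainder are fixed to reference, with a
warning — dense SNP clusters would otherwise blow up exponentially and a
seed only needs *some* window containing its particular allele combination
near the centre SNP.

Both texts get a plain FM-index (BWT, cumulative counts, uncompressed
per-symbol occurrence arrays, full suffix array; symbol order
`$ < # < A < C < G < T`).  Suffix arrays are built by prefix doubling.  No
occurrence-table checkpointing or SA sampling is done: at the scales this
package targets (up to a few megabases) the flat arrays are small, and
clarity wins.  If the reference contains N, the primary text is indexed
over a 6-symbol alphabet with N ranked last; patterns containing N are
rejected at the search surface, so an N in the text can never participate
in a match.

The RFM-index stores, for every ALT-REF suffix beginning with `#`, the
primary coordinate of the window that follows.  `altLocate` walks backward
from a match row with LF-mapping, counting steps until the preceding symbol
is `#`; the match's primary coordinate is that window's anchor plus the
step count.  The first window has no preceding `#` — its boundary is the
`$` sentinel, which the anchor table treats as the boundary of window 0.
Because patterns never contain `#`, a match can never straddle two windows.

## Seeding

Seeds start every `stride_x` nt (default 21) on the read and its reverse
complement and are extended to maximal exact matches against each index
independently.  Maximal extension is found by exponential probing plus
binary search on the prefix length — "prefix of an occurring string occurs"
is monotone — at O(L log L) backward-search steps per seed.  Seeds shorter
than `min_seed_len` (default 19) or with more than `max_hits_per_seed`
(default 512) occurrences are dropped.  Only the read's reverse complement
is searched; the reference itself is indexed on one strand.

Each located hit votes on a diagonal (hit position minus read offset).
Hits on the same contig and strand whose diagonals differ by at most 8 bp
merge into one candidate locus (the tolerance absorbs small indel shifts);
loci are ranked by vote count, capped at 64.  The merge tolerance and cap
are plumbing, not model: their only job is to keep the extension stage
bounded in repetitive regions, and the seeding completeness properties are
tested directly.

## Extension

**snpLV** is a k-difference Landau–Vishkin extension over the masks.  The
read must be consumed in full; the target — a reference slab from
`candidate - e_max` to `candidate + read_length + e_max`, Gray-encoded on
the fly from the primary reference and panel — has free start and end.
States are (diagonal `d = target_pos − query_pos`, differences `e`), the
value is the furthest query index reached, and every transition
(substitution / deletion / insertion, unit cost each) is followed by a
longest-common-extension jump.  Start diagonals range over
`[0, n − m + e_max]`; `e` is explored in increasing order, so the first
completed layer is the minimal distance.  Published statements of the
recurrence differ in their LCE index conventions, so the recurrence here
was re-derived in this formulation and is verified against a quadratic
semi-global DP oracle with the identical match rule (hundreds of random
mask instances, plus the one-hot reduction checked against an independent
edit-distance library).  Traceback ties prefer substitution, then deletion,
then insertion, which keeps gap placement deterministic and avoids spurious
single-base gaps.  The difference budget `e_max` is
`floor(0.10 × read_length)`, matching the output filter, so an alignment
that would be discarded is never computed.

**snpSW** is Smith–Waterman with Gotoh's affine-gap recurrences
(`H`, `E`, `F` matrices), substitution `a` if masks intersect else `b`,
defaults `a=1, b=−4, o=6, e=1` (BWA-like; the method itself prescribes no
values).  Scalar DP with full traceback matrices; the deletion matrix is
vectorised per row, the insertion recurrence runs sequentially.  Unaligned
query ends become soft clips.  snpLV is the default extension everywhere;
snpSW is used where a local alignment with free both-ends placement is the
right tool: mate rescue and Polish.

The per-alignment SNP report walks the final traceback and emits the panel
id of every aligned column where the read base is one of the site's
alternative alleles (reference-allele columns do not count).

## Mapping, pairing, output

Per read: seed, collect candidates, snpLV at each, keep the minimal
edit-distance alignment and its ties, drop everything above the 10% filter.
Ties beyond the first are emitted as secondary records (flag 0x100), on by
default.  MAPQ is an explicit placeholder heuristic, not part of the
method: 0 on ties, 60 with no runner-up, else `min(60, 6·Δscore)`.

Paired ends use the insert window `[u − 3σ, u + 3σ]` (defaults u=400,
σ=50, taken from flags — estimation from data is out of scope).  The pair
distance is outer: leftmost start of the forward alignment to rightmost end
of the reverse one.  Proper pairs need forward–reverse orientation with the
forward mate leftmost.  If exactly one mate maps, the other is rescued by
snpSW inside the window implied by the anchor, accepted at score
≥ 0.5·a·|mate|.

SAM output (via pysam) carries NM (SNP-aware edit distance), AS, and a `ZS`
tag with the consumed SNP ids; records appear in input order; POS is
1-based in the file, all internal coordinates are 0-based half-open.

## Polish

Realignment to the linear reference uses plain Gotoh SW (both sides
one-hot) over the window `[POS − L, POS + 2L]`, rewriting POS/CIGAR/NM —
so a read carrying a panel alt allele goes from NM=0 to NM=1, which is
exactly what linear-genome downstream tools expect.  Records scoring below
0.3·a·L keep their original coordinates and get a `ZP` tag rather than
being dropped.  QNAME/SEQ/QUAL are never modified.

## The simulator and the evaluation metrics

The simulator emulates a single-sample resequencing experiment: an i.i.d.
uniform genome; panel sites at rate 0.5% by default, with 1–3 alternative
alleles (probabilities 0.90/0.08/0.02 — most real common SNPs are
biallelic); a donor haplotype carrying the alternative allele at 50% of
panel sites, plus novel SNPs at 0.1%, indel events at 0.02% (lengths 1–3),
and per-base substitution sequencing errors at 0.4%; reads sampled
uniformly from the donor on both strands with constant 'I' base quality.
Truth records give the reference-projected coordinate of each read's
leftmost base (donor indels are projected through a donor-to-reference
coordinate map, as a read simulator's truth files do) plus the injected
error count.  One seeded RNG stream with a fixed draw order makes output
byte-reproducible.

What it does **not** emulate: real base-composition and repeat structure
(an i.i.d. genome has almost no repeats, so candidate ambiguity is rare),
linkage between panel sites, quality-dependent error profiles, indel
sequencing errors, or structural variants.  Passing the end-to-end tests
therefore demonstrates correctness of the machinery under the stated error
model, not mapping accuracy on a real genome's repeat landscape.

Evaluation follows the perfect-alignment convention: simulated mode counts
a mapped read as PA when its position is within 4 bp of the truth; real
mode when NM plus clipped bases is under 10% of the read length.  The
summary reports `Sen = #PA/n × 100` and `Acc = n/N × 100` (n mapped of N
total) — these formula names are used verbatim for continuity even though
this "Sen" is precision-like; no attempt is made to rename them.  "Uniq" is
the fraction with MAPQ > 0, and Sen is reported as 0 when nothing maps.

## Default problem sizes

The bundled end-to-end experiment uses a 100 kb genome, 0.5% panel rate,
and 5,000 × 100 bp reads — large enough that every pipeline stage
(including ALT-REF window combinatorics and indel projection) is exercised
thousands of times, small enough that the whole suite runs in well under a
minute on one core.  Index construction and alignment scale roughly
linearly in genome and read count at these sizes; nothing in the
implementation assumes the desk-scale inputs beyond the flat (unsampled)
index arrays.

## Known limitations

- Indels and structural variants in the *panel* are out of scope (the
  windows enumerate substitution haplotypes only); donor/novel indels are
  handled by the extension stage like any other difference.
- MAPQ is a placeholder heuristic; do not feed it to probabilistic callers.
- The 64-candidate cap with a vote-ranked order can, in principle, evict
  the true locus in extremely repetitive references.
- Memory: flat occurrence tables are O(σ·n) words; fine at megabase scale,
  unsuitable for mammalian genomes without the usual sampling/checkpointing.
- Secondary records for ties carry no mate information refinement.
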