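# Methods

This note documents the models, parameters and design choices behind the
package, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Similarity search and statistics

The internal engine is an exact Smith–Waterman local aligner (via
Biopython's `PairwiseAligner`, which implements the affine-gap DP in C)
under BLOSUM62 with gap existence 11 and extension 1 — the classic
protein-BLAST defaults. `X` is scored 0 against every residue, and
sequences are restricted at parse time to the 20 standard amino acids
plus `X` so scoring is always defined. Raw scores S are converted to bit
scores with the gapped Karlin–Altschul parameters published for this
scheme (λ = 0.267, K = 0.041):

    S' = (λS − ln K) / ln 2,    E = m · n · 2^(−S')

with n the subject length for a single pair and the total residue count
of the database in a database search. This reproduces blastp's statistics
closely enough for thresholding, while remaining exact and deterministic;
an adapter that shells out to a real `blastp` (tabular output) exists for
large genome databases, with the caveat that its composition-adjusted
scores differ slightly from the internal engine's.

Threshold semantics, fixed once and used everywhere:

* expansion search: E ≤ 0.001 **and** bit score ≥ 100, both inclusive;
* NP-DB recruitment search: E ≤ 0.001 only;
* BBH conservation/Enzyme-DB profile: reciprocal best hits at ≥ 30 %
  identity (identities / alignment columns, gaps counted in the length)
  across an alignment of ≥ 80 % of **both** sequence lengths;
* best-hit ties break by bit score, then E-value, then subject id —
  arbitrary but deterministic.

Percent identity is computed over aligned columns rather than over the
shorter sequence; combined with the 80 %-of-both-lengths rule this makes
the 30 % filter unambiguous.

**Conservation is a per-genome call.** The "most conserved" copies of an
expanded family are the reciprocal best hits between the family seeds and
each genome's members, evaluated genome by genome. Orthology is a
per-proteome notion: the seed's best partner in genome A and its best
partner in genome B are both conserved copies, while additional paralogs
in either genome are not. Evaluating reciprocity globally across all
genomes would instead mark exactly one copy in the whole database, which
is not what a conservation call means here.

## Copy-number statistics

Per family, counts are taken over **all** genomes of the database, zeros
included; this is what makes per-genome means below 1 meaningful for
families missing from part of a lineage. The mean over genomes that do
have a copy is reported separately (`mean_nonzero`). The SD is the
population SD (divide by n); with a single genome the SD is reported as 0
and significance calling is disabled with a warning. The mode is taken
over genomes with at least one copy, smallest value on ties, and is 0 for
a family absent everywhere. "Beyond" is read strictly: a significant
expansion requires count > mean + 2 SD, an extra copy requires count >
mode. Conservation classes partition families totally: core (fraction of
genomes with a copy = 1), shell (> 0.5, configurable, and < 1), cloud
(≤ 0.5). A member hit by several seeds is counted once — copy counts are
per protein, not per seed-hit.

## Alignment and curation

The internal multiple aligner is progressive: a UPGMA guide tree on 3-mer
composition distances, then profile–profile Needleman–Wunsch with affine
gaps (open −10, extend −0.5), columns scored as the BLOSUM62 expectation
between residue-frequency vectors with gaps contributing zero. Ties in
the DP resolve in a fixed order (match, then gap in the second profile),
so alignments are deterministic for a fixed input order. A `mafft`
adapter is provided; the classification logic only consumes relative
distances, so the engines are interchangeable at that level.

Curation keeps conserved blocks: (1) columns with a gap in more than half
the rows are removed; (2) a column is conserved when its modal residue
(gaps excluded) occurs in more than half of all rows — this majority
criterion stands in for Gblocks' minimum-conservation default, which that
tool does not expose as a single number, and is configurable; (3) runs of
more than 10 consecutive non-conserved columns are removed, splitting the
alignment; (4) blocks are trimmed to start and end on conserved columns
and kept only at length ≥ 5. Defaults (5 / 10 / 50 %) are the standard
curation parameters for these family trees. Curation is idempotent —
block boundaries are conserved columns, so a second pass finds the same
column set — and an alignment where nothing survives signals the caller,
which falls back to the uncurated alignment with a warning.

## Trees, distances, labels

Pairwise distances are Poisson-corrected, d = −ln(1 − p), with p the
mismatch fraction over columns where both rows have a residue; p is
capped at 0.95 so saturated pairs get a large finite distance. Trees are
neighbor-joining (scikit-bio), which is exact on additive matrices and
assigns no meaning to the root; negative NJ branch lengths are clamped to
zero. NJ rather than approximate ML is the default because the label
rules depend only on relative distances and NJ is dependency-free and
deterministic; a FastTree adapter exists for parity on large families.
Trees are kept unrooted internally; midpoint or outgroup rooting is
applied only for display export. With two rows a cherry is returned with
the distance split evenly.

"Closer to recruitments than to conserved enzymes" is implemented as the
minimum patristic distance to the nearest blue leaf being strictly
smaller than to the nearest red leaf (purple counts as red — a transition
enzyme is conserved). Patristic distance was chosen over clade
membership as the most faithful computable reading of a rule that is
otherwise stated pictorially; the helper computing the two minima is the
single place to swap in an alternative. Exact ties go grey: a prediction
requires strict evidence. Only NP-DB sequences are coloured blue; genome
members that hit the NP DB earn green through the tree, and NP leaves are
excluded from copy counts (they are not genome copies). Cluster
membership is inclusive ≥ 1 bp overlap on the same genome and contig.

## Synthetic data

The fixture generator emulates the four input databases with planted
truth. Seeds are uniform-random proteins (default length 300); conserved
copies are point-mutated descendants at divergence 0.05; orphan extras at
0.3; NP homologs diverge 0.35 from the seed and recruited copies 0.05
from the NP sequence, so recruited copies sit unambiguously nearer the
blue leaf. Substitutions are uniform over the 19 alternatives with no
indels by default (an indel-rate option exists for curation tests);
filler genes are drawn from the shuffled residue composition of the
seeds, so spurious similarity is possible but falls far below the search
thresholds. The default plan (10 genomes × 50 genes, 3 families) plants
one core family with a significant expansion (6 copies vs μ + 2σ = 4.5 in
one genome), one shell family (7/10 genomes) with a green and a cyan
recruitment plus a purple transition, and one core family whose NP
homolog is never recruited. Generation validates that every planted copy
passes the expansion thresholds, and fails fast on an infeasible plan.

What the generator does **not** emulate: tree-structured evolution,
rate heterogeneity, domain shuffling, fragmented gene calls, and
contamination. Passing the label-recovery tests therefore shows the
algorithmic chain is correct under clean planted signal, not that the
thresholds are optimal for real proteomes — on real data the 30/80 BBH
profile and the E/bit-score gates do the work the fixtures make trivial.

## Problem sizes and numerical notes

The bundled runs use the default fixture scale (10 genomes × 50 genes,
~540 proteins, 3 families), where a full pipeline run takes a few seconds
on one core; the same code paths take genome databases limited only by
the quadratic cost of exact search, for which the external blastp adapter
is the intended escape hatch. Coordinates are 1-based inclusive
everywhere (GenBank convention). Copy tables are plain pandas frames;
exports are TSV/CSV/Newick/JSON only. The pipeline is deterministic end
to end — the only randomness in the package lives in the fixture
generator, seeded from a single integer.

## Known limitations

* Enzyme-DB construction pools each lineage's seed genomes for the BBH
  search rather than requiring a partner in every individual seed genome;
  a family is retained when every lineage contributed at least one seed.
* The curation block rules approximate Gblocks semantics but are not a
  re-implementation; unstated Gblocks internals (e.g. its two-tier
  conservation thresholds) are replaced by the single majority criterion.
* No bootstrap or Bayesian support values; label calls carry distances,
  not confidence.
* The QC rule for draft genomes (mean ≥ 5 genes per contig) is exposed as
  an optional filter and off by default, since it describes an inclusion
  criterion rather than a mandatory transformation.
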