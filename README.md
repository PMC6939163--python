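# evomine

Genome mining by evolution: detect lineage-specific **expansions** of
conserved enzyme families across a genome database, find family copies
**recruited** into natural-product (NP) biosynthetic gene clusters (BGCs),
and label every copy on a family phylogeny by its metabolic **origin and
fate**. The approach complements rule-based BGC finders (antiSMASH-style
tools): instead of searching for known biosynthetic signatures, it asks
which central-metabolic enzymes have gained extra copies and where those
copies drifted — candidate enzymes for genuinely novel chemistry.

It is aimed at microbial comparative genomicists and natural-product
researchers who want to mine their own lineage of interest with their own
enzyme families.

## Method

Inputs are four databases: a **Genome DB** (annotated genomes, GenBank or
GFF3 + protein FASTA), an **Enzyme DB** (seed sequences of conserved
enzyme families), an **NP DB** (BGC proteins with accessions, MIBiG-style
`>bgc_id|protein_id` headers), and optionally a table of externally
predicted cluster intervals per genome.

1. **Expansion.** Each family's seeds are searched against every genome
   proteome (exact Smith–Waterman under BLOSUM62, gap open 11 / extend 1,
   Karlin–Altschul bit scores). Copies with E ≤ 0.001 and bit score ≥ 100
   become family members. Per-family copy counts over genomes give, with
   zeros included, the mean μ and population SD σ; a genome is a
   **significant expansion** when its count > μ + 2σ, and carries **extra
   copies** when its count exceeds the modal copy number. Families are
   classed **core** (a copy in every genome), **shell** (in more than 50 %
   but not all) or **cloud** (in at most half).
2. **Recruitment.** Members are searched against the NP DB at E ≤ 0.001;
   hit NP sequences join the family tree as recruitment evidence.
3. **Tree and labels.** Seeds + members + recruited NP sequences are
   aligned, the alignment is curated by conserved-block filtering (gap >
   50 % columns removed, runs of > 10 non-conserved columns cut, blocks <
   5 columns dropped), and a neighbor-joining tree is built on
   Poisson-corrected distances, d = −ln(1 − p). Each leaf then gets one
   label, first match wins:
   seed (orange) → NP sequence (blue) → conserved ∧ in-cluster
   (**transition**, purple) → conserved, i.e. bidirectional best hit to a
   seed at ≥ 30 % identity over ≥ 80 % of both lengths (red) → in-cluster
   (cyan) → non-conserved copy patristically closer to a blue leaf than to
   a red one (**prediction**, green) → unknown (grey). Cyan wins over
   green; no blue leaves means no green calls.

Outputs per family: Newick tree, label CSV, and Microreact-compatible
tree + metadata; globally, a copy-number heat matrix (extra copies `+`,
significant expansions `*`) and a JSON summary.

## Worked example

Generate a bundled synthetic dataset (10 genomes × 50 genes, 3 families
with planted conserved, expanded, recruited and orphan copies) and run the
pipeline:

```sh
evomine fixtures --seed 1 --out toy
evomine run --genomes toy/genomes --enzymes toy/enzyme_db.faa \
    --npdb toy/np_db.faa --clusters toy/clusters.tsv --out toy_run
```

The summary reports, per family (actual output for seed 1):

```
fam-a core  mean=1.50 mode=1 significant=['g00'] labels={'conserved': 10, 'seed': 1, 'unknown': 5}
fam-b shell mean=0.90 mode=1 significant=[]      labels={'antismash': 1, 'conserved': 6, 'prediction': 1, 'recruitment': 1, 'seed': 1, 'transition': 1}
fam-c core  mean=1.10 mode=1 significant=['g05'] labels={'conserved': 10, 'recruitment': 1, 'seed': 1, 'unknown': 1}
```

`fam-a` is a core family whose genome `g00` carries a significant
expansion (6 copies vs μ + 2σ = 4.5); its five extra copies stay grey
because no NP homolog exists. `fam-b` is a shell family (7/10 genomes):
one recruited copy is called green (closer on the tree to the blue MIBiG-
style leaf than to any red conserved copy), the one inside a declared
cluster is cyan, and the conserved copy sharing that cluster is purple.
The heat matrix marks `g00`'s cell `6+*` (extra copies and significant),
and `fam-b.labels.csv` carries the per-leaf distances behind each call,
e.g. the green copy at `nearest_blue=0.026` vs `nearest_red=0.474`.

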