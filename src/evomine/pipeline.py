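"""End-to-end orchestration: expansion, statistics, trees, labels, exports.

A run reads the genome, enzyme and NP databases (plus optional cluster
annotations), then for every family: expands it across the genomes,
computes copy-number statistics, and — when the family has at least three
tree leaves — aligns seeds + members + recruited NP sequences, curates the
alignment, builds the tree, assigns origin-and-fate labels, and writes the
Newick, label CSV and Microreact-compatible exports. Families with fewer
than three leaves are reported and skipped for trees. Per-family failures
are logged and isolated so one degenerate family cannot kill a run.

The pipeline itself is deterministic; the seed in the config is recorded
for provenance and feeds only fixture generation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import classify as cl
from . import families as fam_mod
from .families import EnzymeFamily
from .io import (
    LABEL_COLOURS,
    qc_filter_genomes,
    read_cluster_annotations,
    read_enzyme_db,
    read_genome_dir,
    read_np_db,
    write_microreact,
)
from .msa import (
    Alignment,
    EmptyAlignmentError,
    align_family,
    align_family_mafft,
    curate_alignment,
)
from .records import ClusterAnnotation, Genome, NPRecord
from .search import Thresholds
from .tree import build_tree, build_tree_fasttree

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (bad path or out-of-range threshold)."""


@dataclass
class RunConfig:
    genome_dir: str
    enzyme_db: str
    out_dir: str
    np_db: str | None = None
    clusters: str | None = None
    max_evalue: float = 0.001
    min_bitscore: float = 100.0
    bbh_min_identity: float = 30.0
    bbh_min_len_frac: float = 0.8
    shell_fraction: float = 0.5
    curation_min_block: int = 5
    curation_max_noncons: int = 10
    curation_max_gap_frac: float = 0.5
    qc_min_mean_genes_per_contig: float | None = None
    aligner: str = "internal"       # internal | mafft
    tree_method: str = "nj"         # nj | fasttree
    seed: int = 0

    def validate(self) -> None:
        for p, required in (
            (self.genome_dir, True), (self.enzyme_db, True),
            (self.np_db, False), (self.clusters, False),
        ):
            if required and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
            if not required and p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not (0 < self.max_evalue):
            raise ConfigError("max_evalue must be positive")
        if self.min_bitscore < 0:
            raise ConfigError("min_bitscore must be >= 0")
        if not (0 <= self.bbh_min_identity <= 100):
            raise ConfigError("bbh_min_identity must be in [0, 100]")
        if not (0 <= self.bbh_min_len_frac <= 1):
            raise ConfigError("bbh_min_len_frac must be in [0, 1]")
        if self.aligner not in ("internal", "mafft"):
            raise ConfigError(f"unknown aligner {self.aligner!r}")
        if self.tree_method not in ("nj", "fasttree"):
            raise ConfigError(f"unknown tree method {self.tree_method!r}")

    @property
    def expansion_thresholds(self) -> Thresholds:
        return Thresholds(max_evalue=self.max_evalue,
                          min_bitscore=self.min_bitscore)

    @property
    def bbh_thresholds(self) -> Thresholds:
        return Thresholds(max_evalue=self.max_evalue, min_bitscore=0.0,
                          min_identity=self.bbh_min_identity,
                          min_len_frac=self.bbh_min_len_frac)


@dataclass
class FamilyResult:
    family_id: str
    n_members: int
    label_counts: dict[str, int] = field(default_factory=dict)
    tree_file: str | None = None
    label_file: str | None = None
    skipped: bool = False
    error: str | None = None


@dataclass
class RunReport:
    families: list[FamilyResult]
    heat_matrix_file: str
    summary_file: str
    n_genomes: int
    n_genomes_filtered: int
    total_members: int

    @property
    def skipped_families(self) -> list[str]:
        return [f.family_id for f in self.families if f.skipped]


def _setup_logging(out_dir: Path) -> None:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("evomine")
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    t0 = time.time()

    genomes = read_genome_dir(config.genome_dir)
    n_loaded = len(genomes)
    if config.qc_min_mean_genes_per_contig is not None:
        genomes = qc_filter_genomes(
            genomes, config.qc_min_mean_genes_per_contig
        )
    families = read_enzyme_db(config.enzyme_db)
    np_db = read_np_db(config.np_db) if config.np_db else []
    clusters = (
        read_cluster_annotations(config.clusters) if config.clusters else []
    )
    logger.info(
        "loaded %d genomes (%d after QC), %d families, %d NP records, "
        "%d clusters", n_loaded, len(genomes), len(families), len(np_db),
        len(clusters),
    )
    return run_loaded(
        genomes, families, np_db, clusters, config, out_dir,
        n_genomes_loaded=n_loaded,
    )


def run_loaded(
    genomes: Sequence[Genome],
    families: Sequence[EnzymeFamily],
    np_db: Sequence[NPRecord],
    clusters: Sequence[ClusterAnnotation],
    config: RunConfig,
    out_dir: str | Path,
    n_genomes_loaded: int | None = None,
) -> RunReport:
    """Pipeline body over already-loaded inputs (used by the CLI, the
    fixture round-trip tests and the acceptance run alike)."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expanded = [
        fam_mod.expand_family(f, list(genomes), config.expansion_thresholds)
        for f in families
    ]
    table = fam_mod.copy_table(expanded, genomes)
    stats = fam_mod.expansion_stats(table, config.shell_fraction)
    heat_path = out_dir / "heat_matrix.tsv"
    fam_mod.heat_matrix(table, stats, path=heat_path)

    results: list[FamilyResult] = []
    all_labels: dict[str, list[cl.LeafLabel]] = {}
    for family, fam_stats in zip(expanded, stats):
        try:
            result = _family_phase(
                family, np_db, clusters, config, out_dir, all_labels
            )
        except Exception as exc:  # per-family isolation
            logger.exception("family %s failed", family.family_id)
            result = FamilyResult(
                family_id=family.family_id, n_members=len(family.members),
                error=str(exc),
            )
        results.append(result)

    summary = {
        "config": asdict(config),
        "n_genomes": len(genomes),
        "families": {
            fam.family_id: {
                "n_members": len(fam.members),
                "mean_all": st.mean_all,
                "sd_all": st.sd_all,
                "mode": st.mode,
                "mean_nonzero": st.mean_nonzero,
                "frac_genomes_with_copy": st.frac_genomes_with_copy,
                "conservation_class": st.conservation_class,
                "significant_genomes": sorted(st.significant_genomes),
                "extra_copy_genomes": sorted(st.extra_copy_genomes),
                "label_counts": res.label_counts,
                "tree_file": res.tree_file,
                "skipped": res.skipped,
                "error": res.error,
            }
            for fam, st, res in zip(expanded, stats, results)
        },
        "total_members": int(table.df.values.sum()),
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run finished in %.1f s", time.time() - t0)
    return RunReport(
        families=results,
        heat_matrix_file=str(heat_path),
        summary_file=str(summary_path),
        n_genomes=n_genomes_loaded or len(genomes),
        n_genomes_filtered=len(genomes),
        total_members=int(table.df.values.sum()),
    )


def _family_phase(
    family: EnzymeFamily,
    np_db: Sequence[NPRecord],
    clusters: Sequence[ClusterAnnotation],
    config: RunConfig,
    out_dir: Path,
    all_labels: dict,
) -> FamilyResult:
    blue_ids: list[str] = []
    np_by_id = {r.protein_id: r for r in np_db}
    if np_db and family.members:
        blue_ids, _evidence = cl.find_recruitments(
            family, list(np_db),
            Thresholds(max_evalue=config.max_evalue, min_bitscore=0.0),
        )
    leaves = (
        [(s.protein_id, s.sequence) for s in family.seeds]
        + [(m.protein_id, m.sequence) for m in family.members]
        + [(pid, np_by_id[pid].sequence) for pid in blue_ids]
    )
    if len(leaves) < 3:
        logger.info("family %s: %d leaves, tree skipped",
                    family.family_id, len(leaves))
        return FamilyResult(
            family_id=family.family_id, n_members=len(family.members),
            skipped=True,
        )
    aligner = align_family_mafft if config.aligner == "mafft" else align_family
    aln = aligner(leaves)
    try:
        curated = curate_alignment(
            aln,
            min_block=config.curation_min_block,
            max_contig_noncons=config.curation_max_noncons,
            max_gap_frac=config.curation_max_gap_frac,
        )
    except EmptyAlignmentError:
        logger.warning("family %s: curation removed everything, "
                       "falling back to the uncurated alignment",
                       family.family_id)
        curated = aln
    builder = (
        build_tree_fasttree if config.tree_method == "fasttree" else build_tree
    )
    tree = builder(curated)
    conserved = cl.find_conserved(family, config.bbh_thresholds)
    antismash = cl.find_antismash(family, clusters)
    labels = cl.assign_labels(
        tree, family,
        conserved_set=conserved,
        blue_set=set(blue_ids),
        antismash_set=antismash,
    )
    all_labels[family.family_id] = labels
    safe = family.family_id.replace("/", "_")
    tree_path = out_dir / f"{safe}.nwk"
    label_path = out_dir / f"{safe}.labels.csv"
    micro_csv = out_dir / f"{safe}.microreact.csv"
    cl.label_table(family, labels, path=label_path)
    genome_of = {m.protein_id: m.genome_id for m in family.members}
    copy_of = {}
    for m in family.members:
        copy_of[m.genome_id] = copy_of.get(m.genome_id, 0) + 1
    rows = [
        {
            "id": l.sequence_id,
            "genome_id": genome_of.get(l.sequence_id, ""),
            "label": l.label,
            "colour": LABEL_COLOURS[l.label],
            "copy_number": copy_of.get(genome_of.get(l.sequence_id, ""), ""),
            "annotation": l.evidence,
        }
        for l in labels
    ]
    write_microreact(tree, rows, tree_path, micro_csv)
    return FamilyResult(
        family_id=family.family_id,
        n_members=len(family.members),
        label_counts=cl.summarize_labels(labels),
        tree_file=str(tree_path),
        label_file=str(label_path),
    )
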