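"""Enzyme families: database construction, expansion across a genome
database, and copy-number statistics.

An enzyme family (EF) starts from per-lineage seed sequences. Expansion
collects every genome protein hit by a seed at E <= 0.001 and bitscore
>= 100 (inclusive). Copy counts per genome then yield:

* significant expansions — genomes whose copy count is strictly beyond the
  family mean plus two standard deviations (mean and population SD over
  ALL genomes of the database, zeros included);
* extra copies — genomes strictly beyond the modal copy number (mode taken
  over genomes with at least one copy; smallest value on ties);
* a conservation class — core (copy in every genome), shell (in more than
  half but not all), cloud (in at most half).

Zeros are included in the mean/SD because per-genome means below 1 (e.g. a
family present in only part of a lineage) are meaningful for shell
families; the mean over genomes that do have a copy is reported separately
as ``mean_nonzero``.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import Genome, ProteinRecord
from .search import ENZYME_DB_BBH, Hit, Thresholds, bbh, search_db

logger = logging.getLogger(__name__)


@dataclass
class EnzymeFamily:
    """A conserved enzyme family: seeds plus (after expansion) members."""

    family_id: str
    name: str = ""
    seeds: list[ProteinRecord] = field(default_factory=list)
    members: list[ProteinRecord] = field(default_factory=list)
    #: member protein_id -> (seed protein_id that recruited it, best Hit)
    member_evidence: dict[str, tuple[str, Hit]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError(f"family {self.family_id}: needs at least one seed")

    @property
    def seed_ids(self) -> set[str]:
        return {s.protein_id for s in self.seeds}

    def members_of(self, genome_id: str) -> list[ProteinRecord]:
        return [m for m in self.members if m.genome_id == genome_id]


def build_enzyme_db(
    reference_families: Sequence[EnzymeFamily],
    seed_genomes_by_lineage: Mapping[str, Sequence[Genome]],
    thresholds: Thresholds = ENZYME_DB_BBH,
) -> tuple[list[EnzymeFamily], dict[str, list[str]]]:
    """Re-seed reference families on a new set of lineages by BBH.

    For every reference family and lineage, the BBH partners of the
    family's reference seeds among the lineage's seed-genome proteins
    (passing the >=30 % identity / >=80 % length profile) become that
    lineage's seeds. Families are retained only when every lineage
    contributed at least one seed.

    Returns (retained families, report mapping dropped family_id -> the
    lineages where no BBH partner was found).
    """
    if not reference_families:
        raise ValueError("empty reference family set")
    if not seed_genomes_by_lineage:
        raise ValueError("need at least one lineage")
    pools = {
        lineage: [p for g in genomes for p in g.proteins]
        for lineage, genomes in seed_genomes_by_lineage.items()
    }
    for lineage, pool in pools.items():
        if not pool:
            raise ValueError(f"lineage {lineage!r}: no seed-genome proteins")
    retained: list[EnzymeFamily] = []
    dropped: dict[str, list[str]] = {}
    for fam in reference_families:
        by_id = {p.protein_id: p for pool in pools.values() for p in pool}
        new_seeds: list[ProteinRecord] = []
        missing: list[str] = []
        for lineage, pool in pools.items():
            pairs = bbh(fam.seeds, pool, thresholds)
            if pairs:
                new_seeds.extend(by_id[b] for _a, b in pairs)
            else:
                missing.append(lineage)
        if missing:
            dropped[fam.family_id] = missing
            logger.info("family %s dropped: no BBH partner in %s",
                        fam.family_id, missing)
        else:
            retained.append(
                EnzymeFamily(family_id=fam.family_id, name=fam.name,
                             seeds=new_seeds)
            )
    return retained, dropped


def expand_family(
    family: EnzymeFamily,
    genome_db: Sequence[Genome],
    thresholds: Thresholds = Thresholds(max_evalue=0.001, min_bitscore=100.0),
) -> EnzymeFamily:
    """Collect every genome protein hit by any seed at the expansion
    thresholds (E <= 0.001, bitscore >= 100 by default).

    Members are deduplicated by protein id; each is tagged with the seed
    whose hit scored the highest bitscore (ties: lower E, then seed id).
    Returns a new family; the input is not mutated.
    """
    if not genome_db:
        raise ValueError("empty genome database")
    all_proteins = [p for g in genome_db for p in g.proteins]
    by_id = {p.protein_id: p for p in all_proteins}
    evidence: dict[str, tuple[str, Hit]] = {}
    for seed in sorted(family.seeds, key=lambda s: s.protein_id):
        for hit in search_db(seed, all_proteins, thresholds):
            prev = evidence.get(hit.subject_id)
            if prev is None or (
                (-hit.bitscore, hit.evalue, seed.protein_id)
                < (-prev[1].bitscore, prev[1].evalue, prev[0])
            ):
                evidence[hit.subject_id] = (seed.protein_id, hit)
    members = [by_id[pid] for pid in sorted(evidence)]
    return EnzymeFamily(
        family_id=family.family_id, name=family.name,
        seeds=list(family.seeds), members=members, member_evidence=evidence,
    )


# ---------------------------------------------------------------------------
# copy-number statistics


class CopyTable:
    """Families x genomes matrix of non-negative integer copy counts."""

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("copy counts must be non-negative")
        self.df = df.astype(int)

    @property
    def families(self) -> list[str]:
        return list(self.df.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.df.columns)

    def counts(self, family_id: str) -> pd.Series:
        return self.df.loc[family_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, CopyTable) and self.df.equals(other.df)


def copy_table(
    families: Sequence[EnzymeFamily], genomes: Sequence[Genome]
) -> CopyTable:
    genome_ids = [g.genome_id for g in genomes]
    data = {
        fam.family_id: [
            sum(1 for m in fam.members if m.genome_id == gid)
            for gid in genome_ids
        ]
        for fam in families
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=genome_ids)
    return CopyTable(df)


@dataclass
class ExpansionStats:
    family_id: str
    mean_all: float
    sd_all: float
    mode: int
    mean_nonzero: float
    frac_genomes_with_copy: float
    significant_genomes: set[str]
    extra_copy_genomes: set[str]
    conservation_class: str  # core | shell | cloud
    significance_enabled: bool = True


def _classify(frac: float, shell_fraction: float) -> str:
    if frac == 1.0:
        return "core"
    if frac > shell_fraction:
        return "shell"
    return "cloud"


def expansion_stats(
    table: CopyTable, shell_fraction: float = 0.5
) -> list[ExpansionStats]:
    """Per-family statistics over the whole genome database.

    ``shell_fraction`` is the conservation cut between shell and cloud: a
    family present in more than that fraction of genomes (but not all) is
    shell, at or below it cloud. With a single genome the SD is reported
    as 0 and significance calling is disabled (a warning is logged).
    """
    n = len(table.genomes)
    if n < 1:
        raise ValueError("need at least one genome")
    single = n == 1
    if single:
        logger.warning("single genome: SD undefined, significance disabled")
    out = []
    for fam in table.families:
        counts = table.counts(fam)
        values = counts.to_numpy()
        mean_all = float(values.mean())
        sd_all = 0.0 if single else float(values.std(ddof=0))
        nonzero = values[values > 0]
        frac = float(len(nonzero)) / n
        if len(nonzero):
            freq = Counter(int(v) for v in nonzero)
            top = max(freq.values())
            mode = min(v for v, c in freq.items() if c == top)
            mean_nonzero = float(nonzero.mean())
        else:
            mode = 0
            mean_nonzero = 0.0
        threshold = mean_all + 2.0 * sd_all
        significant = (
            set() if single
            else {g for g, v in counts.items() if v > threshold}
        )
        extra = {g for g, v in counts.items() if v > mode}
        out.append(
            ExpansionStats(
                family_id=fam,
                mean_all=mean_all,
                sd_all=sd_all,
                mode=mode,
                mean_nonzero=mean_nonzero,
                frac_genomes_with_copy=frac,
                significant_genomes=significant,
                extra_copy_genomes=extra,
                conservation_class=_classify(frac, shell_fraction),
                significance_enabled=not single,
            )
        )
    return out


def heat_matrix(
    table: CopyTable,
    stats: Sequence[ExpansionStats],
    genome_order: Sequence[str] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Families x genomes matrix of annotated count cells.

    Cell format: the count, suffixed ``+`` for an extra copy (beyond the
    mode) and ``*`` for a significant expansion (beyond mean + 2 SD), e.g.
    ``"4+*"``. Columns follow ``genome_order`` when given (typically the
    genome order of a species tree). Written as TSV when ``path`` is set.
    """
    order = list(genome_order) if genome_order is not None else table.genomes
    if set(order) != set(table.genomes):
        raise ValueError("genome_order must be a permutation of the genomes")
    by_family = {s.family_id: s for s in stats}
    rows = {}
    for fam in table.families:
        st = by_family[fam]
        cells = []
        for g in order:
            v = int(table.df.loc[fam, g])
            cell = str(v)
            if g in st.extra_copy_genomes:
                cell += "+"
            if g in st.significant_genomes:
                cell += "*"
            cells.append(cell)
        rows[fam] = cells
    df = pd.DataFrame.from_dict(rows, orient="index", columns=order)
    if path is not None:
        df.to_csv(path, sep="\t", index_label="family_id")
    return df


def render_heat_matrix(table: CopyTable, path: str | Path,
                       genome_order: Sequence[str] | None = None) -> None:
    """Optional matplotlib rendering of the copy-number heat plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(genome_order) if genome_order is not None else table.genomes
    data = table.df[order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * len(order)), max(3, 0.3 * len(data)))
    )
    im = ax.imshow(data.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(data)), data.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="copies")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def expansion_vs_genome_size(
    genomes: Sequence[Genome], table: CopyTable
) -> pd.DataFrame:
    """Per-genome gene count vs total family copies, for profiling how
    expansions track genome size."""
    rows = []
    for g in genomes:
        total = int(table.df[g.genome_id].sum()) if g.genome_id in table.df else 0
        rows.append({"genome_id": g.genome_id, "n_genes": g.n_genes,
                     "total_family_copies": total})
    return pd.DataFrame(rows).set_index("genome_id")
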