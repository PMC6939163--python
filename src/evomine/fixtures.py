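"""Self-contained toy Genome/Enzyme/NP databases with planted truth.

The generator emulates the four pipeline inputs at desk scale: an
annotated genome database, seed enzyme families, an NP (BGC protein)
database, and externally predicted cluster intervals. Every planted
protein carries an intended origin-and-fate label in the truth table, so
the full pipeline can be scored against a known answer.

Evolution model: seeds are uniform-random proteins; descendants are
point-mutated copies at a chosen divergence (expected substitution
fraction; substitutions uniform over the 19 alternatives; no indels unless
``indel_rate`` is set). Filler genes are drawn from the shuffled residue
composition of the seeds, so spurious similarity is possible but falls far
below the search thresholds. There is no tree-structured evolution: label
recovery only needs the planted distance relations (conserved copies near
seeds, recruited copies near their NP ancestor), not a realistic
phylogeny.

Default plan (10 genomes x 50 genes, 3 families):

* ``fam_a`` — core; genome 0 carries 5 extra paralogs (a significant
  expansion beyond mean + 2 SD); no NP homolog, so the extras stay grey.
* ``fam_b`` — shell (7/10 genomes); an NP homolog is planted, and two
  genomes carry recruited copies descended from it: one free (green
  prediction) and one inside a declared cluster (cyan), whose genome also
  has its conserved copy inside the cluster (purple transition).
* ``fam_c`` — core; NP homolog planted but never recruited; one orphan
  extra copy sits closer to the conserved side, staying grey with blue
  leaves present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import ClusterAnnotation, Genome, NPRecord, ProteinRecord
from .search import bitscore_from_raw, raw_score

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: gene slots are this many bp apart, wide enough that genes never overlap
_SLOT = 2000


class FixtureSpecError(ValueError):
    """The plan cannot fit in the declared genomes."""


@dataclass(frozen=True)
class RecruitmentPlan:
    genome: int            # genome index carrying the recruited copy
    in_cluster: bool       # True -> cyan (antismash), False -> green
    divergence: float = 0.05   # from the planted NP sequence


@dataclass
class FamilyPlan:
    family_id: str
    present_in: list[int]                  # genomes with a conserved copy
    conserved_divergence: float = 0.05
    extra_copies: dict[int, int] = field(default_factory=dict)
    extra_divergence: float = 0.3
    np_homolog: bool = False
    np_divergence: float = 0.35            # NP sequence vs seed
    recruitments: list[RecruitmentPlan] = field(default_factory=list)
    cluster_over_conserved: list[int] = field(default_factory=list)


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genomes: int = 10
    genes_per_genome: int = 50
    seq_len: int = 300
    indel_rate: float = 0.0
    plans: list[FamilyPlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.plans:
            self.plans = default_plans(self.n_genomes)
        for plan in self.plans:
            for d in (
                [plan.conserved_divergence, plan.extra_divergence,
                 plan.np_divergence]
                + [r.divergence for r in plan.recruitments]
            ):
                if not 0.0 <= d <= 0.95:
                    raise FixtureSpecError(
                        f"{plan.family_id}: divergence {d} outside [0, 0.95]"
                    )


def default_plans(n_genomes: int) -> list[FamilyPlan]:
    if n_genomes < 4:
        raise FixtureSpecError("default plans need at least 4 genomes")
    shell_n = max(3, int(np.ceil(n_genomes * 0.7)))
    return [
        FamilyPlan(
            family_id="fam-a",
            present_in=list(range(n_genomes)),
            extra_copies={0: 5},
        ),
        FamilyPlan(
            family_id="fam-b",
            present_in=list(range(shell_n)),
            np_homolog=True,
            recruitments=[
                RecruitmentPlan(genome=1, in_cluster=False),
                RecruitmentPlan(genome=2, in_cluster=True),
            ],
            cluster_over_conserved=[2],
        ),
        FamilyPlan(
            family_id="fam-c",
            present_in=list(range(n_genomes)),
            extra_copies={min(5, n_genomes - 1): 1},
            np_homolog=True,
        ),
    ]


@dataclass
class FixtureBundle:
    genomes: list[Genome]
    enzyme_db: list          # list[EnzymeFamily]
    np_db: list[NPRecord]
    clusters: list[ClusterAnnotation]
    truth: dict[str, str]    # protein_id -> intended label
    spec: FixtureSpec


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def mutate(
    sequence: str,
    divergence: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
) -> str:
    """Point-mutate a protein at the expected substitution fraction
    ``divergence`` (uniform over the 19 alternatives); optionally apply
    single-residue insertions/deletions at ``indel_rate`` per position."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    out = []
    for aa in sequence:
        if rng.random() < divergence:
            choices = _AA20.replace(aa, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
        if indel_rate > 0.0:
            r = rng.random()
            if r < indel_rate / 2 and out:
                out.pop()
            elif r < indel_rate:
                out.append(_AA20[rng.integers(20)])
    return "".join(out)


def _shuffled_filler(rng: np.random.Generator, pool: str, length: int) -> str:
    idx = rng.integers(0, len(pool), size=length)
    return "".join(pool[i] for i in idx)


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Deterministically generate the four databases plus the truth table.

    Validates at generation time that every planted family copy passes the
    expansion search thresholds (bitscore >= 100 against its seed).
    """
    from .families import EnzymeFamily

    rng = np.random.default_rng(spec.seed)
    gids = [f"g{i:02d}" for i in range(spec.n_genomes)]
    truth: dict[str, str] = {}

    seeds: dict[str, str] = {}
    np_seqs: dict[str, str] = {}
    for plan in spec.plans:
        seeds[plan.family_id] = random_protein(rng, spec.seq_len)
        if plan.np_homolog:
            np_seqs[plan.family_id] = mutate(
                seeds[plan.family_id], plan.np_divergence, rng,
                spec.indel_rate,
            )

    # planted genes per genome: list of (protein_id, sequence, label,
    # cluster_group or None); cluster_group ties adjacent genes into one
    # declared cluster interval
    planted: dict[str, list[tuple[str, str, str, str | None]]] = {
        g: [] for g in gids
    }
    for plan in spec.plans:
        fam = plan.family_id
        seed_seq = seeds[fam]
        for gi in plan.present_in:
            pid = f"{gids[gi]}.{fam}.cons"
            seq = mutate(seed_seq, plan.conserved_divergence, rng,
                         spec.indel_rate)
            cluster = fam if gi in plan.cluster_over_conserved else None
            label = "transition" if cluster else "conserved"
            planted[gids[gi]].append((pid, seq, label, cluster))
            truth[pid] = label
        for gi, n_extra in plan.extra_copies.items():
            for k in range(n_extra):
                pid = f"{gids[gi]}.{fam}.extra{k}"
                seq = mutate(seed_seq, plan.extra_divergence, rng,
                             spec.indel_rate)
                planted[gids[gi]].append((pid, seq, "unknown", None))
                truth[pid] = "unknown"
        for r in plan.recruitments:
            if not plan.np_homolog:
                raise FixtureSpecError(
                    f"{fam}: recruitment planned without an NP homolog"
                )
            pid = f"{gids[r.genome]}.{fam}.rec"
            seq = mutate(np_seqs[fam], r.divergence, rng, spec.indel_rate)
            cluster = fam if r.in_cluster else None
            label = "antismash" if r.in_cluster else "prediction"
            planted[gids[r.genome]].append((pid, seq, label, cluster))
            truth[pid] = label

    # validate planted copies against the expansion thresholds
    for g, genes in planted.items():
        for pid, seq, _label, _cluster in genes:
            fam = pid.split(".")[1]
            if bitscore_from_raw(raw_score(seeds[fam], seq)) < 100:
                raise FixtureSpecError(
                    f"{pid}: planted divergence too high to pass the "
                    "expansion thresholds"
                )

    # assemble genomes: filler genes plus planted genes, over two contigs
    filler_pool = "".join(seeds.values())
    genomes = []
    clusters: list[ClusterAnnotation] = []
    for g in gids:
        n_planted = len(planted[g])
        n_filler = spec.genes_per_genome - n_planted
        if n_filler < 0:
            raise FixtureSpecError(
                f"{g}: {n_planted} planted genes exceed genome capacity "
                f"{spec.genes_per_genome}"
            )
        genes: list[tuple[str, str, str | None, bool]] = [
            (f"{g}.f{i:03d}",
             _shuffled_filler(rng, filler_pool,
                              int(rng.integers(200, 401))),
             None, True)
            for i in range(n_filler)
        ]
        genes += [(pid, seq, cluster, False)
                  for pid, seq, _l, cluster in planted[g]]
        half = (len(genes) + 1) // 2
        contigs: dict[str, list[ProteinRecord]] = {}
        cluster_spans: dict[str, list[tuple[int, int, str]]] = {}
        for idx, (pid, seq, cluster, is_filler) in enumerate(genes):
            contig_id = f"{g}.c1" if idx < half else f"{g}.c2"
            slot = idx if idx < half else idx - half
            start = 1 + slot * _SLOT
            end = start + 3 * len(seq) - 1
            contigs.setdefault(contig_id, []).append(
                ProteinRecord(
                    protein_id=pid, genome_id=g, contig_id=contig_id,
                    start=start, end=end,
                    strand="+" if idx % 2 == 0 else "-",
                    sequence=seq,
                    annotation=(
                        "synthetic filler" if is_filler
                        else "synthetic planted gene"
                    ),
                )
            )
            if cluster is not None:
                cluster_spans.setdefault(cluster, []).append(
                    (start, end, contig_id)
                )
        for cname, spans in cluster_spans.items():
            by_contig: dict[str, list[tuple[int, int]]] = {}
            for s, e, c in spans:
                by_contig.setdefault(c, []).append((s, e))
            for contig_id, ivals in by_contig.items():
                clusters.append(
                    ClusterAnnotation(
                        genome_id=g, contig_id=contig_id,
                        start=min(s for s, _e in ivals),
                        end=max(e for _s, e in ivals),
                        cluster_type=f"synthetic-{cname}",
                    )
                )
        genomes.append(Genome(genome_id=g, contigs=contigs,
                              lineage="lineage-1"))

    enzyme_db = []
    for plan in spec.plans:
        pid = f"{plan.family_id}.seed"
        truth[pid] = "seed"
        enzyme_db.append(
            EnzymeFamily(
                family_id=plan.family_id,
                name=f"synthetic family {plan.family_id}",
                seeds=[ProteinRecord(
                    protein_id=pid, genome_id="seedref", contig_id="seed",
                    start=1, end=3 * len(seeds[plan.family_id]),
                    strand="+", sequence=seeds[plan.family_id],
                )],
            )
        )

    np_db = []
    for i, plan in enumerate(spec.plans):
        if plan.np_homolog:
            pid = f"np.{plan.family_id}"
            truth[pid] = "recruitment"
            np_db.append(NPRecord(
                protein_id=pid, bgc_id=f"BGC{i + 1:07d}",
                sequence=np_seqs[plan.family_id],
                compound=f"synthetic compound {i + 1}",
            ))
    # decoy NP records unrelated to any family
    for i in range(2):
        np_db.append(NPRecord(
            protein_id=f"np.decoy{i}",
            bgc_id=f"BGC{900 + i:07d}",
            sequence=random_protein(rng, spec.seq_len),
            compound="synthetic decoy",
        ))

    return FixtureBundle(
        genomes=genomes, enzyme_db=enzyme_db, np_db=np_db,
        clusters=clusters, truth=truth, spec=spec,
    )


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's external formats: GFF3 + protein
    FASTA per genome, seed FASTA, NP FASTA, cluster TSV and truth CSV."""
    from .io import write_cluster_annotations, write_fasta

    outdir = Path(outdir)
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"genomes": gdir}
    for genome in bundle.genomes:
        gff = gdir / f"{genome.genome_id}.gff3"
        faa = gdir / f"{genome.genome_id}.faa"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig_id, records in genome.contigs.items():
                for p in records:
                    fh.write(
                        f"{contig_id}\tevomine-fixture\tCDS\t{p.start}\t"
                        f"{p.end}\t.\t{p.strand}\t0\tID={p.protein_id};"
                        f"product={p.annotation}\n"
                    )
        write_fasta(genome.proteins, faa)
    enzymes = outdir / "enzyme_db.faa"
    write_fasta(
        [(f"{fam.family_id}|{s.protein_id} {fam.name}", s.sequence)
         for fam in bundle.enzyme_db for s in fam.seeds],
        enzymes,
    )
    paths["enzyme_db"] = enzymes
    npdb = outdir / "np_db.faa"
    write_fasta(
        [(f"{r.bgc_id}|{r.protein_id} {r.compound}", r.sequence)
         for r in bundle.np_db],
        npdb,
    )
    paths["np_db"] = npdb
    cl = outdir / "clusters.tsv"
    write_cluster_annotations(bundle.clusters, cl)
    paths["clusters"] = cl
    truth = outdir / "truth.csv"
    with open(truth, "w") as fh:
        fh.write("protein_id,label\n")
        for pid in sorted(bundle.truth):
            fh.write(f"{pid},{bundle.truth[pid]}\n")
    paths["truth"] = truth
    return paths
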