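"""Readers and writers for every external format the pipeline touches.

Formats: protein FASTA, GenBank flat files, GFF3 + protein FASTA genome
pairs, Newick trees, a neutral TSV for externally predicted biosynthetic
gene clusters, and Microreact-compatible tree + metadata exports.

Header dialects
---------------
* NP DB FASTA: the first ``|``-separated token of the header is the BGC
  accession, the second the protein id (``>BGC0000001|ctg1_12 compound``).
* Enzyme DB FASTA: first token is the family id, second the protein id
  (``>fam_gdh|P00001 glutamate dehydrogenase``).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from skbio import TreeNode

from .records import ClusterAnnotation, Genome, NPRecord, ProteinRecord

logger = logging.getLogger(__name__)

LABEL_COLOURS = {
    "seed": "orange",
    "conserved": "red",
    "recruitment": "blue",
    "antismash": "cyan",
    "transition": "purple",
    "prediction": "green",
    "unknown": "grey",
}

COLOUR_HEX = {
    "orange": "#FFA500",
    "red": "#FF0000",
    "blue": "#0000FF",
    "cyan": "#00FFFF",
    "purple": "#800080",
    "green": "#008000",
    "grey": "#808080",
}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


# ---------------------------------------------------------------------------
# genomes


def read_genome(
    path: str | Path,
    format: str = "genbank",
    protein_fasta: str | Path | None = None,
    genome_id: str | None = None,
    lineage: str = "",
) -> Genome:
    """Read one annotated genome.

    ``format`` is ``"genbank"`` (CDS translations taken from the flat file)
    or ``"gff3"`` (CDS coordinates from the GFF3, sequences from the
    ``protein_fasta`` companion keyed by the CDS ``ID``/``protein_id``
    attribute).  CDS features without a resolvable protein sequence are
    skipped with a warning and counted on ``Genome.skipped_records``.
    """
    path = Path(path)
    gid = genome_id or path.stem
    if format == "genbank":
        return _read_genbank(path, gid, lineage)
    if format in ("gff3", "gff3+fasta"):
        if protein_fasta is None:
            fasta = path.with_suffix(".faa")
            if not fasta.exists():
                raise FormatError(
                    f"{path}: gff3 format needs a protein FASTA companion"
                )
            protein_fasta = fasta
        return _read_gff3(path, Path(protein_fasta), gid, lineage)
    raise FormatError(f"unknown genome format {format!r}")


def _read_genbank(path: Path, genome_id: str, lineage: str) -> Genome:
    contigs: dict[str, list[ProteinRecord]] = {}
    skipped = 0
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises bare ValueError subclasses
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not seqrecords:
        raise FormatError(f"{path}: no GenBank records found")
    for rec in seqrecords:
        contig = contigs.setdefault(rec.id, [])
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            pid = (
                quals.get("protein_id", [None])[0]
                or quals.get("locus_tag", [None])[0]
            )
            if not translation or not pid:
                skipped += 1
                logger.warning(
                    "%s: CDS at %s skipped (missing translation or id)",
                    path, feat.location,
                )
                continue
            product = quals.get("product", [""])[0]
            contig.append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=genome_id,
                    contig_id=rec.id,
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    sequence=translation,
                    annotation=product,
                )
            )
    return Genome(genome_id=genome_id, contigs=contigs, lineage=lineage,
                  skipped_records=skipped)


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(gff: Path, fasta: Path, genome_id: str, lineage: str) -> Genome:
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
    contigs: dict[str, list[ProteinRecord]] = {}
    skipped = 0
    with open(gff) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{gff}:{lineno}: expected 9 GFF3 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
            if ftype != "CDS":
                continue
            attr = _gff3_attributes(attrs)
            pid = attr.get("protein_id") or attr.get("ID")
            if not pid or pid not in proteins:
                skipped += 1
                logger.warning("%s:%d: CDS without protein sequence skipped",
                               gff, lineno)
                continue
            contigs.setdefault(seqid, []).append(
                ProteinRecord(
                    protein_id=pid,
                    genome_id=genome_id,
                    contig_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    sequence=proteins[pid],
                    annotation=attr.get("product", ""),
                )
            )
    return Genome(genome_id=genome_id, contigs=contigs, lineage=lineage,
                  skipped_records=skipped)


def read_genome_dir(
    directory: str | Path, lineage: str = ""
) -> list[Genome]:
    """Read every genome in a directory (``*.gbk``/``*.gb`` as GenBank,
    ``*.gff``/``*.gff3`` with a sibling ``.faa`` as GFF3+FASTA)."""
    directory = Path(directory)
    genomes = []
    for path in sorted(directory.iterdir()):
        if path.suffix in (".gbk", ".gb", ".gbff"):
            genomes.append(read_genome(path, "genbank", lineage=lineage))
        elif path.suffix in (".gff", ".gff3"):
            genomes.append(read_genome(path, "gff3", lineage=lineage))
    if not genomes:
        raise FormatError(f"{directory}: no genome files found")
    return genomes


def qc_filter_genomes(
    genomes: Sequence[Genome], min_mean_genes_per_contig: float = 5
) -> list[Genome]:
    """Keep genomes whose mean genes-per-contig meets the draft-quality
    threshold; order preserved. With the default of 5 this reproduces the
    inclusion rule for draft genomes."""
    return [
        g for g in genomes
        if g.mean_genes_per_contig() >= min_mean_genes_per_contig
    ]


def extract_vicinity(genome: Genome, protein_id: str, k: int) -> list[ProteinRecord]:
    """Up to ``k`` genes upstream and downstream of the query on its contig,
    in contig order, truncated at contig edges. ``k=30`` mirrors the
    vicinity window used to study BGC neighbourhoods."""
    if k < 0:
        raise ValueError("k must be >= 0")
    for contig in genome.contigs.values():
        for i, p in enumerate(contig):
            if p.protein_id == protein_id:
                return contig[max(0, i - k): i + k + 1]
    raise KeyError(f"{protein_id!r} not found in genome {genome.genome_id}")


# ---------------------------------------------------------------------------
# enzyme / NP / cluster databases


def read_np_db(path: str | Path) -> list[NPRecord]:
    """Parse an NP-DB FASTA (``>bgc_id|protein_id compound``)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2 or not parts[0]:
            raise FormatError(
                f"{path}: record {rec.id!r} lacks the 'bgc_id|protein_id' "
                "header dialect"
            )
        compound = rec.description.partition(" ")[2]
        out.append(NPRecord(protein_id=parts[1], bgc_id=parts[0],
                            sequence=str(rec.seq), compound=compound))
    return out


def read_enzyme_db(path: str | Path):
    """Parse a seed-enzyme FASTA (``>family_id|protein_id name``) into
    EnzymeFamily objects, grouped and ordered by first appearance."""
    from .families import EnzymeFamily

    seeds_by_family: dict[str, list[ProteinRecord]] = {}
    names: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2 or not parts[0]:
            raise FormatError(
                f"{path}: record {rec.id!r} lacks the 'family_id|protein_id' "
                "header dialect"
            )
        fam, pid = parts[0], parts[1]
        lineage = parts[2] if len(parts) > 2 else ""
        seeds_by_family.setdefault(fam, []).append(
            ProteinRecord(
                protein_id=pid, genome_id=f"seed:{lineage or fam}",
                contig_id="seed", start=1, end=3 * len(rec.seq),
                strand="+", sequence=str(rec.seq),
                annotation=rec.description.partition(" ")[2],
            )
        )
        names.setdefault(fam, rec.description.partition(" ")[2])
    return [
        EnzymeFamily(family_id=fam, name=names[fam], seeds=seeds)
        for fam, seeds in seeds_by_family.items()
    ]


def read_cluster_annotations(path: str | Path) -> list[ClusterAnnotation]:
    """Read the neutral cluster TSV (columns: genome_id, contig_id, start,
    end, cluster_type)."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"genome_id", "contig_id", "start", "end", "cluster_type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: cluster TSV must have columns {sorted(required)}"
            )
        for row_num, row in enumerate(reader, 2):
            try:
                out.append(
                    ClusterAnnotation(
                        genome_id=row["genome_id"],
                        contig_id=row["contig_id"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        cluster_type=row["cluster_type"],
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {row_num}: {exc}") from exc
    return out


def write_cluster_annotations(
    clusters: Iterable[ClusterAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "contig_id", "start", "end", "cluster_type"])
        for c in clusters:
            w.writerow([c.genome_id, c.contig_id, c.start, c.end,
                        c.cluster_type])


# ---------------------------------------------------------------------------
# FASTA / Newick


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write ProteinRecords/NPRecords (or (id, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, tuple):
                rid, seq = rec
            else:
                rid, seq = rec.protein_id, rec.sequence
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def read_newick(path: str | Path) -> TreeNode:
    # convert_underscores off: leaf names are opaque ids, not taxon labels
    return TreeNode.read(str(path), format="newick",
                         convert_underscores=False)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Microreact export


def write_microreact(
    tree: TreeNode,
    metadata_rows: Sequence[dict],
    tree_path: str | Path,
    csv_path: str | Path,
) -> None:
    """Write a Newick file plus a metadata CSV whose ``id`` column matches
    the leaf names, ready for upload to Microreact.

    Each metadata row needs ``id``, ``genome_id``, ``label``; ``colour``
    (hex) is derived from the label when absent; ``copy_number`` and
    ``annotation`` default to empty.
    """
    leaf_names = {t.name for t in tree.tips()}
    ids = {row["id"] for row in metadata_rows}
    if not leaf_names <= ids:
        missing = sorted(leaf_names - ids)
        raise ValueError(f"metadata missing tree leaves: {missing[:5]}")
    write_newick(tree, tree_path)
    with open(csv_path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["id", "genome_id", "label", "label__colour",
                        "copy_number", "annotation"],
            lineterminator="\n",
        )
        w.writeheader()
        for row in metadata_rows:
            colour = row.get("colour") or LABEL_COLOURS.get(row["label"], "grey")
            w.writerow({
                "id": row["id"],
                "genome_id": row.get("genome_id", ""),
                "label": row["label"],
                "label__colour": COLOUR_HEX.get(colour, colour),
                "copy_number": row.get("copy_number", ""),
                "annotation": row.get("annotation", ""),
            })
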