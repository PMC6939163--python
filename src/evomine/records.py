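"""Core domain records shared by every pipeline stage.

Coordinates are 1-based inclusive throughout (GenBank convention); GFF3
input already matches, and no half-open intervals are used internally.
Protein sequences are restricted to the 20 standard amino acids plus ``X``;
anything else is rejected at construction so that downstream substitution
scoring is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains residues outside the 20 AAs + X."""


def validate_protein_sequence(sequence: str, *, who: str = "sequence") -> str:
    seq = sequence.upper().rstrip("*")
    if not seq:
        raise ValueError(f"{who}: empty protein sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"{who}: non-standard residues {sorted(bad)}; "
            "only the 20 standard amino acids plus X are accepted"
        )
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein anchored to its genome, contig, coordinates and strand."""

    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence",
            validate_protein_sequence(self.sequence, who=self.protein_id),
        )
        if self.start > self.end:
            raise ValueError(
                f"{self.protein_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.protein_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """One annotated genome: contigs holding start-sorted ProteinRecords."""

    genome_id: str
    contigs: dict[str, list[ProteinRecord]] = field(default_factory=dict)
    lineage: str = ""
    skipped_records: int = 0

    def __post_init__(self) -> None:
        for contig in self.contigs.values():
            contig.sort(key=lambda p: (p.start, p.end, p.protein_id))

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    @property
    def proteins(self) -> list[ProteinRecord]:
        return [p for contig in self.contigs.values() for p in contig]

    def get(self, protein_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(f"{protein_id!r} not found in genome {self.genome_id}")

    def mean_genes_per_contig(self) -> float:
        return self.n_genes / self.n_contigs if self.n_contigs else 0.0


@dataclass(frozen=True)
class NPRecord:
    """A natural-product biosynthetic protein tied to its BGC accession."""

    protein_id: str
    bgc_id: str
    sequence: str
    compound: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence",
            validate_protein_sequence(self.sequence, who=self.protein_id),
        )
        if not self.bgc_id:
            raise ValueError(f"{self.protein_id}: empty bgc_id")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClusterAnnotation:
    """A predicted biosynthetic gene cluster interval on a contig."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    cluster_type: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"cluster on {self.genome_id}/{self.contig_id}: "
                f"start {self.start} > end {self.end}"
            )

    def overlaps(self, record: ProteinRecord) -> bool:
        """Inclusive >=1 bp overlap on the same genome and contig."""
        return (
            record.genome_id == self.genome_id
            and record.contig_id == self.contig_id
            and record.start <= self.end
            and record.end >= self.start
        )
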