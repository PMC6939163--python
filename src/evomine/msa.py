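"""Multiple sequence alignment and block-based curation.

The internal aligner is a deterministic progressive aligner: a UPGMA guide
tree on 3-mer composition distances, then profile-profile Needleman-Wunsch
with affine gaps, columns scored as BLOSUM62 expected score between the
residue frequency vectors of the two profiles (gaps contribute zero, which
down-weights gappy columns). An adapter around an external ``mafft``
binary is available for parity with heavier aligners.

Curation follows the classic block-filtering recipe:

1. columns with a gap in more than half the rows are removed;
2. a remaining column is *conserved* when its modal residue (gaps
   excluded) occurs in more than half of all rows;
3. runs of more than ``max_contig_noncons`` consecutive non-conserved
   columns are removed, splitting the alignment;
4. each resulting block is trimmed to start and end on conserved columns
   and kept only if at least ``min_block`` columns long.

The defaults (min block 5, max 10 contiguous non-conserved, gap fraction
50 %) are the standard curation parameters for family trees here.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHA)}


def _blosum_array() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    arr = np.zeros((len(_ALPHA), len(_ALPHA)))
    for i, a in enumerate(_ALPHA):
        for j, b in enumerate(_ALPHA):
            arr[i, j] = 0.0 if "X" in (a, b) else m[a, b]
    return arr


_SUB = _blosum_array()
_GAP_OPEN = -10.0
_GAP_EXTEND = -0.5


class EmptyAlignmentError(ValueError):
    """Curation removed every column; caller should fall back to the
    uncurated alignment."""


@dataclass
class Alignment:
    """Ordered rows of equal-length gapped sequences."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> list[tuple[str, str]]:
        return [(i, r.replace("-", "")) for i, r in zip(self.ids, self.rows)]

    def select_columns(self, columns: Sequence[int]) -> "Alignment":
        cols = list(columns)
        return Alignment(
            ids=list(self.ids),
            rows=["".join(r[c] for c in cols) for r in self.rows],
        )


# ---------------------------------------------------------------------------
# progressive alignment


def _kmer_counts(seq: str, k: int = 3) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        out[kmer] = out.get(kmer, 0) + 1
    return out


def _kmer_distance_matrix(seqs: Sequence[str]) -> np.ndarray:
    kmers = [_kmer_counts(s) for s in seqs]
    vocab = sorted(set().union(*kmers)) if kmers else []
    idx = {k: i for i, k in enumerate(vocab)}
    mat = np.zeros((len(seqs), len(vocab)))
    for r, counts in enumerate(kmers):
        for k, c in counts.items():
            mat[r, idx[k]] = c
    with np.errstate(invalid="ignore"):
        d = pdist(mat, metric="cosine")
    return np.nan_to_num(d, nan=1.0)


def _profile(rows: list[str]) -> np.ndarray:
    n = len(rows)
    L = len(rows[0])
    prof = np.zeros((L, len(_ALPHA)))
    for row in rows:
        for c, aa in enumerate(row):
            if aa != "-":
                prof[c, _AA_INDEX[aa]] += 1.0
    return prof / n


def _align_profiles(
    a: list[tuple[str, str]], b: list[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Needleman-Wunsch between two profiles; ties prefer diagonal, then a
    gap in profile b, for determinism."""
    rows_a = [r for _i, r in a]
    rows_b = [r for _i, r in b]
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = (pa @ _SUB @ pb.T).tolist()
    la, lb = len(pa), len(pb)
    NEG = float("-inf")
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap columns in b
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap columns in a
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = _GAP_OPEN + _GAP_EXTEND * (i - 1)
    for j in range(1, lb + 1):
        Y[0][j] = _GAP_OPEN + _GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            best = Mp[j - 1]
            if Xp[j - 1] > best:
                best = Xp[j - 1]
            if Yp[j - 1] > best:
                best = Yp[j - 1]
            Mi[j] = best + Si[j - 1]
            Xi[j] = max(Mp[j] + _GAP_OPEN, Xp[j] + _GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + _GAP_OPEN, Yi[j - 1] + _GAP_EXTEND)
    # traceback; ties resolved in the fixed order M > X > Y
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    finals = [("M", M[i][j]), ("X", X[i][j]), ("Y", Y[i][j])]
    best_final = max(v for _s, v in finals)
    state = next(s for s, v in finals if v == best_final)
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            out_a.append("B"); out_b.append("B")
            target = M[i][j] - S[i - 1][j - 1]
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            i, j = i - 1, j - 1
            state = next(
                s for s, v in zip(("M", "X", "Y"), prev)
                if abs(v - target) < 1e-9
            )
        elif state == "X" or (j == 0 and i > 0):
            out_a.append("B"); out_b.append("-")
            if i > 1 and abs(X[i][j] - (X[i - 1][j] + _GAP_EXTEND)) < 1e-9 \
                    and X[i - 1][j] > float("-inf"):
                state = "X"
            else:
                state = "M"
            i -= 1
        else:
            out_a.append("-"); out_b.append("B")
            if j > 1 and abs(Y[i][j] - (Y[i][j - 1] + _GAP_EXTEND)) < 1e-9 \
                    and Y[i][j - 1] > float("-inf"):
                state = "Y"
            else:
                state = "M"
            j -= 1
    path_a = out_a[::-1]
    path_b = out_b[::-1]

    def _expand(rows: list[tuple[str, str]], path: list[str]):
        result = []
        for rid, row in rows:
            chars = []
            pos = 0
            for step in path:
                if step == "-":
                    chars.append("-")
                else:
                    chars.append(row[pos])
                    pos += 1
            result.append((rid, "".join(chars)))
        return result

    return _expand(a, path_a) + _expand(b, path_b)


def align_family(sequences: Sequence[tuple[str, str]]) -> Alignment:
    """Progressively align (id, sequence) pairs.

    Deterministic for a fixed input order. Raises on fewer than two
    sequences.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    ids = [i for i, _s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = [s for _i, s in sequences]
    if len(sequences) == 2:
        merged = _align_profiles([sequences[0]], [sequences[1]])
    else:
        d = _kmer_distance_matrix(seqs)
        Z = linkage(d, method="average")
        clusters: dict[int, list[tuple[str, str]]] = {
            i: [sequences[i]] for i in range(len(sequences))
        }
        nxt = len(sequences)
        for left, right, _h, _n in Z:
            clusters[nxt] = _align_profiles(
                clusters.pop(int(left)), clusters.pop(int(right))
            )
            nxt += 1
        merged = clusters[nxt - 1]
    by_id = dict(merged)
    return Alignment(ids=ids, rows=[by_id[i] for i in ids])


def align_family_mafft(
    sequences: Sequence[tuple[str, str]], binary: str = "mafft"
) -> Alignment:
    """External-aligner adapter (mafft); row order restored to input order."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences to align")
    if shutil.which(binary) is None:
        raise RuntimeError(f"{binary} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.faa"
        with open(fasta, "w") as fh:
            for rid, seq in sequences:
                fh.write(f">{rid}\n{seq}\n")
        proc = subprocess.run(
            [binary, "--auto", "--anysymbol", str(fasta)],
            capture_output=True, text=True, check=True,
        )
    rows: dict[str, str] = {}
    rid = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            rid = line[1:].split()[0]
            rows[rid] = ""
        elif rid is not None:
            rows[rid] += line.strip().upper()
    ids = [i for i, _s in sequences]
    return Alignment(ids=ids, rows=[rows[i] for i in ids])


# ---------------------------------------------------------------------------
# curation


def conserved_columns(aln: Alignment, max_gap_frac: float = 0.5) -> list[bool]:
    """Per-column conservation flags after notional gap filtering: a column
    is conserved when its modal residue occurs in more than half of ALL
    rows (gaps excluded from the modal count)."""
    n = aln.n_rows
    flags = []
    for c in range(aln.n_cols):
        col = [r[c] for r in aln.rows]
        residues = [x for x in col if x != "-"]
        if not residues:
            flags.append(False)
            continue
        top = max(residues.count(x) for x in set(residues))
        flags.append(top > n / 2)
    return flags


def curate_alignment(
    aln: Alignment,
    min_block: int = 5,
    max_contig_noncons: int = 10,
    max_gap_frac: float = 0.5,
) -> Alignment:
    """Filter an alignment down to its conserved blocks (see module
    docstring for the four steps). Raises :class:`EmptyAlignmentError`
    when nothing survives.
    """
    n = aln.n_rows
    kept = [
        c for c in range(aln.n_cols)
        if sum(1 for r in aln.rows if r[c] == "-") / n <= max_gap_frac
    ]
    if not kept:
        raise EmptyAlignmentError("all columns exceed the gap fraction")
    sub = aln.select_columns(kept)
    cons = conserved_columns(sub)
    # split on runs of > max_contig_noncons consecutive non-conserved columns
    segments: list[list[int]] = [[]]
    run = 0
    for idx, flag in enumerate(cons):
        if flag:
            run = 0
            segments[-1].append(idx)
        else:
            run += 1
            if run == max_contig_noncons + 1:
                # the current run is too long: retroactively remove it
                seg = segments[-1]
                while seg and not cons[seg[-1]]:
                    seg.pop()
                segments.append([])
            elif run <= max_contig_noncons:
                segments[-1].append(idx)
    surviving: list[int] = []
    for seg in segments:
        # trim to conserved ends
        while seg and not cons[seg[0]]:
            seg.pop(0)
        while seg and not cons[seg[-1]]:
            seg.pop()
        if len(seg) >= min_block:
            surviving.extend(seg)
    if not surviving:
        raise EmptyAlignmentError("no block survived curation")
    return sub.select_columns(surviving)
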