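"""Pairwise protein similarity search: exact local alignment with
BLAST-style statistics, database search, best hits and bidirectional
best hits (BBH).

The internal engine is an exact Smith-Waterman under BLOSUM62 with affine
gaps (existence 11, extension 1 — the blastp defaults), run through
Bio.Align.PairwiseAligner. Raw scores are converted to bit scores with the
gapped Karlin-Altschul parameters published for that scheme
(lambda = 0.267, K = 0.041):

    bitscore = (lambda * S - ln K) / ln 2
    E        = m * n * 2^(-bitscore)

where ``m`` is the query length and ``n`` the subject length for a single
pair, or the total residue count of the database in ``search_db``. ``X`` is
scored 0 against every residue. An adapter around an external ``blastp``
binary (tabular outfmt 6) is provided for larger runs; the internal engine
is the default and the reference.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

LN2 = math.log(2.0)

#: Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@dataclass(frozen=True)
class Thresholds:
    """Hit-acceptance thresholds. All comparisons are inclusive."""

    max_evalue: float = 0.001
    min_bitscore: float = 100.0
    min_identity: float = 0.0      # percent, over aligned columns
    min_len_frac: float = 0.0      # alignment length vs each sequence length


#: Profile used when building/querying the Enzyme DB by BBH: at least 30 %
#: identity across an alignment spanning at least 80 % of both proteins.
ENZYME_DB_BBH = Thresholds(max_evalue=0.001, min_bitscore=0.0,
                           min_identity=30.0, min_len_frac=0.8)


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    pct_identity: float
    aln_length: int
    q_cov: float
    s_cov: float

    def passes(self, t: Thresholds, qlen: int, slen: int) -> bool:
        return (
            self.evalue <= t.max_evalue
            and self.bitscore >= t.min_bitscore
            and self.pct_identity >= t.min_identity
            and self.aln_length >= t.min_len_frac * qlen
            and self.aln_length >= t.min_len_frac * slen
        )


def _make_aligner() -> Align.PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62").copy()
    for aa in matrix.alphabet:
        matrix["X", aa] = 0.0
        matrix[aa, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = "local"
    # BLAST cost for a gap of length L is 11 + L; Biopython charges
    # open_gap_score once plus extend_gap_score per further residue.
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def bitscore_from_raw(raw: float) -> float:
    return (BLOSUM62_GAPPED_LAMBDA * raw - math.log(BLOSUM62_GAPPED_K)) / LN2


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    return m * n * math.pow(2.0, -bitscore)


def raw_score(a: str, b: str) -> float:
    """Optimal Smith-Waterman score only (no traceback); 0 if no
    positive-scoring local alignment exists."""
    if not a or not b:
        raise ValueError("empty sequence")
    return max(_ALIGNER.score(a, b), 0.0)


def _seq_of(obj) -> str:
    return obj if isinstance(obj, str) else obj.sequence


def _id_of(obj, default: str = "query") -> str:
    return getattr(obj, "protein_id", default)


def align_pair(a, b, query_id: str = "query", subject_id: str = "subject") -> Hit:
    """Optimal local alignment of two sequences as a fully populated Hit.

    The E-value here uses the pair's own lengths (m*n); ``search_db``
    substitutes the database residue count.
    """
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise ValueError("empty sequence")
    qid = _id_of(a, query_id)
    sid = _id_of(b, subject_id)
    score = _ALIGNER.score(sa, sb)
    if score <= 0:
        return Hit(qid, sid, 0.0, float(len(sa) * len(sb)), 0.0, 0, 0.0, 0.0)
    aln = _ALIGNER.align(sa, sb)[0]
    counts = aln.counts()
    length = aln.length
    coords = aln.coordinates
    q_span = int(coords[0, -1] - coords[0, 0])
    s_span = int(coords[1, -1] - coords[1, 0])
    bits = bitscore_from_raw(score)
    return Hit(
        query_id=qid,
        subject_id=sid,
        bitscore=bits,
        evalue=evalue_from_bitscore(bits, len(sa), len(sb)),
        pct_identity=100.0 * counts.identities / length if length else 0.0,
        aln_length=length,
        q_cov=q_span / len(sa),
        s_cov=s_span / len(sb),
    )


def search_db(
    query,
    db: Sequence,
    thresholds: Thresholds = Thresholds(),
) -> list[Hit]:
    """Search one query against a sequence collection.

    E-values are corrected for the total residue count of the database.
    Hits failing any inclusive threshold are dropped; survivors are sorted
    by descending bitscore, then ascending E-value, then subject id.
    """
    if not db:
        raise ValueError("empty database")
    qseq = _seq_of(query)
    qid = _id_of(query)
    n_db = sum(len(_seq_of(s)) for s in db)
    hits = []
    for subject in db:
        sseq = _seq_of(subject)
        sid = _id_of(subject, "subject")
        score = _ALIGNER.score(qseq, sseq) if qseq and sseq else 0.0
        if score <= 0:
            continue
        bits = bitscore_from_raw(score)
        evalue = evalue_from_bitscore(bits, len(qseq), n_db)
        if bits < thresholds.min_bitscore or evalue > thresholds.max_evalue:
            continue
        hit = align_pair(qseq, sseq, query_id=qid, subject_id=sid)
        hit = replace(hit, evalue=evalue)
        if not hit.passes(thresholds, len(qseq), len(sseq)):
            continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return hits


def best_hit(query, db: Sequence, thresholds: Thresholds = Thresholds()) -> Hit | None:
    hits = search_db(query, db, thresholds)
    return hits[0] if hits else None


def bbh(
    set_a: Sequence,
    set_b: Sequence,
    thresholds: Thresholds = ENZYME_DB_BBH,
) -> list[tuple[str, str]]:
    """Bidirectional best hits between two sequence sets.

    A pair (a, b) is reported when b is a's best hit in ``set_b`` and a is
    b's best hit in ``set_a``, and the pairwise alignment passes the
    identity/length fractions of ``thresholds`` (the Enzyme-DB profile by
    default: >=30 % identity across >=80 % of both sequence lengths).
    Result is a partial matching sorted by a-side id.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    ids_a = [_id_of(x, f"a{i}") for i, x in enumerate(set_a)]
    ids_b = [_id_of(x, f"b{i}") for i, x in enumerate(set_b)]
    # score-only matrix; tie-break on the partner's id keeps it deterministic
    scores = [[_ALIGNER.score(_seq_of(x), _seq_of(y)) for y in set_b]
              for x in set_a]
    gate = Thresholds(max_evalue=thresholds.max_evalue,
                      min_bitscore=thresholds.min_bitscore)

    def _best(row_scores, ids, lens_other, qlen):
        best_j = None
        for j, s in enumerate(row_scores):
            if s <= 0:
                continue
            bits = bitscore_from_raw(s)
            ev = evalue_from_bitscore(bits, qlen, lens_other)
            if bits < gate.min_bitscore or ev > gate.max_evalue:
                continue
            if best_j is None or (
                (-s, ids[j]) < (-row_scores[best_j], ids[best_j])
            ):
                best_j = j
        return best_j

    n_b = sum(len(_seq_of(y)) for y in set_b)
    n_a = sum(len(_seq_of(x)) for x in set_a)
    best_in_b = [
        _best(scores[i], ids_b, n_b, len(_seq_of(set_a[i])))
        for i in range(len(set_a))
    ]
    best_in_a = [
        _best([scores[i][j] for i in range(len(set_a))], ids_a, n_a,
              len(_seq_of(set_b[j])))
        for j in range(len(set_b))
    ]
    pairs = []
    for i, j in enumerate(best_in_b):
        if j is None or best_in_a[j] != i:
            continue
        sa, sb = _seq_of(set_a[i]), _seq_of(set_b[j])
        hit = align_pair(sa, sb, query_id=ids_a[i], subject_id=ids_b[j])
        if (
            hit.pct_identity >= thresholds.min_identity
            and hit.aln_length >= thresholds.min_len_frac * len(sa)
            and hit.aln_length >= thresholds.min_len_frac * len(sb)
        ):
            pairs.append((ids_a[i], ids_b[j]))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# external engine adapter


def external_blastp(
    queries: Iterable,
    subjects: Iterable,
    thresholds: Thresholds = Thresholds(),
    binary: str = "blastp",
) -> list[Hit]:
    """Run an external blastp over the two collections and return Hits.

    Uses tabular output (qseqid sseqid pident length evalue bitscore qlen
    slen). Intended for large genome databases; results follow the external
    engine's own statistics, so scores differ slightly from the internal
    engine's.
    """
    from .io import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "q.faa"
        spath = Path(tmp) / "s.faa"
        write_fasta(
            [(_id_of(q, f"q{i}"), _seq_of(q)) for i, q in enumerate(queries)],
            qpath,
        )
        write_fasta(
            [(_id_of(s, f"s{i}"), _seq_of(s)) for i, s in enumerate(subjects)],
            spath,
        )
        fmt = "6 qseqid sseqid pident length evalue bitscore qlen slen"
        proc = subprocess.run(
            [binary, "-query", str(qpath), "-subject", str(spath),
             "-outfmt", fmt, "-evalue", str(max(thresholds.max_evalue, 10))],
            capture_output=True, text=True, check=True,
        )
    hits = []
    for line in proc.stdout.splitlines():
        qid, sid, pident, length, evalue, bits, qlen, slen = line.split("\t")
        hit = Hit(
            query_id=qid, subject_id=sid, bitscore=float(bits),
            evalue=float(evalue), pct_identity=float(pident),
            aln_length=int(length),
            q_cov=min(1.0, int(length) / int(qlen)),
            s_cov=min(1.0, int(length) / int(slen)),
        )
        if hit.passes(thresholds, int(qlen), int(slen)):
            hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id))
    return hits
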