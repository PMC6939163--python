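import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evomine import search
from evomine.search import (
    ENZYME_DB_BBH,
    Thresholds,
    align_pair,
    bbh,
    best_hit,
    bitscore_from_raw,
    raw_score,
    search_db,
)

from .oracles import sw_score

AA20 = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA20, min_size=10, max_size=60)


def _random_seq(rng, n):
    return "".join(rng.choice(list(AA20), size=n))


class TestAlignPair:
    def test_self_alignment(self):
        rng = np.random.default_rng(7)
        s = _random_seq(rng, 80)
        hit = align_pair(s, s)
        assert hit.pct_identity == 100.0
        assert hit.q_cov == 1.0 and hit.s_cov == 1.0
        assert hit.aln_length == 80

    def test_all_mismatch_has_zero_bitscore(self):
        hit = align_pair("AAAA", "WWWW")
        assert hit.bitscore == 0.0
        assert hit.aln_length == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKV")

    def test_scores_match_reference_dp(self):
        rng = np.random.default_rng(11)
        for k in range(12):
            a = _random_seq(rng, int(rng.integers(30, 120)))
            b = _random_seq(rng, int(rng.integers(30, 120)))
            if k % 2:  # half the pairs share a block, so positives occur
                b = a[: len(a) // 2] + b[: len(b) // 2]
            assert raw_score(a, b) == pytest.approx(sw_score(a, b))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seqs, seqs)
    def test_score_symmetry(self, a, b):
        assert raw_score(a, b) == pytest.approx(raw_score(b, a))


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(3)
    query = _random_seq(rng, 200)
    related = [
        ("near", "".join(
            c if rng.random() > 0.1 else _random_seq(rng, 1)
            for c in query)),
        ("far", "".join(
            c if rng.random() > 0.4 else _random_seq(rng, 1)
            for c in query)),
    ]
    noise = [(f"n{i}", _random_seq(rng, 200)) for i in range(5)]
    return query, related + noise


@pytest.fixture(scope="module")
def sets():
    rng = np.random.default_rng(9)
    base = [_random_seq(rng, 150) for _ in range(4)]

    def _mut(s, frac):
        return "".join(
            c if rng.random() > frac else _random_seq(rng, 1) for c in s
        )

    set_a = [(f"a{i}", s) for i, s in enumerate(base)]
    set_b = [(f"b{i}", _mut(s, 0.1)) for i, s in enumerate(base)]
    return set_a, set_b


class TestSearchDb:
    def test_identical_member_ranks_first(self, db):
        query, entries = db
        hits = search_db(query, [s for _i, s in entries] + [query])
        assert hits[0].pct_identity == 100.0

    def test_results_equal_brute_force_filter(self, db):
        query, entries = db
        t = Thresholds(max_evalue=0.001, min_bitscore=100.0)
        n_db = sum(len(s) for _i, s in entries)
        expected = set()
        for sid, s in entries:
            bits = bitscore_from_raw(sw_score(query, s))
            ev = len(query) * n_db * 2.0 ** (-bits)
            if bits >= 100.0 and ev <= 0.001:
                expected.add(s)
        got = {h for h in search_db(query, [s for _i, s in entries], t)}
        assert len(got) == len(expected)

    def test_evalue_gate_excludes_marginal_hit(self):
        # a short perfect match: positive bitscore but E-value above 0.001
        rng = np.random.default_rng(5)
        query = _random_seq(rng, 15)
        db = [query + _random_seq(rng, 200)]
        hits = search_db(query, db, Thresholds(max_evalue=1e-30,
                                               min_bitscore=0))
        assert hits == []

    def test_order_invariant_under_db_permutation(self, db):
        query, entries = db
        t = Thresholds(max_evalue=10, min_bitscore=0)
        fwd = search_db(query, [s for _i, s in entries], t)
        rev = search_db(query, [s for _i, s in entries][::-1], t)
        assert [(h.bitscore, h.pct_identity) for h in fwd] == [
            (h.bitscore, h.pct_identity) for h in rev
        ]


class TestBbh:
    def test_mutual_identical_pair_reported(self):
        rng = np.random.default_rng(1)
        s = _random_seq(rng, 120)
        t = _random_seq(rng, 120)

        class Rec:
            def __init__(self, pid, seq):
                self.protein_id = pid
                self.sequence = seq

        pairs = bbh([Rec("a", s)], [Rec("b", s), Rec("c", t)])
        assert pairs == [("a", "b")]

    def test_partial_matching_and_transpose(self, sets):
        set_a, set_b = sets
        a_seqs = [s for _i, s in set_a]
        b_seqs = [s for _i, s in set_b]

        class Rec:
            def __init__(self, pid, seq):
                self.protein_id = pid
                self.sequence = seq

        ra = [Rec(i, s) for i, s in set_a]
        rb = [Rec(i, s) for i, s in set_b]
        fwd = bbh(ra, rb)
        rev = bbh(rb, ra)
        assert sorted(fwd) == sorted((b, a) for a, b in rev)
        assert len({a for a, _b in fwd}) == len(fwd)
        assert len({b for _a, b in fwd}) == len(fwd)

    def test_low_identity_rejected_under_enzyme_profile(self):
        rng = np.random.default_rng(13)
        s = _random_seq(rng, 200)
        # ~85 % of positions substituted: well below the 30 % identity floor
        other = "".join(
            c if rng.random() > 0.85 else _random_seq(rng, 1) for c in s
        )

        class Rec:
            def __init__(self, pid, seq):
                self.protein_id = pid
                self.sequence = seq

        pairs = bbh(
            [Rec("a", s)], [Rec("b", other)],
            Thresholds(max_evalue=10, min_bitscore=0, min_identity=30.0,
                       min_len_frac=0.8),
        )
        assert pairs == []

    def test_short_alignment_span_rejected(self):
        rng = np.random.default_rng(17)
        core = _random_seq(rng, 100)
        a = core
        b = core + _random_seq(rng, 150)  # alignment covers 40 % of b

        class Rec:
            def __init__(self, pid, seq):
                self.protein_id = pid
                self.sequence = seq

        assert bbh([Rec("a", a)], [Rec("b", b)], ENZYME_DB_BBH) == []
        relaxed = Thresholds(max_evalue=10, min_bitscore=0)
        assert bbh([Rec("a", a)], [Rec("b", b)], relaxed) == [("a", "b")]


def test_best_hit_none_when_nothing_passes():
    rng = np.random.default_rng(2)
    q = "".join(rng.choice(list(AA20), size=50))
    db = ["".join(rng.choice(list(AA20), size=50)) for _ in range(3)]
    assert best_hit(q, db, Thresholds(max_evalue=1e-50, min_bitscore=500)) is None
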