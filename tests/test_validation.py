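import numpy as np
import pytest

from adeconcord import validation as val
from adeconcord.errors import CoverageError, DegenerateInputError
from adeconcord.vocab import MeddraMap

from conftest import snap


def make_ref(pos, neg, label="ref"):
    return val.ReferenceStandard(frozenset(pos), frozenset(neg), label)


def brute_force_auroc(scores, ref):
    """Exhaustive pairwise comparison with half-credit ties."""
    total = 0.0
    for p in ref.positives:
        for n in ref.negatives:
            sp, sn = scores[p], scores[n]
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(ref.positives) * len(ref.negatives))


class TestBuildReference:
    def test_enumeration(self):
        training = snap({("d1", "h1")})
        validation = snap({("d1", "h1"), ("d2", "h2")})
        ref = val.build_reference(training, validation, {"d1", "d2"}, {"h1", "h2"})
        assert ref.positives == {("d2", "h2")}
        assert ref.negatives == {("d1", "h2"), ("d2", "h1")}

    def test_no_new_links_degenerate(self):
        s = snap({("d1", "h1")})
        with pytest.raises(DegenerateInputError):
            val.build_reference(s, s, {"d1"}, {"h1"})

    def test_partition_of_common_universe(self):
        rng = np.random.default_rng(0)
        drugs = [f"d{i}" for i in range(8)]
        terms = [f"h{j}" for j in range(6)]
        univ = [(d, t) for d in drugs for t in terms]
        train_pairs = {p for p in univ if rng.random() < 0.3}
        extra = {p for p in univ if rng.random() < 0.2} - train_pairs
        training = snap(train_pairs)
        validation = snap(train_pairs | extra)
        ref = val.build_reference(training, validation, set(drugs), set(terms))
        n_train_in_univ = len(train_pairs)
        assert len(ref.positives) + len(ref.negatives) + n_train_in_univ == \
            len(drugs) * len(terms)


class TestAuroc:
    def test_perfect_separation(self):
        scores = {("p", "1"): 0.9, ("p", "2"): 0.8, ("n", "1"): 0.2}
        ref = make_ref([("p", "1"), ("p", "2")], [("n", "1")])
        assert val.auroc(scores, ref) == 1.0

    def test_all_ties_give_half(self):
        scores = {("x", str(i)): 0.5 for i in range(6)}
        ref = make_ref([("x", "0"), ("x", "1")],
                       [("x", str(i)) for i in range(2, 6)])
        assert val.auroc(scores, ref) == 0.5

    def test_hand_set_scores_match_brute_force(self):
        rng = np.random.default_rng(1)
        pos = [("p", str(i)) for i in range(4)]
        neg = [("n", str(i)) for i in range(6)]
        scores = {p: float(rng.integers(0, 5)) / 4 for p in pos + neg}
        ref = make_ref(pos, neg)
        assert val.auroc(scores, ref) == pytest.approx(
            brute_force_auroc(scores, ref), abs=1e-15)

    def test_rank_formula_equals_brute_force_randomized(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n_pos = int(rng.integers(2, 15))
            n_neg = int(rng.integers(2, 40))
            pos = [("p", str(i)) for i in range(n_pos)]
            neg = [("n", str(i)) for i in range(n_neg)]
            # coarse grid forces plenty of ties
            scores = {p: float(rng.integers(0, 6)) for p in pos + neg}
            ref = make_ref(pos, neg)
            assert val.auroc(scores, ref) == pytest.approx(
                brute_force_auroc(scores, ref), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        pos = [("p", str(i)) for i in range(10)]
        neg = [("n", str(i)) for i in range(20)]
        scores = {p: float(rng.random()) for p in pos + neg}
        ref = make_ref(pos, neg)
        warped = {p: float(np.exp(7 * s)) for p, s in scores.items()}
        assert val.auroc(scores, ref) == pytest.approx(val.auroc(warped, ref))

    def test_label_permutation_null_centers_at_half(self):
        rng = np.random.default_rng(4)
        items = [("x", str(i)) for i in range(60)]
        scores = {p: float(rng.random()) for p in items}
        aucs = []
        for _ in range(200):
            perm = rng.permutation(60)
            pos = [items[i] for i in perm[:20]]
            neg = [items[i] for i in perm[20:]]
            aucs.append(val.auroc(scores, make_ref(pos, neg)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_missing_score_raises(self):
        ref = make_ref([("p", "1")], [("n", "1")])
        with pytest.raises(CoverageError):
            val.auroc({("p", "1"): 0.9}, ref)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        pos = [("p", str(i)) for i in range(30)]
        neg = [("n", str(i)) for i in range(70)]
        scores = {p: float(rng.integers(0, 10)) for p in pos + neg}
        ref = make_ref(pos, neg)
        y = [1] * 30 + [0] * 70
        s = [scores[p] for p in pos + neg]
        assert val.auroc(scores, ref) == pytest.approx(roc_auc_score(y, s))


class TestAurocCI:
    def test_perfect_separation_interval_is_degenerate(self):
        scores = {("p", "1"): 0.9, ("p", "2"): 0.8,
                  ("n", "1"): 0.2, ("n", "2"): 0.1}
        ref = make_ref([("p", "1"), ("p", "2")], [("n", "1"), ("n", "2")])
        assert val.auroc_ci(scores, ref, n_boot=100) == (1.0, 1.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(6)
        pos = [("p", str(i)) for i in range(30)]
        neg = [("n", str(i)) for i in range(60)]
        for seed in range(10):
            scores = {p: float(rng.random()) + (0.3 if p[0] == "p" else 0)
                      for p in pos + neg}
            ref = make_ref(pos, neg)
            a = val.auroc(scores, ref)
            lo, hi = val.auroc_ci(scores, ref, n_boot=300, seed=seed)
            assert lo - 0.05 <= a <= hi + 0.05

    def test_halving_positives_widens_interval(self):
        rng = np.random.default_rng(7)
        neg = [("n", str(i)) for i in range(80)]
        widths = {}
        for n_pos in (40, 10):
            ws = []
            for seed in range(10):
                pos = [("p", str(i)) for i in range(n_pos)]
                scores = {p: float(rng.random()) + (0.2 if p[0] == "p" else 0)
                          for p in pos + neg}
                lo, hi = val.auroc_ci(scores, make_ref(pos, neg),
                                      n_boot=300, seed=seed)
                ws.append(hi - lo)
            widths[n_pos] = np.median(ws)
        assert widths[10] > widths[40]

    def test_too_few_raises(self):
        scores = {("p", "1"): 0.9, ("n", "1"): 0.2, ("n", "2"): 0.3}
        ref = make_ref([("p", "1")], [("n", "1"), ("n", "2")])
        with pytest.raises(DegenerateInputError):
            val.auroc_ci(scores, ref)


class TestRocCurve:
    def test_perfect_separation_passes_through_0_1(self):
        scores = {("p", "1"): 0.9, ("n", "1"): 0.2, ("n", "2"): 0.1}
        roc = val.roc_curve(scores, make_ref([("p", "1")],
                                             [("n", "1"), ("n", "2")]))
        assert (0.0, 1.0) in roc.points
        assert roc.points[0] == (0.0, 0.0) and roc.points[-1] == (1.0, 1.0)

    def test_identical_scores_are_diagonal(self):
        scores = {("x", str(i)): 0.4 for i in range(5)}
        roc = val.roc_curve(scores, make_ref([("x", "0")],
                                             [("x", str(i)) for i in range(1, 5)]))
        assert roc.points == ((0.0, 0.0), (1.0, 1.0))
        assert roc.auroc == 0.5

    def test_trapezoid_area_equals_rank_auroc(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n_pos = int(rng.integers(2, 20))
            n_neg = int(rng.integers(2, 40))
            pos = [("p", str(i)) for i in range(n_pos)]
            neg = [("n", str(i)) for i in range(n_neg)]
            scores = {p: float(rng.integers(0, 8)) for p in pos + neg}
            ref = make_ref(pos, neg)
            roc = val.roc_curve(scores, ref)
            assert roc.auroc == pytest.approx(val.auroc(scores, ref), abs=1e-12)

    def test_monotone_points(self):
        rng = np.random.default_rng(9)
        pos = [("p", str(i)) for i in range(10)]
        neg = [("n", str(i)) for i in range(15)]
        scores = {p: float(rng.random()) for p in pos + neg}
        roc = val.roc_curve(scores, make_ref(pos, neg))
        fprs = [p[0] for p in roc.points]
        tprs = [p[1] for p in roc.points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)


class TestRelativeChange:
    @pytest.mark.parametrize("a, b, decimals, expected", [
        (0.91, 0.60, 0, 34.0),
        (0.82, 0.66, 0, 20.0),
        (0.86, 0.76, 0, 12.0),
        (0.86, 0.80, 0, 7.0),
        (0.78, 0.74, 1, 5.1),
        (0.8, 0.8, 0, 0.0),
    ])
    def test_printed_rounding(self, a, b, decimals, expected):
        assert val.relative_change(a, b, decimals) == expected

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(DegenerateInputError):
            val.relative_change(0.0, 0.5)


@pytest.fixture()
def three_soc_world():
    rng = np.random.default_rng(10)
    socs = {"s1": 6, "s2": 6, "s3": 6}
    terms = []
    hlt_to_soc = {}
    for soc, n in socs.items():
        for k in range(n):
            t = f"{soc}_h{k}"
            terms.append(t)
            hlt_to_soc[t] = (soc,)
    meddra = MeddraMap({"p": frozenset({terms[0]})}, hlt_to_soc)
    pos, neg, scores = [], [], {}
    for t in terms:
        for i in range(6):
            pair = (f"d{i}", t)
            (pos if rng.random() < 0.4 else neg).append(pair)
            scores[pair] = float(rng.random())
    return meddra, make_ref(pos, neg, "a"), scores


class TestStratifiedAuroc:
    def test_matches_brute_force_per_soc(self, three_soc_world):
        meddra, ref, scores = three_soc_world
        rows = val.stratified_auroc(scores, ref, scores, ref, meddra,
                                    n_boot=50, seed=0)
        assert len(rows) == 3
        for row in rows:
            assert not row.flagged
            sub_pos = [p for p in ref.positives if meddra.primary_soc(p[1]) == row.soc]
            sub_neg = [p for p in ref.negatives if meddra.primary_soc(p[1]) == row.soc]
            expected = brute_force_auroc(scores, make_ref(sub_pos, sub_neg))
            assert row.auroc_a == pytest.approx(expected)
            assert row.relative_change_pct == val.relative_change(
                row.auroc_a, row.auroc_b)

    def test_single_soc_equals_overall(self):
        meddra = MeddraMap({"p": frozenset({"h0"})},
                           {f"h{k}": ("only",) for k in range(5)})
        rng = np.random.default_rng(11)
        pos = [(f"d{i}", f"h{i % 5}") for i in range(6)]
        neg = [(f"e{i}", f"h{i % 5}") for i in range(8)]
        scores = {p: float(rng.random()) for p in pos + neg}
        ref = make_ref(pos, neg)
        rows = val.stratified_auroc(scores, ref, scores, ref, meddra,
                                    n_boot=50, seed=0)
        assert len(rows) == 1
        assert rows[0].auroc_a == pytest.approx(val.auroc(scores, ref))

    def test_permuting_scores_within_soc_leaves_other_rows_unchanged(self, three_soc_world):
        meddra, ref, scores = three_soc_world
        before = val.stratified_auroc(scores, ref, scores, ref, meddra,
                                      n_boot=10, seed=0)
        s1_pairs = sorted(p for p in scores if meddra.primary_soc(p[1]) == "s1")
        permuted = dict(scores)
        vals = [scores[p] for p in s1_pairs]
        for p, v in zip(s1_pairs, vals[::-1]):
            permuted[p] = v
        after = val.stratified_auroc(permuted, ref, permuted, ref, meddra,
                                     n_boot=10, seed=0)
        for b, a in zip(before, after):
            if b.soc != "s1":
                assert b.auroc_a == pytest.approx(a.auroc_a)

    def test_sparse_stratum_flagged_not_dropped(self):
        meddra = MeddraMap({"p": frozenset({"h0"})},
                           {"h0": ("big",), "h1": ("tiny",)})
        pos = [(f"d{i}", "h0") for i in range(4)] + [("d0", "h1")]
        neg = [(f"e{i}", "h0") for i in range(4)] + [("e0", "h1")]
        scores = {p: 0.5 + 0.01 * i for i, p in enumerate(pos + neg)}
        ref = make_ref(pos, neg)
        rows = val.stratified_auroc(scores, ref, scores, ref, meddra,
                                    n_boot=10, seed=0)
        flags = {r.soc: r.flagged for r in rows}
        assert flags == {"big": False, "tiny": True}


class TestCaseStudyMetrics:
    def test_pair_above_all_negatives(self):
        scores = {("p", "1"): 0.9, ("n", "1"): 0.5, ("n", "2"): 0.2}
        ref = make_ref([("p", "1")], [("n", "1"), ("n", "2")])
        spec, ppv = val.case_study_metrics(scores, ref, ("p", "1"))
        assert spec == 1.0 and ppv == 1.0

    def test_hand_enumeration(self):
        scores = {("p", "1"): 0.9, ("p", "2"): 0.6,
                  ("n", "1"): 0.5, ("n", "2"): 0.2}
        ref = make_ref([("p", "1"), ("p", "2")], [("n", "1"), ("n", "2")])
        spec, ppv = val.case_study_metrics(scores, ref, ("p", "2"))
        assert spec == 1.0   # both negatives strictly below 0.6
        assert ppv == 1.0    # two pairs at/above 0.6, both positive

    def test_all_scores_equal(self):
        scores = {("p", "1"): 0.5, ("p", "2"): 0.5,
                  ("n", "1"): 0.5, ("n", "2"): 0.5}
        ref = make_ref([("p", "1"), ("p", "2")], [("n", "1"), ("n", "2")])
        spec, ppv = val.case_study_metrics(scores, ref, ("p", "1"))
        assert spec == 0.0
        assert ppv == 0.5   # n_pos / (n_pos + n_neg)

    def test_unknown_pair_raises(self):
        scores = {("p", "1"): 0.9, ("n", "1"): 0.1}
        ref = make_ref([("p", "1")], [("n", "1")])
        with pytest.raises(CoverageError):
            val.case_study_metrics(scores, ref, ("x", "y"))
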