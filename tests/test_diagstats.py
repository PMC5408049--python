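import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmpi import diagstats as ds

# published per-territory contingency counts and the integer percentages
# printed alongside them (sens, spec, ppv, npv, acc)
PUBLISHED_ROWS = [
    ("mbf_all", (36, 10, 36, 12), (75, 78, 78, 75, 77)),
    ("tpr_all", (31, 11, 35, 17), (65, 76, 74, 67, 70)),
    ("mbf_intermediate", (29, 10, 22, 4), (88, 69, 74, 85, 78)),
    ("tpr_intermediate", (24, 8, 24, 9), (73, 75, 75, 73, 74)),
]


def brute_force_auc(scores, labels, orientation="lower"):
    """Exhaustive Mann-Whitney pair counting."""
    s = -np.asarray(scores, float) if orientation == "lower" else np.asarray(
        scores, float)
    lab = np.asarray(labels, bool)
    pos, neg = s[lab], s[~lab]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_youden(scores, labels, orientation="lower"):
    best_j = -np.inf
    for c in np.unique(scores):
        call = (scores <= c) if orientation == "lower" else (scores >= c)
        lab = np.asarray(labels, bool)
        sens = (call & lab).sum() / lab.sum()
        spec = (~call & ~lab).sum() / (~lab).sum()
        best_j = max(best_j, sens + spec - 1.0)
    return best_j


class TestContingency:
    @pytest.mark.parametrize("name,counts,printed", PUBLISHED_ROWS)
    def test_published_counts_reproduce_printed_percentages(
            self, name, counts, printed):
        tp, fp, tn, fn = counts
        m = ds.contingency_metrics(ds.ContingencyTable(tp, fp, tn, fn))
        got = tuple(int(ds.round_half_away(m[k])) for k in
                    ("sensitivity", "specificity", "ppv", "npv", "accuracy"))
        assert got == printed

    def test_perfect_classifier(self):
        m = ds.contingency_metrics(ds.ContingencyTable(1, 0, 1, 0))
        assert all(v == 100.0 for v in m.values())

    def test_zero_denominator_flagged_as_nan(self):
        m = ds.contingency_metrics(ds.ContingencyTable(0, 0, 3, 2))
        assert np.isnan(m["ppv"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ds.ContingencyTable(-1, 0, 1, 0)


class TestClusterCI:
    def test_singleton_clusters_reduce_to_wald(self):
        outcomes = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 1], float)
        clusters = np.arange(10)
        m = ds.cluster_adjusted_ci(outcomes, clusters)
        p = outcomes.mean()
        wald_half = 100 * ds.Z95 * np.sqrt(p * (1 - p) / len(outcomes))
        assert m.estimate == pytest.approx(100 * p)
        assert m.ci_high - m.estimate == pytest.approx(wald_half, rel=1e-9)
        assert not m.cluster_adjusted

    def test_concordant_clusters_widen_ci(self):
        # three territories per patient, all concordant within patients
        outcomes = np.repeat([1, 0, 1, 1, 0, 1, 0, 1], 3).astype(float)
        clusters = np.repeat(np.arange(8), 3)
        adj = ds.cluster_adjusted_ci(outcomes, clusters)
        flat = ds.cluster_adjusted_ci(outcomes, np.arange(len(outcomes)))
        assert adj.cluster_adjusted
        assert (adj.ci_high - adj.ci_low) > (flat.ci_high - flat.ci_low)

    def test_boundary_estimates_clipped(self):
        ones = np.ones(6)
        m = ds.cluster_adjusted_ci(ones, np.repeat([0, 1, 2], 2))
        assert m.estimate == 100.0 and m.ci_high == 100.0 and m.ci_low >= 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ds.cluster_adjusted_ci(np.array([1.0, 0.0]), np.array([1, 1]))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 4, 5, 6], float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)  # low score = diseased
        assert ds.roc_auc(scores, labels).auc == 1.0

    def test_all_tied_scores(self):
        scores = np.ones(8)
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        assert ds.roc_auc(scores, labels).auc == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 30)
        scores = rng.integers(0, 10, n).astype(float)  # ties likely
        labels = np.zeros(n, bool)
        labels[rng.permutation(n)[: rng.integers(1, n - 1)]] = True
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        got = ds.roc_auc(scores, labels).auc
        assert got == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(42)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        got = ds.roc_auc(scores, labels, orientation="lower").auc
        assert got == pytest.approx(roc_auc_score(labels, -scores))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40),
           st.randoms(use_true_random=False))
    def test_orientation_flip_mirrors_auc(self, values, rnd):
        scores = np.asarray(values)
        labels = np.array([rnd.random() < 0.5 for _ in scores])
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        lo = ds.roc_auc(scores, labels, orientation="lower").auc
        hi = ds.roc_auc(scores, labels, orientation="higher").auc
        assert lo + hi == pytest.approx(1.0)
        assert 0.0 <= lo <= 1.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ds.roc_auc(np.arange(5.0), np.ones(5, bool))


class TestDeLong:
    def _cohort(self, seed, n=40):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, bool)
        labels[: n // 2] = True
        scores = np.where(labels, rng.normal(70, 20, n), rng.normal(92, 20, n))
        return scores, labels

    def test_identical_classifiers_give_p_one(self):
        scores, labels = self._cohort(0)
        out = ds.delong_compare(scores, scores, labels)
        assert out["diff"] == 0.0
        assert out["p_value"] == 1.0

    def test_single_auc_variance_matches_bootstrap(self):
        scores, labels = self._cohort(1)
        var = ds.delong_variance(scores, labels)
        rng = np.random.default_rng(123)
        aucs = []
        idx_pos = np.flatnonzero(labels)
        idx_neg = np.flatnonzero(~labels)
        for _ in range(2000):
            take = np.concatenate([rng.choice(idx_pos, len(idx_pos)),
                                   rng.choice(idx_neg, len(idx_neg))])
            aucs.append(ds.roc_auc(scores[take], labels[take]).auc)
        boot = np.var(aucs, ddof=1)
        assert var == pytest.approx(boot, rel=0.30)

    def test_detects_auc_gap_on_paired_cohort(self):
        # paired indices on 94 territories (48 diseased) generated with
        # population AUCs 0.78 vs 0.65 and correlation 0.7 between the two
        # indices (both derive from the same perfusion map): the
        # correlated-AUC test should typically reject at the 5 % level
        from scipy.stats import norm

        pvals = []
        rho = 0.7
        for seed in range(11):
            rng = np.random.default_rng(seed)
            n = 94
            labels = np.zeros(n, bool)
            labels[:48] = True
            shared = rng.normal(0, 1, n)
            za = rho * shared + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
            zb = rho * shared + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
            d_a = norm.ppf(0.78) * np.sqrt(2)
            d_b = norm.ppf(0.65) * np.sqrt(2)
            mbf = 92.2 + 24.0 * (za - d_a * labels)
            tpr = 1.05 + 0.31 * (zb - d_b * labels)
            pvals.append(ds.delong_compare(mbf, tpr, labels)["p_value"])
        assert np.median(pvals) < 0.05

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            ds.delong_compare(np.arange(5.0), np.arange(6.0),
                              np.ones(5, bool))


class TestYouden:
    def test_perfect_separation_returns_gap_midpoint(self):
        scores = np.array([1, 2, 3, 4, 5, 6], float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        out = ds.youden_threshold(scores, labels)
        assert out.j == pytest.approx(1.0)
        assert out.threshold == pytest.approx(3.5)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        scores = np.round(rng.normal(75, 20, n), 1)
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        out = ds.youden_threshold(scores, labels)
        assert out.j == pytest.approx(brute_force_youden(scores, labels))
        # the returned threshold attains the optimal J
        call = scores <= out.threshold
        sens = (call & labels).sum() / labels.sum()
        spec = (~call & ~labels).sum() / (~labels).sum()
        assert sens + spec - 1.0 == pytest.approx(out.j)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(75, 15, 30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        base = ds.youden_threshold(scores, labels)
        shifted = ds.youden_threshold(scores + 13.5, labels)
        assert shifted.threshold == pytest.approx(base.threshold + 13.5)
        assert shifted.j == pytest.approx(base.j)


class TestAgreementAndAssociation:
    def test_combined_score(self):
        assert ds.combined_score(76.0, 0.82) == pytest.approx(62.32)
        assert ds.combined_score(55.0, 1.0) == 55.0
        assert ds.combined_score(0.0, 0.7) == 0.0

    def test_pearson_exact_linear(self):
        x = np.arange(10.0)
        assert ds.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert ds.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        xc, yc = x - x.mean(), y - y.mean()
        direct = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert ds.pearson_r(x, y) == pytest.approx(direct)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ds.pearson_r(np.ones(5), np.arange(5.0))

    def test_icc_identical_readers(self):
        x = np.array([60.0, 75.0, 90.0, 110.0, 45.0])
        assert ds.icc_two_readers(x, x) == pytest.approx(1.0)

    def test_absolute_agreement_penalises_reader_offset(self):
        rng = np.random.default_rng(5)
        a = rng.normal(80, 15, 20)
        b = a + 25.0
        assert ds.icc_two_readers(a, b) < ds.icc_consistency(a, b)

    def test_icc_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        a = rng.normal(80, 15, 12)
        b = a + rng.normal(2, 6, 12)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(12), 2),
            "rater": np.repeat(["r1", "r2"], 12),
            "score": np.concatenate([a, b]),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        want = float(ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]),
                             "ICC"].iloc[0])
        assert ds.icc_two_readers(a, b) == pytest.approx(want, abs=1e-6)

    def test_kappa_identical_and_opposite(self):
        a = np.array([1, 1, 0, 0, 1, 0])
        assert ds.cohen_kappa(a, a) == 1.0
        assert ds.cohen_kappa(a, 1 - a) == pytest.approx(-1.0)

    def test_kappa_near_zero_for_independent_labels(self):
        rng = np.random.default_rng(13)
        a = rng.random(10_000) < 0.5
        b = rng.random(10_000) < 0.5
        assert abs(ds.cohen_kappa(a, b)) < 0.03

    def test_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(17)
        a = rng.integers(0, 2, 60)
        b = np.where(rng.random(60) < 0.75, a, 1 - a)
        assert ds.cohen_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b))


class TestDoseAndGroups:
    def test_effective_dose_conversion(self):
        assert ds.round_half_away(ds.effective_dose(640.0), 1) == 9.0
        assert ds.effective_dose(0.0) == 0.0
        assert ds.effective_dose(1000.0) == pytest.approx(14.0)
        with pytest.raises(ValueError):
            ds.effective_dose(-5.0)

    def test_identical_groups_give_p_one(self):
        vals = np.array([70.0, 80, 90, 70, 80, 90])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        out = ds.group_summary(vals, groups)
        assert out.p_value == pytest.approx(1.0)

    def test_textbook_two_sample_t(self):
        # pooled t for {1,2,3,4} vs {3,4,5,6}: equal group variances 5/3,
        # SE = sqrt((5/3) * (1/4 + 1/4)), t = -2 / sqrt(5/6)
        vals = np.array([1, 2, 3, 4, 3, 4, 5, 6], float)
        groups = np.repeat(["a", "b"], 4)
        out = ds.group_summary(vals, groups)
        assert out.t == pytest.approx(-2.0 / np.sqrt(5.0 / 6.0))
        assert out.means["a"] == 2.5 and out.means["b"] == 4.5

    def test_mbf_subrange_filter_is_inclusive(self):
        df = pd.DataFrame({"mbf": [49.9, 50.0, 75.0, 100.0, 100.1]})
        out = ds.filter_mbf_range(df)
        assert out["mbf"].tolist() == [50.0, 75.0, 100.0]

    def test_quadrant_counts_cover_all_records(self):
        rng = np.random.default_rng(19)
        mbf = rng.normal(80, 20, 50)
        tpr = rng.normal(0.9, 0.15, 50)
        q = ds.quadrant_counts(mbf, tpr)
        assert q["n"].sum() == 50
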