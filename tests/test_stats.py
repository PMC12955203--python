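"""Statistics vs independent oracles: brute-force pair counts, delete-one
jackknife, exhaustive enumeration, scipy/pingouin cross-checks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps
from scipy.integrate import quad

import clotburden.stats as st
from clotburden import (
    ConstantInputError,
    DegenerateLabelsError,
    OutcomeLabels,
    auc_power_posthoc,
    delong_paired,
    dichotomize,
    fisher_exact,
    icc,
    icc_band,
    roc,
    score_outcome_table,
    spearman,
    stratified_spearman,
    wilcoxon_rank_sum,
    youden,
)
from conftest import random_labelled_scores

# ---------------------------------------------------------------------------
# independent oracles


def auc_pair_oracle(scores, labels):
    """Brute-force Mann-Whitney count over all case-control pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p < q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def jackknife_auc_cov(scores_a, scores_b, labels):
    """Delete-one jackknife covariance of two correlated AUCs.

    Positives and negatives are jackknifed separately and the two class
    contributions added; every leave-one-out AUC is recomputed from scratch
    with the brute-force pair count.
    """
    labels = np.asarray(labels)
    cov = 0.0
    for cls in (1, 0):
        idx = np.where(labels == cls)[0]
        k = len(idx)
        loo_a, loo_b = [], []
        for i in idx:
            mask = np.ones(len(labels), dtype=bool)
            mask[i] = False
            loo_a.append(auc_pair_oracle(scores_a[mask], labels[mask]))
            loo_b.append(auc_pair_oracle(scores_b[mask], labels[mask]))
        loo_a = np.asarray(loo_a) - np.mean(loo_a)
        loo_b = np.asarray(loo_b) - np.mean(loo_b)
        cov += (k - 1) / k * float(loo_a @ loo_b)
    return cov


# ---------------------------------------------------------------------------
# dichotomization


@pytest.mark.parametrize(
    "mrs90, nihss, expected",
    [
        (6, 20, (1, 1, 1)),  # death implies every adverse label
        (1, 14, (0, 0, 0)),  # mRS90 0-1 is "no disability"
        (2, 15, (0, 1, 1)),  # boundary: disability at mRS90=2, severity at NIHSS=15
        (0, 0, (0, 0, 0)),
        (5, 42, (0, 1, 1)),
    ],
)
def test_dichotomize(mrs90, nihss, expected):
    assert dichotomize(mrs90, nihss) == expected


def test_dichotomize_rejects_out_of_range():
    with pytest.raises(ValueError):
        dichotomize(7, 10)
    with pytest.raises(ValueError):
        dichotomize(3, 43)


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_data_equals_pearson_of_midranks(self):
        x = np.array([1, 2, 2, 4], dtype=float)
        y = np.array([3, 1, 4, 4], dtype=float)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-14)

    def test_rho_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, size=15).astype(float)
            y = rng.integers(0, 10, size=15).astype(float)
            if np.unique(x).size == 1 or np.unique(y).size == 1:
                continue
            res = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            assert res.method == "t-approximation"

    def test_small_n_permutation_p_matches_exhaustive_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        res = spearman(x, y)
        assert res.method == "permutation"
        obs = abs(sps.spearmanr(x, y).statistic)
        hits = sum(
            abs(sps.spearmanr(x, np.array(p)).statistic) >= obs - 1e-12
            for p in itertools.permutations(y)
        )
        assert res.p_value == pytest.approx(hits / math.factorial(5), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


class TestRoc:
    def test_perfect_separation_low_scores_positive(self):
        labels = OutcomeLabels(np.array([1, 1, 0, 0]), "mortality")
        assert roc(np.array([0, 0, 10, 10]), labels).auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        labels = OutcomeLabels(np.array([1, 0, 1, 0]), "mortality")
        assert roc(np.array([5, 5, 5, 5]), labels).auc == pytest.approx(0.5)

    def test_interleaved_fixture_matches_pair_enumeration(self):
        scores = np.array([1, 3, 2, 4])
        labels = np.array([1, 1, 0, 0])
        expected = auc_pair_oracle(scores, labels)  # 3 of 4 pairs favourable
        assert expected == 0.75
        assert roc(scores, OutcomeLabels(labels, "mortality")).auc == expected

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            roc(np.array([1, 2, 3]), OutcomeLabels(np.array([1, 1, 1]), "mortality"))

    def test_operating_points_monotone(self, rng):
        scores, labels = random_labelled_scores(rng, n=40)
        res = roc(scores, OutcomeLabels(labels, "disability"))
        sens = [p[1] for p in res.operating_points]
        spec = [p[2] for p in res.operating_points]
        assert all(a <= b + 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(spec, spec[1:]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(hst.data())
    def test_trapezoid_equals_mann_whitney(self, data):
        n = data.draw(hst.integers(6, 30))
        scores = np.array(
            data.draw(hst.lists(hst.integers(0, 10), min_size=n, max_size=n))
        )
        labels = np.array(
            data.draw(hst.lists(hst.integers(0, 1), min_size=n, max_size=n))
        )
        if not 0 < labels.sum() < n:
            return
        res = roc(scores, OutcomeLabels(labels, "disability"))
        assert st.trapezoid_auc(res) == pytest.approx(res.auc, abs=1e-12)
        assert res.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    def test_orientation_flip_leaves_auc_unchanged(self, rng):
        """Negating scores and scoring with a >=-positivity oracle matches."""
        scores, labels = random_labelled_scores(rng, n=25)
        res = roc(scores, OutcomeLabels(labels, "severity"))
        neg_scores = -scores
        pos = neg_scores[labels == 1]
        negv = neg_scores[labels == 0]
        total = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in negv
        )
        assert total / (len(pos) * len(negv)) == pytest.approx(res.auc, abs=1e-12)


class TestDeLong:
    def test_variance_matches_jackknife_oracle_on_random_fixtures(self, rng):
        """DeLong's structural-component variance is the two-sample
        delete-one jackknife variance; check on >= 20 random fixtures."""
        for _ in range(25):
            scores, labels = random_labelled_scores(rng, n=rng.integers(8, 20))
            res = roc(scores, OutcomeLabels(labels, "mortality"))
            var_jack = jackknife_auc_cov(scores, scores, labels)
            assert res.auc_se**2 == pytest.approx(var_jack, abs=1e-6)

    def test_paired_z_matches_jackknife_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 18))
            scores_a, labels = random_labelled_scores(rng, n=n)
            scores_b = np.clip(scores_a + rng.integers(-3, 4, size=n), 0, 10)
            if np.array_equal(scores_a, scores_b):
                continue
            lab = OutcomeLabels(labels, "disability")
            try:
                res = delong_paired(scores_a, scores_b, lab)
            except st.ZeroVarianceError:
                continue
            var = (
                jackknife_auc_cov(scores_a, scores_a, labels)
                + jackknife_auc_cov(scores_b, scores_b, labels)
                - 2 * jackknife_auc_cov(scores_a, scores_b, labels)
            )
            delta = auc_pair_oracle(scores_a, labels) - auc_pair_oracle(
                scores_b, labels
            )
            z = delta / math.sqrt(var)
            assert res.z == pytest.approx(z, abs=1e-6)
            assert res.p_value == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-6)

    def test_self_comparison_is_null(self):
        labels = OutcomeLabels(np.array([1, 0, 1, 0, 1, 0]), "mortality")
        s = np.array([1, 2, 3, 4, 5, 6])
        res = delong_paired(s, s, labels)
        assert res.delta == 0.0
        assert res.z == 0.0
        assert res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        scores_a, labels = random_labelled_scores(rng, n=15)
        scores_b = (scores_a + rng.integers(0, 5, size=15)) % 11
        lab = OutcomeLabels(labels, "severity")
        ab = delong_paired(scores_a, scores_b, lab)
        ba = delong_paired(scores_b, scores_a, lab)
        assert ab.delta == pytest.approx(-ba.delta)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p_value == pytest.approx(ba.p_value)


class TestYouden:
    def test_perfect_classifier(self):
        labels = OutcomeLabels(np.array([1, 1, 0, 0]), "mortality")
        res = youden(roc(np.array([0, 1, 8, 9]), labels))
        assert res.j == pytest.approx(1.0)
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_uninformative_classifier(self):
        labels = OutcomeLabels(np.array([1, 0, 1, 0]), "mortality")
        res = youden(roc(np.array([5, 5, 5, 5]), labels))
        assert res.j == pytest.approx(0.0)

    def test_fixture_matches_exhaustive_criterion_scan(self):
        scores = np.array([1, 3, 2, 4])
        labels = np.array([1, 1, 0, 0])
        res = youden(roc(scores, OutcomeLabels(labels, "mortality")))
        # scan all criteria by hand
        best = max(
            (np.mean(scores[labels == 1] <= c) + np.mean(scores[labels == 0] > c) - 1, -c)
            for c in np.unique(scores)
        )
        assert res.j == pytest.approx(best[0])
        assert res.criterion == 1  # smallest criterion among the maximizers
        assert res.j == pytest.approx(res.sensitivity + res.specificity - 1.0)

    def test_j_recomputes_from_reported_sens_spec(self, rng):
        for _ in range(10):
            scores, labels = random_labelled_scores(rng, n=30)
            res = youden(roc(scores, OutcomeLabels(labels, "disability")))
            assert res.j == pytest.approx(res.sensitivity + res.specificity - 1.0)


# ---------------------------------------------------------------------------
# ICC


class TestIcc:
    def test_identical_raters_give_one(self):
        m = np.array([[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [6, 6]])
        res = icc(m)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "very good"

    def test_six_by_two_fixture_matches_anova_oracle(self):
        m = np.array([[9, 2], [8, 1], [7, 2], [10, 5], [6, 2], [5, 1]], dtype=float)
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((m - m.mean(1)[:, None] - m.mean(0)[None, :] + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(m).icc == pytest.approx(expected, abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            m = rng.normal(5, 2, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
            res = icc(m)
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(12), 3),
                    "rater": np.tile(np.arange(3), 12),
                    "score": m.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")
            row = ref.loc["ICC(A,1)"]  # two-way random, absolute agreement, single
            assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
            lo, hi = row[[c for c in ref.columns if c.startswith("CI95")][0]]
            # pingouin rounds its CI to 2 dp
            assert res.ci95[0] == pytest.approx(lo, abs=6e-3)
            assert res.ci95[1] == pytest.approx(hi, abs=6e-3)

    def test_null_icc_near_zero_on_independent_columns(self):
        """Independent N(0,1) raters: mean ICC over 100 replicates is ~0."""
        values = []
        rng = np.random.default_rng(777)
        for _ in range(100):
            values.append(icc(rng.normal(size=(500, 2))).icc)
        assert -0.1 < float(np.mean(values)) < 0.1

    def test_degenerate_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(np.full((6, 2), 3.0))

    @pytest.mark.parametrize(
        "value, band",
        [
            (0.10, "poor"),
            (0.20, "poor"),
            (0.21, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.61, "good"),
            (0.80, "good"),
            (0.81, "very good"),
            (0.96, "very good"),
            (1.0, "very good"),
        ],
    )
    def test_band_boundaries(self, value, band):
        assert icc_band(value) == band


# ---------------------------------------------------------------------------
# rank-sum and Fisher


class TestWilcoxonRankSum:
    def test_identical_groups_not_significant(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5] * 4, [1, 2, 3, 4, 5] * 4)
        assert p >= 0.99

    def test_exact_p_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        w, p = wilcoxon_rank_sum(x, y)
        assert w == 6.0
        # oracle: enumerate all C(6,3) assignments of the pooled values
        pooled = np.array(x + y)
        order = pooled.argsort().argsort() + 1.0
        mu = 3 * 7 / 2.0
        obs = abs(w - mu)
        hits = sum(
            abs(order[list(idx)].sum() - mu) >= obs - 1e-12
            for idx in itertools.combinations(range(6), 3)
        )
        assert p == pytest.approx(hits / math.comb(6, 3))
        assert p == pytest.approx(0.1)

    def test_swap_symmetry(self, rng):
        x = rng.integers(0, 20, size=9).astype(float)
        y = rng.integers(0, 20, size=14).astype(float)
        assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(
            wilcoxon_rank_sum(y, x)[1]
        )

    def test_tied_large_sample_matches_scipy_normal_approximation(self, rng):
        x = rng.integers(0, 6, size=30).astype(float)
        y = rng.integers(1, 7, size=25).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration_and_scipy(self, rng):
        tables = [[[3, 1], [1, 3]], [[8, 2], [1, 5]], [[10, 10], [10, 1]]]
        for _ in range(10):
            t = rng.integers(0, 12, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) > 0:
                tables.append(t.tolist())
        for t in tables:
            odds, p = fisher_exact(t)
            ref_odds, ref_p = sps.fisher_exact(t)
            assert p == pytest.approx(ref_p, abs=1e-12)
            assert 0.0 < p <= 1.0

    def test_pmf_over_fixed_margins_sums_to_one(self):
        a, b, c, d = 3, 4, 5, 2
        n = a + b + c + d
        hg = sps.hypergeom(n, a + b, a + c)
        ks = np.arange(max(0, a + b + a + c - n), min(a + b, a + c) + 1)
        assert hg.pmf(ks).sum() == pytest.approx(1.0, abs=1e-12)

    def test_transpose_invariance(self):
        t = [[7, 2], [3, 9]]
        assert fisher_exact(t)[1] == pytest.approx(
            fisher_exact(np.transpose(t))[1], abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])


# ---------------------------------------------------------------------------
# stratified correlations and contingency


class TestCohortHelpers:
    def test_single_stratum_equals_pooled(self, rng):
        df = pd.DataFrame(
            {
                "score": rng.integers(0, 10, 20),
                "outcome": rng.integers(0, 2, 20),
                "grp": ["A"] * 20,
            }
        )
        recs = stratified_spearman(df, "score", "outcome", "grp")
        assert len(recs) == 1
        pooled = spearman(df["score"], df["outcome"])
        assert recs[0]["result"].rho == pytest.approx(pooled.rho)

    def test_small_stratum_skipped_with_reason(self):
        df = pd.DataFrame(
            {
                "score": [1, 2, 3, 4, 5, 6],
                "outcome": [0, 1, 0, 1, 0, 1],
                "grp": ["A", "A", "A", "A", "B", "B"],
            }
        )
        recs = {r["group"]: r for r in stratified_spearman(df, "score", "outcome", "grp")}
        assert recs["A"]["result"] is not None
        assert recs["B"]["result"] is None
        assert "fewer than 3" in recs["B"]["skipped_reason"]

    def test_unknown_group_column_rejected(self):
        df = pd.DataFrame({"score": [1], "outcome": [0]})
        with pytest.raises(KeyError):
            stratified_spearman(df, "score", "outcome", "treatment")

    def test_score_outcome_table_tally_and_marginals(self):
        scores = np.array([0, 0, 5, 5])
        labels = OutcomeLabels(np.array([1, 1, 0, 0]), "disability")
        tab = score_outcome_table(scores, labels)
        assert list(tab.index) == [0, 5]
        assert tab.loc[0].tolist() == [0, 2]
        assert tab.loc[5].tolist() == [2, 0]
        assert tab.to_numpy().sum() == 4
        assert tab["n_pos"].sum() == labels.n_pos
        assert tab["n_neg"].sum() == labels.n_neg


# ---------------------------------------------------------------------------
# post-hoc power


class TestAucPower:
    def test_null_difference_gives_alpha(self):
        assert auc_power_posthoc(0.7, 0.7, 29, 101, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_difference(self):
        powers = [
            auc_power_posthoc(0.70, 0.70 + d, 40, 90, corr=0.5)
            for d in (0.0, 0.05, 0.10, 0.15, 0.20)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_matches_numeric_integration_oracle(self):
        auc_a, auc_b, n_pos, n_neg, alpha, corr = 0.807, 0.735, 83, 47, 0.05, 0.5

        def hm(a):
            q1 = a / (2 - a)
            q2 = 2 * a * a / (1 + a)
            return (
                a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
            ) / (n_pos * n_neg)

        se = math.sqrt(hm(auc_a) + hm(auc_b) - 2 * corr * math.sqrt(hm(auc_a) * hm(auc_b)))
        shift = (auc_a - auc_b) / se
        z_a = sps.norm.ppf(1 - alpha / 2)
        left, _ = quad(lambda t: sps.norm.pdf(t - shift), -np.inf, -z_a)
        right, _ = quad(lambda t: sps.norm.pdf(t - shift), z_a, np.inf)
        assert auc_power_posthoc(auc_a, auc_b, n_pos, n_neg, alpha, corr) == (
            pytest.approx(left + right, abs=1e-6)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc_power_posthoc(0.4, 0.7, 10, 10)
        with pytest.raises(ValueError):
            auc_power_posthoc(0.7, 0.8, 10, 10, alpha=0.0)
        with pytest.raises(ValueError):
            auc_power_posthoc(0.7, 0.8, 10, 10, corr=1.0)
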