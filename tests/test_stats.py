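import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from crtsync.stats import (
    ContingencyTable2x2,
    StatsError,
    bootstrap_fit,
    cohens_kappa,
    esv_response,
    fisher_exact_2x2,
    logistic_fit,
    mann_whitney,
    odds_ratio_ci,
    roc_auc_delong,
    ttest_from_summary,
)
from crtsync.synth import OutcomeModel, generate_cohort


def fisher_bruteforce(a, b, c, d):
    """Independent exact oracle: enumerate all tables with the observed
    margins via the transposed binomial decomposition, in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    N = a + b + c + d
    c2 = N - c1
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 1.0
    lo, hi = max(0, r1 - c2), min(r1, c1)
    weights = {k: math.comb(c1, k) * math.comb(c2, r1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    total = sum(weights.values())
    return float(Fraction(sum(w for w in weights.values() if w <= obs), total))


class TestEsvResponse:
    def test_boundary_inclusive(self):
        assert esv_response(150.0, 127.5)  # exactly 15 %
        assert esv_response(150.0, 120.0)
        assert not esv_response(100.0, 90.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(StatsError):
            esv_response(0.0, 10.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((11, 1, 7, 14), 0.003),
            ((7, 6, 20, 0), 0.002),
            ((1, 1, 1, 1), 1.0),
        ],
    )
    def test_reference_values(self, table, expected):
        p = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert round(p, 3) == expected

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            ours = fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            theirs = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, rel=1e-6, abs=1e-9)

    def test_matches_bruteforce_small_exhaustive(self):
        # exhaustive over all tables with total <= 12 (full sweep at total
        # <= 40 runs in the acceptance suite)
        for N in range(1, 13):
            for a in range(N + 1):
                for b in range(N + 1 - a):
                    for c in range(N + 1 - a - b):
                        d = N - a - b - c
                        t = ContingencyTable2x2(a, b, c, d)
                        assert fisher_exact_2x2(t) == pytest.approx(
                            fisher_bruteforce(a, b, c, d), abs=1e-12
                        )

    def test_zero_margin_convention(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4)) == 1.0


class TestOddsRatio:
    def test_printed_tables(self):
        orr, ci = odds_ratio_ci(ContingencyTable2x2(11, 1, 7, 14))
        assert orr == pytest.approx(22.0)
        assert ci[0] == pytest.approx(2.3, abs=0.05)
        assert ci[1] == pytest.approx(206, rel=0.005)
        orr, _ = odds_ratio_ci(ContingencyTable2x2(13, 5, 5, 10))
        assert orr == pytest.approx(5.2)
        assert odds_ratio_ci(ContingencyTable2x2(5, 5, 5, 5))[0] == pytest.approx(1.0)

    def test_zero_cell_rejected(self):
        with pytest.raises(StatsError):
            odds_ratio_ci(ContingencyTable2x2(5, 0, 3, 4))

    def test_transformation_invariance(self):
        t = ContingencyTable2x2(11, 1, 7, 14)
        orr, _ = odds_ratio_ci(t)
        # swapping rows and columns simultaneously leaves the OR unchanged
        assert odds_ratio_ci(ContingencyTable2x2(14, 7, 1, 11))[0] == pytest.approx(orr)
        # swapping rows alone inverts it
        assert odds_ratio_ci(ContingencyTable2x2(7, 14, 11, 1))[0] == pytest.approx(1 / orr)


class TestLogistic:
    def test_univariate_equals_cross_product_or(self):
        for counts in [(11, 1, 7, 14), (13, 5, 5, 10), (14, 6, 4, 9), (17, 1, 9, 6)]:
            t = ContingencyTable2x2(*counts)
            x, y = t.expand()
            fit = logistic_fit(x, y)
            assert fit.odds_ratios[1] == pytest.approx(odds_ratio_ci(t)[0], rel=1e-6)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(StatsError):
            logistic_fit(np.array([0, 1, 0, 1]), np.ones(4))

    def test_separation_flagged(self):
        x = np.repeat([0, 1], 20)
        y = x.copy()  # perfectly separated
        fit = logistic_fit(x, y)
        assert fit.separation

    def test_wald_ci_ordered(self):
        t = ContingencyTable2x2(11, 1, 7, 14)
        fit = logistic_fit(*t.expand())
        ci = fit.conf_int()
        assert (ci[:, 0] < ci[:, 1]).all()


class TestBootstrap:
    def test_deterministic_given_seed(self):
        df = generate_cohort(120, seed=3)
        x = df.t2cl.astype(float).to_numpy()
        y = df.responder.astype(float).to_numpy()
        s1 = bootstrap_fit(x, y, B=50, seed=9)
        s2 = bootstrap_fit(x, y, B=50, seed=9)
        assert s1.sign_agreement == s2.sign_agreement
        assert s1.percentile_ci == s2.percentile_ci

    def test_strong_effect_high_sign_agreement(self):
        df = generate_cohort(330, seed=4)
        x = df.t2cl.astype(float).to_numpy()
        y = df.responder.astype(float).to_numpy()
        s = bootstrap_fit(x, y, B=300, seed=10)
        assert s.sign_agreement["x1"] > 0.95

    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 400).astype(float)
        y = rng.integers(0, 2, 400).astype(float)
        s = bootstrap_fit(x, y, B=300, seed=11)
        lo, hi = s.percentile_ci["x1"]
        assert lo < 1.0 < hi


class TestDeLong:
    def test_perfect_scores_auc_one(self):
        y = np.array([0, 1] * 20)
        base = np.full(40, 0.5)
        a0, a1, p = roc_auc_delong(base, y.astype(float), y)
        assert a0 == 0.5 and a1 == 1.0
        assert p < 0.01

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 1000)
        s1 = rng.random(1000)
        s2 = rng.random(1000)
        a0, a1, p = roc_auc_delong(s1, s2, y)
        assert a0 == pytest.approx(0.5, abs=0.05)
        assert a1 == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 300)
        s = rng.random(300) + 0.5 * y
        a0, _, _ = roc_auc_delong(s, s * 2, y)
        assert a0 == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_adding_true_predictor_significant(self):
        df = generate_cohort(
            330, outcome_model=OutcomeModel(beta_nicm=np.log(3.0)), seed=8
        )
        y = df.responder.astype(int).to_numpy()
        base_design = df[["nicm"]].astype(float).to_numpy()
        aug_design = df[["nicm", "t2cl"]].astype(float).to_numpy()
        base = logistic_fit(base_design, y).predict(base_design)
        aug = logistic_fit(aug_design, y).predict(aug_design)
        a0, a1, p = roc_auc_delong(base, aug, y)
        assert a1 > a0
        assert p < 0.05


class TestKappa:
    def test_identical_labels(self):
        assert cohens_kappa([0, 1, 0, 1, 1], [0, 1, 0, 1, 1]) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 2, 5000)
        b = rng.integers(0, 2, 5000)
        assert cohens_kappa(a, b) == pytest.approx(0.0, abs=0.05)

    def test_against_bruteforce_expected_agreement(self):
        # 33 reads, 29 agreements, marginals near a 13/20 split
        rater1 = np.array([0] * 13 + [1] * 20)
        rater2 = rater1.copy()
        rater2[[0, 1, 13, 14]] ^= 1  # 4 disagreements
        po = float(np.mean(rater1 == rater2))
        pe = 0.0
        for k in (0, 1):
            pe += np.mean(rater1 == k) * np.mean(rater2 == k)
        expected = (po - pe) / (1 - pe)
        assert cohens_kappa(rater1, rater2) == pytest.approx(expected, abs=1e-12)

    def test_single_category_undefined(self):
        with pytest.raises(StatsError):
            cohens_kappa([1, 1, 1], [1, 1, 1])


class TestLocationTests:
    def test_equal_means_t_is_zero(self):
        assert ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10) == pytest.approx(1.0)

    def test_printed_wall_delay_row(self):
        p = ttest_from_summary(371, 117, 13, 471, 106, 20)
        assert round(p, 3) == 0.016

    def test_doubling_n_decreases_p(self):
        p1 = ttest_from_summary(5.0, 2.0, 10, 6.0, 2.0, 10)
        p2 = ttest_from_summary(5.0, 2.0, 20, 6.0, 2.0, 20)
        assert p2 < p1

    def test_mann_whitney_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        assert mann_whitney(x, x) == 1.0

    def test_mann_whitney_complete_separation_exact(self):
        x = [6.0, 7.0, 8.0, 9.0, 10.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        # exact two-sided p = 2 / C(10, 5)
        assert mann_whitney(x, y) == pytest.approx(2 / math.comb(10, 5))

    def test_mann_whitney_agrees_with_t_direction(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0.0, 1.0, 200)
        y = rng.normal(0.6, 1.0, 200)
        p_u = mann_whitney(x, y)
        p_t = sps.ttest_ind(x, y).pvalue
        assert p_u < 0.01 and p_t < 0.01
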