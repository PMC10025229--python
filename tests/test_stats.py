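"""Mann-Whitney, chi-square, ROC, Spearman matrix and severity cutoffs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glymphflow.stats import (
    Subject,
    chi_square_2x2,
    mann_whitney,
    roc_analysis,
    severity_grouping,
    spearman_matrix,
)


def _exact_mw_p(x, y):
    """Full-enumeration oracle for the two-sided exact Mann-Whitney p."""
    pooled = list(x) + list(y)
    n, m = len(x), len(y)

    def u_stat(x_idx):
        xs = [pooled[i] for i in x_idx]
        ys = [pooled[i] for i in range(n + m) if i not in x_idx]
        return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
            1.0 for a in xs for b in ys if a == b
        )

    observed = u_stat(tuple(range(n)))
    us = [u_stat(c) for c in itertools.combinations(range(n + m), n)]
    mid = n * m / 2.0
    # two-sided: as or more extreme in distance from the null mean
    p = sum(1 for u in us if abs(u - mid) >= abs(observed - mid) - 1e-12)
    return p / len(us)


class TestMannWhitney:
    def test_separated_triples_exact_p(self):
        """{1,2,3} vs {4,5,6}: U = 0 and two-sided exact p = 0.1, verified by
        full enumeration of all C(6,3) = 20 group assignments."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        oracle = _exact_mw_p(x, y)
        assert oracle == pytest.approx(0.1)
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p == pytest.approx(oracle)

    def test_exact_matches_enumeration_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(_exact_mw_p(x, y))

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney(x, y)[1] == pytest.approx(mann_whitney(y, x)[1])

    def test_null_rejection_rate_calibrated(self):
        """i.i.d. samples from one distribution reject at ~5% over 2000
        replicates (within the 95% binomial CI of 0.05)."""
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            x, y = rng.normal(size=30), rng.normal(size=30)
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < half_width

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        # expected counts are all 10; sum (O-E)^2/E = 4 * 100/10 = 40
        stat, _ = chi_square_2x2([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_transposition_invariance(self):
        table = np.array([[12, 5], [7, 20]])
        assert chi_square_2x2(table) == pytest.approx(chi_square_2x2(table.T))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        res = roc_analysis(scores, labels)
        assert res.auroc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=4000)
        labels = rng.random(4000) < 0.5
        res = roc_analysis(scores, labels, direction="greater")
        assert abs(res.auroc - 0.5) < 0.03

    def test_auroc_equals_u_over_n1n2(self):
        """Rank-statistic identity AUROC = U / (n1 n2), including ties."""
        rng = np.random.default_rng(4)
        for rep in range(100):
            n1, n2 = rng.integers(5, 30), rng.integers(5, 30)
            pos = np.round(rng.normal(0.5, 1, n1), 1)  # rounding makes ties
            neg = np.round(rng.normal(0.0, 1, n2), 1)
            scores = np.r_[pos, neg]
            labels = np.r_[np.ones(n1, bool), np.zeros(n2, bool)]
            res = roc_analysis(scores, labels, direction="greater")
            u, _ = mann_whitney(pos, neg)
            assert res.auroc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_auto_direction_orients_auroc_above_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = scores < -0.2  # low scores indicate the positive class
        res = roc_analysis(scores, labels, direction="auto")
        assert res.auroc >= 0.5
        assert res.direction == "less"

    def test_youden_tie_prefers_higher_specificity(self):
        # two operating points share J; the lower-FPR one must win
        scores = np.array([3.0, 2.0, 1.0, 0.0])
        labels = np.array([True, False, True, False])
        res = roc_analysis(scores, labels, direction="greater")
        assert res.specificity == 1.0
        assert res.sensitivity == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5, bool))


class TestSpearman:
    def test_self_correlation_is_unity_and_strong(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = df["a"]
        corr = spearman_matrix(df)
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)
        assert corr.strength.loc["a", "b"] == "strong"

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=25)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        corr = spearman_matrix(df)
        assert corr.rho.loc["x", "y"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        corr = spearman_matrix(df)
        ra = pd.Series(df["a"]).rank().to_numpy()
        rb = pd.Series(df["b"]).rank().to_numpy()
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert corr.rho.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        corr = spearman_matrix(df)
        np.testing.assert_allclose(corr.rho.to_numpy(), corr.rho.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.rho.to_numpy()), 1.0)
        assert np.all(np.abs(corr.rho.to_numpy()) <= 1.0 + 1e-12)

    def test_constant_variable_undefined_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.warns(RuntimeWarning, match="constant"):
            corr = spearman_matrix(df)
        assert np.isnan(corr.rho.loc["a", "b"])
        assert corr.strength.loc["a", "b"] == "undefined"

    def test_pairwise_complete_handling(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        df.loc[3, "a"] = np.nan
        corr = spearman_matrix(df)
        sub = df.dropna()
        oracle = np.corrcoef(sub["a"].rank(), sub["b"].rank())[0, 1]
        assert corr.rho.loc["a", "b"] == pytest.approx(oracle, abs=1e-12)

    def test_bh_correction_never_decreases_p(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        raw = spearman_matrix(df)
        adj = spearman_matrix(df, bh_correction=True)
        off = ~np.eye(4, dtype=bool)
        assert np.all(adj.p.to_numpy()[off] >= raw.p.to_numpy()[off] - 1e-15)


class TestSeverityGrouping:
    @pytest.mark.parametrize("ahi,expected", [
        (4.9, "no_OSA"),
        (5.0, "mild_moderate_OSA"),
        (29.9, "mild_moderate_OSA"),
        (30.0, "severe_OSA"),
        (80.0, "severe_OSA"),
    ])
    def test_osa_cutoffs(self, ahi, expected):
        s = Subject("s", "OSA_pre", AHI=ahi, LSaO2=85.0)
        assert severity_grouping(s)[0] == expected

    @pytest.mark.parametrize("lsao2,expected", [
        (95.0, "no_hypoxemia"),
        (90.0, "no_hypoxemia"),
        (89.9, "mild_hypoxemia"),
        (80.0, "mild_hypoxemia"),
        (79.9, "severe_hypoxemia"),
    ])
    def test_hypoxemia_cutoffs(self, lsao2, expected):
        s = Subject("s", "OSA_pre", AHI=20.0, LSaO2=lsao2)
        assert severity_grouping(s)[1] == expected

    def test_missing_values_unclassified_with_warning(self):
        s = Subject("s", "OSA_pre")
        with pytest.warns(RuntimeWarning):
            osa_class, hyp_class = severity_grouping(s)
        assert osa_class is None and hyp_class is None

    def test_subject_validation(self):
        with pytest.raises(ValueError):
            Subject("s", "bogus_group")
        with pytest.raises(ValueError):
            Subject("s", "NC", AHI=-1.0)
        with pytest.raises(ValueError):
            Subject("s", "NC", LSaO2=130.0)
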