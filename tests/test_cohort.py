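"""Group statistics: Welch tests, Fisher discriminant, classification,
regression — each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import stats

from cortox.cohort import (
    classify_and_report,
    composite_index,
    fisher_lda2,
    regress_score,
    welch_from_samples,
    welch_from_summary,
)
from cortox.exceptions import (
    DegenerateStatisticError,
    InsufficientDataError,
    SchemaError,
)


# ------------------------------------------------------------------ Welch test

class TestWelch:
    def test_identical_summaries_give_t0_p1(self):
        cmp = welch_from_summary(1.0, 2.0, 10, 1.0, 2.0, 10)
        assert cmp.t == 0.0
        assert cmp.p == pytest.approx(1.0)

    def test_identical_samples_give_t0_p1(self):
        cmp = welch_from_samples([1, 2, 3], [1, 2, 3])
        assert cmp.t == 0.0
        assert cmp.p == pytest.approx(1.0)

    def test_symmetry_under_group_swap(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 36)
        fwd = welch_from_samples(a, b)
        rev = welch_from_samples(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.df == pytest.approx(rev.df)
        assert fwd.p == pytest.approx(rev.p)

    def test_samples_agree_with_summary_to_machine_precision(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.normal(size=rng.integers(2, 30))
            s = welch_from_samples(a, b)
            m = welch_from_summary(a.mean(), a.std(ddof=1), a.size,
                                   b.mean(), b.std(ddof=1), b.size)
            assert s.t == pytest.approx(m.t, abs=1e-12)
            assert s.p == pytest.approx(m.p, abs=1e-12)

    def test_agrees_with_scipy_ttest_ind(self, rng):
        """Cross-library oracle: scipy's Welch implementation."""
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(3, 40)))
            b = rng.normal(0.3, 2, int(rng.integers(3, 40)))
            ours = welch_from_samples(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_df_bounds(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0, 3, 36)
        cmp = welch_from_samples(a, b)
        assert min(12, 36) - 1 <= cmp.df <= 12 + 36 - 2

    def test_matches_permutation_oracle_on_small_gaussians(self):
        """Analytic p within Monte-Carlo error of a permutation test."""
        rng = np.random.default_rng(2024)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.0, 1.0, 12)
        obs = abs(welch_from_samples(a, b).t)
        pooled = np.concatenate([a, b])
        n_perm = 100000
        keys = rng.random((n_perm, pooled.size)).argsort(axis=1)
        perms = pooled[keys]
        ga, gb = perms[:, :10], perms[:, 10:]
        t = (ga.mean(1) - gb.mean(1)) / np.sqrt(
            ga.var(1, ddof=1) / 10 + gb.var(1, ddof=1) / 12)
        p_perm = np.mean(np.abs(t) >= obs)
        p_analytic = welch_from_samples(a, b).p
        mc_err = 3.0 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_analytic - p_perm) <= mc_err + 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_from_summary(0, 1, 1, 0, 1, 10)
        with pytest.raises(DegenerateStatisticError):
            welch_from_summary(0, 0, 10, 1, 0, 10)


# ------------------------------------------------------------------ Fisher LDA

class TestFisherLda:
    def labels(self, na, nb):
        return np.array(["control"] * na + ["patient"] * nb)

    def test_axis_aligned_classes_give_unit_weight(self):
        """Means (1,0) vs (0,0) with isotropic within-class scatter -> w = (1, 0)."""
        cross = np.array([[1.0, 0], [-1.0, 0], [0, 1.0], [0, -1.0]] * 3)
        Xa = cross + [1.0, 0.0]   # exact mean (1,0), covariance prop. to I
        Xb = cross.copy()         # exact mean (0,0)
        model = fisher_lda2(np.vstack([Xa, Xb]), self.labels(12, 12))
        assert model.weights[0] == 1.0
        assert model.weights[1] == pytest.approx(0.0, abs=1e-12)
        assert model.threshold == pytest.approx(0.5, abs=1e-12)

    def test_fisher_criterion_invariant_to_feature_rescaling(self, rng):
        X = np.vstack([rng.normal(0, 1, (20, 2)) + [1, 0.5],
                       rng.normal(0, 1, (30, 2))])
        y = self.labels(20, 30)

        def separation(features):
            m = fisher_lda2(features, y)
            proj = m.project(features)
            pa, pb = proj[y == "control"], proj[y == "patient"]
            within = ((pa.size - 1) * pa.var(ddof=1)
                      + (pb.size - 1) * pb.var(ddof=1))
            return (pa.mean() - pb.mean()) ** 2 / within

        X2 = X.copy()
        X2[:, 1] = 7.3 * X2[:, 1] - 2.0
        assert separation(X) == pytest.approx(separation(X2), rel=1e-9)

    def test_matches_closed_form_oracle(self, rng):
        X = np.vstack([rng.normal(0, 1, (12, 2)) + [0.5, -0.2],
                       rng.normal(0, 1.5, (36, 2))])
        y = self.labels(12, 36)
        model = fisher_lda2(X, y)
        Xa, Xb = X[:12], X[12:]
        Sw = (11 * np.cov(Xa, rowvar=False) + 35 * np.cov(Xb, rowvar=False)) / 46
        w = np.linalg.inv(Sw) @ (Xa.mean(0) - Xb.mean(0))
        w = w / w[0]
        np.testing.assert_allclose(model.weights, w, atol=1e-10)
        assert model.threshold == pytest.approx(
            0.5 * (Xa.mean(0) @ w + Xb.mean(0) @ w), abs=1e-10)

    def test_too_small_class_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(InsufficientDataError):
            fisher_lda2(X, np.array(["control", "patient", "patient"]))


# ------------------------------------------------------------------ classification

class TestClassify:
    def test_perfectly_separated_data_scores_100(self, rng):
        Xa = rng.normal(0, 0.1, (10, 2)) + [5, 0]
        Xb = rng.normal(0, 0.1, (15, 2))
        X = np.vstack([Xa, Xb])
        y = np.array(["control"] * 10 + ["patient"] * 15)
        model = fisher_lda2(X, y)
        rep = classify_and_report(model, X, y)
        assert (rep.sensitivity_pct, rep.specificity_pct, rep.accuracy_pct) \
            == (100.0, 100.0, 100.0)

    def test_all_predicted_control_edge_case(self, rng):
        """Patients projected on the control side: sens 0, spec 100."""
        Xa = rng.normal(0, 0.1, (10, 2)) + [5, 0]
        Xb = rng.normal(0, 0.1, (15, 2))
        X = np.vstack([Xa, Xb])
        y = np.array(["control"] * 10 + ["patient"] * 15)
        model = fisher_lda2(X, y)
        shifted = X + [5, 0]  # everything lands on the control side
        rep = classify_and_report(model, shifted, y)
        assert rep.sensitivity_pct == 0.0
        assert rep.specificity_pct == 100.0

    def test_unknown_label_rejected(self, rng):
        X = np.vstack([rng.normal(0, 1, (5, 2)) + [3, 0],
                       rng.normal(0, 1, (5, 2))])
        y = np.array(["control"] * 5 + ["patient"] * 5)
        model = fisher_lda2(X, y)
        bad = y.copy().astype(object)
        bad[0] = "mystery"
        with pytest.raises(SchemaError):
            classify_and_report(model, X, bad)


# ------------------------------------------------------------------ composites

class TestCompositeIndex:
    def test_identity_weight_returns_feature(self):
        f = {"ccr": 0.2, "ctp": 0.1}
        assert composite_index(f, ("ccr", "ctp"), (1.0, 0.0)) == 0.2

    def test_linear_in_each_feature(self):
        w = (1.0, 1.337)
        a = composite_index({"ccr": 0.2, "ctp": 0.1}, ("ccr", "ctp"), w)
        b = composite_index({"ccr": 0.4, "ctp": 0.1}, ("ccr", "ctp"), w)
        c = composite_index({"ccr": 0.2, "ctp": 0.3}, ("ccr", "ctp"), w)
        assert b - a == pytest.approx(0.2)
        assert c - a == pytest.approx(1.337 * 0.2)

    def test_missing_feature_rejected(self):
        with pytest.raises(SchemaError):
            composite_index({"ccr": 0.2}, ("ccr", "nmse"), (1.0, -1.77))


# ------------------------------------------------------------------ regression

class TestRegressScore:
    def test_collinear_data_r_is_one(self):
        x = np.arange(10.0)
        res = regress_score(3.0 * x - 1.0, x)
        assert abs(res.r) == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_r_squared_equals_explained_variance_ratio(self, rng):
        x = rng.normal(size=48)
        y = 2.0 * x + rng.normal(size=48)
        res = regress_score(y, x)
        fitted = res.slope * x + res.intercept
        explained = np.var(fitted) / np.var(y)
        assert res.r ** 2 == pytest.approx(explained, rel=1e-9)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=48)
        y = 0.4 * x + rng.normal(size=48)
        res = regress_score(y, x)
        obs = abs(res.r)
        n_perm = 10000
        keys = rng.random((n_perm, x.size)).argsort(axis=1)
        xp = (x - x.mean())[keys]
        yc = y - y.mean()
        r = (xp @ yc) / np.sqrt(np.sum(xp ** 2, axis=1) * np.sum(yc ** 2))
        p_perm = np.mean(np.abs(r) >= obs)
        mc_err = 3.0 * np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / n_perm)
        assert abs(res.p - p_perm) <= mc_err + 0.01

    def test_zero_variance_index_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            regress_score([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
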