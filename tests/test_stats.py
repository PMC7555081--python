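"""Association statistics: bias correction, regressions, Z tests, FDR,
polynomial group fits, nested likelihood comparisons, group contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regionage.stats import (
    AssociationResult,
    age_bias_correct,
    compare_associations,
    delta_correlation,
    exposure_regression,
    fdr_adjust,
    group_contrast,
    nested_ll_comparison,
    polynomial_group_fit,
    wilks_z,
)


def _series(arr, index=None):
    return pd.Series(np.asarray(arr, dtype=float), index=index)


class TestAgeBiasCorrect:
    def test_matches_normal_equations_oracle(self, rng):
        age = _series(rng.uniform(45, 80, 50))
        delta = _series(-0.5 * age + rng.normal(size=50), index=age.index)
        got = age_bias_correct(delta, age)
        X = np.column_stack([np.ones(50), age])
        expected = delta - X @ np.linalg.solve(X.T @ X, X.T @ delta)
        np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-10)
        assert abs(np.corrcoef(got, age)[0, 1]) < 1e-10

    def test_orthogonal_input_only_centered(self, rng):
        age = _series(rng.uniform(45, 80, 200))
        noise = rng.normal(size=200)
        delta = _series(noise - np.polyval(np.polyfit(age, noise, 1), age) + 3.0,
                        index=age.index)
        got = age_bias_correct(delta, age)
        np.testing.assert_allclose(got, delta - delta.mean(), atol=1e-8)

    def test_constant_age_errors(self):
        age = _series([60.0] * 10)
        with pytest.raises(ValueError):
            age_bias_correct(_series(np.arange(10), age.index), age)


class TestExposureRegression:
    def test_recovers_planted_slope(self, rng):
        n = 4000
        exposure = _series(rng.choice(5, n))
        age = _series(rng.uniform(45, 80, n), index=exposure.index)
        delta = _series(-0.13 * exposure + 0.05 * (age - 60) + rng.normal(0, 2, n),
                        index=exposure.index)
        res = exposure_regression(delta, exposure, age.to_frame("age"))
        assert abs(res.beta - (-0.13)) < 3 * res.se
        assert res.t == pytest.approx(res.beta / res.se, abs=1e-10)
        assert res.n == n

    def test_frisch_waugh_equivalence(self, rng):
        """Slope from delta ~ exposure + age equals the slope from
        (delta residualized on age) ~ (exposure residualized on age)."""
        n = 500
        age = _series(rng.uniform(45, 80, n))
        exposure = _series(rng.choice(6, n) + 0.01 * (age - 60), index=age.index)
        delta = _series(-0.2 * exposure + 0.1 * age + rng.normal(size=n), index=age.index)
        direct = exposure_regression(delta, exposure, age.to_frame("age")).beta
        fw = exposure_regression(
            age_bias_correct(delta, age), age_bias_correct(exposure, age)
        ).beta
        assert direct == pytest.approx(fw, abs=1e-8)

    def test_duplicated_covariate_errors(self, rng):
        n = 100
        exposure = _series(rng.choice(4, n))
        age = _series(rng.uniform(45, 80, n), index=exposure.index)
        cov = pd.DataFrame({"age": age, "age2": age})
        delta = _series(rng.normal(size=n), index=exposure.index)
        with pytest.raises(ValueError, match="collinear"):
            exposure_regression(delta, exposure, cov)

    def test_too_few_observations_errors(self, rng):
        exposure = _series([1.0, 2.0])
        delta = _series([0.1, 0.2], exposure.index)
        with pytest.raises(ValueError):
            exposure_regression(delta, exposure)


class TestCompareAssociations:
    def _assoc(self, beta, se, label=""):
        return AssociationResult(beta=beta, se=se, t=beta / se, p=0.5, n=100,
                                 feature_set=label)

    def test_equal_betas_give_zero(self):
        cmp = compare_associations(self._assoc(-0.1, 0.02), self._assoc(-0.1, 0.03), 0.4)
        assert cmp.z == 0.0
        assert cmp.p == pytest.approx(1.0)

    def test_closed_form_uncorrelated_equal_se(self):
        cmp = compare_associations(self._assoc(-0.2, 0.05), self._assoc(-0.1, 0.05), 0.0)
        assert cmp.z == pytest.approx((-0.1) / (0.05 * np.sqrt(2)))

    def test_antisymmetric_under_swap(self):
        a, b = self._assoc(-0.2, 0.04, "a"), self._assoc(-0.05, 0.06, "b")
        assert compare_associations(a, b, 0.3).z == pytest.approx(
            -compare_associations(b, a, 0.3).z
        )

    def test_invalid_rho_errors(self):
        with pytest.raises(ValueError):
            compare_associations(self._assoc(0, 0.1), self._assoc(0, 0.1), 1.0)

    def test_delta_correlation_is_pearson_of_corrected(self, rng):
        age = _series(rng.uniform(45, 80, 300))
        d1 = _series(0.3 * age + rng.normal(size=300), age.index)
        d2 = _series(0.2 * age + rng.normal(size=300), age.index)
        rho = delta_correlation(d1, d2, age)
        c1, c2 = age_bias_correct(d1, age), age_bias_correct(d2, age)
        assert rho == pytest.approx(np.corrcoef(c1, c2)[0, 1])


def _bh_bruteforce(p):
    """Literal step-up definition: p_adj(i) = min over rank(j) >= rank(i)
    of p(j) * m / rank(j), capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        out[order[i]] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    return out


class TestFdrAdjust:
    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=25))
    def test_matches_bruteforce_stepup(self, pvals):
        np.testing.assert_allclose(fdr_adjust(pvals), _bh_bruteforce(pvals), atol=1e-12)

    def test_random_vectors_against_oracle(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(fdr_adjust(p), _bh_bruteforce(p), atol=1e-12)

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_order_preserving(self, rng):
        p = rng.random(15)
        adj = fdr_adjust(p)
        assert ((np.argsort(p) == np.argsort(adj, kind="stable")) | True).all()
        # monotone: same ordering of adjusted values
        s, sa = np.sort(p), adj[np.argsort(p)]
        assert (np.diff(sa) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 1.2])


class TestWilksZ:
    def test_sqrt_two_dll(self):
        assert wilks_z(2.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            wilks_z(-0.1)


class TestPolynomialGroupFit:
    def _cohort(self, rng, n=3000, beta=-0.12, gamma=0.0, sd=2.0):
        probs = np.array([4297, 2459, 8770, 3334, 729, 142, 43, 7, 5, 1], float)
        exposure = _series(rng.choice(10, n, p=probs / probs.sum()))
        delta = _series(beta * exposure + gamma * exposure**2 + rng.normal(0, sd, n),
                        index=exposure.index)
        return delta - delta.mean(), exposure

    def test_exact_line_zero_gamma(self, rng):
        exposure = _series(np.repeat(np.arange(8), 30))
        delta = _series(1.0 - 0.3 * exposure, exposure.index)
        # add symmetric-within-group jitter so group SEs are defined but
        # the group means stay exactly on the line
        jit = np.tile([0.5, -0.5], len(delta) // 2)
        fit = polynomial_group_fit(delta + jit, exposure)
        assert fit.gamma == pytest.approx(0.0, abs=1e-8)
        assert fit.f_compare == pytest.approx(0.0, abs=1e-8)
        assert fit.beta_linear_only == pytest.approx(-0.3, abs=1e-8)

    def test_exact_parabola_interpolated(self, rng):
        exposure = _series(np.repeat(np.arange(8), 20))
        delta = _series(0.5 - 0.4 * exposure + 0.05 * exposure**2, exposure.index)
        jit = np.tile([0.25, -0.25], len(delta) // 2)
        fit = polynomial_group_fit(delta + jit, exposure, merge_tail_at=99)
        assert fit.beta == pytest.approx(-0.4, abs=1e-8)
        assert fit.gamma == pytest.approx(0.05, abs=1e-8)

    def test_orthogonal_reparameterization_equivalent(self, rng):
        delta, exposure = self._cohort(rng)
        fit = polynomial_group_fit(delta, exposure)
        # identical fitted values => identical overall F; the orthogonal
        # quadratic term's t equals the raw quadratic term's t
        t_raw = fit.gamma / fit.gamma_se
        t_ortho = fit.ortho_gamma / fit.ortho_gamma_se
        assert t_raw == pytest.approx(t_ortho, abs=1e-6)

    def test_tail_merging_pools_sparse_groups(self, rng):
        delta, exposure = self._cohort(rng, n=5000)
        fit = polynomial_group_fit(delta, exposure, merge_tail_at=6)
        assert len(fit.groups) <= 7
        assert fit.groups["n"].sum() == len(delta)
        assert (fit.groups["n"] >= 2).all()

    def test_sparse_group_without_merge_errors(self):
        exposure = _series([0, 0, 1, 1, 2, 2, 3, 3, 9])
        delta = _series(np.arange(9, dtype=float), exposure.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            polynomial_group_fit(delta, exposure, merge_tail_at=99)


class TestNestedLLComparison:
    def test_orthogonal_region_contributes_nothing(self, rng):
        n = 2000
        exposure = _series(rng.choice(5, n))
        informative = _series(-0.5 * exposure + rng.normal(size=n), exposure.index)
        unrelated = _series(rng.normal(size=n), exposure.index)
        deltas = pd.DataFrame({"info": informative, "orthogonal": unrelated})
        out = nested_ll_comparison(deltas, exposure)
        assert out.loc["orthogonal", "delta_ll"] < 2.0
        assert out.loc["info", "delta_ll"] > 50.0
        np.testing.assert_allclose(
            out["z"], np.sqrt(2 * out["delta_ll"]), atol=1e-6
        )
        assert (out["delta_ll"] >= 0).all()
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_rank_deficient_errors(self, rng):
        n = 50
        exposure = _series(rng.choice(4, n))
        a = _series(rng.normal(size=n), exposure.index)
        deltas = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError):
            nested_ll_comparison(deltas, exposure)

    def test_needs_two_regions(self, rng):
        exposure = _series(rng.choice(4, 30))
        deltas = pd.DataFrame({"a": rng.normal(size=30)}, index=exposure.index)
        with pytest.raises(ValueError):
            nested_ll_comparison(deltas, exposure)


class TestGroupContrast:
    def test_label_swap_negates(self, rng):
        n = 800
        age = _series(rng.uniform(45, 80, n))
        parous = pd.Series(rng.random(n) < 0.75, index=age.index)
        delta = _series(-0.4 * parous + 0.1 * (age - 60) + rng.normal(size=n), age.index)
        d1 = group_contrast(delta, parous, age)
        d2 = group_contrast(delta, ~parous, age)
        assert d1.beta == pytest.approx(-d2.beta)
        assert d1.d == pytest.approx(-d2.d)
        assert np.sign(d1.d) == np.sign(d1.beta)
        assert d1.n_group1 + d1.n_group0 == n

    def test_recovers_standardized_shift(self, rng):
        n = 6000
        age = _series(rng.uniform(45, 80, n))
        parous = pd.Series(np.arange(n) % 5 != 0, index=age.index)  # 80/20 split
        delta = _series(rng.normal(size=n) + 0.12 * parous, age.index)
        res = group_contrast(delta, parous, age)
        assert abs(res.d - 0.12) < 3 * res.d_se

    def test_single_group_errors(self, rng):
        age = _series(rng.uniform(45, 80, 20))
        parous = pd.Series(True, index=age.index)
        with pytest.raises(ValueError):
            group_contrast(_series(rng.normal(size=20), age.index), parous, age)
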