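"""Inference on brain-age deltas and their exposure associations.

Covers: age-bias correction of deltas; OLS exposure regressions with
optional covariates; the correlated-estimates Z test for comparing two
regression coefficients estimated on the same participants,

    Z = (b1 - b2) / sqrt(s1^2 + s2^2 - 2 rho s1 s2),

where rho is the correlation inducing dependence between the two
estimates (operationalized here as the Pearson correlation between the
two age-corrected delta vectors); Benjamini-Hochberg FDR adjustment;
weighted polynomial fits to parity-group means; leave-one-out
log-likelihood comparisons of nested OLS models with the Wilks chi^2(1)
reference (Z reported as sqrt(2 dLL)); and the parous/nulliparous group
contrast with Cohen's d.

All p-values are two-sided; standard errors are classical OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    beta: float          # years per unit exposure
    se: float
    t: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()
    feature_set: str = ""
    p_adj: float = float("nan")


@dataclass
class ComparisonResult:
    z: float
    rho: float
    p: float
    pair: tuple[str, str] = ("", "")


@dataclass
class PolynomialFit:
    beta: float
    beta_se: float
    gamma: float
    gamma_se: float
    f_linear: float          # overall F of the degree-1 fit
    p_linear: float
    f_quadratic: float       # overall F of the degree-2 fit
    p_quadratic: float
    f_compare: float         # linear vs quadratic
    p_compare: float
    beta_linear_only: float  # slope of the degree-1 fit
    beta_linear_only_se: float
    ortho_beta: float        # degree-2 fit in orthogonal-polynomial basis
    ortho_beta_se: float
    ortho_gamma: float
    ortho_gamma_se: float
    groups: pd.DataFrame = field(repr=False, default=None)


@dataclass
class GroupDifference:
    beta: float
    se: float
    t: float
    p: float
    d: float
    d_se: float
    n_group1: int
    n_group0: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def age_bias_correct(delta: pd.Series, age: pd.Series) -> pd.Series:
    """Residualize the brain-age delta on intercept + chronological age.

    Removes the regression-to-the-mean age bias of brain-age predictions;
    the output is exactly uncorrelated with age.
    """
    if not delta.index.equals(age.index):
        raise ValueError("delta and age must share the same index")
    a = age.to_numpy(dtype=float)
    if np.var(a) == 0:
        raise ValueError("constant age: correction undefined")
    X = np.column_stack([np.ones_like(a), a])
    beta, *_ = np.linalg.lstsq(X, delta.to_numpy(dtype=float), rcond=None)
    return pd.Series(delta.to_numpy() - X @ beta, index=delta.index, name="delta_corrected")


def _design_frame(exposure: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    parts = [exposure.rename("exposure").astype(float)]
    names: list[str] = []
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
                parts.append(s.astype(float))
            else:
                parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
            names.append(col)
    X = sm.add_constant(pd.concat(parts, axis=1))
    return X


def exposure_regression(
    delta: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    feature_set: str = "",
) -> AssociationResult:
    """OLS of delta on exposure (+ covariates); reports the exposure slope.

    Categorical covariates are one-hot encoded with the first level
    dropped.  Raises on a rank-deficient design.
    """
    X = _design_frame(exposure, covariates)
    y = delta.to_numpy(dtype=float)
    arr = X.to_numpy(dtype=float)
    if len(y) <= arr.shape[1]:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        kept: list[str] = []
        bad: list[str] = []
        for c in X.columns:
            if np.linalg.matrix_rank(X[kept + [c]].to_numpy(dtype=float)) == len(kept):
                bad.append(c)
            else:
                kept.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, arr).fit()
    j = list(X.columns).index("exposure")
    cov_names = tuple(c for c in covariates.columns) if covariates is not None else ()
    return AssociationResult(
        beta=float(fit.params[j]),
        se=float(fit.bse[j]),
        t=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]),
        n=int(fit.nobs),
        covariates=cov_names,
        feature_set=feature_set,
    )


def compare_associations(
    a: AssociationResult, b: AssociationResult, rho: float
) -> ComparisonResult:
    """Correlated-estimates Z test for the difference of two slopes."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    var = a.se**2 + b.se**2 - 2.0 * rho * a.se * b.se
    if var <= 0:
        raise ValueError("non-positive variance under the radical")
    z = (a.beta - b.beta) / np.sqrt(var)
    return ComparisonResult(
        z=float(z),
        rho=float(rho),
        p=float(2.0 * sps.norm.sf(abs(z))),
        pair=(a.feature_set, b.feature_set),
    )


def delta_correlation(delta_a: pd.Series, delta_b: pd.Series, age: pd.Series) -> float:
    """Pearson correlation of two age-corrected delta vectors (the rho of
    the correlated-estimates Z test)."""
    ca = age_bias_correct(delta_a, age)
    cb = age_bias_correct(delta_b, age)
    return float(np.corrcoef(ca.to_numpy(), cb.to_numpy())[0, 1])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilks_z(delta_ll: float) -> float:
    """Z equivalent of a 1-df log-likelihood difference: sqrt(2 dLL)."""
    if delta_ll < 0:
        raise ValueError("delta_ll must be non-negative")
    return float(np.sqrt(2.0 * delta_ll))


def polynomial_group_fit(
    delta_corrected: pd.Series,
    exposure: pd.Series,
    merge_tail_at: int = 6,
) -> PolynomialFit:
    """Weighted polynomial fits to parity-group means of corrected deltas.

    Exposure groups with value >= ``merge_tail_at`` are pooled (placed at
    their count-weighted mean exposure).  Group means get SE = SD/sqrt(n);
    weighted least squares (weights 1/SE^2) fits a line and a parabola to
    the group means; overall F statistics per model and an F comparing the
    two are reported, plus the degree-2 fit re-expressed in a
    weighted-orthonormal polynomial basis (identical fitted values).
    """
    e = exposure.to_numpy(dtype=float)
    y = delta_corrected.to_numpy(dtype=float)
    g = np.where(e >= merge_tail_at, -1, e)  # -1 marks the pooled tail
    rows = []
    for val in np.unique(g):
        m = g == val
        if m.sum() < 2:
            raise ValueError(
                f"exposure group {val if val >= 0 else f'>={merge_tail_at}'} has "
                "fewer than 2 members; SE undefined"
            )
        x = e[m].mean()  # count-weighted mean exposure of the group
        rows.append(
            {"exposure": x, "mean": y[m].mean(),
             "se": y[m].std(ddof=1) / np.sqrt(m.sum()), "n": int(m.sum())}
        )
    groups = pd.DataFrame(rows).sort_values("exposure").reset_index(drop=True)
    k = len(groups)
    if k < 4:
        raise ValueError("need >= 4 exposure groups after merging")
    x = groups["exposure"].to_numpy()
    m = groups["mean"].to_numpy()
    w = 1.0 / groups["se"].to_numpy() ** 2

    def _wls(deg: int):
        X = np.vander(x, deg + 1, increasing=True)
        fit = sm.WLS(m, X, weights=w).fit()
        rss = float((w * fit.resid**2).sum())
        return fit, rss, X

    fit0_rss = float((w * (m - np.average(m, weights=w)) ** 2).sum())
    fit1, rss1, _ = _wls(1)
    fit2, rss2, X2 = _wls(2)

    def _overall_f(rss_model, p_slopes):
        dfe = k - p_slopes - 1
        if rss_model < 1e-12 * max(fit0_rss, 1.0):
            return float("inf"), 0.0
        f = ((fit0_rss - rss_model) / p_slopes) / (rss_model / dfe)
        return float(f), float(sps.f.sf(f, p_slopes, dfe))

    f1, p1 = _overall_f(rss1, 1)
    f2, p2 = _overall_f(rss2, 2)
    # guard against exact fits, where both residual sums vanish
    tiny = 1e-12 * max(fit0_rss, 1.0)
    num = max(rss1 - rss2, 0.0)
    den = rss2 / (k - 3)
    fc = 0.0 if num < tiny else (np.inf if den < tiny else num / den)
    pc = float(sps.f.sf(fc, 1, k - 3))

    # weighted-orthonormal basis (QR of sqrt(w)-scaled Vandermonde)
    sw = np.sqrt(w)
    Q, R = np.linalg.qr(sw[:, None] * X2)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs  # fix sign convention so the basis is reproducible
    fit_o = sm.WLS(m, Q / sw[:, None], weights=w).fit()

    return PolynomialFit(
        beta=float(fit2.params[1]), beta_se=float(fit2.bse[1]),
        gamma=float(fit2.params[2]), gamma_se=float(fit2.bse[2]),
        f_linear=f1, p_linear=p1,
        f_quadratic=f2, p_quadratic=p2,
        f_compare=float(fc), p_compare=pc,
        beta_linear_only=float(fit1.params[1]), beta_linear_only_se=float(fit1.bse[1]),
        ortho_beta=float(fit_o.params[1]), ortho_beta_se=float(fit_o.bse[1]),
        ortho_gamma=float(fit_o.params[2]), ortho_gamma_se=float(fit_o.bse[2]),
        groups=groups,
    )


def nested_ll_comparison(
    region_deltas: pd.DataFrame, exposure: pd.Series
) -> pd.DataFrame:
    """Leave-one-region-out log-likelihood comparison.

    Fits OLS of exposure on all region deltas (full model) and with each
    region left out (reduced); per region reports dLL = LL_full -
    LL_reduced (>= 0), Z = sqrt(2 dLL), the chi^2(1) tail p, and BH-FDR
    adjusted p across regions.
    """
    if region_deltas.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    X_full = sm.add_constant(region_deltas.astype(float))
    arr = X_full.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("rank-deficient region-delta design")
    y = exposure.to_numpy(dtype=float)
    ll_full = sm.OLS(y, arr).fit().llf
    rows = []
    for col in region_deltas.columns:
        X_red = sm.add_constant(region_deltas.drop(columns=[col]).astype(float))
        ll_red = sm.OLS(y, X_red.to_numpy()).fit().llf
        dll = max(float(ll_full - ll_red), 0.0)
        rows.append(
            {"region": col, "delta_ll": dll, "z": wilks_z(dll),
             "p": float(sps.chi2.sf(2.0 * dll, df=1))}
        )
    out = pd.DataFrame(rows).set_index("region")
    out["p_adj"] = fdr_adjust(out["p"].to_numpy())
    return out


def group_contrast(
    delta: pd.Series, parous: pd.Series, age: pd.Series
) -> GroupDifference:
    """Parous vs nulliparous contrast: OLS of delta on indicator + age,
    plus Cohen's d on age-corrected deltas with its large-sample SE."""
    g = parous.astype(bool)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be non-empty")
    res = exposure_regression(
        delta, g.astype(float).rename("parous"),
        covariates=age.to_frame("age"), feature_set="group_contrast",
    )
    corrected = age_bias_correct(delta, age)
    x1, x0 = corrected[g], corrected[~g]
    sp = np.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / (n1 + n0 - 2)
    )
    d = float((x1.mean() - x0.mean()) / sp)
    d_se = float(np.sqrt((n1 + n0) / (n1 * n0) + d**2 / (2 * (n1 + n0))))
    return GroupDifference(
        beta=res.beta, se=res.se, t=res.t, p=res.p,
        d=d, d_se=d_se, n_group1=n1, n_group0=n0,
    )
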