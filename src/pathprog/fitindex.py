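"""Model-adequacy measures for covariance-structure fits.

Five measures assess whether a path model reproduces the sample covariance
within random fluctuation: the model chi-square (non-significant is good),
the chi-square/df ratio (< 2 acceptable), CFI and TLI against an
independence baseline (> 0.95 desired), RMSEA with a 90% confidence
interval from the noncentral chi-square (< 0.05 close fit), and SRMR
(< 0.08 reliable fit).  A Satorra-Bentler-type scaled chi-square provides
the robust (MLR) correction when raw data with fourth moments are
available.

Conventions that differ across SEM software are explicit parameters here:
the chi-square multiplier is (n-1)*F by default (``convention='n-1'``) with
``'n'`` available, and the independence baseline frees variances while
fixing every covariance at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.tsa.tsatools import duplication_matrix

from .cohort import PatientTable
from .moments import MomentSet, compute_moments, cov_to_cor

__all__ = [
    "FitIndexReport",
    "chi_square_test",
    "baseline_model",
    "cfi_tli",
    "rmsea_with_ci",
    "srmr",
    "satorra_bentler_scaling",
    "fit_index_report",
]

#: Conventional adequacy cutoffs, annotated in rendered reports.
CUTOFFS = {"chi2_df_ratio": 2.0, "cfi": 0.95, "tli": 0.95, "rmsea": 0.05,
           "srmr": 0.08}


def _multiplier(n: int, convention: str) -> float:
    if convention == "n-1":
        return float(n - 1)
    if convention == "n":
        return float(n)
    raise ValueError("convention must be 'n-1' or 'n'")


def chi_square_test(
    F_ML: float, n: int, df: int, convention: str = "n-1"
) -> tuple[float, float]:
    """chi2 = multiplier * F with its upper-tail p-value.

    For a saturated model (df = 0) the p-value is defined as 1.
    """
    if F_ML < 0:
        raise ValueError("discrepancy must be nonnegative")
    if df < 0:
        raise ValueError("df must be nonnegative")
    chi2 = _multiplier(n, convention) * F_ML
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return float(chi2), p


def baseline_model(
    moments: MomentSet, variables: Sequence[str] | None = None,
    convention: str = "n-1",
) -> tuple[float, int]:
    """Independence baseline: all covariances zero, variances free.

    F_baseline = -ln|R| with R the sample correlation matrix, since the
    implied covariance is diag(S).  Returns (chi2_baseline, df_baseline)
    with df = p(p-1)/2.
    """
    ms = moments if variables is None else moments.subset(variables)
    sign, logdet = np.linalg.slogdet(ms.corr)
    if sign <= 0:
        raise ValueError("sample correlation matrix not positive definite")
    F_b = max(-float(logdet), 0.0)
    p = ms.p
    chi2_b = _multiplier(ms.n, convention) * F_b
    return chi2_b, p * (p - 1) // 2


def cfi_tli(
    chi2: float, df: int, chi2_baseline: float, df_baseline: int
) -> tuple[float, float]:
    """Comparative Fit Index and Tucker-Lewis Index.

    CFI = 1 - max(chi2-df, 0)/max(chi2-df, chi2_b-df_b, 0), clipped to
    [0, 1].  TLI = (chi2_b/df_b - chi2/df)/(chi2_b/df_b - 1); it is not
    bounded above by 1.  A degenerate baseline (chi2_b <= df_b) means the
    data look independent already; CFI is 1 by convention then.
    """
    if df_baseline <= 0:
        raise ValueError("baseline df must be positive")
    num = max(chi2 - df, 0.0)
    denom = max(chi2 - df, chi2_baseline - df_baseline, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    base_ratio = chi2_baseline / df_baseline
    if df > 0 and base_ratio != 1.0:
        tli = (base_ratio - chi2 / df) / (base_ratio - 1.0)
    else:
        tli = 1.0
    return cfi, float(tli)


def rmsea_with_ci(
    chi2: float, df: int, n: int, confidence: float = 0.90,
    convention: str = "n-1",
) -> tuple[float, float, float]:
    """RMSEA point estimate with a confidence interval.

    Point estimate sqrt(max(chi2 - df, 0)/(df * n_eff)), n_eff per the
    multiplier convention.  The CI inverts the noncentral chi-square in its
    noncentrality parameter lambda: the lower bound solves
    P(X <= chi2 | lambda) = 1 - (1-conf)/2, the upper bound solves
    P(X <= chi2 | lambda) = (1-conf)/2, each bound mapped through
    sqrt(lambda/(df * n_eff)).  Bounds that have no root (already-good fit)
    are 0.
    """
    if df <= 0:
        raise ValueError("RMSEA undefined for df = 0")
    if n <= 1:
        raise ValueError("need n > 1")
    n_eff = _multiplier(n, convention)
    point = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_eff)))
    alpha = (1.0 - confidence) / 2.0

    def solve(target: float) -> float:
        # find lambda >= 0 with ncx2.cdf(chi2, df, lambda) = target;
        # the cdf is strictly decreasing in lambda
        f0 = stats.ncx2.cdf(chi2, df, 1e-12) - target
        if f0 <= 0:
            return 0.0
        hi = max(chi2, 1.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        lam = optimize.brentq(
            lambda l: stats.ncx2.cdf(chi2, df, l) - target, 1e-12, hi,
            xtol=1e-8, rtol=1e-12,
        )
        return float(lam)

    lam_lower = solve(1.0 - alpha)
    lam_upper = solve(alpha)
    lower = float(np.sqrt(lam_lower / (df * n_eff)))
    upper = float(np.sqrt(lam_upper / (df * n_eff)))
    return point, lower, upper


def srmr(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """Standardized root mean square residual.

    Root mean square of the differences between sample and model-implied
    correlations over the lower triangle including the diagonal (diagonal
    residuals vanish whenever the implied variances match the sample ones,
    as they do for this model class).
    """
    sample_cov = np.asarray(sample_cov, dtype=float)
    implied_cov = np.asarray(implied_cov, dtype=float)
    if sample_cov.shape != implied_cov.shape:
        raise ValueError("dimension mismatch between sample and implied")
    r_s, _ = cov_to_cor(sample_cov)
    r_i, _ = cov_to_cor(implied_cov)
    # correlation residual diagonal is zero by construction; keep variance
    # residuals visible by comparing standardized diagonals too
    d_s, d_i = np.sqrt(np.diag(sample_cov)), np.sqrt(np.diag(implied_cov))
    np.fill_diagonal(r_i, (d_i / d_s) ** 2)
    np.fill_diagonal(r_s, 1.0)
    idx = np.tril_indices(sample_cov.shape[0])
    resid = (r_s - r_i)[idx]
    return float(np.sqrt(np.mean(resid**2)))


def _vech_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Column-major lower-triangle indices, matching the duplication matrix."""
    rows = np.concatenate([np.arange(j, p) for j in range(p)])
    cols = np.concatenate([np.full(p - j, j) for j in range(p)])
    return rows, cols


def _vech(a: np.ndarray) -> np.ndarray:
    return a[_vech_indices(a.shape[0])]


def _model_jacobian(spec, Sxx: np.ndarray, b: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """d vech(Sigma) / d theta for theta = (vech Phi, free b, vech Psi)."""
    from .pathmodel import _implied_cov

    k, q = spec.k_total, spec.q
    mask = spec.free_mask()
    free_idx = np.argwhere(mask)
    tril_k = np.tril_indices(k)
    tril_q = np.tril_indices(q)

    def pack():
        return np.concatenate([Sxx[tril_k], b[free_idx[:, 0], free_idx[:, 1]],
                               psi[tril_q]])

    def sigma_of(theta: np.ndarray) -> np.ndarray:
        nk = len(tril_k[0])
        nb = len(free_idx)
        phi = np.zeros((k, k))
        phi[tril_k] = theta[:nk]
        phi = phi + np.tril(phi, -1).T
        bb = np.zeros((k, q))
        bb[free_idx[:, 0], free_idx[:, 1]] = theta[nk:nk + nb]
        ps = np.zeros((q, q))
        ps[tril_q] = theta[nk + nb:]
        ps = ps + np.tril(ps, -1).T
        return _vech(_implied_cov(phi, bb, ps))

    theta0 = pack()
    m = len(_vech(_implied_cov(Sxx, b, psi)))
    jac = np.empty((m, len(theta0)))
    h = 1e-6
    for t in range(len(theta0)):
        tp, tm = theta0.copy(), theta0.copy()
        step = h * max(1.0, abs(theta0[t]))
        tp[t] += step
        tm[t] -= step
        jac[:, t] = (sigma_of(tp) - sigma_of(tm)) / (2 * step)
    return jac


def satorra_bentler_scaling(
    table: PatientTable, spec, convention: str = "n-1"
) -> tuple[float, float]:
    """Robust scaling factor and scaled chi-square from raw data.

    Estimates the asymptotic covariance Gamma of the half-vectorized sample
    covariance from centered fourth moments, forms the residual weight
    operator U = W - W D (D'WD)^-1 D'W with W the normal-theory weight and
    D the model Jacobian, and returns (c, chi2/c) with c = tr(U Gamma)/df.
    Under multivariate normality c -> 1; heavy tails push c above 1,
    shrinking the chi-square.
    """
    from .pathmodel import count_degrees_of_freedom, fit_ml

    fit = fit_ml(table, spec)
    df = count_degrees_of_freedom(spec)
    if df == 0:
        raise ValueError("scaling undefined for a saturated model (df = 0)")
    chi2, _ = fit.chi_square(convention)

    names = spec.variables
    frame = table.data.loc[:, names].dropna()
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if n < p * (p + 1) // 2:
        import warnings

        warnings.warn(
            "n is small relative to the number of covariance moments; "
            "the robust scaling factor may be unstable"
        )
    Xc = X - X.mean(axis=0)
    # d_t = vech(xc xc'); Gamma = asymptotic covariance of sqrt(n)*vech(S)
    idx = _vech_indices(p)
    D_t = Xc[:, idx[0]] * Xc[:, idx[1]]
    Gamma = np.cov(D_t, rowvar=False, ddof=0)

    sigma_inv = np.linalg.inv(fit.implied_cov)
    Dup = np.asarray(duplication_matrix(p), dtype=float)
    W = 0.5 * Dup.T @ np.kron(sigma_inv, sigma_inv) @ Dup
    k = spec.k_total
    Delta = _model_jacobian(spec, fit.sample_cov[:k, :k], fit.b, fit.psi)
    WD = W @ Delta
    U = W - WD @ np.linalg.solve(Delta.T @ WD, WD.T)
    c = float(np.trace(U @ Gamma)) / df
    if c <= 0:
        raise RuntimeError("nonpositive scaling factor; inspect the data")
    return c, chi2 / c


@dataclass
class FitIndexReport:
    """The five adequacy measures plus the optional robust correction."""

    chi2: float
    df: int
    pvalue: float
    chi2_df_ratio: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    srmr: float
    scaling_factor: float | None = None
    chi2_scaled: float | None = None
    pvalue_scaled: float | None = None

    def to_dict(self) -> dict:
        d = {
            "chi2": self.chi2, "df": self.df, "pvalue": self.pvalue,
            "chi2_df_ratio": self.chi2_df_ratio, "cfi": self.cfi,
            "tli": self.tli, "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90), "srmr": self.srmr,
        }
        if self.scaling_factor is not None:
            d.update(scaling_factor=self.scaling_factor,
                     chi2_scaled=self.chi2_scaled,
                     pvalue_scaled=self.pvalue_scaled)
        return d

    def to_text(self) -> str:
        ok = lambda cond: "ok" if cond else "POOR"
        lines = [
            f"chi-square        {self.chi2:8.2f}  (df = {self.df}, "
            f"P = {self.pvalue:.2f})  [{ok(self.pvalue > 0.05)}]",
            (f"chi-square / df   {self.chi2_df_ratio:8.2f}  "
             f"[< {CUTOFFS['chi2_df_ratio']:.1f}: {ok(self.chi2_df_ratio < 2)}]"
             if self.df > 0 else
             "chi-square / df        --  (saturated model, df = 0)"),
            f"CFI               {self.cfi:8.2f}  "
            f"[> {CUTOFFS['cfi']:.2f}: {ok(self.cfi > 0.95)}]",
            f"TLI               {self.tli:8.2f}  "
            f"[> {CUTOFFS['tli']:.2f}: {ok(self.tli > 0.95)}]",
            f"RMSEA             {self.rmsea:8.3f}  "
            f"(90% CI {self.rmsea_ci90[0]:.3f} to {self.rmsea_ci90[1]:.3f})  "
            f"[< {CUTOFFS['rmsea']:.2f}: {ok(self.rmsea < 0.05)}]",
            f"SRMR              {self.srmr:8.3f}  "
            f"[< {CUTOFFS['srmr']:.2f}: {ok(self.srmr < 0.08)}]",
        ]
        if self.scaling_factor is not None:
            lines.append(
                f"robust chi-square {self.chi2_scaled:8.2f}  "
                f"(scaling {self.scaling_factor:.3f}, P = {self.pvalue_scaled:.2f})"
            )
        return "\n".join(lines)


def fit_index_report(
    fit, moments: MomentSet | None = None, convention: str = "n-1",
    table: PatientTable | None = None,
) -> FitIndexReport:
    """Assemble the full adequacy report for a fitted path model.

    ``moments`` defaults to the moments the model was fitted on; ``table``
    (raw data) enables the robust scaled chi-square when the fit's spec
    requests the MLR estimator.
    """
    chi2, p = fit.chi_square(convention)
    df = fit.df
    if moments is None:
        from .moments import MomentSet as _MS, cov_to_cor as _c2c

        corr, sds = _c2c(fit.sample_cov)
        moments = _MS(fit.spec.variables, fit.n, fit.means, sds, corr)
    chi2_b, df_b = baseline_model(moments, fit.spec.variables, convention)
    cfi, tli = cfi_tli(chi2, df, chi2_b, df_b)
    if df > 0:
        rmsea, lo, hi = rmsea_with_ci(chi2, df, fit.n, convention=convention)
        ratio = chi2 / df
    else:
        rmsea, lo, hi = 0.0, 0.0, 0.0
        ratio = float("nan")
    s = srmr(fit.sample_cov, fit.implied_cov)
    report = FitIndexReport(chi2, df, p, ratio, cfi, tli, rmsea, (lo, hi), s)
    if fit.spec.estimator == "MLR" and table is not None and df > 0:
        c, chi2_sc = satorra_bentler_scaling(table, fit.spec, convention)
        report.scaling_factor = c
        report.chi2_scaled = chi2_sc
        report.pvalue_scaled = float(stats.chi2.sf(chi2_sc, df))
    return report
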