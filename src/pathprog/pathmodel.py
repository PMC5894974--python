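"""Joint linear path model: several outcomes regressed on shared predictors.

The model is a structural equation model among observed variables only.
With predictors x (exogenous, moments fixed at their sample values) and
outcomes y:

    y = a + b' x + e,        e ~ (0, Psi),  Psi unstructured

Selected paths b[i, j] may be constrained to zero; everything else is free,
including all residual covariances in Psi.  The model-implied covariance is

    Sigma = [[ Sxx,        Sxx b      ],
             [ b' Sxx,  b' Sxx b + Psi]]

and fitting minimizes the maximum-likelihood discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^{-1}) - ln|S| - p .

When every outcome shares the same free-predictor set (the usual case here:
eliminated predictors have *all* their paths fixed at zero), the minimizer
is available in closed form as per-equation least squares on the retained
predictors; otherwise a quasi-Newton iteration with analytic gradient is
used.  The closed form doubles as an internal cross-check of the iterative
path.

Degrees of freedom follow covariance-moment counting: p(p+1)/2 sample
moments minus free parameters, which reduces to the number of
zero-constrained paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort import PatientTable
from .moments import MomentSet, compute_moments

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "count_degrees_of_freedom",
    "fit_ml",
    "ml_discrepancy",
    "standardize",
    "explained_variance",
    "wald_pvalues",
    "single_predictor_sensitivity",
    "important_effects",
]


@dataclass(frozen=True)
class PathModelSpec:
    """Which paths exist: outcomes, predictors, and paths fixed at zero.

    ``zero_paths`` is a set of (predictor, outcome) pairs constrained to 0.
    A predictor with every path zeroed remains in the model's variable set
    (its covariances with everything are still modeled) but carries no
    regression — this is how eliminated predictors stay in the degrees-of-
    freedom accounting.  ``estimator`` selects plain ML or MLR (ML point
    estimates with a robust scaled chi-square; requires raw data).
    """

    outcomes: tuple[str, ...]
    predictors: tuple[str, ...]
    zero_paths: frozenset[tuple[str, str]] = frozenset()
    estimator: str = "ML"

    def __init__(self, outcomes, predictors, zero_paths=(), estimator="ML"):
        object.__setattr__(self, "outcomes", tuple(outcomes))
        object.__setattr__(self, "predictors", tuple(predictors))
        object.__setattr__(self, "zero_paths", frozenset(tuple(zp) for zp in zero_paths))
        object.__setattr__(self, "estimator", estimator)
        if estimator not in ("ML", "MLR"):
            raise ValueError("estimator must be 'ML' or 'MLR'")
        names = self.outcomes + self.predictors
        if len(set(names)) != len(names):
            raise ValueError("outcome/predictor names must be unique")
        for pred, out in self.zero_paths:
            if pred not in self.predictors or out not in self.outcomes:
                raise ValueError(f"zero path ({pred!r}, {out!r}) outside the spec")
        if not self.retained_predictors:
            raise ValueError("no predictor has a free path")

    @property
    def q(self) -> int:
        return len(self.outcomes)

    @property
    def k_total(self) -> int:
        return len(self.predictors)

    @property
    def variables(self) -> list[str]:
        """Model variable order: predictors first, then outcomes."""
        return list(self.predictors) + list(self.outcomes)

    def free_mask(self) -> np.ndarray:
        """Boolean (k_total, q) mask of free paths."""
        mask = np.ones((self.k_total, self.q), dtype=bool)
        for pred, out in self.zero_paths:
            mask[self.predictors.index(pred), self.outcomes.index(out)] = False
        return mask

    @property
    def retained_predictors(self) -> tuple[str, ...]:
        """Predictors with at least one free path."""
        mask = np.ones((len(self.predictors), len(self.outcomes)), dtype=bool)
        for pred, out in self.zero_paths:
            mask[self.predictors.index(pred), self.outcomes.index(out)] = False
        return tuple(p for p, row in zip(self.predictors, mask) if row.any())

    @property
    def eliminated_predictors(self) -> tuple[str, ...]:
        retained = set(self.retained_predictors)
        return tuple(p for p in self.predictors if p not in retained)

    def drop_predictor(self, name: str) -> "PathModelSpec":
        """Fix every path of ``name`` at zero (backward-elimination step)."""
        if name not in self.predictors:
            raise KeyError(f"{name!r} not a predictor")
        extra = {(name, out) for out in self.outcomes}
        return PathModelSpec(self.outcomes, self.predictors,
                             self.zero_paths | extra, self.estimator)

    def has_equal_regressors(self) -> bool:
        """True when every predictor's paths are all-free or all-zero."""
        mask = self.free_mask()
        return bool(np.all(mask.all(axis=1) | (~mask).all(axis=1)))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "outcomes": list(self.outcomes),
            "predictors": list(self.predictors),
            "zero_paths": sorted([list(zp) for zp in self.zero_paths]),
            "estimator": self.estimator,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "PathModelSpec":
        return cls(obj["outcomes"], obj["predictors"], obj.get("zero_paths", ()),
                   obj.get("estimator", "ML"))


def count_degrees_of_freedom(spec: PathModelSpec) -> int:
    """Model df by moment-minus-parameter counting.

    Sample covariance moments: p(p+1)/2 with p = k_total + q.  Free
    parameters: k(k+1)/2 exogenous (co)variances + free paths + q(q+1)/2
    residual (co)variances.  The difference equals the number of
    zero-constrained paths.
    """
    k, q = spec.k_total, spec.q
    p = k + q
    free_paths = int(spec.free_mask().sum())
    df = p * (p + 1) // 2 - (k * (k + 1) // 2 + free_paths + q * (q + 1) // 2)
    assert df == len(spec.zero_paths)
    return df


def ml_discrepancy(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (>= 0, 0 iff Sigma = S)."""
    s_sign, s_logdet = np.linalg.slogdet(sample_cov)
    i_sign, i_logdet = np.linalg.slogdet(implied_cov)
    if s_sign <= 0 or i_sign <= 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    p = sample_cov.shape[0]
    tr = float(np.trace(np.linalg.solve(implied_cov, sample_cov)))
    return max(float(i_logdet + tr - s_logdet - p), 0.0)


@dataclass
class PathModelFit:
    """Result of fitting a :class:`PathModelSpec`.

    ``b`` and ``B`` are (k_total, q) unstandardized and standardized path
    matrices with exact zeros at constrained entries; ``se``/``pvals`` are
    NaN there.  ``psi`` is the residual covariance of the outcomes,
    ``implied_cov`` the model-implied covariance over predictors+outcomes
    in spec order.  ``r2``/``r2_adj`` are per-outcome explained variances
    (adjusted with k = number of retained predictors).
    """

    spec: PathModelSpec
    n: int
    b: np.ndarray
    intercepts: np.ndarray
    B: np.ndarray
    psi: np.ndarray
    implied_cov: np.ndarray
    sample_cov: np.ndarray
    F_ML: float
    df: int
    r2: np.ndarray
    r2_adj: np.ndarray
    se: np.ndarray
    pvals: np.ndarray
    sds: np.ndarray  # sample SDs in spec variable order
    means: np.ndarray
    converged: bool = True
    n_iter: int = 0
    method: str = "closed_form"

    def chi_square(self, convention: str = "n-1") -> tuple[float, float]:
        """Model chi-square and its upper-tail p-value."""
        from .fitindex import chi_square_test

        return chi_square_test(self.F_ML, self.n, self.df, convention)

    def path(self, predictor: str, outcome: str, standardized: bool = True) -> float:
        i = self.spec.predictors.index(predictor)
        j = self.spec.outcomes.index(outcome)
        return float((self.B if standardized else self.b)[i, j])

    def residual_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.psi))
        rc = self.psi / np.outer(d, d)
        np.fill_diagonal(rc, 1.0)
        return rc

    def coefficient_frame(self):
        """Long-format table of free paths: b, se, p, B per (outcome, predictor)."""
        import pandas as pd

        mask = self.spec.free_mask()
        rows = []
        for j, out in enumerate(self.spec.outcomes):
            for i, pred in enumerate(self.spec.predictors):
                if mask[i, j]:
                    rows.append(
                        {"outcome": out, "predictor": pred, "b": self.b[i, j],
                         "se": self.se[i, j], "p": self.pvals[i, j],
                         "B": self.B[i, j]}
                    )
        return pd.DataFrame(rows)


def _closed_form_fit(S: np.ndarray, spec: PathModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-equation least squares on the retained predictors.

    Valid as the exact ML optimum when all outcomes share one regressor set.
    Returns (b over all predictors with zero rows for eliminated ones, psi).
    """
    k, q = spec.k_total, spec.q
    ridx = [spec.predictors.index(p) for p in spec.retained_predictors]
    Sxx = S[np.ix_(ridx, ridx)]
    Sxy = S[np.ix_(ridx, range(k, k + q))]
    Syy = S[k:, k:]
    b_ret = np.linalg.solve(Sxx, Sxy)
    psi = Syy - Sxy.T @ b_ret
    b = np.zeros((k, q))
    b[ridx, :] = b_ret
    return b, (psi + psi.T) / 2


def _implied_cov(Sxx: np.ndarray, b: np.ndarray, psi: np.ndarray) -> np.ndarray:
    sxy = Sxx @ b
    return np.block([[Sxx, sxy], [sxy.T, b.T @ sxy + psi]])


def _iterative_fit(
    S: np.ndarray, spec: PathModelSpec, tol: float = 1e-10, maxiter: int = 2000
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Quasi-Newton minimization of F over free b entries and chol(Psi)."""
    k, q = spec.k_total, spec.q
    mask = spec.free_mask()
    Sxx = S[:k, :k]
    free_idx = np.argwhere(mask)

    # start from per-equation OLS restricted to each equation's free set
    b0 = np.zeros((k, q))
    for j in range(q):
        cols = np.flatnonzero(mask[:, j])
        if cols.size:
            b0[cols, j] = np.linalg.solve(
                S[np.ix_(cols, cols)], S[np.ix_(cols, [k + j])]
            ).ravel()
    psi0 = S[k:, k:] - b0.T @ Sxx @ b0
    w, v = np.linalg.eigh((psi0 + psi0.T) / 2)
    psi0 = (v * np.clip(w, 1e-6, None)) @ v.T
    L0 = np.linalg.cholesky(psi0)
    tril = np.tril_indices(q)

    def unpack(theta):
        b = np.zeros((k, q))
        b[free_idx[:, 0], free_idx[:, 1]] = theta[: len(free_idx)]
        L = np.zeros((q, q))
        L[tril] = theta[len(free_idx):]
        return b, L

    def fun_grad(theta):
        b, L = unpack(theta)
        psi = L @ L.T
        sigma = _implied_cov(Sxx, b, psi)
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf, np.zeros_like(theta)
        _, s_logdet = np.linalg.slogdet(S)
        f = logdet + float(np.trace(sigma_inv @ S)) - s_logdet - (k + q)
        G = sigma_inv @ (sigma - S) @ sigma_inv  # dF/dSigma (full matrix)
        Gxy = G[:k, k:]
        Gyy = G[k:, k:]
        db = 2.0 * Sxx @ (Gxy + b @ Gyy)
        dL = 2.0 * Gyy @ L
        grad = np.concatenate([db[free_idx[:, 0], free_idx[:, 1]], dL[tril]])
        return f, grad

    theta0 = np.concatenate([b0[free_idx[:, 0], free_idx[:, 1]], L0[tril]])
    res = optimize.minimize(
        fun_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-9},
    )
    b, L = unpack(res.x)
    grad_norm = float(np.linalg.norm(res.jac))
    converged = bool(res.success or grad_norm < 1e-5)
    if not converged:
        raise RuntimeError(
            f"path-model optimizer did not converge: gradient norm {grad_norm:.2e} "
            f"after {res.nit} iterations"
        )
    return b, L @ L.T, converged, int(res.nit)


def _sur_information_se(
    Sxx: np.ndarray, psi: np.ndarray, mask: np.ndarray, n: int
) -> np.ndarray:
    """Expected-information SEs for free paths (general zero-path patterns)."""
    k, q = mask.shape
    free = np.flatnonzero(mask.T.ravel())  # vec by equation: j*k + i
    info = np.kron(np.linalg.inv(psi), Sxx)
    cov = np.linalg.inv(info[np.ix_(free, free)]) / (n - 1)
    se = np.full((k, q), np.nan)
    se.T.ravel()[free] = np.sqrt(np.diag(cov))
    return se


def fit_ml(
    data: MomentSet | PatientTable,
    spec: PathModelSpec,
    n: int | None = None,
) -> PathModelFit:
    """Fit the path model by maximum likelihood on covariance structure.

    ``data`` may be a :class:`MomentSet` or a :class:`PatientTable` (moments
    are then computed listwise on the model variables).  The sample
    covariance must be positive definite; repair indefinite printed moments
    with :meth:`MomentSet.repaired` first.

    Standard errors: in the closed-form branch (all outcomes share one
    regressor set) they are the textbook least-squares SEs,
    sqrt(psi_jj * (Sxx^-1)_ii / (n - k - 1)); in the iterative branch they
    come from the expected information of the regression block.  Wald
    p-values refer b/se to the standard normal.
    """
    if isinstance(data, PatientTable):
        moments = compute_moments(data, spec.variables, deletion="listwise")
    else:
        moments = data.subset(spec.variables)
    n_eff = int(n if n is not None else moments.n)
    S = moments.cov
    k, q = spec.k_total, spec.q
    eigmin = float(np.linalg.eigvalsh(S).min())
    singular = eigmin <= 0
    if singular and np.linalg.eigvalsh(S[:k, :k]).min() <= 0:
        raise ValueError(
            f"sample covariance not positive definite (min eigenvalue {eigmin:.3g}); "
            "repair the moment set (MomentSet.repaired) before fitting"
        )
    n_free_per_eq = spec.free_mask().sum(axis=0).max()
    if n_eff <= n_free_per_eq + 1:
        raise ValueError("effective n too small for the number of free paths")

    mask = spec.free_mask()
    equal_regressors = bool(np.all(mask.all(axis=1) | (~mask).all(axis=1)))
    if equal_regressors:
        b, psi = _closed_form_fit(S, spec)
        converged, n_iter, method = True, 0, "closed_form"
    elif singular:
        raise ValueError(
            "sample covariance is singular; only the closed-form "
            "(equal-regressor) branch tolerates exact collinearity"
        )
    else:
        b, psi, converged, n_iter = _iterative_fit(S, spec)
        method = "iterative"

    psi_eigmin = float(np.linalg.eigvalsh(psi).min())
    if psi_eigmin < -1e-10:
        raise ValueError(
            f"fitted residual covariance is indefinite (min eigenvalue "
            f"{psi_eigmin:.3g}); repair the moment set before fitting"
        )
    Sxx = S[:k, :k]
    implied = _implied_cov(Sxx, b, psi)
    if singular:
        # degenerate but exactly-reproduced moments (e.g. collinear outcome)
        if not np.allclose(implied, S, atol=1e-8 * max(1.0, np.abs(S).max())):
            raise ValueError(
                "sample covariance not positive definite and not reproduced "
                "by the model; repair the moment set before fitting"
            )
        F = 0.0
    else:
        F = ml_discrepancy(S, implied)
    df = count_degrees_of_freedom(spec)

    sds = moments.sds
    sd_x, sd_y = sds[:k], sds[k:]
    B = b * sd_x[:, None] / sd_y[None, :]
    mask_f = mask.astype(float)
    b = b * mask_f  # exact zeros at constraints
    B = B * mask_f

    implied_var_y = np.diag(implied)[k:]
    r2 = 1.0 - np.diag(psi) / implied_var_y
    k_retained = len(spec.retained_predictors)
    r2_adj = adjusted_r2(r2, n_eff, k_retained)

    if equal_regressors:
        ridx = [spec.predictors.index(p) for p in spec.retained_predictors]
        Sxx_inv = np.linalg.inv(S[np.ix_(ridx, ridx)])
        dof = n_eff - k_retained - 1
        if dof <= 0:
            raise ValueError("n too small for least-squares standard errors")
        se = np.full((k, q), np.nan)
        se[ridx, :] = np.sqrt(
            np.clip(np.outer(np.diag(Sxx_inv), np.diag(psi)), 0.0, None) / dof
        )
    else:
        se = _sur_information_se(Sxx, psi, mask, n_eff)
    se[~mask] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(mask, b, np.nan) / se
        pv = 2.0 * stats.norm.sf(np.abs(z))

    intercepts = moments.means[k:] - b.T @ moments.means[:k]
    return PathModelFit(
        spec=spec, n=n_eff, b=b, intercepts=intercepts, B=B, psi=psi,
        implied_cov=implied, sample_cov=S, F_ML=F, df=df, r2=r2,
        r2_adj=r2_adj, se=se, pvals=pv, sds=sds, means=moments.means,
        converged=converged, n_iter=n_iter, method=method,
    )


def standardize(b_entry: float, sd_predictor: float, sd_outcome: float) -> float:
    """B = b * sd(x) / sd(y): effect in SD units of both variables."""
    if sd_predictor <= 0 or sd_outcome <= 0:
        raise ValueError("standard deviations must be positive")
    return b_entry * sd_predictor / sd_outcome


def adjusted_r2(r2, n: int, k: int):
    """1 - (1 - R^2)(n - 1)/(n - k - 1); penalizes predictor count."""
    if n <= k + 1:
        raise ValueError("need n > k + 1 for the adjustment")
    return 1.0 - (1.0 - np.asarray(r2, dtype=float)) * (n - 1) / (n - k - 1)


def explained_variance(
    fit: PathModelFit, n: int | None = None, k: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-outcome (R^2, adjusted R^2) from a fitted model.

    R^2_j = 1 - psi_jj / implied variance of outcome j.  ``k`` defaults to
    the number of retained predictors; ``n`` to the fit's effective n.
    """
    n = int(n if n is not None else fit.n)
    k = int(k if k is not None else len(fit.spec.retained_predictors))
    implied_var_y = np.diag(fit.implied_cov)[fit.spec.k_total:]
    r2 = 1.0 - np.diag(fit.psi) / implied_var_y
    return r2, adjusted_r2(r2, n, k)


def wald_pvalues(fit: PathModelFit) -> np.ndarray:
    """Two-sided normal-reference p-values for the free paths (NaN at zeros)."""
    mask = fit.spec.free_mask()
    if np.any(fit.se[mask] == 0):
        raise ValueError("zero standard error: Wald statistic undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(mask, fit.b, np.nan) / fit.se
    return 2.0 * stats.norm.sf(np.abs(z))


def single_predictor_sensitivity(
    moments: MomentSet, predictor: str, outcomes: Sequence[str]
) -> dict[str, float]:
    """R^2 per outcome when a single predictor carries the whole model.

    With one standardized predictor the regression slope equals the
    correlation, so R^2_j = r(predictor, outcome_j)^2.
    """
    i = moments.index(predictor)
    return {
        out: float(moments.corr[i, moments.index(out)] ** 2) for out in outcomes
    }


def important_effects(
    fit: PathModelFit, threshold: float = 0.20
) -> list[tuple[str, str, float]]:
    """Free paths with |standardized estimate| >= threshold.

    Returned as (predictor, outcome, B) tuples grouped by outcome in spec
    order, sorted within each outcome by |B| descending.  The default 0.20
    is the conventional cutoff for a prognostically prominent effect.
    """
    mask = fit.spec.free_mask()
    out: list[tuple[str, str, float]] = []
    for j, outcome in enumerate(fit.spec.outcomes):
        hits = [
            (fit.spec.predictors[i], outcome, float(fit.B[i, j]))
            for i in range(fit.spec.k_total)
            if mask[i, j] and abs(fit.B[i, j]) >= threshold
        ]
        hits.sort(key=lambda t: -abs(t[2]))
        out.extend(hits)
    return out
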