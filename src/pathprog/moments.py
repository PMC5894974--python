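"""Sufficient statistics: means, SDs and correlations for a variable roster.

Everything downstream — the joint path model, its fit indices, the backward
elimination — consumes only a :class:`MomentSet`.  A moment set can be
computed from patient-level data or reconstructed from published summary
tables; the packaged :func:`daycase_moments` fixture holds the printed
moments of a 398-patient day-case surgery cohort (383 complete at day-7
follow-up).

Correlation matrices transcribed from tables rounded to two decimals can be
indefinite; :func:`ensure_positive_definite` repairs them by eigenvalue
clipping with diagonal renormalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import PatientTable, apply_missingness_policy

__all__ = [
    "MomentSet",
    "compute_moments",
    "cor_to_cov",
    "cov_to_cor",
    "ensure_positive_definite",
    "daycase_moments",
]


@dataclass
class MomentSet:
    """Means, SDs and a correlation matrix for ``p`` named variables.

    ``n`` is the effective sample size behind the moments (listwise n for
    complete-case estimates).  The correlation matrix must be symmetric
    with unit diagonal and off-diagonals in [-1, 1]; positive definiteness
    is required only after repair, since printed matrices may violate it.
    """

    names: list[str]
    n: int
    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.names)
        if len(set(self.names)) != p:
            raise ValueError("duplicate variable names")
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.means.shape != (p,) or self.sds.shape != (p,):
            raise ValueError("means/sds length must match roster")
        if self.corr.shape != (p, p):
            raise ValueError("correlation matrix shape must match roster")
        if np.any(self.sds <= 0):
            bad = self.names[int(np.argmin(self.sds))]
            raise ValueError(f"nonpositive SD for {bad!r}")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(self.corr) > 1 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def p(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"{name!r} not in moment roster") from None

    @property
    def cov(self) -> np.ndarray:
        """Covariance matrix implied by corr and sds."""
        return cor_to_cov(self)

    def subset(self, names: Sequence[str]) -> "MomentSet":
        idx = [self.index(n) for n in names]
        return MomentSet(
            list(names), self.n, self.means[idx], self.sds[idx],
            self.corr[np.ix_(idx, idx)],
        )

    def repaired(self, min_eigenvalue: float = 1e-8) -> "MomentSet":
        """Copy with the correlation matrix projected to positive definite."""
        fixed = ensure_positive_definite(self.corr, min_eigenvalue)
        return MomentSet(list(self.names), self.n, self.means.copy(),
                         self.sds.copy(), fixed)

    def is_positive_definite(self, tol: float = 0.0) -> bool:
        return bool(np.linalg.eigvalsh(self.corr).min() > tol)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "roster": self.names,
                "n": self.n,
                "means": dict(zip(self.names, self.means.tolist())),
                "sds": dict(zip(self.names, self.sds.tolist())),
                "corr": self.corr.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MomentSet":
        obj = json.loads(text)
        names = list(obj["roster"])
        return cls(
            names,
            int(obj["n"]),
            np.array([obj["means"][k] for k in names]),
            np.array([obj["sds"][k] for k in names]),
            np.array(obj["corr"]),
        )

    def corr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.corr, index=self.names, columns=self.names)


def compute_moments(
    table: PatientTable,
    variables: Sequence[str] | None = None,
    deletion: str = "listwise",
) -> MomentSet:
    """Pearson moments of the listed variables.

    ``deletion='listwise'`` (default) drops every row with any missing value
    among the variables and records the complete-case count as effective n.
    ``'pairwise'`` uses all available pairs — only appropriate for
    descriptive correlation tables, since a pairwise matrix need not be
    positive definite.
    """
    names = list(variables) if variables is not None else table.names
    if deletion not in ("listwise", "pairwise"):
        raise ValueError("deletion must be 'listwise' or 'pairwise'")
    if deletion == "listwise":
        complete, _ = apply_missingness_policy(table, names)
        frame = complete.data.loc[:, names]
        n_eff = len(frame)
    else:
        frame = table.data.loc[:, names]
        n_eff = int(frame.notna().all(axis=1).sum())
    if (deletion == "listwise" and len(frame) < 3) or (
        deletion == "pairwise"
        and (frame.notna().astype(int).T @ frame.notna().astype(int)).min().min() < 3
    ):
        raise ValueError("need at least 3 complete observations per pair")
    sds = frame.std(ddof=1)
    zero_var = sds[sds <= 0]
    if len(zero_var):
        raise ValueError(f"zero variance for variable {zero_var.index[0]!r}")
    corr = frame.corr(method="pearson").to_numpy()  # pairwise-complete by default
    np.fill_diagonal(corr, 1.0)
    return MomentSet(names, n_eff, frame.mean().to_numpy(), sds.to_numpy(),
                     (corr + corr.T) / 2)


def cor_to_cov(moments: MomentSet) -> np.ndarray:
    """cov[i, j] = corr[i, j] * sd[i] * sd[j]."""
    s = moments.sds
    return moments.corr * np.outer(s, s)


def cov_to_cor(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a covariance matrix into (correlation matrix, SD vector)."""
    cov = np.asarray(cov, dtype=float)
    s = np.sqrt(np.diag(cov))
    if np.any(s <= 0):
        raise ValueError("nonpositive variance on the diagonal")
    corr = cov / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    return corr, s


def ensure_positive_definite(
    matrix: np.ndarray, min_eigenvalue: float = 1e-8
) -> np.ndarray:
    """Project a symmetric matrix to the positive-definite cone.

    Eigenvalues below ``min_eigenvalue`` are clipped up to it; when the
    input had a unit diagonal the result is renormalized back to unit
    diagonal (a correlation matrix).  Renormalization can push the smallest
    eigenvalue slightly below the floor again, so the clip/renormalize pair
    iterates to a fixed point.  Already-PD input is returned unchanged,
    making the repair idempotent.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    a = (a + a.T) / 2
    unit_diag = np.allclose(np.diag(a), 1.0, atol=1e-8)
    out = a.copy()
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        if w.min() >= min_eigenvalue * (1 - 1e-10):
            break
        out = (v * np.clip(w, min_eigenvalue, None)) @ v.T
        out = (out + out.T) / 2
        if unit_diag:
            d = np.sqrt(np.diag(out))
            out = out / np.outer(d, d)
            np.fill_diagonal(out, 1.0)
    return out


def daycase_moments(repaired: bool = False, n: int | None = None) -> MomentSet:
    """Published moments of the day-case surgery cohort (17 variables).

    Means/SDs of the questionnaire scores, prevalences of the two binary
    demographics (as Bernoulli mean and SD), and the 17x17 correlation
    matrix printed to two decimals.  Effective n defaults to 383, the
    number of patients with complete day-7 follow-up; pass ``n`` to
    override.  With ``repaired=True`` the correlation matrix is run through
    :func:`ensure_positive_definite` (the transcription is already PD, so
    this is a guard, not a change).
    """
    pkg = resources.files("pathprog") / "data" / "daycase"
    obj = json.loads((pkg / "moments.json").read_text())
    with (pkg / "correlations.csv").open() as fh:
        corr = pd.read_csv(fh, index_col=0)
    names = list(obj["roster"])
    ms = MomentSet(
        names,
        int(n if n is not None else obj["n"]),
        np.array([obj["means"][k] for k in names]),
        np.array([obj["sds"][k] for k in names]),
        corr.loc[names, names].to_numpy(),
    )
    return ms.repaired() if repaired else ms
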