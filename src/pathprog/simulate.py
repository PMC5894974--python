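"""Synthetic day-case surgery cohorts with the study's moment structure.

The generator draws a latent multivariate normal whose correlation matrix
is adjusted so that, after dichotomizing the binary columns at the normal
quantile of their target prevalence, the *observed* moments match the
published tables: dichotomization attenuates correlations, so latent
correlations involving binary variables are inflated beforehand
(point-biserial attenuation factor for binary-continuous pairs,
tetrachoric inversion for binary-binary pairs).

On top of the 17 final-model variables, eleven baseline columns with no
prognostic signal are appended — the sociodemographic/medical variables
and baseline self-esteem that the published analysis fixed at zero — with
cross-correlations drawn uniformly from a small window around zero.
Education is generated as one latent 3-level variable cut at the observed
prevalences and expanded to low/high indicator columns against the
middle-level reference.  Loss to follow-up is emulated as whole-row MCAR
missingness of all day-7 scores.

Scores stay continuous by default so the covariance targets hold exactly
in expectation; ``truncate_to_range`` rounds and clips to the printed
scale ranges for realism at the cost of small moment distortions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import PatientTable, VariableDef, daycase_roster
from .moments import MomentSet, daycase_moments, ensure_positive_definite

__all__ = [
    "SyntheticConfig",
    "ItemGenSpec",
    "generate_cohort",
    "inflate_binary_correlations",
    "generate_items",
    "NULL_PREDICTORS",
]

#: Stand-ins for the eliminated baseline columns, with target prevalence for
#: binary ones (None = continuous).  Education appears as two indicators cut
#: from one latent 3-level variable (low 15.8%, middle 67.8%, high 16.3%).
NULL_PREDICTORS: dict[str, float | None] = {
    "nationality": 0.940,   # 1 = Dutch
    "marital_status": 0.603,  # 1 = living together
    "religion": 0.322,
    "edu_low": 0.158,
    "edu_high": 0.163,
    "employment": 0.756,
    "age": None,
    "bmi": None,
    "heart_rate": None,
    "t0_rses": None,
    "intervention": 0.497,  # randomized premedication arm
}

#: Means/SDs for the continuous null columns.  Age, BMI and heart rate are
#: matched to the published quartiles (mean = median, SD = IQR/1.349);
#: baseline self-esteem has its printed mean/SD.
_NULL_CONTINUOUS_MOMENTS = {
    "age": (36.7, (49.4 - 28.8) / 1.349),
    "bmi": (24.6, (27.7 - 22.4) / 1.349),
    "heart_rate": (69.0, (78.0 - 62.0) / 1.349),
    "t0_rses": (33.5, 4.4),
}

_EDU_PREVALENCE = {"low": 0.158, "high": 0.163}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated cohort.

    Defaults reproduce the published cohort: n = 398 enrolled, the printed
    17-variable moment structure, sex/children prevalences 0.437/0.518,
    eleven near-null extra baseline columns, and a 15/398 whole-row
    loss-to-follow-up rate.

    ``null_corr_max`` sets the window of the uniform draw for the null
    columns' cross-correlations.  The default 0.025 is calibrated so that
    the true final model (null paths fixed at zero) has the population
    discrepancy the study itself reports — chi-square about 99 on 77
    degrees of freedom, i.e. an aggregate noncentrality near 22; the
    misfit grows with the square of the window, so much wider windows
    describe a study in which the reported final model would not fit.
    """

    target_moments: MomentSet | None = None  # None -> packaged day-case moments
    binary_prevalences: dict | None = None   # None -> from target moment means
    extra_null_predictors: bool = True
    null_corr_max: float = 0.025
    missing_rate_t1: float = 15.0 / 398.0
    n: int = 398
    seed: int = 0
    truncate_to_range: bool = False

    def resolved_moments(self) -> MomentSet:
        return (self.target_moments if self.target_moments is not None
                else daycase_moments(repaired=True))


@dataclass(frozen=True)
class ItemGenSpec:
    """Parallel-item generator settings for one questionnaire scale."""

    scale: str
    k: int
    alpha: float
    n: int

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("target alpha must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("need at least 2 items")


def _phi(x):
    return stats.norm.pdf(x)


def inflate_binary_correlations(
    target_corr: np.ndarray,
    prevalences: dict[int, float],
    clip: float = 0.99,
) -> np.ndarray:
    """Latent normal correlations that yield the target observed ones.

    ``prevalences`` maps column index -> success probability for binary
    columns; all other columns are continuous.  For a binary-continuous
    pair the observed point-biserial r relates to the latent r by
    r_obs = r_lat * phi(z_p)/sqrt(p(1-p)), so the latent value is
    r_obs * sqrt(p(1-p))/phi(z_p).  Binary-binary (phi-coefficient)
    targets are inverted numerically through the bivariate-normal
    quadrant probability (tetrachoric inversion).  The result is clipped
    to +-``clip`` and must be PD-repaired before use.
    """
    R = np.asarray(target_corr, dtype=float).copy()
    p_dim = R.shape[0]
    for p in prevalences.values():
        if not 0 < p < 1:
            raise ValueError("prevalences must lie in (0, 1)")
    thresholds = {i: stats.norm.ppf(1 - p) for i, p in prevalences.items()}

    def phi_coeff(rho: float, i: int, j: int) -> float:
        pi, pj = prevalences[i], prevalences[j]
        hi, hj = thresholds[i], thresholds[j]
        p11 = stats.multivariate_normal.cdf(
            [-hi, -hj], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - pi * pj) / np.sqrt(pi * (1 - pi) * pj * (1 - pj))

    for i in range(p_dim):
        for j in range(i):
            r = R[i, j]
            if r == 0 or (i not in prevalences and j not in prevalences):
                continue
            if i in prevalences and j in prevalences:
                lo, hi_b = -0.999, 0.999
                f = lambda rho: phi_coeff(rho, i, j) - r
                if f(lo) * f(hi_b) > 0:
                    raise ValueError(
                        f"target phi coefficient {r} unattainable for pair "
                        f"({i}, {j}) at these prevalences"
                    )
                lat = optimize.brentq(f, lo, hi_b, xtol=1e-10)
            else:
                bi = i if i in prevalences else j
                p = prevalences[bi]
                lat = r * np.sqrt(p * (1 - p)) / _phi(stats.norm.ppf(p))
                if abs(lat) > 1:
                    raise ValueError(
                        f"point-biserial target {r} unattainable for pair "
                        f"({i}, {j}): implied latent correlation {lat:.3f}"
                    )
            lat = float(np.clip(lat, -clip, clip))
            R[i, j] = R[j, i] = lat
    return R


def _extended_targets(config: SyntheticConfig, rng: np.random.Generator):
    """Assemble roster, moments and binary map for the full generated cohort."""
    base = config.resolved_moments()
    names = list(base.names)
    means = list(base.means)
    sds = list(base.sds)
    binary = dict(config.binary_prevalences or {})
    if not binary:
        # binary columns of the packaged roster: mean is the prevalence
        for nm in ("sex", "children"):
            if nm in names:
                binary[nm] = float(base.means[base.index(nm)])

    null_names: list[str] = []
    if config.extra_null_predictors:
        for nm, prev in NULL_PREDICTORS.items():
            null_names.append(nm)
            if prev is not None and nm not in ("edu_low", "edu_high"):
                binary[nm] = prev
                means.append(prev)
                sds.append(float(np.sqrt(prev * (1 - prev))))
            elif nm in ("edu_low", "edu_high"):
                prev = NULL_PREDICTORS[nm]
                means.append(prev)
                sds.append(float(np.sqrt(prev * (1 - prev))))
            else:
                m, s = _NULL_CONTINUOUS_MOMENTS[nm]
                means.append(m)
                sds.append(s)
        names = names + null_names

    p = len(names)
    corr = np.eye(p)
    pb = base.p
    corr[:pb, :pb] = base.corr
    if null_names:
        # near-null cross-correlations, drawn once per seed
        lim = config.null_corr_max
        for a in range(pb, p):
            corr[a, :a] = rng.uniform(-lim, lim, size=a)
            corr[:a, a] = corr[a, :a]
        # the two education indicators come from one latent column and are
        # handled jointly at draw time; their mutual entry is irrelevant
    return names, np.array(means), np.array(sds), corr, binary


def generate_cohort(config: SyntheticConfig) -> PatientTable:
    """Draw a synthetic patient table under the configured conditions.

    Deterministic for a fixed config (seed included).  Returns a
    :class:`PatientTable` whose roster mirrors the day-case study; with
    ``truncate_to_range`` off (default), continuous questionnaire scores
    keep their exact normal distribution and the roster carries open
    ranges, so moment-level checks are exact in expectation.
    """
    if config.n < 10:
        raise ValueError("cohort size must be at least 10")
    rng = np.random.default_rng(config.seed)
    names, means, sds, corr, binary = _extended_targets(config, rng)

    # education: replace the two indicator columns by one latent column
    has_edu = "edu_low" in names
    latent_names = [n for n in names if n != "edu_high"]
    if has_edu:
        li = latent_names.index("edu_low")
        latent_names[li] = "edu"
    keep = [names.index(n) for n in names if n != "edu_high"]
    corr_l = corr[np.ix_(keep, keep)]

    prev_idx = {
        latent_names.index(nm): pv for nm, pv in binary.items()
        if nm in latent_names
    }
    corr_lat = inflate_binary_correlations(corr_l, prev_idx)
    corr_lat = ensure_positive_definite(corr_lat, 1e-6)

    Z = rng.multivariate_normal(
        np.zeros(len(latent_names)), corr_lat, size=config.n,
        method="cholesky",
    )
    data: dict[str, np.ndarray] = {}
    for col, nm in enumerate(latent_names):
        z = Z[:, col]
        if nm == "edu":
            lo_cut = stats.norm.ppf(_EDU_PREVALENCE["low"])
            hi_cut = stats.norm.ppf(1 - _EDU_PREVALENCE["high"])
            data["edu_low"] = (z < lo_cut).astype(float)
            data["edu_high"] = (z > hi_cut).astype(float)
        elif nm in binary:
            cut = stats.norm.ppf(1 - binary[nm])
            data[nm] = (z > cut).astype(float)
        else:
            i = names.index(nm)
            data[nm] = means[i] + sds[i] * z

    frame = pd.DataFrame({nm: data[nm] for nm in names})

    # loss to follow-up: whole rows lose every day-7 score
    t1_cols = [nm for nm in names if nm.startswith("t1_")]
    if config.missing_rate_t1 > 0 and t1_cols:
        lost = rng.random(config.n) < config.missing_rate_t1
        frame.loc[lost, t1_cols] = np.nan

    known = {v.name: v for v in daycase_roster(extended=True)}
    roster = []
    for nm in names:
        if nm in known:
            roster.append(known[nm])
        elif nm in binary:
            roster.append(VariableDef(nm, "psych_predictor", "T0", "binary", (0, 1)))
        else:
            tp = "T1" if nm.startswith("t1_") else "T0"
            role = "outcome" if tp == "T1" else "psych_predictor"
            roster.append(VariableDef(nm, role, tp, "continuous"))
    if config.truncate_to_range:
        for v in roster:
            if v.kind == "continuous" and np.isfinite(v.valid_range[0]):
                frame[v.name] = frame[v.name].round().clip(*v.valid_range)
    else:
        # continuous scores are left un-truncated; widen the roster ranges so
        # the table invariant refers to what was actually generated
        roster = [
            replace(v, valid_range=(-np.inf, np.inf), kind=v.kind)
            if v.kind == "continuous" else v
            for v in roster
        ]
    order = [v.name for v in roster]
    return PatientTable(roster, frame.loc[:, order])


def generate_items(spec: ItemGenSpec, seed: int = 0) -> np.ndarray:
    """Item-level scores whose Cronbach's alpha approximates a target.

    Items are parallel: equicorrelated standard normals with inter-item
    correlation r = alpha/(k - alpha*(k-1)), for which the population
    alpha equals the target exactly.
    """
    r = spec.alpha / (spec.k - spec.alpha * (spec.k - 1))
    if not 0 < r < 1:
        raise ValueError(f"implied inter-item correlation {r:.3f} outside (0, 1)")
    C = np.full((spec.k, spec.k), r)
    np.fill_diagonal(C, 1.0)
    rng = np.random.default_rng(seed)
    return rng.multivariate_normal(np.zeros(spec.k), C, size=spec.n)
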