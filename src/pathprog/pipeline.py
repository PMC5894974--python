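"""End-to-end analysis: score, filter, fit, select, validate, report.

`run_full_analysis` executes the whole prognostic workflow on one of three
input sources — a patient-level table, a reconstructed moment set, or a
synthetic-cohort configuration — and returns a :class:`ReportBundle` of
study-style tables: descriptives, the starred correlation matrix, the
elimination trace, coefficient tables (b with bootstrap CI and B), nested
explained-variance blocks (demographic / +medical / +psychological), fit
indices, and the residual intercorrelation summary.

The helpers `final_model_spec` / `initial_model_spec` encode the day-case
surgery model: seven day-7 outcomes, ten retained baseline predictors, and
eleven further baseline columns whose paths the final model fixes at zero
(education as two indicator columns), giving 77 degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import BootstrapResult, bootstrap_fit
from .cohort import DescriptiveReport, PatientTable, apply_missingness_policy, describe
from .fitindex import FitIndexReport, fit_index_report
from .moments import MomentSet, compute_moments, daycase_moments
from .pathmodel import (
    PathModelFit,
    PathModelSpec,
    adjusted_r2,
    fit_ml,
    important_effects,
)
from .selection import EliminationThresholds, EliminationTrace, eliminate_backward
from .simulate import NULL_PREDICTORS, SyntheticConfig, generate_cohort

__all__ = [
    "OUTCOMES",
    "RETAINED_PREDICTORS",
    "ELIMINATED_PREDICTORS",
    "PREDICTOR_BLOCKS",
    "final_model_spec",
    "initial_model_spec",
    "ReportBundle",
    "run_full_analysis",
    "nested_block_r2",
    "residual_correlation_summary",
    "correlation_star_table",
]

OUTCOMES = (
    "t1_stai_state", "t1_stai_trait", "t1_hads_a", "t1_mfi",
    "t1_stas_state", "t1_stas_trait", "t1_hads_d",
)

RETAINED_PREDICTORS = (
    "sex", "children", "t0_stai_state", "t0_stai_trait", "t0_hads_a",
    "t0_mfi", "t0_stas_state", "t0_stas_trait", "t0_hads_d", "t0_gses",
)

#: Baseline columns fixed at zero in the final model (education expands to
#: two indicator columns against the middle-level reference).
ELIMINATED_PREDICTORS = tuple(NULL_PREDICTORS)

#: Cumulative predictor blocks for the nested explained-variance table.
PREDICTOR_BLOCKS: dict[str, tuple[str, ...]] = {
    "A_demographic": (
        "sex", "children", "nationality", "marital_status", "religion",
        "edu_low", "edu_high", "employment", "age",
    ),
    "B_medical": ("bmi", "heart_rate"),
    "C_psychological": (
        "t0_stai_state", "t0_stai_trait", "t0_hads_a", "t0_mfi",
        "t0_stas_state", "t0_stas_trait", "t0_hads_d", "t0_gses", "t0_rses",
    ),
}

EDUCATION_GROUP = {"education": ("edu_low", "edu_high")}


def final_model_spec(
    include_eliminated: bool = True, estimator: str = "ML"
) -> PathModelSpec:
    """The final day-case model: 10 free predictors, 11 zeroed columns.

    With ``include_eliminated`` (default) the zeroed columns stay in the
    variable set, so df = 11 x 7 = 77; without them the model is saturated
    on the 17 fixture variables (df = 0), which is what moment-only fitting
    uses since the printed tables exclude the eliminated columns.
    """
    if include_eliminated:
        predictors = RETAINED_PREDICTORS + ELIMINATED_PREDICTORS
        zero = frozenset(
            (p, o) for p in ELIMINATED_PREDICTORS for o in OUTCOMES
        )
    else:
        predictors = RETAINED_PREDICTORS
        zero = frozenset()
    return PathModelSpec(OUTCOMES, predictors, zero, estimator)


def initial_model_spec(estimator: str = "ML") -> PathModelSpec:
    """All 21 baseline columns entered with free paths to every outcome."""
    return PathModelSpec(
        OUTCOMES, RETAINED_PREDICTORS + ELIMINATED_PREDICTORS, frozenset(),
        estimator,
    )


def correlation_star_table(moments: MomentSet) -> pd.DataFrame:
    """Correlations rendered to 2 dp with ``*`` at two-sided p < 0.05.

    Significance uses the t reference for a Pearson correlation,
    t = r sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    r = moments.corr
    n = moments.n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-12, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame("", index=moments.names, columns=moments.names)
    for i in range(moments.p):
        for j in range(moments.p):
            if i == j:
                out.iat[i, j] = "1"
            else:
                star = "*" if p[i, j] < 0.05 else ""
                out.iat[i, j] = f"{r[i, j]:.2f}{star}"
    return out


def nested_block_r2(
    data: MomentSet | PatientTable,
    blocks: Mapping[str, Sequence[str]] | None = None,
    outcomes: Sequence[str] = OUTCOMES,
    n: int | None = None,
) -> pd.DataFrame:
    """Adjusted R^2 per outcome for cumulative predictor blocks.

    Blocks are added in order (demographics; + medical; + psychological by
    default) and each cumulative model is refitted saturated on its own
    predictor set, with the adjustment using that fit's own predictor
    count.  Rows are outcomes, columns the cumulative blocks.
    """
    blocks = dict(blocks if blocks is not None else PREDICTOR_BLOCKS)
    if isinstance(data, MomentSet):
        available = set(data.names)
    else:
        available = set(data.names)
    cols = {}
    cumulative: list[str] = []
    for bname, members in blocks.items():
        missing = [m for m in members if m not in available]
        if missing:
            raise KeyError(f"block {bname!r} has unknown variables: {missing}")
        cumulative = cumulative + [m for m in members if m not in cumulative]
        spec = PathModelSpec(tuple(outcomes), tuple(cumulative))
        fit = fit_ml(data, spec, n=n)
        cols[bname] = pd.Series(fit.r2_adj, index=list(outcomes))
    return pd.DataFrame(cols)


def residual_correlation_summary(
    fit: PathModelFit,
) -> tuple[float, float, pd.DataFrame]:
    """(min, max, matrix) of the outcome residual intercorrelations."""
    rc = fit.residual_correlations()
    frame = pd.DataFrame(rc, index=fit.spec.outcomes, columns=fit.spec.outcomes)
    off = rc[np.triu_indices(rc.shape[0], 1)]
    return float(off.min()), float(off.max()), frame


@dataclass
class ReportBundle:
    """Everything the full analysis produces."""

    source: str
    descriptives: DescriptiveReport | None
    moments: MomentSet
    correlation_table: pd.DataFrame
    initial_fit: PathModelFit | None
    trace: EliminationTrace | None
    final_fit: PathModelFit
    fit_report: FitIndexReport
    coefficients: pd.DataFrame
    nested_r2: pd.DataFrame | None
    residual_range: tuple[float, float]
    residual_correlations: pd.DataFrame
    important: list[tuple[str, str, float]]
    bootstrap: BootstrapResult | None = None

    def coefficient_table(self) -> pd.DataFrame:
        """Study-style table: b, bootstrap 95% CI (when run), B per path."""
        tab = self.coefficients.copy()
        if self.bootstrap is not None:
            ci = self.bootstrap.ci
            key = tab["outcome"] + "<-" + tab["predictor"]
            tab["ci_lower"] = key.map(ci["lower"]).astype(float)
            tab["ci_upper"] = key.map(ci["upper"]).astype(float)
        return tab

    def write(self, outdir) -> None:
        """Write all tables, a JSON report and a manifest to ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.correlation_table.to_csv(out / "correlations.csv")
        self.coefficient_table().round(6).to_csv(out / "coefficients.csv",
                                                 index=False)
        if self.nested_r2 is not None:
            self.nested_r2.round(4).to_csv(out / "explained_variance.csv")
        self.residual_correlations.round(4).to_csv(out / "residual_correlations.csv")
        report = {
            "source": self.source,
            "n": self.final_fit.n,
            "fit_indices": self.fit_report.to_dict(),
            "r2": dict(zip(self.final_fit.spec.outcomes,
                           np.round(self.final_fit.r2, 6))),
            "r2_adj": dict(zip(self.final_fit.spec.outcomes,
                               np.round(self.final_fit.r2_adj, 6))),
            "residual_range": list(self.residual_range),
            "important_effects": [
                {"predictor": p, "outcome": o, "B": round(b, 4)}
                for p, o, b in self.important
            ],
        }
        if self.trace is not None:
            report["elimination"] = self.trace.to_dict()
        if self.descriptives is not None:
            report["descriptives"] = self.descriptives.to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=1))
        manifest = {
            "source": self.source,
            "spec": self.final_fit.spec.to_dict(),
            "spec_sha1": hashlib.sha1(
                json.dumps(self.final_fit.spec.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    def to_text(self) -> str:
        lines = [f"input: {self.source}; n = {self.final_fit.n}", ""]
        if self.trace is not None:
            lines += [self.trace.to_text(), ""]
        lines += ["model fit:", self.fit_report.to_text(), ""]
        lines.append("explained variance (adjusted R^2):")
        for o, r in zip(self.final_fit.spec.outcomes, self.final_fit.r2_adj):
            lines.append(f"  {o:<16}{r:6.2f}")
        lines.append("")
        lines.append("prominent standardized effects (|B| >= 0.20):")
        for p, o, b in self.important:
            lines.append(f"  {p:<16} -> {o:<16} B = {b:5.2f}")
        lo, hi = self.residual_range
        lines.append("")
        lines.append(f"residual outcome intercorrelations: {lo:.2f} to {hi:.2f}")
        return "\n".join(lines)


def run_full_analysis(
    source: PatientTable | MomentSet | SyntheticConfig,
    estimator: str = "ML",
    thresholds: EliminationThresholds = EliminationThresholds(),
    eliminate: bool | None = None,
    bootstrap_reps: int = 0,
    seed: int = 0,
    convention: str = "n-1",
    outdir=None,
) -> ReportBundle:
    """Run the whole prognostic analysis on one input source.

    Patient tables (or synthetic configs, which generate one) go through
    the complete workflow: listwise filtering, moments, initial 21-predictor
    model, backward elimination, final fit, fit indices (with the robust
    scaled chi-square under MLR), nested explained-variance blocks, and —
    when ``bootstrap_reps`` > 0 — BC bootstrap intervals.  A bare moment
    set skips elimination by default and fits the final published model
    structure on whatever variables it carries.
    """
    if isinstance(source, SyntheticConfig):
        table: PatientTable | None = generate_cohort(source)
        src_name = f"synthetic cohort (seed {source.seed}, n {source.n})"
    elif isinstance(source, PatientTable):
        table = source
        src_name = f"patient table (n {source.n_enrolled})"
    elif isinstance(source, MomentSet):
        table = None
        src_name = f"moment set (n {source.n})"
    else:
        raise TypeError("source must be PatientTable, MomentSet or SyntheticConfig")

    if table is not None:
        have = set(table.names)
        full_preds = [
            p for p in RETAINED_PREDICTORS + ELIMINATED_PREDICTORS if p in have
        ]
        missing_outcomes = [o for o in OUTCOMES if o not in have]
        if missing_outcomes:
            raise ValueError(f"table lacks outcome variables: {missing_outcomes}")
        initial = PathModelSpec(OUTCOMES, tuple(full_preds), frozenset(), estimator)
        complete, _ = apply_missingness_policy(table, initial.variables)
        descriptives = describe(table)
        moments = compute_moments(complete, initial.variables)
        do_eliminate = True if eliminate is None else eliminate
    else:
        descriptives = None
        moments = source
        missing = [o for o in OUTCOMES if o not in moments.names]
        if missing:
            raise ValueError(f"moment set lacks outcome variables: {missing}")
        initial = None
        do_eliminate = False if eliminate is None else eliminate

    if do_eliminate:
        data = complete if table is not None else moments
        initial_fit = fit_ml(data, initial)
        groups = {
            g: m for g, m in EDUCATION_GROUP.items()
            if all(x in initial.predictors for x in m)
        }
        trace = eliminate_backward(data, initial, thresholds, groups, convention)
        final_fit = trace.final_fit
        final_spec = trace.final_spec
    else:
        trace = None
        initial_fit = None
        if table is not None:
            final_spec = initial
            data = complete
        else:
            retained = [p for p in RETAINED_PREDICTORS if p in moments.names]
            elim = [p for p in ELIMINATED_PREDICTORS if p in moments.names]
            zero = frozenset((p, o) for p in elim for o in OUTCOMES)
            final_spec = PathModelSpec(OUTCOMES, tuple(retained + elim), zero,
                                       estimator)
            data = moments
        final_fit = fit_ml(data, final_spec)

    fit_report = fit_index_report(
        final_fit, moments.subset(final_fit.spec.variables),
        convention=convention,
        table=complete if table is not None else None,
    )
    coefficients = final_fit.coefficient_frame()
    nested = None
    if table is not None:
        block_vars = {m for ms in PREDICTOR_BLOCKS.values() for m in ms}
        if block_vars <= set(table.names):
            nested = nested_block_r2(complete, PREDICTOR_BLOCKS)
    lo, hi, resid = residual_correlation_summary(final_fit)
    important = important_effects(final_fit, 0.20)

    boot = None
    if bootstrap_reps and table is not None:
        boot = bootstrap_fit(complete, final_fit.spec, bootstrap_reps, seed)

    bundle = ReportBundle(
        source=src_name,
        descriptives=descriptives,
        moments=moments,
        correlation_table=correlation_star_table(
            moments.subset(final_fit.spec.variables)
            if set(final_fit.spec.variables) <= set(moments.names) else moments
        ),
        initial_fit=initial_fit,
        trace=trace,
        final_fit=final_fit,
        fit_report=fit_report,
        coefficients=coefficients,
        nested_r2=nested,
        residual_range=(lo, hi),
        residual_correlations=resid,
        important=important,
        bootstrap=boot,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
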