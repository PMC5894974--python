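"""Backward elimination of predictors jointly across all outcomes.

A predictor is a removal candidate when its Wald p-value exceeds the
p-to-remove threshold (default 0.20) on at least ``min_outcomes`` of the
outcomes (default 4 of 7).  One candidate is removed per iteration — the
one that is weak on the most outcomes, ties broken by the larger median
p across outcomes, then by roster order — and the removal is accepted
unless the overall model-fit p-value drops by at least ``fit_p_drop``
(default 0.10) relative to the model just before the removal, in which
case the predictor is restored and never reconsidered.

Grouped predictors (the two education indicator columns encode one 3-level
concept) are removed as a block; the block's p-value per outcome is the
minimum across its member columns, so a block leaves only when every
member is expendable.

The procedure is deterministic given the data and thresholds, and the
returned trace replays to the final specification exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import PatientTable
from .moments import MomentSet
from .pathmodel import PathModelFit, PathModelSpec, fit_ml

__all__ = [
    "EliminationThresholds",
    "EliminationStep",
    "EliminationTrace",
    "eliminate_backward",
    "compare_nested",
]


@dataclass(frozen=True)
class EliminationThresholds:
    """The three constants of the elimination rule."""

    p_to_remove: float = 0.20
    min_outcomes: int = 4
    fit_p_drop: float = 0.10

    def __post_init__(self):
        if not (0 < self.p_to_remove < 1 and 0 < self.fit_p_drop < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.min_outcomes < 1:
            raise ValueError("min_outcomes must be >= 1")


@dataclass
class EliminationStep:
    """One candidate decision."""

    candidate: tuple[str, ...]  # block members (singletons for plain predictors)
    n_weak_outcomes: int
    fit_p_before: float
    fit_p_after: float
    action: str  # "removed" | "kept"

    def to_dict(self) -> dict:
        return {
            "candidate": list(self.candidate),
            "n_weak_outcomes": self.n_weak_outcomes,
            "fit_p_before": self.fit_p_before,
            "fit_p_after": self.fit_p_after,
            "action": self.action,
        }


@dataclass
class EliminationTrace:
    """Full audit trail of a backward-elimination run."""

    steps: list[EliminationStep]
    initial_spec: PathModelSpec
    final_spec: PathModelSpec
    thresholds: EliminationThresholds
    final_fit: PathModelFit | None = None

    def removed(self) -> list[str]:
        out: list[str] = []
        for s in self.steps:
            if s.action == "removed":
                out.extend(s.candidate)
        return out

    def replay(self) -> PathModelSpec:
        """Reapply the recorded removals to the initial spec."""
        spec = self.initial_spec
        for name in self.removed():
            spec = spec.drop_predictor(name)
        return spec

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "p_to_remove": self.thresholds.p_to_remove,
                "min_outcomes": self.thresholds.min_outcomes,
                "fit_p_drop": self.thresholds.fit_p_drop,
            },
            "steps": [s.to_dict() for s in self.steps],
            "final_spec": self.final_spec.to_dict(),
        }

    def to_text(self) -> str:
        lines = [
            f"backward elimination (p-to-remove > {self.thresholds.p_to_remove} "
            f"on >= {self.thresholds.min_outcomes} outcomes, "
            f"fit-P guard {self.thresholds.fit_p_drop})"
        ]
        for i, s in enumerate(self.steps, 1):
            lines.append(
                f"  step {i}: {'+'.join(s.candidate):<24} weak on "
                f"{s.n_weak_outcomes} outcomes, fit P {s.fit_p_before:.3f} -> "
                f"{s.fit_p_after:.3f}: {s.action}"
            )
        kept = ", ".join(self.final_spec.retained_predictors)
        lines.append(f"  retained: {kept}")
        return "\n".join(lines)


def _block_pvalues(
    fit: PathModelFit, members: Sequence[str]
) -> np.ndarray:
    """Per-outcome p for a predictor block: minimum over member columns."""
    rows = [fit.spec.predictors.index(m) for m in members]
    return np.nanmin(fit.pvals[rows, :], axis=0)


def eliminate_backward(
    data: MomentSet | PatientTable,
    initial_spec: PathModelSpec,
    thresholds: EliminationThresholds = EliminationThresholds(),
    groups: Mapping[str, Sequence[str]] | None = None,
    convention: str = "n-1",
) -> EliminationTrace:
    """Run the multi-outcome backward-elimination procedure.

    ``groups`` maps a block name to its member predictor columns (e.g.
    ``{"education": ["edu_low", "edu_high"]}``); unlisted predictors are
    their own singleton blocks.  Returns a trace whose ``final_fit`` is the
    fitted final model.
    """
    groups = dict(groups or {})
    member_of: dict[str, str] = {}
    for gname, members in groups.items():
        for m in members:
            member_of[m] = gname
    blocks: dict[str, tuple[str, ...]] = {}
    for pred in initial_spec.predictors:
        g = member_of.get(pred, pred)
        blocks.setdefault(g, ())
        blocks[g] = blocks[g] + (pred,)
    block_order = list(blocks)  # roster order of first member

    spec = initial_spec
    fit = fit_ml(data, spec)
    steps: list[EliminationStep] = []
    protected: set[str] = set()  # blocks restored by the fit-P guard

    while True:
        # a saturated reference (df = 0) has no meaningful fit p-value; the
        # loss-of-information guard only applies once the model is testable
        _, fit_p_before = fit.chi_square(convention)
        guard_active = fit.df > 0
        active = [
            g for g in block_order
            if g not in protected
            and all(m in spec.retained_predictors for m in blocks[g])
        ]
        candidates = []
        for g in active:
            pvals = _block_pvalues(fit, blocks[g])
            n_weak = int(np.sum(pvals > thresholds.p_to_remove))
            if n_weak >= thresholds.min_outcomes:
                candidates.append((g, n_weak, float(np.nanmedian(pvals))))
        if not candidates:
            break
        # weakest first: most weak outcomes, then larger median p, then order
        candidates.sort(
            key=lambda t: (-t[1], -t[2], block_order.index(t[0]))
        )
        gname, n_weak, _ = candidates[0]
        trial = spec
        for m in blocks[gname]:
            trial = trial.drop_predictor(m)
        trial_fit = fit_ml(data, trial)
        _, fit_p_after = trial_fit.chi_square(convention)
        if guard_active and fit_p_before - fit_p_after >= thresholds.fit_p_drop:
            steps.append(EliminationStep(blocks[gname], n_weak,
                                         fit_p_before, fit_p_after, "kept"))
            protected.add(gname)
        else:
            steps.append(EliminationStep(blocks[gname], n_weak,
                                         fit_p_before, fit_p_after, "removed"))
            spec, fit = trial, trial_fit
    return EliminationTrace(steps, initial_spec, spec, thresholds, fit)


def compare_nested(
    fit_full: PathModelFit, fit_reduced: PathModelFit, n: int | None = None,
    convention: str = "n-1",
) -> tuple[float, int, float]:
    """Likelihood-ratio (chi-square difference) test of nested path models.

    The reduced model's free paths must be a subset of the full model's,
    over the same variables.  Returns (delta chi2, delta df, p).
    """
    sf, sr = fit_full.spec, fit_reduced.spec
    if sf.outcomes != sr.outcomes or sf.predictors != sr.predictors:
        raise ValueError("specs must share the same variable rosters")
    if not sf.zero_paths <= sr.zero_paths:
        raise ValueError("models are not nested (reduced must constrain more)")
    n = int(n if n is not None else fit_full.n)
    mult = float(n - 1) if convention == "n-1" else float(n)
    d_chi2 = mult * (fit_reduced.F_ML - fit_full.F_ML)
    d_df = fit_reduced.df - fit_full.df
    if d_chi2 < 0:
        if d_chi2 < -1e-6 * max(1.0, mult * fit_full.F_ML):
            raise RuntimeError("negative chi-square difference: check convergence")
        d_chi2 = 0.0
    p = 1.0 if d_df == 0 else float(stats.chi2.sf(d_chi2, d_df))
    return float(d_chi2), int(d_df), p
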