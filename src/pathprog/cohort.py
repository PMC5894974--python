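"""Patient-level tables of questionnaire sum scores.

A cohort is a :class:`PatientTable`: one row per patient, one column per
variable in a roster of :class:`VariableDef` entries.  Variables carry a
role (outcome, psychological predictor, demographic, medical, intervention),
a timepoint (T0 = baseline on the day of surgery, T1 = seventh postoperative
day), a kind, and a closed valid range.  Questionnaire scores are plain item
sums: STAI scales run 20-80 (20 items), MFI 20-100 (20 items), each HADS
subscale 0-21 (7 items), STAS scales and RSES/GSES 10-40 (10 items each).

Missing follow-up data are handled listwise: a model is fitted on the rows
that are complete on exactly the variables it uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableDef",
    "PatientTable",
    "DescriptiveReport",
    "MissingnessWarning",
    "score_scale",
    "apply_missingness_policy",
    "describe",
    "cronbach_alpha",
    "daycase_roster",
]

ROLES = ("outcome", "psych_predictor", "demographic", "medical", "intervention")
TIMEPOINTS = ("T0", "T1")
KINDS = ("continuous", "binary", "count")

#: Fraction of missing values above which the listwise policy warns that the
#: "little missing data" assumption is strained.
MISSINGNESS_WARN_FRACTION = 0.05


class MissingnessWarning(UserWarning):
    """A variable exceeds the tolerated missingness fraction."""


@dataclass(frozen=True)
class VariableDef:
    """Definition of one roster variable.

    Parameters
    ----------
    name : str
        Short identifier, unique within a roster.
    role : str
        One of ``outcome``, ``psych_predictor``, ``demographic``,
        ``medical``, ``intervention``.
    timepoint : str
        ``T0`` (baseline) or ``T1`` (day 7).  Outcomes are always T1.
    kind : str
        ``continuous``, ``binary`` or ``count``.
    valid_range : tuple of float
        Closed interval of permitted values; ``(0, 1)`` for binary.
    n_items : int, optional
        Number of questionnaire items for sum-scored scales.
    item_range : tuple of float, optional
        Permitted range of a single item score.
    """

    name: str
    role: str
    timepoint: str
    kind: str = "continuous"
    valid_range: tuple[float, float] = (-np.inf, np.inf)
    n_items: int | None = None
    item_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r} for {self.name!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        lo, hi = self.valid_range
        if not lo <= hi:
            raise ValueError(f"valid_range lower > upper for {self.name!r}")
        if self.kind == "binary" and self.valid_range != (0, 1):
            raise ValueError(f"binary variable {self.name!r} must have range (0, 1)")
        if self.role == "outcome" and self.timepoint != "T1":
            raise ValueError(f"outcome {self.name!r} must be measured at T1")


@dataclass
class PatientTable:
    """A cohort: roster of variable definitions plus one row per patient.

    ``data`` is a :class:`pandas.DataFrame` whose columns are exactly the
    roster names (in roster order); ``NaN`` encodes missing.  Non-missing
    values must lie inside each variable's valid range.
    """

    roster: list[VariableDef]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        names = [v.name for v in self.roster]
        if len(set(names)) != len(names):
            raise ValueError("duplicate names in roster")
        missing_cols = [n for n in names if n not in self.data.columns]
        if missing_cols:
            raise ValueError(f"data lacks roster columns: {missing_cols}")
        self.data = self.data.loc[:, names].astype(float)
        for v in self.roster:
            col = self.data[v.name]
            ok = col.isna() | ((col >= v.valid_range[0]) & (col <= v.valid_range[1]))
            if not ok.all():
                bad = col[~ok].iloc[0]
                raise ValueError(
                    f"value {bad!r} outside valid range {v.valid_range} "
                    f"for variable {v.name!r}"
                )

    @property
    def n_enrolled(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.roster]

    def variable(self, name: str) -> VariableDef:
        for v in self.roster:
            if v.name == name:
                return v
        raise KeyError(f"{name!r} not in roster")

    def subset(self, names: Sequence[str]) -> "PatientTable":
        """Restrict to the given variables (order preserved as given)."""
        defs = [self.variable(n) for n in names]
        return PatientTable(defs, self.data.loc[:, list(names)].copy())

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, roster: Sequence[VariableDef]) -> "PatientTable":
        """Read a delimited table; empty cells are missing."""
        frame = pd.read_csv(path)
        return cls(list(roster), frame)


def score_scale(item_values, scale_def: VariableDef):
    """Sum questionnaire items into the scale score.

    ``item_values`` is a length-k vector (one respondent) or an (n, k)
    matrix.  The item count must match ``scale_def.n_items`` and every item
    must lie inside ``scale_def.item_range``.  The result is the plain
    arithmetic sum, which by construction lies in the scale's valid range.
    """
    if scale_def.n_items is None or scale_def.item_range is None:
        raise ValueError(f"{scale_def.name!r} is not an item-scored scale")
    arr = np.asarray(item_values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    elif arr.ndim == 2:
        squeeze = False
    else:
        raise ValueError("item_values must be 1-D or 2-D")
    if arr.shape[1] != scale_def.n_items:
        raise ValueError(
            f"{scale_def.name!r} expects {scale_def.n_items} items, "
            f"got {arr.shape[1]}"
        )
    lo, hi = scale_def.item_range
    if np.any((arr < lo) | (arr > hi)):
        raise ValueError(f"item score outside [{lo}, {hi}] for {scale_def.name!r}")
    total = arr.sum(axis=1)
    return float(total[0]) if squeeze else total


def apply_missingness_policy(
    table: PatientTable, variables: Sequence[str]
) -> tuple[PatientTable, dict[str, int]]:
    """Listwise deletion on the listed variables.

    Returns the complete-case table together with a per-variable count of
    rows that were missing that variable.  A variable missing in at least
    5% of rows triggers a :class:`MissingnessWarning` — the policy assumes
    little missing data, and heavier loss deserves an explicit look.

    Idempotent: reapplying with the same variables changes nothing.
    """
    for name in variables:
        table.variable(name)  # raises KeyError on unknown names
    sub = table.data.loc[:, list(variables)]
    dropped_per_var = {n: int(sub[n].isna().sum()) for n in variables}
    n = len(table.data)
    for name, lost in dropped_per_var.items():
        if n and lost / n >= MISSINGNESS_WARN_FRACTION:
            warnings.warn(
                f"variable {name!r} missing in {lost}/{n} rows "
                f"(>= {MISSINGNESS_WARN_FRACTION:.0%})",
                MissingnessWarning,
                stacklevel=2,
            )
    keep = sub.notna().all(axis=1)
    out = PatientTable(list(table.roster), table.data.loc[keep].reset_index(drop=True))
    return out, dropped_per_var


@dataclass
class DescriptiveReport:
    """Cohort descriptives.

    ``categorical`` maps a variable to ``{level: (count, percent)}`` over
    non-missing rows; ``percentiles`` maps a continuous variable to its
    (25th, 50th, 75th) percentiles; ``moments`` maps a variable to its
    (mean, SD).  ``n`` is the number of rows described.
    """

    n: int
    categorical: dict[str, dict[float, tuple[int, float]]] = field(default_factory=dict)
    percentiles: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    moments: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "categorical": {
                k: {str(lv): [c, p] for lv, (c, p) in v.items()}
                for k, v in self.categorical.items()
            },
            "percentiles": {k: list(v) for k, v in self.percentiles.items()},
            "moments": {k: list(v) for k, v in self.moments.items()},
        }

    def to_text(self) -> str:
        lines = [f"Descriptives (n = {self.n})", ""]
        if self.categorical:
            lines.append(f"{'variable':<16}{'level':>8}{'n':>8}{'%':>8}")
            for name, levels in self.categorical.items():
                for level, (count, pct) in sorted(levels.items()):
                    lines.append(f"{name:<16}{level:>8g}{count:>8d}{pct:>8.1f}")
            lines.append("")
        if self.percentiles or self.moments:
            lines.append(
                f"{'variable':<16}{'p25':>8}{'p50':>8}{'p75':>8}{'mean':>8}{'SD':>8}"
            )
            for name in {*self.percentiles} | {*self.moments}:
                p = self.percentiles.get(name, (np.nan,) * 3)
                m = self.moments.get(name, (np.nan,) * 2)
                lines.append(
                    f"{name:<16}{p[0]:>8.1f}{p[1]:>8.1f}{p[2]:>8.1f}"
                    f"{m[0]:>8.1f}{m[1]:>8.1f}"
                )
        return "\n".join(lines)


def describe(table: PatientTable) -> DescriptiveReport:
    """Tabulate counts/percentages, quartiles and means/SDs per variable.

    Percentiles use linear interpolation between order statistics.
    Categorical percentages are 100*count/non-missing n.  All-missing
    variables are excluded with a warning.
    """
    if table.n_enrolled == 0:
        raise ValueError("empty table")
    report = DescriptiveReport(n=table.n_enrolled)
    for v in table.roster:
        col = table.data[v.name].dropna()
        if col.empty:
            warnings.warn(f"variable {v.name!r} is entirely missing; skipped")
            continue
        if v.kind == "binary":
            counts = col.value_counts().sort_index()
            report.categorical[v.name] = {
                float(level): (int(c), 100.0 * c / len(col))
                for level, c in counts.items()
            }
        else:
            q = np.percentile(col.to_numpy(), [25, 50, 75], method="linear")
            report.percentiles[v.name] = (float(q[0]), float(q[1]), float(q[2]))
            report.moments[v.name] = (float(col.mean()), float(col.std(ddof=1)))
    return report


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of item sums),
    using unbiased (ddof=1) variances.  Requires at least two items, three
    subjects, and nonzero total-score variance.  The result lies in
    (-inf, 1]; values near 1 indicate the items measure one construct.
    """
    arr = np.asarray(item_matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(arr).any():
        raise ValueError("missing values not allowed in item matrix")
    totals = arr.sum(axis=1)
    total_var = totals.var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance: alpha undefined")
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def roster_to_json(roster: Sequence[VariableDef]) -> str:
    """Serialize a roster as a JSON document of VariableDef fields."""
    import json

    def enc(v: VariableDef) -> dict:
        d = {"name": v.name, "role": v.role, "timepoint": v.timepoint,
             "kind": v.kind, "valid_range": list(v.valid_range)}
        if v.n_items is not None:
            d["n_items"] = v.n_items
            d["item_range"] = list(v.item_range)
        return d

    return json.dumps([enc(v) for v in roster], indent=1)


def roster_from_json(text: str) -> list[VariableDef]:
    import json

    out = []
    for d in json.loads(text):
        out.append(VariableDef(
            d["name"], d["role"], d["timepoint"], d.get("kind", "continuous"),
            tuple(d.get("valid_range", (-np.inf, np.inf))),
            n_items=d.get("n_items"),
            item_range=tuple(d["item_range"]) if "item_range" in d else None,
        ))
    return out


# --- the day-case surgery roster -----------------------------------------

_SCALES = {
    # name -> (range, items, item range)
    "stai_state": ((20, 80), 20, (1, 4)),
    "stai_trait": ((20, 80), 20, (1, 4)),
    "hads_a": ((0, 21), 7, (0, 3)),
    "hads_d": ((0, 21), 7, (0, 3)),
    "mfi": ((20, 100), 20, (1, 5)),
    "stas_state": ((10, 40), 10, (1, 4)),
    "stas_trait": ((10, 40), 10, (1, 4)),
    "rses": ((10, 40), 10, (1, 4)),
    "gses": ((10, 40), 10, (1, 4)),
}

#: The seven questionnaire scales measured at both timepoints.
OUTCOME_SCALES = (
    "stai_state",
    "stai_trait",
    "hads_a",
    "mfi",
    "stas_state",
    "stas_trait",
    "hads_d",
)


def daycase_roster(extended: bool = True) -> list[VariableDef]:
    """Variable roster of the day-case surgery cohort.

    The core roster holds the 17 final-model variables: sex and children
    (binary demographics), eight baseline psychological predictors, and the
    seven day-7 outcomes.  With ``extended=True`` (default) the eleven
    additional baseline columns that carry no prognostic signal in the final
    model are appended: nationality, marital status, religion, two education
    indicators (low/high vs middle reference), employment, age, BMI, heart
    rate, baseline self-esteem (RSES), and the randomized premedication
    indicator.
    """

    def scale(name: str, tp: str, role: str) -> VariableDef:
        rng, k, irng = _SCALES[name]
        return VariableDef(
            f"{tp.lower()}_{name}", role, tp, "continuous", rng, n_items=k,
            item_range=irng,
        )

    roster = [
        VariableDef("sex", "demographic", "T0", "binary", (0, 1)),
        VariableDef("children", "demographic", "T0", "binary", (0, 1)),
    ]
    roster += [
        scale(s, "T0", "psych_predictor")
        for s in ("stai_state", "stai_trait", "hads_a", "mfi",
                  "stas_state", "stas_trait", "hads_d", "gses")
    ]
    roster += [scale(s, "T1", "outcome") for s in OUTCOME_SCALES]
    if extended:
        roster += [
            VariableDef("nationality", "demographic", "T0", "binary", (0, 1)),
            VariableDef("marital_status", "demographic", "T0", "binary", (0, 1)),
            VariableDef("religion", "demographic", "T0", "binary", (0, 1)),
            VariableDef("edu_low", "demographic", "T0", "binary", (0, 1)),
            VariableDef("edu_high", "demographic", "T0", "binary", (0, 1)),
            VariableDef("employment", "demographic", "T0", "binary", (0, 1)),
            VariableDef("age", "demographic", "T0", "continuous", (18, 110)),
            VariableDef("bmi", "medical", "T0", "continuous", (10, 80)),
            VariableDef("heart_rate", "medical", "T0", "continuous", (30, 220)),
            scale("rses", "T0", "psych_predictor"),
            VariableDef("intervention", "intervention", "T0", "binary", (0, 1)),
        ]
    return roster
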