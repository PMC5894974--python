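import numpy as np
import pandas as pd
import pytest

import pathprog as pp
from pathprog.cohort import PatientTable, VariableDef


@pytest.fixture(scope="session")
def daycase():
    """The packaged 17-variable moment fixture, PD-repaired."""
    return pp.daycase_moments(repaired=True)


@pytest.fixture(scope="session")
def final_fit(daycase):
    """Final published model refitted on the moment fixture (saturated on
    the 17 variables: eliminated columns are absent from printed moments)."""
    return pp.fit_ml(daycase, pp.final_model_spec(include_eliminated=False))


@pytest.fixture()
def toy_moments():
    """Small PD 4-variable moment set (2 predictors, 2 outcomes)."""
    corr = np.array(
        [[1.0, 0.3, 0.4, 0.2],
         [0.3, 1.0, 0.1, 0.5],
         [0.4, 0.1, 1.0, 0.3],
         [0.2, 0.5, 0.3, 1.0]]
    )
    return pp.MomentSet(["x1", "x2", "y1", "y2"], 500,
                        np.zeros(4), np.ones(4), corr)


def simple_table(X: np.ndarray, n_pred: int, names=None) -> PatientTable:
    """Wrap a raw matrix as a PatientTable: first n_pred columns are
    baseline predictors, the rest day-7 outcomes."""
    p = X.shape[1]
    if names is None:
        names = [f"x{i+1}" for i in range(n_pred)] + \
                [f"y{j+1}" for j in range(p - n_pred)]
    roster = [VariableDef(n, "psych_predictor", "T0") for n in names[:n_pred]]
    roster += [VariableDef(n, "outcome", "T1") for n in names[n_pred:]]
    return PatientTable(roster, pd.DataFrame(X, columns=names))
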