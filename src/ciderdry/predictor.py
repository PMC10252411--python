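"""Linear dryness predictors on the 0-8 panel scale.

The production-ready predictor is a named linear equation over routine lab
measurements. The published selected-variables model is shipped as
``EQUATION_1``:

    dryness = 5.928 - 0.929*pH + 0.0687*TA - 0.425*Abs280
              - 0.0395*Abs320 + 0.0005243*RS

with titratable acidity (TA) in g/L as malic acid, residual sugar (RS) in
mg/100 mL and absorbances in AU (1-cm path). With RS in mg/100 mL the sugar
coefficient spans roughly four scale units over the observed sugar range,
the only unit reading under which the equation's arithmetic is plausible.
Predicted scores live on the sensory 0-8 scale, so sensory category
boundaries apply to them.
"""
from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .categories import DrynessCategory
from .pls import PLSModel, fit_pls1
from .records import CiderSample
from .scales import categorize_sensory_score

SampleLike = Union[CiderSample, Mapping[str, float], pd.Series]


@dataclass(frozen=True)
class DrynessEquation:
    """Named linear coefficients + intercept; evaluation requires exactly
    these variables in the canonical units."""

    intercept: float
    coefficients: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", MappingProxyType(dict(self.coefficients))
        )

    @property
    def variables(self) -> tuple:
        return tuple(self.coefficients)

    def as_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": dict(self.coefficients)}


#: the published selected-variables dryness equation
EQUATION_1 = DrynessEquation(
    intercept=5.928,
    coefficients={
        "ph": -0.929,
        "titratable_acidity": 0.0687,
        "abs280": -0.425,
        "abs320": -0.0395,
        "residual_sugar": 0.0005243,
    },
)

#: variable subsets of the three calibration models
MODEL1_VARIABLES = (
    "residual_sugar",
    "titratable_acidity",
    "malic_acid",
    "tannins",
    "polyphenols",
    "hydroxycinnamic",
    "hydroxybenzoic",
    "abs280",
    "abs320",
    "alcohol",
    "ph",
)
#: the important-variables model is named two ways in the source narrative;
#: both presets ship and the choice is a configuration value
MODEL2_VARIABLES = ("residual_sugar", "ph", "abs280")
MODEL2_VARIABLES_ALT = ("residual_sugar", "hydroxycinnamic", "abs280")
MODEL3_VARIABLES = ("residual_sugar", "titratable_acidity", "abs280", "abs320", "ph")


def _get_variable(sample: SampleLike, name: str) -> float:
    if isinstance(sample, CiderSample):
        value = getattr(sample, name, None)
    elif isinstance(sample, pd.Series):
        value = sample.get(name)
    else:
        value = sample.get(name) if hasattr(sample, "get") else None
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"sample is missing required variable {name!r}")
    return float(value)


def predict_dryness(eq: DrynessEquation, sample: SampleLike, clip: bool = True) -> float:
    """Evaluate the equation for one sample; scores are clipped to [0, 8]."""
    score = eq.intercept + sum(
        coef * _get_variable(sample, name) for name, coef in eq.coefficients.items()
    )
    return float(np.clip(score, 0.0, 8.0)) if clip else float(score)


def predict_rating(eq: DrynessEquation, sample: SampleLike) -> DrynessCategory:
    """Predicted dryness category (sensory-scale boundaries)."""
    return categorize_sensory_score(predict_dryness(eq, sample))


def predict_table(eq: DrynessEquation, chemistry: pd.DataFrame) -> pd.DataFrame:
    """Per-sample predicted score and rating for a chemistry table."""
    rows = []
    for _, row in chemistry.iterrows():
        score = predict_dryness(eq, row)
        rows.append(
            {
                "sample_id": row["sample_id"],
                "predicted_score": score,
                "predicted_rating": categorize_sensory_score(score).label,
            }
        )
    return pd.DataFrame(rows)


def make_equation(
    model: PLSModel, variable_subset: Optional[Sequence[str]] = None
) -> DrynessEquation:
    """Extract a model's raw-scale coefficients into a DrynessEquation.

    The subset must equal the model's fitted variable set: PLS coefficients
    are not transferable across variable sets, so narrowing the variables
    requires a new fit (see :func:`fit_equation`), never zeroing.
    """
    if not model.feature_names:
        raise ValueError("model was fitted without feature names")
    names = tuple(model.feature_names)
    if variable_subset is None:
        variable_subset = names
    unknown = [v for v in variable_subset if v not in names]
    if unknown:
        raise ValueError(f"unknown variable name(s): {unknown}")
    if set(variable_subset) != set(names):
        raise ValueError(
            "variable subset differs from the fitted set; refit on the subset "
            "(coefficients are not transferable)"
        )
    coefs = dict(zip(names, model.b_raw))
    return DrynessEquation(intercept=model.intercept, coefficients=coefs)


def fit_equation(
    chemistry: pd.DataFrame,
    y: Sequence[float],
    variables: Sequence[str],
    n_factors: Optional[int] = None,
    autoscale: bool = True,
) -> DrynessEquation:
    """Fit a PLS1 model on a variable subset and extract its equation.

    ``n_factors`` defaults to the full min(n-1, p), which makes the fit
    equivalent to least squares on the subset.
    """
    X = chemistry[list(variables)]
    if n_factors is None:
        n_factors = min(len(X) - 1, len(variables))
    model = fit_pls1(X, np.asarray(y, dtype=float), n_factors, autoscale=autoscale)
    return make_equation(model)
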