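"""Rule-based dryness scales: IRF ratio, pH shift, NYCA tannin correction.

The IRF (International Riesling Foundation) scale scores a cider by the ratio
of residual sugar to malic acid, optionally shifting the resulting category by
pH thresholds. The NYCA (New York Cider Association) scale subtracts a
tannin-dependent deduction (1/4 to 3/4 of a unit) from the same ratio before
categorization. Sensory dryness is scored by a trained panel on a 0-8 category
scale anchored to glucose references.

Category boundaries reconcile the guideline's interval notation against the
labels the study actually applied. The guideline prints its bins on a
one-decimal grid ("medium dry 1.0 to 2.0", "medium sweet 2.1 to 4.0"),
leaving scores between grid points unassigned; the applied labels (1.000
rated dry, 2.195 semi-dry, 2.587 semi-sweet, 4.000 semi-sweet) show how the
gaps are resolved in practice. The implementation closes the bins as
dry <= 1.0 < semi-dry < 2.2 <= semi-sweet <= 4.0 < sweet, the applied labels
outranking the printed interval edges.
"""
from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import DrynessCategory

#: malic acid (g/L) below which the sugar/acid ratio is numerically meaningless
EPSILON_MALIC = 1e-6

#: sweetness reference anchors: glucose g/L -> panel score (with the origin)
SWEETNESS_ANCHORS = ((0.0, 0.0), (9.0, 2.0), (18.0, 4.0), (45.0, 6.0))

#: panel scale ceiling
MAX_SENSORY_SCORE = 8.0


@dataclass(frozen=True)
class IrfScore:
    """Sugar/acid ratio with a flag for the near-zero-acid degenerate regime.

    The scale produces arbitrarily large scores when malic acid is a fraction
    of a mg/L even though such samples are not perceived as sweet; callers can
    detect that regime via ``unstable`` instead of receiving a silent number.
    """

    value: float
    unstable: bool = False

    def __float__(self) -> float:
        return self.value


def irf_ratio(residual_sugar: float, malic_acid: float) -> IrfScore:
    """Residual-sugar-to-malic-acid ratio (both in g/L).

    If malic acid is below ``EPSILON_MALIC`` the ratio is computed against the
    epsilon and flagged unstable rather than raising: published score tables
    include samples with 0.001 g/L malic acid.
    """
    if residual_sugar < 0 or malic_acid < 0:
        raise ValueError("residual sugar and malic acid must be >= 0")
    if malic_acid < EPSILON_MALIC:
        return IrfScore(residual_sugar / EPSILON_MALIC, unstable=True)
    return IrfScore(residual_sugar / malic_acid, unstable=False)


def categorize_scale_score(score: float) -> DrynessCategory:
    """Map an IRF/NYCA scale score to a dryness category."""
    score = float(score)
    if score < 0:
        raise ValueError(f"scale score must be >= 0, got {score}")
    if score <= 1.0:
        return DrynessCategory.DRY
    if score < 2.2:
        return DrynessCategory.SEMI_DRY
    if score <= 4.0:
        return DrynessCategory.SEMI_SWEET
    return DrynessCategory.SWEET


# pH shift rules per base category, most extreme threshold first; the first
# matching rule wins, unmatched pH leaves the category unchanged.
_GE, _LE = operator.ge, operator.le
_PH_SHIFTS = {
    DrynessCategory.DRY: (
        (_GE, 3.5, DrynessCategory.SEMI_SWEET),
        (_GE, 3.3, DrynessCategory.SEMI_DRY),
    ),
    DrynessCategory.SEMI_DRY: (
        (_GE, 3.3, DrynessCategory.SEMI_SWEET),
        (_LE, 2.9, DrynessCategory.DRY),
    ),
    DrynessCategory.SEMI_SWEET: (
        (_GE, 3.3, DrynessCategory.SWEET),
        (_LE, 2.8, DrynessCategory.DRY),
        (_LE, 2.9, DrynessCategory.SEMI_DRY),
    ),
    DrynessCategory.SWEET: (
        (_LE, 2.8, DrynessCategory.SEMI_DRY),
        (_LE, 2.9, DrynessCategory.SEMI_SWEET),
    ),
}


def irf_ph_adjust(base: DrynessCategory, ph: float) -> DrynessCategory:
    """Shift an IRF category by the pH correction matrix.

    High pH (low perceived acidity) shifts toward sweet, low pH toward dry;
    the shift applies to the category only, not the numeric score.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"ph {ph} outside (0, 14)")
    base = DrynessCategory(base)
    for op, threshold, shifted in _PH_SHIFTS[base]:
        if op(ph, threshold):
            return shifted
    return base


def tannin_deduction(tannins: float) -> float:
    """NYCA deduction (score units) as a step function of tannins in mg/L.

    Bins are half-open so the partition of [0, inf) is exhaustive for a
    continuous measurement: 0 for <=500, 1/4 for (500, 750], 1/2 for
    (750, 1000], 3/4 above 1000.
    """
    tannins = float(tannins)
    if tannins < 0:
        raise ValueError(f"tannins must be >= 0, got {tannins}")
    if tannins <= 500.0:
        return 0.0
    if tannins <= 750.0:
        return 0.25
    if tannins <= 1000.0:
        return 0.5
    return 0.75


def nyca_score(irf_score: float, tannins: float) -> float:
    """IRF score minus the tannin deduction, floored at zero."""
    value = float(irf_score)
    if value < 0:
        raise ValueError(f"IRF score must be >= 0, got {value}")
    return max(value - tannin_deduction(tannins), 0.0)


def categorize_sensory_score(score: float) -> DrynessCategory:
    """Map a 0-8 panel dryness score to a category.

    Boundaries follow the anchored panel scale: dry <= 2 < semi-dry <= 4 <
    semi-sweet <= 6 < sweet.
    """
    score = float(score)
    if not 0.0 <= score <= MAX_SENSORY_SCORE:
        raise ValueError(f"sensory score {score} outside [0, 8]")
    if score <= 2.0:
        return DrynessCategory.DRY
    if score <= 4.0:
        return DrynessCategory.SEMI_DRY
    if score <= 6.0:
        return DrynessCategory.SEMI_SWEET
    return DrynessCategory.SWEET


def anchor_score(glucose: float) -> float:
    """Panel-scale score of a glucose reference solution (g/L).

    Piecewise-linear through the anchors (0,0), (9,2), (18,4), (45,6);
    linear extrapolation above 45 g/L at the last segment's slope, capped at
    the scale ceiling of 8.
    """
    glucose = float(glucose)
    if glucose < 0:
        raise ValueError(f"glucose must be >= 0, got {glucose}")
    xs, ys = zip(*SWEETNESS_ANCHORS)
    if glucose <= xs[-1]:
        return float(np.interp(glucose, xs, ys))
    slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return min(ys[-1] + slope * (glucose - xs[-1]), MAX_SENSORY_SCORE)


def score_table(chemistry: pd.DataFrame) -> pd.DataFrame:
    """Apply all scales to a chemistry table.

    Residual sugar is stored in mg/100 mL and converted to g/L (/100) for the
    sugar/acid ratio. Samples without a tannin value get no NYCA deduction.
    Returns one row per sample with scores, ratings and the instability flag.
    """
    rows = []
    for rec in chemistry.to_dict("records"):
        irf = irf_ratio(rec["residual_sugar"] / 100.0, rec["malic_acid"])
        tannins = rec.get("tannins", 0.0)
        if pd.isna(tannins):
            tannins = 0.0
        nyca = nyca_score(irf.value, tannins)
        irf_cat = categorize_scale_score(irf.value)
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "irf_score": irf.value,
                "irf_unstable": irf.unstable,
                "irf_rating": irf_cat.label,
                "irf_rating_ph": irf_ph_adjust(irf_cat, rec["ph"]).label,
                "nyca_score": nyca,
                "nyca_rating": categorize_scale_score(nyca).label,
            }
        )
    return pd.DataFrame(rows)
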