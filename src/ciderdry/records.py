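"""Domain record types for cider chemistry and dryness ratings.

Units follow the conventions of the study's composition table and are never
auto-converted: alcohol % v/v, acids g/L (titratable acidity expressed as
malic acid), residual sugar mg/100 mL, phenolics mg/L, absorbances in AU for
a 1-cm path. Silent unit conversion is the main failure mode for the dryness
equation, so readers rename columns but never rescale values.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .categories import DrynessCategory

#: numeric chemistry fields required of every sample
CHEMISTRY_FIELDS = (
    "alcohol",
    "ph",
    "malic_acid",
    "titratable_acidity",
    "residual_sugar",
    "polyphenols",
    "hydroxybenzoic",
    "hydroxycinnamic",
    "abs280",
    "abs320",
)


@dataclass
class CiderSample:
    """One cider's chemistry panel.

    ``tannins`` (mg/L catechin equivalents) is optional: it is needed only by
    the NYCA tannin correction and was not part of the routine panel.
    """

    sample_id: str
    alcohol: float
    ph: float
    malic_acid: float
    titratable_acidity: float
    residual_sugar: float
    polyphenols: float
    hydroxybenzoic: float
    hydroxycinnamic: float
    abs280: float
    abs320: float
    tannins: Optional[float] = None
    facility_code: Optional[str] = None

    def __post_init__(self) -> None:
        for name in CHEMISTRY_FIELDS:
            value = float(getattr(self, name))
            setattr(self, name, value)
            if name != "ph" and value < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: field {name!r} is negative ({value})"
                )
        if not 0.0 < self.ph < 14.0:
            raise ValueError(
                f"sample {self.sample_id!r}: ph {self.ph} outside (0, 14)"
            )
        if self.tannins is not None:
            self.tannins = float(self.tannins)
            if self.tannins < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: field 'tannins' is negative "
                    f"({self.tannins})"
                )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class RatedSample:
    """Scale scores and panel rating for one sample (score-table row)."""

    sample_id: str
    irf_score: float
    irf_rating_no_ph: DrynessCategory
    irf_rating_ph: DrynessCategory
    nyca_score: float
    nyca_rating: DrynessCategory
    sensory_score: float
    sensory_rating: DrynessCategory
    set: str = "calibration"

    def __post_init__(self) -> None:
        if self.irf_score < 0 or self.nyca_score < 0:
            raise ValueError(f"sample {self.sample_id!r}: scale scores must be >= 0")
        if not 0.0 <= self.sensory_score <= 8.0:
            raise ValueError(
                f"sample {self.sample_id!r}: sensory score {self.sensory_score} "
                "outside [0, 8]"
            )
        for name in ("irf_rating_no_ph", "irf_rating_ph", "nyca_rating", "sensory_rating"):
            setattr(self, name, DrynessCategory.from_label(getattr(self, name)))


@dataclass
class ValidationRecord:
    """Per-sample ratings of the validation set: NYCA, panel, and models 1-3."""

    sample_id: str
    nyca_rating: DrynessCategory
    sensory_rating: DrynessCategory
    model1_rating: DrynessCategory
    model2_rating: DrynessCategory
    model3_rating: DrynessCategory

    def __post_init__(self) -> None:
        for name in (
            "nyca_rating",
            "sensory_rating",
            "model1_rating",
            "model2_rating",
            "model3_rating",
        ):
            setattr(self, name, DrynessCategory.from_label(getattr(self, name)))
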