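"""Ordinal dryness categories.

Commercial cider is marketed in four dryness classes, historically anchored to
residual sugar: dry (<9 g/L), semi-dry (9-18 g/L), semi-sweet (18-45 g/L) and
sweet (>45 g/L). The classes form a total order, which is what every scale,
predictor and agreement statistic in this package operates on.
"""
from __future__ import annotations

import enum


class DrynessCategory(enum.IntEnum):
    """Four-level ordinal dryness rating, dry < semi-dry < semi-sweet < sweet."""

    DRY = 0
    SEMI_DRY = 1
    SEMI_SWEET = 2
    SWEET = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    @classmethod
    def from_label(cls, label: object) -> "DrynessCategory":
        """Parse a printed label, tolerating spelling variants.

        Published tables mix "semi-dry"/"semidry" and the IRF guideline wording
        "medium dry"/"medium sweet"; all normalize to one category.
        """
        if isinstance(label, cls):
            return label
        key = "".join(ch for ch in str(label).lower() if ch.isalpha())
        try:
            return _ALIASES[key]
        except KeyError:
            raise ValueError(f"unknown dryness label: {label!r}") from None


_LABELS = {
    DrynessCategory.DRY: "dry",
    DrynessCategory.SEMI_DRY: "semi-dry",
    DrynessCategory.SEMI_SWEET: "semi-sweet",
    DrynessCategory.SWEET: "sweet",
}

_ALIASES = {
    "dry": DrynessCategory.DRY,
    "semidry": DrynessCategory.SEMI_DRY,
    "mediumdry": DrynessCategory.SEMI_DRY,
    "semisweet": DrynessCategory.SEMI_SWEET,
    "mediumsweet": DrynessCategory.SEMI_SWEET,
    "sweet": DrynessCategory.SWEET,
}
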