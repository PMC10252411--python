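"""Seeded synthetic cider chemistry with a known latent dryness model.

The generator emulates the marginal structure of the study's composition
summaries (per-variable min/max, median and upper quartile) and induces
dependence between chemically linked pairs through a Gaussian copula:
polyphenols drive the 280-nm absorbance, hydroxycinnamic acids the 320-nm
absorbance, and malic acid dominates titratable acidity. A latent linear
dryness equation plus homoscedastic Gaussian panel noise provides ground
truth for parameter-recovery, significance-screening and outlier tests.

Marginal families are the package's choice (the source gives only summary
statistics): right-skewed concentrations are log-normal matched to the
printed median and upper quartile, pH is uniform over the printed range and
acids are triangular over [min, max] with the printed median as mode. Every
generated value is hard-truncated to the printed min/max. Tannins have no
published summary (they appear only in scale narratives, up to 5000 mg/L),
so their default marginal is uniform on [0, 5000] and deliberately
unanchored.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .predictor import EQUATION_1, DrynessEquation, predict_dryness

_Z_Q3 = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class Marginal:
    """One variable's distribution: family, parameters, hard bounds.

    Families: ``uniform`` over [lo, hi]; ``triangular`` with ``params=(mode,)``
    over [lo, hi]; ``lognormal`` with ``params=(median, q3)``, then truncated
    to [lo, hi].
    """

    family: str
    lo: float
    hi: float
    params: tuple = ()

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"lo {self.lo} > hi {self.hi}")
        if self.family == "triangular":
            (mode,) = self.params
            if not self.lo <= mode <= self.hi:
                raise ValueError(f"triangular mode {mode} outside [{self.lo}, {self.hi}]")
        elif self.family == "lognormal":
            median, q3 = self.params
            if not 0 < median <= q3:
                raise ValueError(f"lognormal needs 0 < median <= q3, got {self.params}")
        elif self.family != "uniform":
            raise ValueError(f"unknown marginal family {self.family!r}")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "uniform":
            values = self.lo + u * (self.hi - self.lo)
        elif self.family == "triangular":
            (mode,) = self.params
            span = self.hi - self.lo
            if span == 0:
                values = np.full_like(u, self.lo)
            else:
                values = stats.triang.ppf(
                    u, c=(mode - self.lo) / span, loc=self.lo, scale=span
                )
        else:  # lognormal
            median, q3 = self.params
            mu = np.log(median)
            sigma = (np.log(q3) - mu) / _Z_Q3 if q3 > median else 0.0
            values = np.exp(mu + sigma * stats.norm.ppf(u))
        return np.clip(values, self.lo, self.hi)


#: defaults matched to the calibration-set composition summaries; each number
#: next to the statistic it targets (median/Q3 for log-normals, min/max bounds)
DEFAULT_MARGINALS: Mapping[str, Marginal] = {
    "alcohol": Marginal("lognormal", 5.03, 20.22, (7.28, 8.16)),
    "ph": Marginal("uniform", 3.26, 3.98),
    "malic_acid": Marginal("triangular", 0.0, 0.83, (0.47,)),
    "titratable_acidity": Marginal("triangular", 0.25, 0.93, (0.56,)),
    "residual_sugar": Marginal("lognormal", 1.0, 7689.0, (361.83, 1738.67)),
    "polyphenols": Marginal("lognormal", 50.4, 5399.0, (435.7, 702.1)),
    "hydroxybenzoic": Marginal("lognormal", 15.0, 109.7, (24.5, 28.8)),
    "hydroxycinnamic": Marginal("lognormal", 7.0, 398.0, (76.5, 139.3)),
    "abs320": Marginal("lognormal", 0.0120, 0.3758, (0.0760, 0.1492)),
    "abs280": Marginal("lognormal", 0.0279, 4.5855, (0.2329, 0.3858)),
    "tannins": Marginal("uniform", 0.0, 5000.0),
}

#: Gaussian-copula correlation targets for chemically linked pairs
DEFAULT_CORRELATIONS: Mapping[tuple, float] = {
    ("polyphenols", "abs280"): 0.8,
    ("hydroxycinnamic", "abs320"): 0.8,
    ("malic_acid", "titratable_acidity"): 0.85,
}


@dataclass(frozen=True)
class OutlierSpec:
    """How many samples to displace and by how many pooled SDs."""

    n_outliers: int
    displacement_sd: float

    def __post_init__(self):
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        if self.n_outliers > 0 and self.displacement_sd <= 0:
            raise ValueError("displacement must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 76
    seed: int = 0
    marginals: Mapping[str, Marginal] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    correlation: Mapping[tuple, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS)
    )
    true_equation: DrynessEquation = EQUATION_1
    panel_noise_sd: float = 0.5
    outlier_spec: Optional[OutlierSpec] = None

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.panel_noise_sd < 0:
            raise ValueError("panel_noise_sd must be >= 0")
        for pair, rho in self.correlation.items():
            if not -1 < rho < 1:
                raise ValueError(f"correlation target for {pair} outside (-1, 1)")
            for name in pair:
                if name not in self.marginals:
                    raise ValueError(f"correlation names unknown variable {name!r}")


def _correlation_matrix(config: SyntheticConfig, names: Sequence[str]) -> np.ndarray:
    k = len(names)
    index = {name: i for i, name in enumerate(names)}
    C = np.eye(k)
    for (a, b), rho in config.correlation.items():
        C[index[a], index[b]] = C[index[b], index[a]] = rho
    return C


def generate_chemistry(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a seeded, reproducible chemistry table.

    Correlated uniforms come from a Gaussian copula over the configured pairs;
    each variable is then mapped through its marginal ppf and hard-truncated
    to the configured bounds.
    """
    names = list(config.marginals)
    rng = np.random.default_rng(config.seed)
    C = _correlation_matrix(config, names)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation targets are not jointly feasible") from exc
    Z = rng.standard_normal((config.n_samples, len(names))) @ L.T
    U = ndtr(Z)
    data = {"sample_id": [f"S{i + 1:03d}" for i in range(config.n_samples)]}
    for j, name in enumerate(names):
        data[name] = config.marginals[name].ppf(U[:, j])
    return pd.DataFrame(data)


def generate_panel_scores(
    chemistry: pd.DataFrame, config: SyntheticConfig
) -> np.ndarray:
    """Latent dryness through the true equation plus panel noise, clipped to [0, 8].

    Uses a noise stream derived from (seed, 1) so chemistry and panel noise are
    independently reproducible.
    """
    truth = np.array(
        [
            predict_dryness(config.true_equation, row, clip=False)
            for _, row in chemistry.iterrows()
        ]
    )
    rng = np.random.default_rng([config.seed, 1])
    noise = rng.normal(0.0, config.panel_noise_sd, size=len(truth))
    return np.clip(truth + noise, 0.0, 8.0)


def inject_outliers(
    chemistry: pd.DataFrame,
    spec: OutlierSpec,
    seed: int,
) -> tuple[pd.DataFrame, list]:
    """Displace chosen samples along the first principal direction.

    The displacement is applied in autoscaled space (so "SD" means pooled
    standard deviations) and mapped back to original units. Returns the new
    table and the displaced sample ids.
    """
    if spec.n_outliers > len(chemistry):
        raise ValueError(
            f"requested {spec.n_outliers} outliers from {len(chemistry)} samples"
        )
    if spec.n_outliers == 0:
        return chemistry.copy(), []
    numeric = [c for c in chemistry.columns if c != "sample_id"]
    X = chemistry[numeric].to_numpy(dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    scales[scales == 0] = 1.0
    Z = (X - means) / scales
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    direction = Vt[0]
    rng = np.random.default_rng(seed)
    rows = rng.choice(len(chemistry), size=spec.n_outliers, replace=False)
    Z[rows] += spec.displacement_sd * direction
    out = chemistry.copy()
    out[numeric] = Z * scales + means
    ids = [chemistry["sample_id"].iloc[i] for i in sorted(rows)]
    return out, ids


def generate_dataset(config: SyntheticConfig):
    """Chemistry + panel scores (+ optional outliers); returns (table, scores, ids)."""
    chemistry = generate_chemistry(config)
    outlier_ids: list = []
    if config.outlier_spec is not None:
        chemistry, outlier_ids = inject_outliers(
            chemistry, config.outlier_spec, seed=config.seed + 7919
        )
    scores = generate_panel_scores(chemistry, config)
    return chemistry, scores, outlier_ids
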