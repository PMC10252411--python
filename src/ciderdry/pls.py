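"""Single-response partial least squares (PLS1) calibration, written from
scratch with the NIPALS algorithm.

The engine covers the full calibration workflow used to relate cider chemistry
to panel dryness: autoscaled NIPALS decomposition, explained variance per
factor, segmented cross-validation with a seeded random partition, weighted
regression coefficients (Bw, on autoscaled predictors, comparable across
variables with different units), Martens-style jackknife 95% uncertainty
limits for coefficient screening, and Hotelling T-squared outlier flagging on
the factor scores.

Numerical conventions
---------------------
* Autoscaling (column centering + unit variance, ddof=1) is the default for X;
  y is centered only. Raw-scale coefficients and an intercept are always
  back-transformed and stored alongside Bw.
* NIPALS factor extraction stops with an error if the residual X norm falls
  below 1e-12 of the original before the requested factor count is reached;
  more factors than the data can support is an error, not silent truncation.
* RMSEC uses the n denominator; SEC is the bias-corrected residual standard
  deviation (mean residual removed, n-1 denominator), so SEC >= RMSEC *
  sqrt((n-1)/n) ... the paired reporting convention of chemometric software.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

ArrayLike = Union[np.ndarray, pd.DataFrame, Sequence[Sequence[float]]]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500
_RESIDUAL_FLOOR = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition and regression coefficients."""

    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    w_weights: np.ndarray        # p x A
    p_loadings: np.ndarray       # p x A
    q_loadings: np.ndarray       # A
    t_scores: np.ndarray         # n x A
    b_weighted: np.ndarray       # coefficients on autoscaled X (Bw)
    b_raw: np.ndarray            # coefficients on original variable scale
    intercept: float
    explained_variance_x: np.ndarray  # per-factor %
    explained_variance_y: np.ndarray  # per-factor %
    n_factors: int
    autoscale: bool
    feature_names: tuple = ()
    sample_ids: tuple = ()

    def predict(self, X: ArrayLike) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        return X @ self.b_raw + self.intercept


@dataclass
class CalibrationMetrics:
    """Calibration fit quality plus the cross-validated error."""

    r2: float
    rmsec: float
    sec: float
    rmsecv: float


@dataclass
class CVResult:
    metrics: CalibrationMetrics
    model: PLSModel                 # fitted on all samples
    submodels: list                 # one PLSModel per held-out segment
    segments: list                  # index arrays of held-out samples
    y_cv: np.ndarray                # held-out predictions in sample order


@dataclass
class UncertaintyResult:
    """Jackknife screening of Bw coefficients: point, 95% limits, flags."""

    feature_names: tuple
    b_weighted: np.ndarray
    standard_error: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray
    alpha: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b_weighted": self.b_weighted,
                "se": self.standard_error,
                "lower": self.lower,
                "upper": self.upper,
                "significant": self.significant,
            },
            index=list(self.feature_names) or None,
        )


@dataclass
class OutlierReport:
    """Hotelling T-squared per sample against the F-based critical value."""

    t2: np.ndarray
    critical_value: float
    flagged: list
    alpha: float
    sample_ids: tuple = ()


def _as_matrix(X: ArrayLike, expected_names: tuple = ()) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if expected_names:
            X = X[list(expected_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def fit_pls1(
    X: ArrayLike,
    y: ArrayLike,
    n_factors: int,
    autoscale: bool = True,
    sample_ids: Optional[Sequence] = None,
) -> PLSModel:
    """Fit a PLS1 model by NIPALS with deflation.

    X may be a DataFrame (column names become feature names) or an array.
    Requires n >= 3, no missing values, every column with nonzero variance,
    and 1 <= n_factors <= min(n - 1, p).
    """
    feature_names = tuple(X.columns) if isinstance(X, pd.DataFrame) else ()
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]}")
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite with no missing values")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(
            f"n_factors={n_factors} outside [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )

    x_means = X.mean(axis=0)
    if autoscale:
        x_scales = X.std(axis=0, ddof=1)
    else:
        x_scales = np.ones(p)
    zero_var = np.flatnonzero(X.std(axis=0, ddof=1) <= 0)
    if zero_var.size:
        names = [feature_names[j] if feature_names else f"column {j}" for j in zero_var]
        raise ValueError(f"zero-variance X column(s): {names}")

    Xc = (X - x_means) / x_scales
    y_mean = float(y.mean())
    yc = y - y_mean

    ssx = float((Xc**2).sum())
    ssy = float((yc**2).sum())

    Xr, yr = Xc.copy(), yc.copy()
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    T = np.empty((n, n_factors))
    q = np.empty(n_factors)
    evx = np.empty(n_factors)
    evy = np.empty(n_factors)

    for a in range(n_factors):
        if np.linalg.norm(Xr) <= _RESIDUAL_FLOOR * max(np.sqrt(ssx), 1.0):
            raise ValueError(
                f"X residual exhausted after {a} factor(s); requested {n_factors}"
            )
        w = np.zeros(p)
        # for a single response the weight converges in one pass; the loop is a
        # guard against pathological inputs
        for _ in range(_NIPALS_MAX_ITER):
            w_new = Xr.T @ yr
            norm = np.linalg.norm(w_new)
            if norm <= _RESIDUAL_FLOOR:
                raise ValueError(
                    f"no covariance left between X and y after {a} factor(s)"
                )
            w_new /= norm
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xr @ w
        tt = float(t @ t)
        if tt <= _RESIDUAL_FLOOR:
            raise ValueError(f"degenerate score vector at factor {a + 1}")
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t) / tt
        Xr -= np.outer(t, p_a)
        yr -= q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        evx[a] = 100.0 * tt * float(p_a @ p_a) / ssx if ssx > 0 else 0.0
        evy[a] = 100.0 * q_a**2 * tt / ssy if ssy > 0 else 0.0

    b_weighted = W @ np.linalg.solve(P.T @ W, q)
    b_raw = b_weighted / x_scales
    intercept = y_mean - float(b_raw @ x_means)

    return PLSModel(
        x_means=x_means,
        x_scales=x_scales,
        y_mean=y_mean,
        w_weights=W,
        p_loadings=P,
        q_loadings=q,
        t_scores=T,
        b_weighted=b_weighted,
        b_raw=b_raw,
        intercept=intercept,
        explained_variance_x=evx,
        explained_variance_y=evy,
        n_factors=n_factors,
        autoscale=autoscale,
        feature_names=feature_names,
        sample_ids=tuple(sample_ids) if sample_ids is not None else (),
    )


def explained_variance(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor explained variance (%) for X and y, as stored at fit time."""
    return model.explained_variance_x, model.explained_variance_y


def select_n_factors(cv_curve: Sequence[float], plateau_tol: float = 0.01) -> int:
    """Smallest factor count after which RMSECV stops improving.

    Returns the smallest k such that the relative improvement from k to k+1 is
    below ``plateau_tol``; the curve length caps the answer.
    """
    curve = np.asarray(cv_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("cv_curve must be non-empty")
    for k in range(1, curve.size):
        prev = curve[k - 1]
        improvement = (prev - curve[k]) / abs(prev) if prev != 0 else 0.0
        if improvement < plateau_tol:
            return k
    return int(curve.size)


def cross_validate(
    X: ArrayLike,
    y: ArrayLike,
    n_factors: int,
    n_segments: int = 20,
    seed: int = 0,
    autoscale: bool = True,
) -> CVResult:
    """Segmented cross-validation with a seeded random partition.

    Samples are permuted by the seeded generator and split into ``n_segments``
    near-equal segments; each segment is predicted by a model fitted on the
    remainder. ``n_segments == n`` gives leave-one-out. Calibration metrics
    (R2, RMSEC, SEC) come from the full-data fit, RMSECV from the held-out
    predictions.
    """
    feature_frame = X if isinstance(X, pd.DataFrame) else None
    Xa = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    n = ya.shape[0]
    if not 2 <= n_segments <= n:
        raise ValueError(f"n_segments={n_segments} outside [2, n={n}]")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    segments = [seg for seg in np.array_split(order, n_segments)]

    def _fit(rows: np.ndarray) -> PLSModel:
        if feature_frame is not None:
            return fit_pls1(feature_frame.iloc[rows], ya[rows], n_factors, autoscale)
        return fit_pls1(Xa[rows], ya[rows], n_factors, autoscale)

    full = _fit(np.arange(n))
    y_cv = np.empty(n)
    submodels = []
    for seg in segments:
        train = np.setdiff1d(np.arange(n), seg)
        sub = _fit(train)
        y_cv[seg] = sub.predict(Xa[seg])
        submodels.append(sub)

    residuals = ya - full.predict(Xa)
    rmsec = float(np.sqrt(np.mean(residuals**2)))
    sec = float(np.sqrt(np.sum((residuals - residuals.mean()) ** 2) / (n - 1)))
    ss_tot = float(np.sum((ya - ya.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else float("nan")
    rmsecv = float(np.sqrt(np.mean((ya - y_cv) ** 2)))

    metrics = CalibrationMetrics(r2=r2, rmsec=rmsec, sec=sec, rmsecv=rmsecv)
    return CVResult(metrics=metrics, model=full, submodels=submodels,
                    segments=segments, y_cv=y_cv)


def jackknife_uncertainty(
    full_model: PLSModel,
    submodels: Sequence[PLSModel],
    alpha: float = 0.05,
) -> UncertaintyResult:
    """Martens jackknife uncertainty limits for the Bw coefficients.

    The jackknife variance for each variable is the sum of squared deviations
    of the segment coefficients from the full-model coefficient, scaled by
    (M-1)/M over M segments; limits use the t quantile with M-1 degrees of
    freedom. A coefficient is significant when its interval excludes zero.
    """
    M = len(submodels)
    if M < 2:
        raise ValueError(f"need at least 2 submodels, got {M}")
    b_full = full_model.b_weighted
    B = np.vstack([m.b_weighted for m in submodels])
    if B.shape[1] != b_full.shape[0]:
        raise ValueError("submodels and full model disagree on the variable set")
    se = np.sqrt((M - 1) / M * np.sum((B - b_full) ** 2, axis=0))
    tq = float(stats.t.ppf(1 - alpha / 2, M - 1))
    lower = b_full - tq * se
    upper = b_full + tq * se
    significant = (lower > 0) | (upper < 0)
    return UncertaintyResult(
        feature_names=full_model.feature_names,
        b_weighted=b_full,
        standard_error=se,
        lower=lower,
        upper=upper,
        significant=significant,
        alpha=alpha,
    )


def hotelling_t2(model: PLSModel, alpha: float = 0.05) -> OutlierReport:
    """Hotelling T-squared outlier flagging on the factor scores.

    Scores of different factors are mutually orthogonal, so the score
    covariance is diagonal and T2 reduces to a variance-scaled squared
    distance. The critical value is k(n-1)/(n-k) * F(1-alpha; k, n-k) over the
    k factors with nonzero score variance.
    """
    T = model.t_scores
    n = T.shape[0]
    variances = T.var(axis=0, ddof=1)
    tol = _RESIDUAL_FLOOR * max(1.0, float(variances.max(initial=0.0)))
    active = variances > tol
    k = int(active.sum())
    if k == 0:
        t2 = np.zeros(n)
        critical = 0.0
    else:
        if n <= k:
            raise ValueError(f"need n > k factors for the F transform (n={n}, k={k})")
        t2 = np.sum(T[:, active] ** 2 / variances[active], axis=1)
        critical = float(
            k * (n - 1) / (n - k) * stats.f.ppf(1 - alpha, k, n - k)
        )
    flagged_idx = np.flatnonzero(t2 > critical)
    ids = model.sample_ids or tuple(range(n))
    flagged = [ids[i] for i in flagged_idx]
    return OutlierReport(
        t2=t2, critical_value=critical, flagged=flagged, alpha=alpha,
        sample_ids=tuple(ids),
    )
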