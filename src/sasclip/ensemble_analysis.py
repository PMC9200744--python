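"""Diversity of scattering curves within a clipped ensemble.

When a single conformational coordinate X (for a hinged protein, the
inter-domain distance D_a-a′) modulates the intensity approximately
linearly,

    I(Q, X) ≈ I(Q, X₀) + (X − X₀) · ∂I(Q, X)/∂X,

the per-frame curves of an ensemble pivot about isosbestic points —
Q values where ∂I/∂X ≈ 0 and all curves intersect. This module detects
such points from the per-Q spread of log₁₀ I, fits the per-Q linear
response of I on a supplied coordinate, and recombines several clipped
ensembles against a secondary observable by non-negative, sum-to-one
least squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .clipper import ProfileSeries

__all__ = [
    "LinearResponseModel",
    "RecombinationResult",
    "intensity_spread",
    "isosbestic_points",
    "linear_response_fit",
    "recombine_ensembles",
]


@dataclass(frozen=True)
class LinearResponseModel:
    """Per-Q OLS fit of I(Q) on a conformational coordinate X.

    ``intercept`` is I(Q, X₀) at the reference X₀ (the sample mean of
    x), ``slope`` the per-Q response ∂I/∂X, ``r2`` the coefficient of
    determination.
    """

    q: np.ndarray
    intercept: np.ndarray
    slope: np.ndarray
    r2: np.ndarray
    x0: float

    def __post_init__(self) -> None:
        for name in ("q", "intercept", "slope", "r2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.q.shape == self.intercept.shape == self.slope.shape == self.r2.shape):
            raise ValueError("per-Q arrays must have equal length")


@dataclass(frozen=True)
class RecombinationResult:
    """Convex-combination weights of clipped ensembles fitting a target."""

    weights: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


def intensity_spread(series: ProfileSeries) -> np.ndarray:
    """Per-Q sample standard deviation of log₁₀ I across frames.

    Requires ≥ 2 frames and strictly positive intensities everywhere.
    """
    I = series.per_frame
    if I.shape[0] < 2:
        raise ValueError("need at least 2 frames for a spread")
    if np.any(I <= 0):
        raise ValueError("non-positive intensity: cannot take log10")
    return np.std(np.log10(I), axis=0, ddof=1)


def isosbestic_points(
    series: ProfileSeries,
    q_band: tuple[float, float],
    tolerance_factor: float = 0.25,
) -> list[float]:
    """Q values where the ensemble's curves (nearly) intersect.

    Candidates are local minima of the per-Q spread of log₁₀ I within
    ``q_band`` whose spread falls below ``tolerance_factor`` × the
    median band spread. A degenerate ensemble (all frames identical,
    spread ≈ 0 everywhere) yields no points, with a warning. Because
    the spread of log₁₀ I is unchanged by a uniform intensity
    rescaling, so is the result.
    """
    spread = intensity_spread(series)
    q = series.q
    lo, hi = q_band
    band = (q >= lo) & (q <= hi)
    if not np.any(band):
        raise ValueError("empty Q band")
    band_spread = spread[band]
    if np.max(spread) < 1e-14:
        warnings.warn("degenerate ensemble: all frames identical", stacklevel=2)
        return []
    threshold = np.median(band_spread) * tolerance_factor
    idx = np.flatnonzero(band)
    points = []
    for i in idx:
        left = spread[i - 1] if i > 0 else np.inf
        right = spread[i + 1] if i < spread.size - 1 else np.inf
        if spread[i] <= left and spread[i] <= right and spread[i] < threshold:
            # plateau tie-break: keep only the first point of a flat run
            if i > 0 and spread[i] == spread[i - 1] and (i - 1) in idx:
                continue
            points.append(float(q[i]))
    return sorted(points)


def linear_response_fit(series: ProfileSeries, x) -> LinearResponseModel:
    """Per-Q ordinary least squares of I(Q) on a coordinate x.

    The fitted line is I(Q) ≈ I(Q, X₀) + (x − X₀)·slope(Q) with
    X₀ = mean(x); the intercept at X₀ is therefore the per-Q mean
    intensity. Unweighted (per-frame curves carry no uncertainties).
    """
    x = np.asarray(x, dtype=float)
    I = series.per_frame
    if x.shape != (I.shape[0],):
        raise ValueError("x must have one value per frame")
    dx = x - x.mean()
    var_x = np.sum(dx * dx)
    if var_x == 0:
        raise ValueError("constant coordinate x")
    mean_I = I.mean(axis=0)
    dI = I - mean_I
    slope = (dx @ dI) / var_x
    ss_tot = np.sum(dI * dI, axis=0)
    ss_reg = slope * slope * var_x
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / ss_tot, 0.0)
    return LinearResponseModel(
        q=series.q,
        intercept=mean_I,
        slope=slope,
        r2=np.clip(r2, 0.0, 1.0),
        x0=float(x.mean()),
    )


def _simplex_lstsq(A: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Minimize ||cᵀA − target|| subject to c ≥ 0, Σc = 1.

    Exact active-set search: every support set is solved as an
    equality-constrained least-squares problem via its KKT system and
    the best feasible solution kept. Exponential in the number of
    series, which is small in practice (≤ ~15 clipped ensembles).
    """
    n = A.shape[0]
    best_c, best_obj = None, np.inf
    for r in range(1, n + 1):
        for support in itertools.combinations(range(n), r):
            S = list(support)
            As = A[S]  # (r, dim)
            G = As @ As.T
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = 2.0 * G
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.concatenate([2.0 * As @ target, [1.0]])
            try:
                sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            except np.linalg.LinAlgError:
                continue
            c_s = sol[:r]
            if np.any(c_s < -1e-9) or abs(c_s.sum() - 1.0) > 1e-8:
                continue
            c = np.zeros(n)
            c[S] = np.clip(c_s, 0.0, None)
            c /= c.sum()
            obj = float(np.linalg.norm(c @ A - target))
            if obj < best_obj - 1e-15:
                best_c, best_obj = c, obj
    assert best_c is not None  # the single-vertex supports are always feasible
    return best_c


def recombine_ensembles(
    per_series_means, target, constrain_simplex: bool = True
) -> RecombinationResult:
    """Weights cᵢ expressing a target observable as X = Σ cᵢ X_SAS-CLIP,i.

    ``per_series_means`` is (n_series, dim): row i is the observable
    averaged over all structures of clipped series i. By default the
    weights form a convex combination (cᵢ ≥ 0, Σ cᵢ = 1), the natural
    constraint for mixing ensemble populations; ``constrain_simplex
    =False`` gives the plain unconstrained least-squares solution.
    """
    A = np.atleast_2d(np.asarray(per_series_means, dtype=float))
    target = np.asarray(target, dtype=float)
    if target.shape != (A.shape[1],):
        raise ValueError("target dimension must match the observable dimension")
    if A.shape[1] < A.shape[0]:
        warnings.warn(
            "fewer observable dimensions than series: weights may be unidentifiable",
            stacklevel=2,
        )
    if constrain_simplex:
        c = _simplex_lstsq(A, target)
    else:
        c = np.linalg.lstsq(A.T, target, rcond=None)[0]
    resid = float(np.linalg.norm(c @ A - target))
    return RecombinationResult(weights=c, residual_norm=resid)
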