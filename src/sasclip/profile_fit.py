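"""Scale/offset fitting of a model curve to a measured SAXS profile.

The model intensity for a window of M frames is

    I_sim(Q_i) = c · Σ_j I_sim,j(Q_i) − offs,

where c and offs are the two adjustment parameters (offs absorbs a
possible buffer mismatch) determined by ∂χ²/∂c = 0, ∂χ²/∂offs = 0, and

    χ² = 1/(N−1) · Σ_i ((I_exp(Q_i) − I_sim(Q_i)) / σ(Q_i))².

The divisor is N−1 by definition here, even though two parameters are
fitted; it is not "corrected" to N−2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import ExperimentalProfile

__all__ = ["FitResult", "BandResult", "fit_scale_offset", "squared_residual_band"]


@dataclass(frozen=True)
class FitResult:
    """Optimal (c, offs) fit of a summed window profile to experiment.

    ``squared_residuals`` holds ((I_exp − I_sim)/σ)² per Q point at the
    optimum; ``chi2`` is their sum divided by N−1. ``n_models`` records
    the number M of frame profiles summed into the model curve.
    """

    c: float
    offs: float
    chi2: float
    squared_residuals: np.ndarray
    n_models: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "squared_residuals", np.asarray(self.squared_residuals, dtype=float)
        )


def _solve_scale_offset(model, intensity, weights):
    """Weighted normal equations for I_exp ≈ c·model − offs.

    Returns (c, offs). Raises on a (weighted-)constant model, for which
    the 2x2 system is singular.
    """
    sw = np.sum(weights)
    sm = np.sum(weights * model)
    smm = np.sum(weights * model * model)
    si = np.sum(weights * intensity)
    smi = np.sum(weights * model * intensity)
    det = smm * sw - sm * sm
    scale = max(smm * sw, sm * sm)
    if det <= 1e-12 * scale:
        raise ValueError("constant model: scale/offset fit is singular")
    c = (smi * sw - sm * si) / det
    offs = (c * sm - si) / sw
    return c, offs


def fit_scale_offset(
    exp: ExperimentalProfile, model, n_models: int = 1
) -> FitResult:
    """Fit ``c·model − offs`` to an experimental profile, weights 1/σ².

    ``model`` is the summed (not averaged) window profile evaluated on
    ``exp.q``; c absorbs the 1/M factor. A negative fitted c is
    physically unreasonable and triggers a warning but not an error.
    """
    model = np.asarray(model, dtype=float)
    n = exp.n_points
    if model.shape != (n,):
        raise ValueError("model length must equal the experimental grid length")
    if n < 3:
        raise ValueError("need at least 3 data points to fit two parameters")
    weights = 1.0 / exp.sigma**2
    c, offs = _solve_scale_offset(model, exp.intensity, weights)
    if c < 0:
        warnings.warn("fitted scale factor c is negative", stacklevel=2)
    resid = (exp.intensity - (c * model - offs)) / exp.sigma
    sq = resid**2
    chi2 = float(np.sum(sq) / (n - 1))
    return FitResult(c=float(c), offs=float(offs), chi2=chi2, squared_residuals=sq, n_models=n_models)


@dataclass(frozen=True)
class BandResult:
    """Maximum squared residual in the low-Q band, with an empty-band flag."""

    value: float
    n_points: int
    empty: bool

    def __float__(self) -> float:
        return float(self.value)


def squared_residual_band(
    fit: FitResult, exp: ExperimentalProfile, q_max: float = 0.25
) -> BandResult:
    """Maximum of ((I_exp − I_sim)/σ)² over grid points with Q < q_max.

    The inequality is strict. With no qualifying point the result is 0
    and the ``empty`` flag is set (with a warning).
    """
    mask = exp.q < q_max
    if not np.any(mask):
        warnings.warn(f"no experimental points with Q < {q_max}", stacklevel=2)
        return BandResult(value=0.0, n_points=0, empty=True)
    band = fit.squared_residuals[mask]
    return BandResult(value=float(band.max()), n_points=int(band.size), empty=False)
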