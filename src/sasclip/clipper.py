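"""The clip search: longest contiguous window matching a SAXS profile.

Per-frame theoretical curves (normalized by their own I(0)) are
precomputed once on the experimental Q grid; prefix sums over frames
then give any window's summed profile in O(N_Q). The search is
exhaustive over all contiguous windows — the acceptance criterion is
*not* monotone in window extent (a passing window can contain a failing
sub-window and vice versa), so incremental two-pointer schemes are
unsound. Scanning window lengths from longest to shortest lets the
longest-window query stop at the first passing length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExperimentalProfile, Trajectory
from .profile_fit import FitResult, fit_scale_offset, squared_residual_band
from .scattering import debye_intensity_series

__all__ = [
    "ProfileSeries",
    "ClipCriteria",
    "ClipResult",
    "build_profile_series",
    "evaluate_window",
    "longest_matching_window",
    "enumerate_matching_windows",
    "duration",
]


@dataclass(frozen=True)
class ProfileSeries:
    """Per-frame normalized theoretical intensities on an experimental grid.

    ``per_frame[j]`` is frame j's Debye curve divided by its I(0);
    ``prefix_sums`` has ``n_frames + 1`` rows with
    ``prefix_sums[e] − prefix_sums[s]`` the summed profile of window
    ``[s, e)``.
    """

    q: np.ndarray
    per_frame: np.ndarray
    prefix_sums: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "per_frame", np.asarray(self.per_frame, dtype=float))
        if self.per_frame.ndim != 2 or self.per_frame.shape[1] != self.q.size:
            raise ValueError("per_frame must be (n_frames, n_q)")
        if np.any(self.per_frame < 0):
            raise ValueError("normalized intensities must be non-negative")
        if self.prefix_sums is None:
            ps = np.zeros((self.per_frame.shape[0] + 1, self.q.size))
            np.cumsum(self.per_frame, axis=0, out=ps[1:])
            object.__setattr__(self, "prefix_sums", ps)

    @property
    def n_frames(self) -> int:
        return int(self.per_frame.shape[0])

    def window_sum(self, start: int, end: int) -> np.ndarray:
        """Summed profile of window [start, end) via the prefix sums."""
        if not (0 <= start < end <= self.n_frames):
            raise ValueError("empty or out-of-range window")
        return self.prefix_sums[end] - self.prefix_sums[start]


@dataclass(frozen=True)
class ClipCriteria:
    """Acceptance thresholds for a clipped window.

    ``chi2_max`` and the per-point squared-residual bound ``resid_max``
    over Q < ``resid_q_max`` are both strict inequalities. With
    ``use_residual_band`` off only χ² is tested (the first-pass
    criterion); on, both conditions must hold (the improved criteria).
    ``min_duration`` (ns) is a reporting threshold only — results are
    flagged against it, never rejected by it.
    """

    chi2_max: float = 3.0
    resid_max: float = 12.5
    resid_q_max: float = 0.25
    min_duration: float = 700.0
    use_residual_band: bool = True

    def __post_init__(self) -> None:
        if min(self.chi2_max, self.resid_max, self.resid_q_max, self.min_duration) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ClipResult:
    """A clipped window [start_frame, end_frame) with its fit statistics."""

    start_frame: int
    end_frame: int
    duration_ns: float
    fit: FitResult | None
    found: bool
    max_sq_residual_band: float | None = None
    meets_min_duration: bool | None = None
    kl: float | None = None

    @classmethod
    def not_found(cls) -> "ClipResult":
        return cls(start_frame=-1, end_frame=-1, duration_ns=0.0, fit=None, found=False)


def duration(start: int, end: int, frame_interval: float = 2.0) -> float:
    """Duration L_t of window [start, end): snapshot count × ns/frame.

    The count is ``end − start`` (the number of snapshots), not
    ``end − start − 1``: a single snapshot lasts one frame interval.
    """
    if start >= end:
        raise ValueError("empty window")
    return (end - start) * frame_interval


def build_profile_series(trajectory: Trajectory, exp: ExperimentalProfile) -> ProfileSeries:
    """Debye curves of every frame on ``exp.q``, each normalized by its I(0)."""
    per_frame = debye_intensity_series(trajectory.frames, exp.q)
    return ProfileSeries(q=exp.q, per_frame=per_frame)


def _batch_window_stats(S: np.ndarray, exp: ExperimentalProfile, criteria: ClipCriteria):
    """Fit statistics for a batch of summed window profiles.

    ``S`` is (k, N_Q). Returns (chi2, band_max, passes, c, offs) arrays.
    Windows with a (weighted-)constant summed profile are marked failing.
    """
    intensity, sigma = exp.intensity, exp.sigma
    w = 1.0 / sigma**2
    n = exp.n_points
    sw = np.sum(w)
    si = np.sum(w * intensity)
    sii = np.sum(w * intensity * intensity)
    sm = S @ w
    smm = (S * S) @ w
    smi = S @ (w * intensity)
    det = smm * sw - sm * sm
    scale = np.maximum(smm * sw, sm * sm)
    ok = det > 1e-12 * np.maximum(scale, 1e-300)
    det_safe = np.where(ok, det, 1.0)
    c = (smi * sw - sm * si) / det_safe
    offs = (c * sm - si) / sw
    rss = sii - 2 * c * smi + 2 * offs * si + c * c * smm - 2 * c * offs * sm + offs * offs * sw
    chi2 = np.maximum(rss, 0.0) / (n - 1)
    band_mask = exp.q < criteria.resid_q_max
    if np.any(band_mask):
        resid_band = (
            intensity[band_mask][None, :]
            - c[:, None] * S[:, band_mask]
            + offs[:, None]
        ) / sigma[band_mask][None, :]
        band_max = np.max(resid_band**2, axis=1)
    else:
        band_max = np.zeros(S.shape[0])
    passes = ok & (chi2 < criteria.chi2_max)
    if criteria.use_residual_band:
        passes &= band_max < criteria.resid_max
    return chi2, band_max, passes, c, offs


def evaluate_window(
    series: ProfileSeries,
    start: int,
    end: int,
    exp: ExperimentalProfile,
    criteria: ClipCriteria,
):
    """Fit one window's summed profile and test it against the criteria.

    Returns ``(FitResult, passes)``. Passing requires χ² < ``chi2_max``
    (strict) and, when the residual band is enabled, every squared
    residual at Q < ``resid_q_max`` below ``resid_max`` (strict).
    """
    model = series.window_sum(start, end)
    fit = fit_scale_offset(exp, model, n_models=end - start)
    passes = fit.chi2 < criteria.chi2_max
    if criteria.use_residual_band:
        band = squared_residual_band(fit, exp, criteria.resid_q_max)
        passes = passes and band.value < criteria.resid_max
    return fit, bool(passes)


def _result_for_window(
    series: ProfileSeries,
    start: int,
    end: int,
    exp: ExperimentalProfile,
    criteria: ClipCriteria,
    frame_interval: float,
) -> ClipResult:
    fit, _ = evaluate_window(series, start, end, exp, criteria)
    band = squared_residual_band(fit, exp, criteria.resid_q_max)
    dur = duration(start, end, frame_interval)
    return ClipResult(
        start_frame=start,
        end_frame=end,
        duration_ns=dur,
        fit=fit,
        found=True,
        max_sq_residual_band=band.value,
        meets_min_duration=dur > criteria.min_duration,
    )


def longest_matching_window(
    series: ProfileSeries,
    exp: ExperimentalProfile,
    criteria: ClipCriteria,
    frame_interval: float = 2.0,
) -> ClipResult:
    """Longest contiguous window whose summed profile passes the criteria.

    All O(n²) windows are candidates; lengths are scanned from longest
    to shortest and, within a length, ties are broken by the smallest
    start. ``min_duration`` is only reported against (the
    ``meets_min_duration`` flag), so short matches are still returned.
    """
    n = series.n_frames
    P = series.prefix_sums
    for length in range(n, 0, -1):
        S = P[length:] - P[:-length]
        _, _, passes, _, _ = _batch_window_stats(S, exp, criteria)
        hits = np.flatnonzero(passes)
        if hits.size:
            start = int(hits[0])
            return _result_for_window(
                series, start, start + length, exp, criteria, frame_interval
            )
    return ClipResult.not_found()


def enumerate_matching_windows(
    series: ProfileSeries,
    exp: ExperimentalProfile,
    criteria: ClipCriteria,
    min_length: int = 1,
) -> list[tuple[int, int, FitResult]]:
    """Every passing window of length ≥ ``min_length``.

    Returned in lexicographic (start, end) order; an empty list when no
    window passes.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    n = series.n_frames
    P = series.prefix_sums
    out: list[tuple[int, int, FitResult]] = []
    for start in range(0, n - min_length + 1):
        ends = np.arange(start + min_length, n + 1)
        S = P[ends] - P[start]
        _, _, passes, _, _ = _batch_window_stats(S, exp, criteria)
        for k in np.flatnonzero(passes):
            end = int(ends[k])
            fit = fit_scale_offset(exp, S[k], n_models=end - start)
            out.append((start, end, fit))
    return out
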