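"""Theoretical SAXS intensities via the Debye equation, and p(r).

The orientation-averaged intensity of a bead model with constant
(small-angle) form factors f_i is

    I(Q) = Σ_i Σ_j f_i f_j sin(Q r_ij) / (Q r_ij),

with the i = j and Q → 0 terms evaluated as the sinc limit 1, so that
I(0) = (Σ f_i)² exactly. No excluded-volume or hydration-layer
corrections are applied: the bead model itself carries the physics, and
the fitted scale factor absorbs overall amplitude differences against a
measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .io_formats import BeadStructure

__all__ = [
    "TheoreticalCurve",
    "PairDistanceDistribution",
    "scattering_vector",
    "correlation_length",
    "debye_intensity",
    "normalize_curve",
    "pair_distance_distribution",
]


@dataclass(frozen=True)
class TheoreticalCurve:
    """A computed scattering curve on a Q grid.

    ``i_zero`` is the forward-scattering value I(0) used for
    normalization; for a Debye computation it equals (Σ f_i)².
    """

    q: np.ndarray
    intensity: np.ndarray
    i_zero: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")


@dataclass(frozen=True)
class PairDistanceDistribution:
    """Electron-weighted pair distance histogram (unnormalized).

    ``p[k]`` is the summed f_i·f_j over unordered pairs whose distance
    falls in ``[r_edges[k], r_edges[k+1])``; units electrons².
    """

    r_edges: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_edges", np.asarray(self.r_edges, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.size != self.r_edges.size - 1:
            raise ValueError("p must have one entry fewer than r_edges")


def scattering_vector(theta: float, lam: float):
    """Magnitude of the scattering vector, Q = 4π sin(θ)/λ.

    ``theta`` is the scattering half-angle in radians, ``lam`` the X-ray
    wavelength in Å; the result is in Å⁻¹.
    """
    if np.any(np.asarray(lam) <= 0):
        raise ValueError("wavelength must be positive")
    return 4.0 * np.pi * np.sin(theta) / lam


def correlation_length(q):
    """Real-space correlation length 2π/Q probed at scattering vector Q (Å)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("Q must be positive")
    out = 2.0 * np.pi / q
    return float(out) if out.ndim == 0 else out


def _pair_data(structure: BeadStructure):
    """Upper-triangle pair distances and weight products f_i·f_j."""
    coords = structure.coordinates
    w = structure.scattering_weight
    d = pdist(coords)
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return d, w[iu] * w[ju]


def debye_intensity(structure: BeadStructure, q_grid) -> TheoreticalCurve:
    """Evaluate the Debye double sum on ``q_grid`` (Å⁻¹).

    The sum runs over all ordered pairs; self-terms contribute f_i² and
    coincident or zero-Q terms take the analytic sinc limit 1. Cost is
    O(n² + n²·N_Q) and is evaluated with vectorized pair arrays.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q_grid must be non-negative")
    w = structure.scattering_weight
    d, wprod = _pair_data(structure)
    self_term = float(np.sum(w * w))
    # sinc(x) in numpy is sin(pi x)/(pi x); rescale so argument is Q*r.
    x = np.outer(q, d) / np.pi
    intensity = self_term + 2.0 * (np.sinc(x) @ wprod)
    i_zero = float(np.sum(w)) ** 2
    return TheoreticalCurve(q=q, intensity=intensity, i_zero=i_zero)


def debye_intensity_series(structures, q_grid) -> np.ndarray:
    """Normalized Debye curves for many frames, stacked as (frames, N_Q).

    Each row is divided by its own I(0) = (Σ f_i)²; frames share one
    topology so the weights are taken from the first frame.
    """
    q = np.asarray(q_grid, dtype=float)
    structures = list(structures)
    if not structures:
        raise ValueError("empty structure sequence")
    w = structures[0].scattering_weight
    n = structures[0].n_beads
    iu, ju = np.triu_indices(n, k=1)
    wprod = w[iu] * w[ju]
    self_term = float(np.sum(w * w))
    i_zero = float(np.sum(w)) ** 2
    if i_zero <= 0:
        raise ValueError("total scattering weight must be positive")
    out = np.empty((len(structures), q.size))
    for k, s in enumerate(structures):
        d = pdist(s.coordinates)
        x = np.outer(q, d) / np.pi
        out[k] = (self_term + 2.0 * (np.sinc(x) @ wprod)) / i_zero
    return out


def normalize_curve(curve: TheoreticalCurve) -> TheoreticalCurve:
    """Divide a curve by its forward scattering I(0).

    After normalization ``i_zero`` is reset to 1, which makes the
    operation idempotent; curves from structures differing only by a
    uniform weight scaling normalize identically.
    """
    if curve.i_zero <= 0:
        raise ValueError("i_zero must be positive to normalize")
    return TheoreticalCurve(
        q=curve.q, intensity=curve.intensity / curve.i_zero, i_zero=1.0
    )


def pair_distance_distribution(
    structure: BeadStructure, bin_width: float = 1.0
) -> PairDistanceDistribution:
    """Electron-weighted pair distance distribution p(r).

    Every unordered pair i < j with both weights > 0 adds f_i·f_j to the
    bin containing r_ij (left-closed bins of ``bin_width`` Å, starting at
    0). Self-pairs are excluded and weight-0 beads (hydrogens under the
    ignore-hydrogens rule) contribute nothing, so the histogram mass is
    exactly ((Σf)² − Σf²)/2.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d, wprod = _pair_data(structure)
    keep = wprod > 0
    d, wprod = d[keep], wprod[keep]
    if d.size == 0:
        edges = np.array([0.0, bin_width])
        return PairDistanceDistribution(r_edges=edges, p=np.zeros(1))
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    idx = np.floor(d / bin_width).astype(int)
    p = np.bincount(idx, weights=wprod, minlength=n_bins)
    return PairDistanceDistribution(r_edges=edges, p=p)
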