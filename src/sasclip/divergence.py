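"""Restricted Kullback–Leibler divergence between conformation maps.

The divergence compares a clipped window's (θ, θ) probability map
P_clip against its source trajectory's map P_orig, but only over the
region C1 ∪ C2, where C1 holds the bins the clipped series actually
visits (P_clip > 0) and C2 the bins adjacent to C1. P_orig is
renormalized to sum 1 over C1 ∪ C2 before the sum

    KL = Σ_{C1∪C2} P_clip · log(P_clip / P̃_orig),

so a window that samples only one of several stable states is not
penalized for the states it never enters — the statistic measures how
faithfully the window reproduces the source distribution *locally*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .descriptors import ProbabilityMap2D, theta_map

__all__ = ["SupportRegion", "support_union", "kl_sas_clip", "kl_vs_duration"]

_STRUCTURES = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass(frozen=True)
class SupportRegion:
    """Boolean masks for the clipped support C1 and its neighborhood C2."""

    c1: np.ndarray
    c2: np.ndarray

    def __post_init__(self) -> None:
        if self.c1.shape != self.c2.shape:
            raise ValueError("C1 and C2 masks must share a shape")
        if np.any(self.c1 & self.c2):
            raise ValueError("C1 and C2 must be disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.c1 | self.c2


def support_union(map_clip: ProbabilityMap2D, adjacency: int = 8) -> SupportRegion:
    """C1 = occupied bins of the clipped map; C2 = their neighborhood.

    ``adjacency`` selects the 8-neighborhood (diagonals included,
    default) or the 4-neighborhood; both are clipped at map borders.
    """
    if adjacency not in _STRUCTURES:
        raise ValueError("adjacency must be 4 or 8")
    c1 = map_clip.p > 0
    if not np.any(c1):
        raise ValueError("empty map: no occupied bins")
    dilated = ndimage.binary_dilation(c1, structure=_STRUCTURES[adjacency])
    return SupportRegion(c1=c1, c2=dilated & ~c1)


def kl_sas_clip(
    map_clip: ProbabilityMap2D,
    map_orig: ProbabilityMap2D,
    adjacency: int = 8,
    log_base: float | None = None,
) -> float:
    """Restricted KL divergence of a clipped map from its source map.

    Both maps must share identical bin edges. The source map is
    restricted to C1 ∪ C2 and renormalized to sum 1 there. Terms with
    P_clip = 0 contribute 0; a bin with P_clip > 0 but P_orig = 0 makes
    the divergence undefined and raises (it cannot occur when the
    clipped frames are a subset of the source frames under identical
    binning). ``log_base`` defaults to e (nats).
    """
    if not map_clip.same_binning(map_orig):
        raise ValueError("maps must share identical bin edges")
    region = support_union(map_clip, adjacency=adjacency)
    u = region.union
    p_clip = map_clip.p[u]
    p_orig = map_orig.p[u]
    if np.any((p_clip > 0) & (p_orig == 0)):
        raise ValueError(
            "undefined divergence: clipped map occupies a bin with zero "
            "source probability (maps come from inconsistent data)"
        )
    total = p_orig.sum()
    if total <= 0:
        raise ValueError("source map has zero mass on C1 ∪ C2")
    p_orig = p_orig / total
    pos = p_clip > 0
    kl = float(np.sum(p_clip[pos] * np.log(p_clip[pos] / p_orig[pos])))
    if log_base is not None:
        kl /= np.log(log_base)
    return kl


def kl_vs_duration(
    series,
    exp,
    criteria,
    desc,
    bin_width: float = 5.0,
    min_length: int = 1,
    frame_interval: float = 2.0,
    adjacency: int = 8,
    theta_range: tuple[float, float] = (0.0, 180.0),
) -> list[tuple[float, float]]:
    """(L_t, KL) pairs for every passing window of a trajectory.

    ``desc`` is the full trajectory's descriptor series; each
    enumerated window's (θ, θ) map is compared against the whole
    trajectory's map with identical binning. Used to reproduce the
    monotone KL-vs-duration decay that motivates the L_t threshold.
    """
    from .clipper import duration, enumerate_matching_windows

    map_orig = theta_map(desc, bin_width=bin_width, theta_range=theta_range)
    windows = enumerate_matching_windows(series, exp, criteria, min_length=min_length)
    out = []
    n = desc.n_frames
    for start, end, _fit in windows:
        mask = np.zeros(n, dtype=bool)
        mask[start:end] = True
        map_clip = theta_map(
            desc, bin_width=bin_width, theta_range=theta_range, frame_mask=mask
        )
        kl = kl_sas_clip(map_clip, map_orig, adjacency=adjacency)
        out.append((duration(start, end, frame_interval), kl))
    return out
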