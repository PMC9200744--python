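"""Per-frame domain-conformation descriptors and binned probability maps.

A multi-domain chain a–b–b′–a′ is summarized per frame by the angles
θ_a-b-b′ and θ_b-b′-a′ at the b and b′ hinges, the inter-domain dihedral
φ_a-b-b′-a′, two domain-orientation dihedrals that use the COM of the
redox-active CGHC motif as the fourth point, and the open–close distance
D_a-a′ between the catalytic domain centers. A domain center is the
unweighted mean of its backbone-bead coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import BeadStructure, DomainDefinition, Trajectory

__all__ = [
    "ConformationDescriptors",
    "ProbabilityMap2D",
    "domain_center",
    "angle_of_three",
    "dihedral_of_four",
    "descriptor_series",
    "probability_map",
]


@dataclass(frozen=True)
class ConformationDescriptors:
    """Per-frame domain geometry series (angles in degrees, D_a-a′ in Å).

    ``valid`` flags frames with non-degenerate geometry; degenerate
    frames carry NaN descriptors instead of aborting the series.
    """

    theta_abb: np.ndarray
    theta_bba: np.ndarray
    phi_abba: np.ndarray
    phi_orient_a: np.ndarray
    phi_orient_ap: np.ndarray
    d_aap: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.theta_abb.size)


@dataclass(frozen=True)
class ProbabilityMap2D:
    """Binned appearance probabilities on a 2-D descriptor space."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_edges", np.asarray(self.x_edges, dtype=float))
        object.__setattr__(self, "y_edges", np.asarray(self.y_edges, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.shape != (self.x_edges.size - 1, self.y_edges.size - 1):
            raise ValueError("p shape must match bin edges")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")

    def same_binning(self, other: "ProbabilityMap2D") -> bool:
        return np.array_equal(self.x_edges, other.x_edges) and np.array_equal(
            self.y_edges, other.y_edges
        )


def domain_center(frame: BeadStructure, domain: DomainDefinition) -> np.ndarray:
    """Unweighted mean of the backbone-bead coordinates in a residue range."""
    mask = domain.mask(frame, backbone_only=True)
    if not np.any(mask):
        raise ValueError(f"domain {domain.name!r} selects no backbone beads")
    return frame.coordinates[mask].mean(axis=0)


def angle_of_three(c1, c2, c3) -> float:
    """Angle at vertex c2 between (c1−c2) and (c3−c2), in degrees [0, 180]."""
    v1 = np.asarray(c1, dtype=float) - np.asarray(c2, dtype=float)
    v2 = np.asarray(c3, dtype=float) - np.asarray(c2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate geometry: coincident points in angle")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_of_four(c1, c2, c3, c4) -> float:
    """Signed IUPAC torsion about the c2–c3 axis, degrees in (−180, 180].

    0° is cis (c1 and c4 eclipsed), 180° trans; mirror-imaging the four
    points flips the sign.
    """
    p = [np.asarray(c, dtype=float) for c in (c1, c2, c3, c4)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0 or nb2 == 0:
        raise ValueError("degenerate geometry: collinear points in dihedral")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = float(np.degrees(np.arctan2(y, x)))
    # represent the cut point as +180, not -180
    return 180.0 if ang <= -180.0 else ang


def descriptor_series(
    trajectory: Trajectory,
    domains: dict,
    motifs: dict | None = None,
) -> ConformationDescriptors:
    """Compute the descriptor series for every frame of a trajectory.

    ``domains`` maps the keys ``"a", "b", "bp", "ap"`` to
    :class:`DomainDefinition`; ``motifs`` optionally maps ``"cghc_a"``
    and ``"cghc_ap"`` to the motif residue ranges (orientation dihedrals
    are NaN when absent). Frames with degenerate geometry are flagged
    invalid (NaN values), not fatal.
    """
    required = ("a", "b", "bp", "ap")
    for key in required:
        if key not in domains:
            raise ValueError(f"missing domain definition {key!r}")
    motifs = motifs or {}
    top = trajectory.topology
    masks = {k: domains[k].mask(top, backbone_only=True) for k in required}
    for k, m in masks.items():
        if not np.any(m):
            raise ValueError(f"domain {k!r} selects no backbone beads")
    motif_masks = {}
    for k in ("cghc_a", "cghc_ap"):
        if k in motifs:
            mm = motifs[k].mask(top, backbone_only=True)
            if not np.any(mm):
                raise ValueError(f"motif {k!r} selects no backbone beads")
            motif_masks[k] = mm

    n = trajectory.n_frames
    out = {
        name: np.full(n, np.nan)
        for name in ("theta_abb", "theta_bba", "phi_abba", "phi_orient_a", "phi_orient_ap", "d_aap")
    }
    valid = np.ones(n, dtype=bool)
    for j, frame in enumerate(trajectory.frames):
        coords = frame.coordinates
        com = {k: coords[m].mean(axis=0) for k, m in masks.items()}
        out["d_aap"][j] = float(np.linalg.norm(com["a"] - com["ap"]))
        try:
            out["theta_abb"][j] = angle_of_three(com["a"], com["b"], com["bp"])
            out["theta_bba"][j] = angle_of_three(com["b"], com["bp"], com["ap"])
            out["phi_abba"][j] = dihedral_of_four(com["a"], com["b"], com["bp"], com["ap"])
            if "cghc_a" in motif_masks:
                motif = coords[motif_masks["cghc_a"]].mean(axis=0)
                out["phi_orient_a"][j] = dihedral_of_four(com["bp"], com["b"], com["a"], motif)
            if "cghc_ap" in motif_masks:
                motif = coords[motif_masks["cghc_ap"]].mean(axis=0)
                out["phi_orient_ap"][j] = dihedral_of_four(com["b"], com["bp"], com["ap"], motif)
        except ValueError:
            valid[j] = False
    return ConformationDescriptors(valid=valid, **out)


def probability_map(xs, ys, x_edges, y_edges) -> ProbabilityMap2D:
    """Bin 2-D samples and normalize counts so the map sums to 1.

    Points outside the outermost edges are clipped into the edge bins
    with a warning; NaN pairs are dropped. Bins are left-closed with the
    final bin right-closed (numpy's histogram2d convention).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(y_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    keep = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[keep], ys[keep]
    if xs.size == 0:
        raise ValueError("zero data points")
    if (
        np.any(xs < x_edges[0]) or np.any(xs > x_edges[-1])
        or np.any(ys < y_edges[0]) or np.any(ys > y_edges[-1])
    ):
        warnings.warn("data outside bin range clipped into edge bins", stacklevel=2)
        xs = np.clip(xs, x_edges[0], x_edges[-1])
        ys = np.clip(ys, y_edges[0], y_edges[-1])
    counts, _, _ = np.histogram2d(xs, ys, bins=(x_edges, y_edges))
    return ProbabilityMap2D(x_edges=x_edges, y_edges=y_edges, p=counts / counts.sum())


def theta_map(
    desc: ConformationDescriptors,
    bin_width: float = 5.0,
    theta_range: tuple[float, float] = (0.0, 180.0),
    frame_mask: np.ndarray | None = None,
) -> ProbabilityMap2D:
    """(θ_a-b-b′, θ_b-b′-a′) appearance-probability map.

    ``bin_width`` is in degrees (default 5°) and must be reported with
    any divergence computed from the map. ``frame_mask`` restricts the
    map to a frame subset (e.g. a clipped window) while keeping the
    binning identical to the full-trajectory map.
    """
    lo, hi = theta_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    xs, ys = desc.theta_abb, desc.theta_bba
    if frame_mask is not None:
        xs, ys = xs[frame_mask], ys[frame_mask]
    return probability_map(xs, ys, edges, edges)
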