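"""Synthetic multi-domain hinge trajectories with planted ground truth.

The generator emulates, at desk scale, a four-domain protein (a–b–b′–a′)
whose catalytic arms open and close about hinge points: rigid
pseudo-domains (random bead blobs, fixed in the lab frame) are strung on
a chain whose internal angles follow a discrete-state renewal process
(state means/stds in degrees, geometric dwell times) with Gaussian
jitter. A "measured" target profile is built as the noisy average of a
known planted window, so every pipeline stage — clipping, divergence,
isosbestic analysis — can be tested against an exact answer.

The planted window is laid out so that it is the *unique* longest
matching window: inside the window the hinge visits the open state for
an incommensurate fraction of frames (default 37/100) and then the
closed state, the frames immediately before the window are open and the
frames immediately after are closed. Any shift, extension or truncation
of the window therefore changes its open-state fraction — and hence its
average scattering curve — while distant windows differ through their
jitter averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BeadStructure, DomainDefinition, ExperimentalProfile, Trajectory
from .scattering import debye_intensity_series

__all__ = [
    "HingeModelConfig",
    "PlantedTruth",
    "generate_hinge_trajectory",
    "make_target_profile",
    "default_domains",
    "default_q_grid",
]

#: Distance between successive domain centers on the chain (Å).
_CHAIN_BOND = 30.0
#: Fixed torsion applied when placing the fourth domain center (degrees),
#: keeping the chain non-planar so the inter-domain dihedral is defined.
_CHAIN_TORSION = 40.0
#: Scattering weight per bead (electrons) — a Martini-class backbone bead
#: bundles several heavy atoms. Cancels under I(0) normalization.
_BEAD_WEIGHT = 30.0


@dataclass(frozen=True)
class HingeModelConfig:
    """Parameters of the synthetic hinge system.

    ``hinge_angle_states`` lists (mean, std) pairs in degrees for the
    discrete conformational states; the same angle drives every internal
    joint of the chain, so state 0 vs 1 is a concerted open–close
    motion. ``state_dwell`` is the mean dwell in frames (geometric).
    ``planted_length``/``planted_open_fraction`` shape the planted
    window; ``guard_run`` is the length of the uniform-state runs placed
    immediately outside it.
    """

    n_domains: int = 4
    beads_per_domain: int = 10
    domain_radius: float = 8.0
    hinge_angle_states: tuple = ((90.0, 4.0), (150.0, 4.0))
    state_dwell: int = 150
    n_frames: int = 2500
    frame_interval: float = 2.0
    seed: int = 0
    planted_length: int = 500
    planted_open_fraction: float = 0.37
    guard_run: int = 60

    def __post_init__(self) -> None:
        if not (2 <= self.n_domains <= 4):
            raise ValueError("n_domains must be between 2 and 4")
        if min(self.beads_per_domain, self.state_dwell, self.n_frames, self.planted_length) < 1:
            raise ValueError("counts must be >= 1")
        if self.domain_radius <= 0 or self.frame_interval <= 0:
            raise ValueError("domain_radius and frame_interval must be positive")
        for mean, std in self.hinge_angle_states:
            if not (0.0 < mean < 180.0):
                raise ValueError("state mean angles must lie in (0, 180)")
            if std < 0:
                raise ValueError("state angle std must be non-negative")
        if not (0.0 < self.planted_open_fraction < 1.0):
            raise ValueError("planted_open_fraction must be in (0, 1)")
        if self.planted_length + 2 * self.guard_run > self.n_frames:
            raise ValueError("planted window plus guard runs exceeds n_frames")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated trajectory."""

    planted_window: tuple[int, int]
    state_labels: np.ndarray
    hinge_angles: np.ndarray

    def __post_init__(self) -> None:
        s, e = self.planted_window
        if not (0 <= s < e <= self.state_labels.size):
            raise ValueError("planted_window out of range")


def default_domains(config: HingeModelConfig) -> tuple[dict, dict]:
    """Domain and motif definitions matching the generator's numbering.

    Beads of domain k carry residues ``100·k + 1 …``; the chain order is
    a, b, b′, a′ and the CGHC-like motifs are the first two beads of the
    a and a′ domains.
    """
    names = ["a", "b", "bp", "ap"][: config.n_domains]
    domains = {}
    for k, name in enumerate(names):
        lo = 100 * k + 1
        domains[name] = DomainDefinition(
            name=name, first_residue=lo, last_residue=lo + config.beads_per_domain - 1
        )
    motifs = {}
    if config.n_domains == 4:
        n_motif = min(2, config.beads_per_domain)
        motifs["cghc_a"] = DomainDefinition("cghc_a", 1, n_motif)
        lo = 100 * 3 + 1
        motifs["cghc_ap"] = DomainDefinition("cghc_ap", lo, lo + n_motif - 1)
    return domains, motifs


def default_q_grid(n_points: int = 100) -> np.ndarray:
    """The default experimental grid: 100 points over 0.01–0.30 Å⁻¹."""
    return np.linspace(0.01, 0.30, n_points)


def _chain_centers(theta_deg: float, n_domains: int) -> np.ndarray:
    """Domain-center positions for internal angle θ at every joint.

    The first three centers are planar; the fourth is placed with a
    fixed torsion so four-center dihedrals are non-degenerate. For the
    a–b–b′–a′ chain, θ is both θ_a-b-b′ and θ_b-b′-a′.
    """
    th = np.radians(theta_deg)
    d = _CHAIN_BOND
    centers = [np.zeros(3), np.array([d, 0.0, 0.0])]
    if n_domains >= 3:
        centers.append(centers[1] + d * np.array([-np.cos(th), np.sin(th), 0.0]))
    if n_domains >= 4:
        # place the 4th center at angle th from the b'-b axis with a fixed
        # torsion about the b-b' bond (NeRF internal-coordinate placement)
        psi = np.radians(_CHAIN_TORSION)
        bc = centers[2] - centers[1]
        bc = bc / np.linalg.norm(bc)
        prev = centers[1] - centers[0]
        n_vec = np.cross(prev, bc)
        n_vec = n_vec / np.linalg.norm(n_vec)
        m_vec = np.cross(n_vec, bc)
        local = d * np.array(
            [-np.cos(th), np.sin(th) * np.cos(psi), np.sin(th) * np.sin(psi)]
        )
        centers.append(centers[2] + local[0] * bc + local[1] * m_vec + local[2] * n_vec)
    return np.asarray(centers)


def _state_sequence(config: HingeModelConfig, rng: np.random.Generator):
    """Renewal state labels with the planted sandwich overwritten in."""
    n = config.n_frames
    n_states = len(config.hinge_angle_states)
    labels = np.empty(n, dtype=int)
    t = 0
    state = int(rng.integers(n_states))
    while t < n:
        dwell = int(rng.geometric(1.0 / config.state_dwell))
        labels[t : t + dwell] = state
        t += dwell
        if n_states > 1:
            step = int(rng.integers(1, n_states))
            state = (state + step) % n_states
    # Plant: [guard open][open run][closed run][guard closed], with the
    # window spanning exactly [start, start + planted_length).
    L = config.planted_length
    g = config.guard_run
    lo = g
    hi = n - L - g
    start = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    n_open = int(round(config.planted_open_fraction * L))
    n_open = min(max(n_open, 1), L - 1)
    open_state, closed_state = (1, 0) if n_states > 1 else (0, 0)
    labels[start - g : start + n_open] = open_state
    labels[start + n_open : start + L + g] = closed_state
    return labels, (start, start + L)


def generate_hinge_trajectory(
    config: HingeModelConfig = HingeModelConfig(),
) -> tuple[Trajectory, PlantedTruth]:
    """Generate a hinge trajectory and its planted ground truth.

    Deterministic given ``config.seed``: bead blobs, state sequence,
    jitter and planted-window placement all flow from one generator.
    Blob offsets are centered so each domain's backbone COM coincides
    exactly with its chain center, making the descriptor-recovered hinge
    angle directly comparable with the truth series.
    """
    rng = np.random.default_rng(config.seed)
    nb = config.beads_per_domain
    offsets = []
    for _ in range(config.n_domains):
        # uniform in a ball of domain_radius, then centered
        raw = rng.normal(size=(nb, 3))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        raw *= config.domain_radius * rng.uniform(size=(nb, 1)) ** (1 / 3)
        offsets.append(raw - raw.mean(axis=0))
    labels, window = _state_sequence(config, rng)
    means = np.array([s[0] for s in config.hinge_angle_states])
    stds = np.array([s[1] for s in config.hinge_angle_states])
    angles = rng.normal(means[labels], stds[labels])
    angles = np.clip(angles, 1.0, 179.0)

    residues = np.concatenate(
        [100 * k + 1 + np.arange(nb) for k in range(config.n_domains)]
    )
    roles = np.array(["backbone"] * (config.n_domains * nb), dtype=object)
    weights = np.full(config.n_domains * nb, _BEAD_WEIGHT)

    frames = []
    for theta in angles:
        centers = _chain_centers(float(theta), config.n_domains)
        coords = np.concatenate(
            [offsets[k] + centers[k] for k in range(config.n_domains)]
        )
        frames.append(
            BeadStructure(
                coordinates=coords,
                scattering_weight=weights,
                residue_index=residues,
                bead_role=roles,
            )
        )
    traj = Trajectory(frames=tuple(frames), frame_interval=config.frame_interval)
    truth = PlantedTruth(planted_window=window, state_labels=labels, hinge_angles=angles)
    return traj, truth


def make_target_profile(
    trajectory: Trajectory,
    window: tuple[int, int],
    noise_fraction: float = 2e-5,
    seed: int | None = None,
    q=None,
    scale: float = 2.0,
    offset: float = 0.0,
) -> ExperimentalProfile:
    """Build a synthetic "experimental" profile from a trajectory window.

    The normalized Debye curves of the window's frames are averaged,
    scaled by ``scale`` and shifted by ``offset``, and Gaussian noise
    with σ(Q) = ``noise_fraction``·I(Q) is added; that σ is reported as
    the uncertainty column, matching the 1/σ² weighting of the χ² fit.
    With ``noise_fraction = 0`` the curve is exact and σ is set to 1
    (arbitrary units) so the profile remains valid.
    """
    start, end = window
    if not (0 <= start < end <= trajectory.n_frames):
        raise ValueError("empty or out-of-range window")
    if scale <= 0:
        raise ValueError("scale must be positive")
    q = default_q_grid() if q is None else np.asarray(q, dtype=float)
    curves = debye_intensity_series(trajectory.frames[start:end], q)
    base = scale * curves.mean(axis=0) + offset
    if noise_fraction > 0:
        sigma = noise_fraction * np.abs(base)
        rng = np.random.default_rng(seed)
        intensity = base + rng.normal(0.0, sigma)
    else:
        sigma = np.ones_like(base)
        intensity = base
    return ExperimentalProfile(q=q, intensity=intensity, sigma=sigma)
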