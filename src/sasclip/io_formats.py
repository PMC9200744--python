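"""Readers and writers for SAXS profiles, bead trajectories, configs and reports.

The on-disk dialects are deliberately plain: reduced SAXS data as
3-column whitespace-separated text with ``#`` comments, trajectories as
multi-model PDB / XYZ / a documented tabular frame table, configuration
as YAML, and clip reports as TSV + JSON twins that round-trip at full
precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExperimentalProfile",
    "BeadStructure",
    "Trajectory",
    "DomainDefinition",
    "ELECTRON_COUNTS",
    "PDI_FAMILY_DOMAIN_PRESET",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_trajectory",
    "write_trajectory",
    "read_domain_config",
    "write_clip_report",
    "read_clip_report",
]

# Q-independent form factors: electron counts of the common protein elements.
# Hydrogens are assigned weight 0 under the default ignore-hydrogens rule
# (all electrons sit at atom centers; H contributes negligibly at small angle).
ELECTRON_COUNTS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "P": 15.0, "S": 16.0}

#: Atom names treated as backbone beads (coarse-grained BB bead or the
#: atomistic N/CA/C/O backbone).
BACKBONE_NAMES = frozenset({"BB", "CA", "C", "N", "O"})

#: Domain preset for a protein-disulfide-isomerase-family (ER-60-like)
#: multi-domain protein: catalytic a and a′ domains flanking the central
#: b-b′ unit. Four-domain analyses need the b/b′ split residue, which is
#: system-specific and must be supplied by the user.
PDI_FAMILY_DOMAIN_PRESET = {
    "a": (26, 130),
    "b_bp": (160, 355),
    "ap": (377, 482),
}


@dataclass(frozen=True)
class ExperimentalProfile:
    """A measured SAXS profile I_exp(Q) with per-point uncertainties.

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes in Å⁻¹, strictly increasing, > 0.
    intensity : array
        Measured intensities (arbitrary units).
    sigma : array
        Standard deviation of each intensity, same units, strictly > 0.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("q", "intensity", "sigma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.q.shape == self.intensity.shape == self.sigma.shape):
            raise ValueError("q, intensity and sigma must have equal length")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("profile must contain at least one point")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("non-monotone Q: q must be strictly increasing and > 0")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")

    @property
    def n_points(self) -> int:
        return int(self.q.size)


@dataclass(frozen=True)
class BeadStructure:
    """One coordinate frame: bead positions with constant scattering weights.

    ``scattering_weight`` holds the per-bead form factor f_i (electrons),
    treated as Q-independent in the small-angle range. ``bead_role`` marks
    beads as ``"backbone"`` or ``"other"``; domain centers average backbone
    beads only.
    """

    coordinates: np.ndarray
    scattering_weight: np.ndarray
    residue_index: np.ndarray
    bead_role: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "coordinates", np.asarray(self.coordinates, dtype=float))
        object.__setattr__(
            self, "scattering_weight", np.asarray(self.scattering_weight, dtype=float)
        )
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, dtype=int))
        object.__setattr__(self, "bead_role", np.asarray(self.bead_role, dtype=object))
        n = self.coordinates.shape[0]
        if n < 1 or self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array with n >= 1")
        if not (
            self.scattering_weight.shape == (n,)
            and self.residue_index.shape == (n,)
            and self.bead_role.shape == (n,)
        ):
            raise ValueError("per-bead arrays must all have length n")
        if np.any(self.scattering_weight < 0):
            raise ValueError("scattering weights must be non-negative")

    @property
    def n_beads(self) -> int:
        return int(self.coordinates.shape[0])


@dataclass(frozen=True)
class Trajectory:
    """An ordered sequence of frames sharing one topology.

    ``frame_interval`` is the time between stored snapshots in ns/frame
    (default 2, the sampling interval the clip duration L_t is based on).
    """

    frames: tuple
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if len(frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        ref = frames[0]
        for k, f in enumerate(frames[1:], start=1):
            if f.n_beads != ref.n_beads:
                raise ValueError(f"frame topology mismatch at frame {k}")
            if not (
                np.array_equal(f.residue_index, ref.residue_index)
                and np.array_equal(f.bead_role, ref.bead_role)
                and np.array_equal(f.scattering_weight, ref.scattering_weight)
            ):
                raise ValueError(f"frame topology mismatch at frame {k}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> BeadStructure:
        return self.frames[0]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> BeadStructure:
        return self.frames[i]


@dataclass(frozen=True)
class DomainDefinition:
    """A named inclusive residue range, e.g. the catalytic a domain 26–130."""

    name: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue must be <= last_residue")

    def mask(self, structure: BeadStructure, backbone_only: bool = True) -> np.ndarray:
        """Boolean bead mask for this residue range in ``structure``."""
        m = (structure.residue_index >= self.first_residue) & (
            structure.residue_index <= self.last_residue
        )
        if backbone_only:
            m &= structure.bead_role == "backbone"
        return m


# ---------------------------------------------------------------------------
# SAXS profile text files
# ---------------------------------------------------------------------------

def read_saxs_dat(path) -> ExperimentalProfile:
    """Read a 3-column (Q, I, σ) whitespace-separated SAXS profile.

    Lines starting with ``#`` are comments; extra columns are ignored;
    rows with non-positive σ are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such SAXS file: {path}")
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise ValueError(f"line {ln}: expected >= 3 columns (Q, I, sigma)")
        try:
            q, i, s = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise ValueError(f"line {ln}: non-numeric value") from exc
        if s <= 0:
            continue  # reject unusable row, keep parsing
        rows.append((q, i, s))
    if not rows:
        raise ValueError(f"zero usable rows in {path}")
    arr = np.asarray(rows, dtype=float)
    return ExperimentalProfile(q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2])


def write_saxs_dat(profile: ExperimentalProfile, path, header: str | None = None) -> None:
    """Write a profile in the 3-column dialect read by :func:`read_saxs_dat`."""
    path = Path(path)
    lines = []
    if header:
        lines.extend("# " + h for h in header.splitlines())
    lines.append("# Q(A^-1)  I  sigma")
    for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
        lines.append(f"{float(q)!r} {float(i)!r} {float(s)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _weight_for_element(element: str, ignore_hydrogens: bool) -> float:
    el = element.strip().capitalize()
    if el in ("H", "D"):
        return 0.0 if ignore_hydrogens else ELECTRON_COUNTS["H"]
    if el not in ELECTRON_COUNTS:
        raise ValueError(f"unknown element {element!r} with no explicit weight")
    return ELECTRON_COUNTS[el]


def _read_pdb(path: Path, ignore_hydrogens: bool, frame_interval: float) -> Trajectory:
    import biotite.structure.io.pdb as pdb_io

    pdb_file = pdb_io.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack, frames x atoms
    elements = [str(e) if str(e) else "C" for e in stack.element]
    weights = np.array([_weight_for_element(e, ignore_hydrogens) for e in elements])
    res_idx = np.asarray(stack.res_id, dtype=int)
    roles = np.array(
        ["backbone" if str(a).strip() in BACKBONE_NAMES else "other" for a in stack.atom_name],
        dtype=object,
    )
    frames = [
        BeadStructure(
            coordinates=np.asarray(stack.coord[m], dtype=float),
            scattering_weight=weights,
            residue_index=res_idx,
            bead_role=roles,
        )
        for m in range(stack.stack_depth())
    ]
    return Trajectory(frames=tuple(frames), frame_interval=frame_interval)


def _read_xyz(path: Path, ignore_hydrogens: bool, frame_interval: float) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    # MDAnalysis silently stops at a frame with a deviating atom count;
    # validate the per-frame counts in the headers first.
    lines = path.read_text().splitlines()
    pos, counts = 0, []
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"malformed XYZ frame header at line {pos + 1}") from exc
        counts.append(n_atoms)
        pos += n_atoms + 2
    if len(set(counts)) > 1:
        raise ValueError(f"frame topology mismatch: atom counts {sorted(set(counts))}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ")
        names = [str(n) for n in u.atoms.names]
        weights = np.array([_weight_for_element(n, ignore_hydrogens) for n in names])
        res_idx = np.arange(1, len(names) + 1)  # XYZ has no residue record
        roles = np.array(["backbone"] * len(names), dtype=object)
        frames = []
        for ts in u.trajectory:
            frames.append(
                BeadStructure(
                    coordinates=np.array(u.atoms.positions, dtype=float),
                    scattering_weight=weights,
                    residue_index=res_idx,
                    bead_role=roles,
                )
            )
    return Trajectory(frames=tuple(frames), frame_interval=frame_interval)


#: Tabular frame format: TSV with columns
#: frame, bead, x, y, z, weight, residue, role — one row per bead per frame.
TABULAR_COLUMNS = ["frame", "bead", "x", "y", "z", "weight", "residue", "role"]


def _read_tabular(path: Path, frame_interval: float) -> Trajectory:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tabular frame file missing columns: {missing}")
    frames = []
    ref_beads = None
    for fid, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("bead")
        if ref_beads is None:
            ref_beads = grp["bead"].to_numpy()
        elif not np.array_equal(grp["bead"].to_numpy(), ref_beads):
            raise ValueError(f"frame topology mismatch at frame {fid}")
        frames.append(
            BeadStructure(
                coordinates=grp[["x", "y", "z"]].to_numpy(dtype=float),
                scattering_weight=grp["weight"].to_numpy(dtype=float),
                residue_index=grp["residue"].to_numpy(dtype=int),
                bead_role=np.array(
                    [str(r) for r in grp["role"]], dtype=object
                ),
            )
        )
    return Trajectory(frames=tuple(frames), frame_interval=frame_interval)


def read_trajectory(
    path,
    format: str | None = None,
    frame_interval: float = 2.0,
    ignore_hydrogens: bool = True,
) -> Trajectory:
    """Read a multi-frame coordinate file.

    Parameters
    ----------
    format : {"pdb", "xyz", "tabular"}, optional
        Inferred from the file suffix when omitted (.pdb/.ent, .xyz,
        .tsv/.frames).
    frame_interval : float
        Sampling interval in ns/frame attached to the trajectory.
    ignore_hydrogens : bool
        Assign hydrogens scattering weight 0 (default), mirroring the
        all-electrons-at-atom-centers, H-ignored convention used for p(r).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trajectory file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".pdb": "pdb",
            ".ent": "pdb",
            ".xyz": "xyz",
            ".tsv": "tabular",
            ".frames": "tabular",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer trajectory format from suffix {suffix!r}")
    format = format.lower()
    if format == "pdb":
        return _read_pdb(path, ignore_hydrogens, frame_interval)
    if format == "xyz":
        try:
            return _read_xyz(path, ignore_hydrogens, frame_interval)
        except ValueError:
            raise
        except Exception as exc:  # MDAnalysis raises various IO errors
            raise ValueError(f"frame topology mismatch or malformed XYZ: {exc}") from exc
    if format == "tabular":
        return _read_tabular(path, frame_interval)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(trajectory: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or the tabular frame format.

    The tabular writer preserves weights, residue numbers and roles
    verbatim; the PDB writer maps beads to CA pseudo-atoms (element C),
    so explicit non-elemental weights do not survive a PDB round trip.
    """
    path = Path(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "tabular"
    format = format.lower()
    if format == "tabular":
        recs = []
        for fid, fr in enumerate(trajectory.frames):
            for b in range(fr.n_beads):
                recs.append(
                    (
                        fid,
                        b,
                        fr.coordinates[b, 0],
                        fr.coordinates[b, 1],
                        fr.coordinates[b, 2],
                        fr.scattering_weight[b],
                        fr.residue_index[b],
                        fr.bead_role[b],
                    )
                )
        pd.DataFrame(recs, columns=TABULAR_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if format == "pdb":
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb_io

        top = trajectory.topology
        n = top.n_beads
        array = struc.AtomArray(n)
        array.coord = np.asarray(top.coordinates, dtype=np.float32)
        array.res_id = np.asarray(top.residue_index, dtype=int)
        array.res_name = np.array(["GLY"] * n)
        array.atom_name = np.array(
            ["CA" if r == "backbone" else "CB" for r in top.bead_role]
        )
        array.element = np.array(["C"] * n)
        array.chain_id = np.array(["A"] * n)
        coords = np.stack([f.coordinates for f in trajectory.frames]).astype(np.float32)
        stack = struc.AtomArrayStack(len(trajectory.frames), n)
        for cat in array.get_annotation_categories():
            stack.set_annotation(cat, array.get_annotation(cat))
        stack.coord = coords
        pdb_file = pdb_io.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
        return
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Domain / criteria config
# ---------------------------------------------------------------------------

def read_domain_config(path) -> dict:
    """Read a YAML config of domain ranges, motifs and clip criteria.

    Layout::

        domains:
          a:  [26, 130]
          b:  [160, 255]
          bp: [256, 355]
          ap: [377, 482]
        motifs:
          cghc_a:  [57, 60]
          cghc_ap: [406, 409]
        criteria:
          chi2_max: 3.0
          resid_max: 12.5
          resid_q_max: 0.25
          min_duration: 700.0

    Returns a dict with ``domains`` mapped to :class:`DomainDefinition`.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    out: dict = {"domains": {}, "motifs": {}, "criteria": dict(raw.get("criteria", {}))}
    for name, rng in (raw.get("domains") or {}).items():
        lo, hi = int(rng[0]), int(rng[1])
        out["domains"][name] = DomainDefinition(name=name, first_residue=lo, last_residue=hi)
    for name, rng in (raw.get("motifs") or {}).items():
        out["motifs"][name] = DomainDefinition(
            name=name, first_residue=int(rng[0]), last_residue=int(rng[1])
        )
    return out


# ---------------------------------------------------------------------------
# Clip reports
# ---------------------------------------------------------------------------

_REPORT_FIELDS = [
    "found",
    "start_frame",
    "end_frame",
    "duration_ns",
    "chi2",
    "c",
    "offs",
    "n_models",
    "max_sq_residual_band",
    "kl",
]


def _result_record(result) -> dict:
    """Flatten a ClipResult (duck-typed) into a plain record."""
    rec: dict = {k: None for k in _REPORT_FIELDS}
    rec["found"] = bool(result.found)
    if result.found:
        rec["start_frame"] = int(result.start_frame)
        rec["end_frame"] = int(result.end_frame)
        rec["duration_ns"] = float(result.duration_ns)
        fit = result.fit
        rec["chi2"] = float(fit.chi2)
        rec["c"] = float(fit.c)
        rec["offs"] = float(fit.offs)
        rec["n_models"] = int(fit.n_models)
        band = getattr(result, "max_sq_residual_band", None)
        rec["max_sq_residual_band"] = None if band is None else float(band)
    kl = getattr(result, "kl", None)
    rec["kl"] = None if kl is None else float(kl)
    return rec


def write_clip_report(result, path) -> None:
    """Write a clip result as TSV and JSON twins.

    ``path`` names the TSV file; a sibling with suffix ``.json`` is written
    alongside. Floats are serialized with ``repr`` and round-trip
    bit-identically. A "no window found" result is an explicit record with
    ``found = False``, not an error.
    """
    path = Path(path)
    rec = _result_record(result)
    lines = ["\t".join(_REPORT_FIELDS)]
    lines.append(
        "\t".join("NA" if rec[k] is None else repr(rec[k]) for k in _REPORT_FIELDS)
    )
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(json.dumps(rec, indent=1) + "\n")


def read_clip_report(path) -> dict:
    """Read back a TSV clip report written by :func:`write_clip_report`."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if len(lines) != 2:
        raise ValueError("malformed clip report")
    header = lines[0].split("\t")
    values = lines[1].split("\t")
    rec: dict = {}
    for key, val in zip(header, values):
        if val == "NA":
            rec[key] = None
        elif key in ("start_frame", "end_frame", "n_models"):
            rec[key] = int(val)
        elif key == "found":
            rec[key] = val == "True"
        else:
            rec[key] = float(val)
    return rec
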