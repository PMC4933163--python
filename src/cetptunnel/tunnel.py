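"""Geometry and chemistry of the lipid-transfer pathway.

The pathway through the protein interior is an ordered polyline with
cumulative arclength.  Along it we measure:

* a probe-sphere diameter profile (largest ball fitting the channel near
  each path point, MOLE-style, with an interior threshold deciding
  open/closed),
* the residues in van der Waals contact with the transiting ligand,
* a SASA-weighted Kyte–Doolittle hydrophobicity profile binned per Å of
  arclength, and
* the orientation of a designated ligand bond against a reference plane.

A greedy step-by-step pathway search is provided as the geometric analog
of pulling a ligand pore-to-pore: from the current point, candidate steps
within a cone of the previous direction are scored by wall clearance and
the best one is taken until the exit region is reached or the channel
pinches shut.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structure import HydropathyScale, ResidueKey, Structure

__all__ = [
    "TransferPath",
    "DiameterProfile",
    "ContactProfile",
    "HydrophobicityProfile",
    "LigandTrajectory",
    "point_clearance",
    "probe_clearance",
    "diameter_profile",
    "path_search",
    "contact_residues",
    "sasa",
    "hydrophobicity_profile",
    "orientation_angle",
]

#: Path points farther than this from every atom are flagged "outside".
OUTSIDE_DISTANCE = 50.0


@dataclass
class TransferPath:
    """Ordered 3-D points with cumulative arclength (Å).

    Consecutive points must be no more than 2 Å apart so per-Å binning of
    profiles is well defined.
    """

    points: np.ndarray
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]
    terminated_early: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ValueError("path points must be an (N, 3) array with N >= 1")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if self.arclength is None:
            self.arclength = np.concatenate([[0.0], np.cumsum(steps)])
        self.arclength = np.asarray(self.arclength, dtype=float)
        if len(self.arclength) != len(self.points):
            raise ValueError("arclength and points must have equal length")
        if self.arclength[0] != 0.0 or np.any(np.diff(self.arclength) < 0):
            raise ValueError("arclength must start at 0 and be non-decreasing")
        if np.any(steps > 2.0 + 1e-9):
            raise ValueError("consecutive path points must be <= 2 Å apart")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def direction(self) -> np.ndarray:
        """Global unit direction from first to last point."""
        d = self.points[-1] - self.points[0]
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("degenerate path: start equals end")
        return d / n

    def to_tsv(self, stream: TextIO | str | Path) -> None:
        df = pd.DataFrame(self.points, columns=["x_A", "y_A", "z_A"])
        df.insert(0, "arclength_A", self.arclength)
        df.to_csv(stream, sep="\t", index=False, float_format="%.4f")


@dataclass
class DiameterProfile:
    """Per path point: arclength, channel diameter, open / outside flags."""

    arclength: np.ndarray
    diameter: np.ndarray
    open_flag: np.ndarray
    outside_flag: np.ndarray
    interior_threshold: float

    def to_dataframe(self) -> pd.DataFrame:
        flag = np.where(self.outside_flag, "outside", np.where(self.open_flag, "open", "closed"))
        return pd.DataFrame(
            {
                "arclength_A": self.arclength,
                "diameter_A": self.diameter,
                "flag": flag,
            }
        )

    def to_tsv(self, stream: TextIO | str | Path) -> None:
        self.to_dataframe().to_csv(stream, sep="\t", index=False, float_format="%.4f")


@dataclass
class ContactProfile:
    """Per path step: the residues within the contact cutoff of the ligand."""

    arclength: np.ndarray
    contacts: list[set[ResidueKey]]
    cutoff: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, cset in zip(self.arclength, self.contacts):
            label = ";".join(f"{c}:{r}{q}" for c, q, r in sorted(cset)) if cset else ""
            rows.append({"arclength_A": s, "n_contacts": len(cset), "residues": label})
        return pd.DataFrame(rows)

    def to_tsv(self, stream: TextIO | str | Path) -> None:
        self.to_dataframe().to_csv(stream, sep="\t", index=False, float_format="%.4f")


@dataclass
class HydrophobicityProfile:
    """SASA-weighted hydropathy per 1-Å arclength bin.

    ``defined`` is False where no frame in the bin contacted the wall;
    ``sd`` is the spread across repeated trajectories (NaN for a single
    one), ``n`` the number of contributing trajectories per bin.
    """

    arclength: np.ndarray  # bin centers
    value: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    defined: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arclength_A": self.arclength,
                "value": self.value,
                "sd": self.sd,
                "n": self.n,
                "flag": np.where(self.defined, "ok", "undefined"),
            }
        )

    def to_tsv(self, stream: TextIO | str | Path) -> None:
        self.to_dataframe().to_csv(stream, sep="\t", index=False, float_format="%.4f")


@dataclass
class LigandTrajectory:
    """Ordered ligand conformations pinned to path arclengths.

    Every frame must contain the two atoms of the designated reference
    bond (for the steroid-ring orientation indicator).
    """

    frames: list[Structure]
    arclength: np.ndarray
    bond: tuple[str, str]

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one frame")
        if len(self.frames) != len(self.arclength):
            raise ValueError("one arclength per frame required")
        a, b = self.bond
        for i, f in enumerate(self.frames):
            names = {atom.name for atom in f.atoms}
            if a not in names or b not in names:
                raise ValueError(f"frame {i}: designated bond atoms {a!r}-{b!r} missing")

    def __len__(self) -> int:
        return len(self.frames)

    def bond_vector(self, i: int) -> np.ndarray:
        a, b = self.bond
        f = self.frames[i]
        return f.atom_by_name(b).position - f.atom_by_name(a).position


# ---------------------------------------------------------------------------
# clearance machinery

def point_clearance(structure: Structure, point: np.ndarray,
                    coords: np.ndarray | None = None,
                    radii: np.ndarray | None = None) -> float:
    """Signed distance from ``point`` to the nearest vdW surface.

    Positive inside open space, negative inside an atom.
    """
    if coords is None:
        coords = structure.coords()
        radii = structure.radii()
    if len(coords) == 0:
        raise ValueError("empty structure")
    d = np.linalg.norm(coords - np.asarray(point, dtype=float), axis=1) - radii
    return float(d.min())


def _grid_offsets(radius: float, spacing: float) -> np.ndarray:
    n = int(math.floor(radius / spacing))
    axis = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return offs[np.linalg.norm(offs, axis=1) <= radius]


def probe_clearance(
    structure: Structure,
    point: np.ndarray,
    probe_radius: float = 3.0,
    grid: float = 0.25,
    refine: bool = True,
    _coords: np.ndarray | None = None,
    _radii: np.ndarray | None = None,
) -> float:
    """Largest-ball clearance near a path point.

    Maximizes min_i(|c - x_i| - r_i) over candidate centers ``c`` within
    ``probe_radius`` of the point: a grid search at ``grid`` spacing
    followed by one local (Nelder–Mead) refinement pass.  Never returns
    less than the clearance at the point itself.
    """
    point = np.asarray(point, dtype=float)
    coords = structure.coords() if _coords is None else _coords
    radii = structure.radii() if _radii is None else _radii
    if len(coords) == 0:
        raise ValueError("empty structure")

    # Atoms beyond this distance cannot set the minimum for any candidate
    # unless the channel is wider than OUTSIDE_DISTANCE anyway.
    dist_to_point = np.linalg.norm(coords - point, axis=1)
    near = dist_to_point - radii <= OUTSIDE_DISTANCE + probe_radius
    coords_n, radii_n = coords[near], radii[near]
    if len(coords_n) == 0:
        return math.inf  # caller flags "outside"

    def clearance_at(pts: np.ndarray) -> np.ndarray:
        # pts (M, 3) -> (M,) min over atoms of (dist - radius)
        out = np.empty(len(pts))
        chunk = 2048
        for i in range(0, len(pts), chunk):
            block = pts[i : i + chunk]
            d = np.linalg.norm(block[:, None, :] - coords_n[None, :, :], axis=2) - radii_n
            out[i : i + chunk] = d.min(axis=1)
        return out

    base = float(clearance_at(point[None])[0])
    candidates = point + _grid_offsets(probe_radius, grid)
    vals = clearance_at(candidates)
    k = int(np.argmax(vals))
    best = float(vals[k])
    best_center = candidates[k]

    if refine:
        def neg(c: np.ndarray) -> float:
            if np.linalg.norm(c - point) > probe_radius:
                return 1e6
            return -float(clearance_at(c[None])[0])

        res = minimize(neg, best_center, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
        if -res.fun > best:
            best = float(-res.fun)

    return max(best, base)


def diameter_profile(
    structure: Structure,
    path: TransferPath,
    probe_radius: float = 3.0,
    interior_threshold: float = 1.25,
    grid: float = 0.25,
    refine: bool = True,
) -> DiameterProfile:
    """Probe-sphere diameter of the channel at every path point.

    ``diameter = 2 * clearance`` clamped at zero; a point is *open* when
    the clearance reaches the interior threshold (minimum sphere radius
    for the point to count as channel), *outside* when no atom surface
    lies within :data:`OUTSIDE_DISTANCE`.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, radii = structure.coords(), structure.radii()
    diam = np.zeros(len(path))
    open_flag = np.zeros(len(path), dtype=bool)
    outside = np.zeros(len(path), dtype=bool)
    for i, p in enumerate(path.points):
        nearest = point_clearance(structure, p, coords, radii)
        if nearest > OUTSIDE_DISTANCE:
            outside[i] = True
            continue
        r = probe_clearance(structure, p, probe_radius, grid, refine,
                            _coords=coords, _radii=radii)
        diam[i] = max(2.0 * r, 0.0)
        open_flag[i] = r >= interior_threshold
    return DiameterProfile(path.arclength.copy(), diam, open_flag, outside, interior_threshold)


# ---------------------------------------------------------------------------
# pathway search

def _cone_directions(direction: np.ndarray, half_angle_deg: float,
                     n_theta: int = 5, n_phi: int = 16) -> np.ndarray:
    """Deterministic fan of unit vectors within a cone about ``direction``."""
    direction = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    dirs = [direction]
    for theta in np.linspace(0, math.radians(half_angle_deg), n_theta + 1)[1:]:
        for phi in np.linspace(0, 2 * math.pi, n_phi, endpoint=False):
            d = (math.cos(theta) * direction
                 + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v))
            dirs.append(d)
    return np.array(dirs)


def _sphere_directions(n: int = 200) -> np.ndarray:
    i = np.arange(n)
    phi = np.arccos(1 - 2 * (i + 0.5) / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def path_search(
    structure: Structure,
    entry_point: np.ndarray,
    exit_region: Callable[[np.ndarray], bool],
    step_length: float = 1.0,
    cone_half_angle: float = 60.0,
    initial_direction: np.ndarray | None = None,
    interior_threshold: float = 1.25,
    max_steps: int = 1000,
) -> TransferPath:
    """Greedy step-by-step pathway search through a channel.

    From the current point, candidate points one ``step_length`` away
    within the cone about the previous direction are scored by wall
    clearance; the best candidate becomes the next point.  The walk stops
    when ``exit_region`` holds or every candidate's clearance falls below
    the interior threshold (dead end → partial path flagged
    ``terminated_early``).
    """
    entry_point = np.asarray(entry_point, dtype=float)
    coords, radii = structure.coords(), structure.radii()
    if len(coords) == 0:
        raise ValueError("empty structure")
    if point_clearance(structure, entry_point, coords, radii) <= 0:
        raise ValueError("entry point has non-positive clearance (inside an atom)")
    if step_length > 2.0:
        raise ValueError("step length must be <= 2 Å to keep the path finely sampled")

    points = [entry_point]
    direction = None
    if initial_direction is not None:
        direction = np.asarray(initial_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
    terminated_early = False
    for _ in range(max_steps):
        current = points[-1]
        if exit_region(current):
            break
        if direction is None:
            dirs = _sphere_directions()
        else:
            dirs = _cone_directions(direction, cone_half_angle)
        candidates = current + step_length * dirs
        clear = np.array(
            [point_clearance(structure, c, coords, radii) for c in candidates]
        )
        k = int(np.argmax(clear))
        if clear[k] < interior_threshold:
            terminated_early = True
            break
        direction = dirs[k]
        points.append(candidates[k])
    else:
        terminated_early = True
    return TransferPath(np.array(points), terminated_early=terminated_early)


# ---------------------------------------------------------------------------
# contacts, SASA, hydrophobicity, orientation

def contact_residues(
    structure: Structure, ligand_frame: Structure, cutoff: float = 2.4
) -> set[ResidueKey]:
    """Residues with any atom strictly closer than ``cutoff`` to any ligand atom.

    Distances are center-to-center; the cutoff (default 2.4 Å, the
    diameter of a hydrogen vdW surface) is strict: exactly-at-cutoff pairs
    do not count.
    """
    if len(structure) == 0 or len(ligand_frame) == 0:
        raise ValueError("both structure and ligand frame must be non-empty")
    coords = structure.coords()
    tree = cKDTree(coords)
    hits: set[int] = set()
    for lp in ligand_frame.coords():
        for j in tree.query_ball_point(lp, cutoff):
            if np.linalg.norm(coords[j] - lp) < cutoff:
                hits.add(j)
    out: set[ResidueKey] = set()
    for j in hits:
        a = structure.atoms[j]
        out.add((a.chain, a.residue_seq, a.residue_name))
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.arccos(1 - 2 * (i + 0.5) / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    structure: Structure, probe_radius: float = 1.4, points_per_atom: int = 960
) -> dict[ResidueKey, float]:
    """Shrake–Rupley solvent-accessible surface area per residue (Å²).

    Each atom's expanded sphere (r_i + probe) is sampled with a
    deterministic Fibonacci-spiral point set; the accessible fraction
    times the sphere area is summed over each residue's atoms.
    """
    if points_per_atom < 50:
        raise ValueError("points_per_atom below 50 is too coarse to be meaningful")
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, radii = structure.coords(), structure.radii()
    expanded = radii + probe_radius
    sphere = _fibonacci_sphere(points_per_atom)
    tree = cKDTree(coords)
    max_reach = expanded.max()
    areas: dict[ResidueKey, float] = {}
    for i, a in enumerate(structure.atoms):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_reach)
                     if j != i]
        if neighbors:
            nb_coords = coords[neighbors]
            nb_exp = expanded[np.array(neighbors)]
            d = np.linalg.norm(pts[:, None, :] - nb_coords[None, :, :], axis=2)
            buried = (d < nb_exp[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = frac * 4.0 * math.pi * expanded[i] ** 2
        key = (a.chain, a.residue_seq, a.residue_name)
        areas[key] = areas.get(key, 0.0) + area
    return areas


def contact_profile(
    structure: Structure, trajectory: LigandTrajectory, cutoff: float = 2.4
) -> ContactProfile:
    """Contact residues at every trajectory frame, indexed by arclength."""
    contacts = [contact_residues(structure, f, cutoff) for f in trajectory.frames]
    return ContactProfile(trajectory.arclength.copy(), contacts, cutoff)


def hydrophobicity_profile(
    structure: Structure,
    trajectories: LigandTrajectory | Sequence[LigandTrajectory],
    scale: HydropathyScale | None = None,
    step: float = 1.0,
    cutoff: float = 2.4,
    probe_radius: float = 1.4,
    points_per_atom: int = 960,
) -> HydrophobicityProfile:
    """SASA-weighted tunnel-wall hydropathy per arclength bin.

    For each frame, the contact residues are weighted by their share of
    the total SASA of the contact set (computed once on the ligand-free
    structure) and their Kyte–Doolittle values averaged.  Frame values are
    averaged within each ``step``-Å bin per trajectory; the mean and SD
    across trajectories make the profile.  Bins never contacted are
    flagged undefined; a profile with no defined bin at all is an error.
    """
    if isinstance(trajectories, LigandTrajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("at least one trajectory required")
    scale = scale or HydropathyScale()
    areas = sasa(structure, probe_radius, points_per_atom)

    max_s = max(float(t.arclength.max()) for t in trajectories)
    n_bins = int(math.floor(max_s / step)) + 1
    centers = (np.arange(n_bins) + 0.5) * step

    per_traj = np.full((len(trajectories), n_bins), np.nan)
    for ti, traj in enumerate(trajectories):
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, dtype=int)
        for fi, frame in enumerate(traj.frames):
            cset = contact_residues(structure, frame, cutoff)
            if not cset:
                continue
            total = sum(areas.get(r, 0.0) for r in cset)
            if total <= 0:
                # fully buried contact set: fall back to equal weights
                value = float(np.mean([scale.value(r[2]) for r in cset]))
            else:
                value = sum(areas.get(r, 0.0) / total * scale.value(r[2]) for r in cset)
            b = min(int(traj.arclength[fi] / step), n_bins - 1)
            sums[b] += value
            counts[b] += 1
        mask = counts > 0
        per_traj[ti, mask] = sums[mask] / counts[mask]

    n = np.sum(~np.isnan(per_traj), axis=0)
    defined = n > 0
    if not defined.any():
        raise ValueError("ligand never contacts the structure: all bins undefined")
    value = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    value[defined] = np.nanmean(per_traj[:, defined], axis=0)
    multi = n > 1
    if multi.any():
        sd[multi] = np.nanstd(per_traj[:, multi], axis=0, ddof=1)
    return HydrophobicityProfile(centers, value, sd, n, defined)


def default_plane_normal(path: TransferPath) -> np.ndarray:
    """A deterministic normal of a plane containing the global path direction."""
    d = path.direction()
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n = np.cross(d, ref)
    return n / np.linalg.norm(n)


def orientation_angle(
    trajectory: LigandTrajectory, plane_normal: np.ndarray
) -> pd.DataFrame:
    """Angle of the designated bond against a reference plane, per frame.

    0° means the bond lies in the plane, 90° along the plane normal:
    ``angle = arcsin(|v̂ · n̂|)`` in degrees.  Returns a frame-indexed
    DataFrame with arclength and angle columns.
    """
    n = np.asarray(plane_normal, dtype=float)
    norm = np.linalg.norm(n)
    if not math.isclose(norm, 1.0, rel_tol=1e-6):
        raise ValueError("plane normal must be a unit vector")
    angles = np.empty(len(trajectory))
    for i in range(len(trajectory)):
        v = trajectory.bond_vector(i)
        vn = np.linalg.norm(v)
        if vn == 0:
            raise ValueError(f"frame {i}: zero-length designated bond")
        s = min(abs(float(v / vn @ n)), 1.0)
        angles[i] = math.degrees(math.asin(s))
    return pd.DataFrame({"arclength_A": trajectory.arclength, "angle_deg": angles})
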