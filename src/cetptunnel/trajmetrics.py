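"""Equilibration-style trajectory metrics.

RMSD with optimal (proper-rotation) superposition, per-atom RMSF about
the time-mean structure, radius of gyration, grid-counting molecular
volume, and the first peak of a radial distribution function.  These are
the standard convergence diagnostics run on simulation trajectories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .structure import Structure

__all__ = [
    "CoordinateSet",
    "Trajectory",
    "kabsch_rmsd",
    "rmsf",
    "radius_of_gyration",
    "molecular_volume",
    "rdf_first_peak",
]


@dataclass
class CoordinateSet:
    """Labeled points (Å) for a selection, with optional per-point masses."""

    labels: list[str]
    coords: np.ndarray
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) < 1:
            raise ValueError("coords must be (N, 3) with N >= 1")
        if len(self.labels) != len(self.coords):
            raise ValueError("one label per point required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (len(self.coords),) or np.any(self.masses <= 0):
                raise ValueError("masses must be positive, one per point")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class Trajectory:
    """Frames over a fixed selection: (T, N, 3) coordinates and times (ns)."""

    labels: list[str]
    coords: np.ndarray
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (T, N, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels must match the selection size")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("one time per frame required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> CoordinateSet:
        return CoordinateSet(self.labels, self.coords[i])


def _match(a: CoordinateSet, b: CoordinateSet) -> tuple[np.ndarray, np.ndarray]:
    if a.labels == b.labels:
        return a.coords, b.coords
    try:
        order = [b.labels.index(lab) for lab in a.labels]
    except ValueError as exc:
        raise ValueError(f"coordinate sets have mismatched labels: {exc}") from None
    if len(order) != len(b.labels):
        raise ValueError("coordinate sets have mismatched labels")
    return a.coords, b.coords[order]


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly move ``mobile`` onto ``target`` (proper rotation only)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def kabsch_rmsd(a: CoordinateSet, b: CoordinateSet, superpose: bool = True) -> float:
    """RMSD between two labeled coordinate sets (Å).

    With ``superpose``, the optimal translation and *proper* rotation
    (determinant +1 — molecules are chiral) is applied to ``b`` first;
    fewer than 3 points make the rotation underdetermined and raise.
    Without, the direct label-matched RMSD is returned.
    """
    xa, xb = _match(a, b)
    if superpose:
        if len(xa) < 3:
            raise ValueError("superposition needs at least 3 points")
        xb = _superpose(xb, xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def rmsf(traj: Trajectory) -> dict[str, float]:
    """Per-label root-mean-square fluctuation about the time-mean (Å).

    Two-pass scheme: every frame is superposed onto the first frame, the
    mean structure is taken, all frames are re-superposed onto that mean,
    and the RMSF is computed about the refreshed mean.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ref = traj.coords[0]
    pass1 = np.array([_superpose(f, ref) for f in traj.coords])
    mean1 = pass1.mean(axis=0)
    pass2 = np.array([_superpose(f, mean1) for f in pass1])
    mean2 = pass2.mean(axis=0)
    dev = np.sqrt(np.mean(np.sum((pass2 - mean2) ** 2, axis=2), axis=0))
    return dict(zip(traj.labels, dev.tolist()))


def radius_of_gyration(c: CoordinateSet) -> float:
    """Mass-weighted radius of gyration √(Σ mᵢ|xᵢ − x̄|² / Σ mᵢ), Å."""
    m = c.masses if c.masses is not None else np.ones(len(c))
    center = (c.coords * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * np.sum((c.coords - center) ** 2, axis=1)).sum() / m.sum()))


def molecular_volume(structure: Structure, grid: float = 0.25) -> float:
    """Union volume of the vdW spheres by grid-cell counting (Å³).

    A cell counts when its center lies inside any atom's sphere; the
    result is cell count × grid³.
    """
    if grid <= 0:
        raise ValueError("grid must be positive")
    if len(structure) == 0:
        raise ValueError("empty structure")
    coords, radii = structure.coords(), structure.radii()
    rmax = radii.max()
    lo = coords.min(axis=0) - rmax - grid
    hi = coords.max(axis=0) + rmax + grid
    shape = np.ceil((hi - lo) / grid).astype(int) + 1
    if np.prod(shape, dtype=float) > 1e9:
        raise ValueError("grid too fine for this structure's extent")
    occupied = np.zeros(shape, dtype=bool)
    for x, r in zip(coords, radii):
        i0 = np.maximum(((x - r - lo) / grid).astype(int), 0)
        i1 = np.minimum(((x + r - lo) / grid).astype(int) + 2, shape)
        ax = [lo[d] + grid * np.arange(i0[d], i1[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        inside = (gx - x[0]) ** 2 + (gy - x[1]) ** 2 + (gz - x[2]) ** 2 <= r * r
        occupied[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    return float(occupied.sum()) * grid ** 3


def rdf_first_peak(
    points: np.ndarray | Sequence[Sequence[float]],
    bin_width: float = 0.5,
    max_radius: float = 20.0,
    dimension: int | None = None,
) -> float:
    """Center of the first peak of the pair radial distribution function (Å).

    The pair-distance histogram is normalized by the shell measure (2πr
    per bin in 2-D, 4πr² in 3-D); the first local maximum exceeding the
    mean normalized density is returned.  No qualifying peak below
    ``max_radius`` is an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    dim = dimension if dimension is not None else pts.shape[1]
    if dim not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    d = pdist(pts)
    d = d[d <= max_radius]
    if d.size == 0:
        raise ValueError("no pair distances below max_radius")
    edges = np.arange(0.0, max_radius + bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if dim == 1:
        shell = np.full_like(centers, bin_width)
    elif dim == 2:
        shell = 2 * math.pi * centers * bin_width
    else:
        shell = 4 * math.pi * centers ** 2 * bin_width
    g = hist / shell
    mean_g = g.mean()
    padded = np.concatenate([[-np.inf], g, [-np.inf]])
    for i in range(len(g)):
        if g[i] > mean_g and padded[i] <= g[i] >= padded[i + 2] and g[i] > 0:
            return float(centers[i])
    raise ValueError("no RDF peak above the mean density below max_radius")
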