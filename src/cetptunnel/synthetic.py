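"""Synthetic inputs for the whole pipeline.

Real inputs to this kind of analysis are an equilibrated protein
structure, a steered-ligand trajectory through its tunnel, and a table of
transfer times versus driving force from repeated pulling simulations.
None of those can be regenerated at desk scale, so this module fabricates
each one with known ground truth:

* :func:`make_barrel` — a hollow atomic barrel whose inner-radius profile
  is specified exactly, so the probe-sphere diameter profiler has a
  construction oracle;
* :func:`make_ligand_trajectory` — a rigid ligand slid along a path with
  a scheduled reference-bond orientation;
* :func:`sample_transfer_times` — force–time replicate tables drawn from
  Time = A·Force^−b with multiplicative log-normal noise, emulating the
  mean ± SD scatter of repeated steered runs;
* :func:`langevin_first_passage` — overdamped 1-D first-passage times
  under constant force, a desk-scale stochastic surrogate for steered
  transfer with closed-form limits (drift: γL/F; diffusive: L²γ/2kBT);
* :func:`make_monolayer_lattice` — a jittered hexagonal phosphorus-like
  lattice for the radial-distribution-function first-peak metric.

Every generator is deterministic under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import constants

from .structure import Atom, Structure
from .tunnel import LigandTrajectory, TransferPath

__all__ = [
    "BarrelSpec",
    "LangevinSpec",
    "LangevinResult",
    "NoiseModel",
    "KB_KCAL_PER_MOL_K",
    "make_barrel",
    "make_rod_ligand",
    "make_ligand_trajectory",
    "sample_transfer_times",
    "langevin_first_passage",
    "make_monolayer_lattice",
]

#: Boltzmann constant in kcal/mol/K (k_B · N_A / 4184); 0.61603 kcal/mol at 310 K.
KB_KCAL_PER_MOL_K = constants.k * constants.N_A / 4184.0


@dataclass
class BarrelSpec:
    """A hollow barrel: stacked atom rings around an axis.

    ``inner_radius`` (constant or a function of arclength, Å) is the
    probe clearance the barrel presents on its axis: ring atom centers
    sit at ``inner_radius(s) + atom_vdw_radius`` from the axis.  The
    default dimensions emulate a protein-scale tunnel: ~60 Å long and
    ~6.6 Å across, lined by hydrophobic residues.
    """

    axis_length: float = 60.0
    ring_spacing: float = 1.0
    inner_radius: float | Callable[[float], float] = 3.3
    atoms_per_ring: int = 24
    ring_residues: Sequence[str] = ("ILE", "LEU", "PHE", "VAL", "MET", "ALA")
    atom_vdw_radius: float = 1.7
    element: str = "C"
    #: extra rings beyond both path ends so the probe-sphere search cannot
    #: escape through the open mouths at the path endpoints
    end_padding: float = 3.0

    def radius_at(self, s: float) -> float:
        s = min(max(s, 0.0), self.axis_length)  # padding rings extend the end profile
        r = self.inner_radius(s) if callable(self.inner_radius) else self.inner_radius
        return float(r)


@dataclass
class LangevinSpec:
    """Overdamped 1-D constant-force first-passage setup.

    Units: tunnel length Å, friction kcal·ps/(mol·Å²), temperature K,
    force kcal/mol/Å, time step ps.  The walker starts at 0 with a
    reflecting boundary there (tunnel entry) and is absorbed at L (exit).
    """

    tunnel_length: float = 60.0
    friction: float = 1.0
    temperature: float = 310.0
    force: float = 1.0
    time_step: float = 0.01
    max_steps: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tunnel_length", "friction", "temperature", "time_step"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.force < 0:
            raise ValueError("force must be non-negative")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if self.force > 0:
            relax = self.friction * self.tunnel_length / self.force
            if self.time_step > 0.1 * relax:
                raise ValueError(
                    "time step too coarse for the drift relaxation scale γL/F"
                )

    @property
    def kBT(self) -> float:
        return KB_KCAL_PER_MOL_K * self.temperature


@dataclass
class NoiseModel:
    """Multiplicative log-normal replicate scatter: time × exp(N(0, σ²))."""

    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class LangevinResult:
    """First-passage times (ps) plus the count of non-passing walkers."""

    times: np.ndarray
    n_nonpassage: int


def _axis_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = tangent / np.linalg.norm(tangent)
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def make_barrel(
    spec: BarrelSpec,
    axis: Callable[[float], np.ndarray] | None = None,
) -> tuple[Structure, TransferPath]:
    """Build the barrel structure and its axial transfer path.

    Ring atom centers sit at radial distance ``inner_radius(s) +
    atom_vdw_radius`` so the probe-sphere clearance on the axis equals
    the specified inner radius.  The returned path is the axis sampled at
    1-Å arclength steps.  ``axis`` optionally maps arclength to a 3-D
    centerline (default: straight line along z); it must be arclength
    parametrized.
    """
    if spec.atoms_per_ring < 3:
        raise ValueError("rings need at least 3 atoms")
    if spec.atom_vdw_radius <= 0:
        raise ValueError("atom vdW radius must be positive")
    if axis is None:
        axis = lambda s: np.array([0.0, 0.0, s])  # noqa: E731

    n_pad = int(math.ceil(spec.end_padding / spec.ring_spacing))
    n_rings = int(round(spec.axis_length / spec.ring_spacing)) + 1 + 2 * n_pad
    ring_s = (np.arange(n_rings) - n_pad) * spec.ring_spacing
    for s in ring_s:
        if spec.radius_at(float(s)) < spec.atom_vdw_radius:
            raise ValueError(
                f"inner radius {spec.radius_at(float(s)):.2f} Å at s={s:.1f} dips below "
                f"the atom vdW radius {spec.atom_vdw_radius:.2f} Å"
            )

    atoms: list[Atom] = []
    serial = 1
    eps = 1e-4
    for k, s in enumerate(ring_s):
        center = np.asarray(axis(float(s)), dtype=float)
        ahead = np.asarray(axis(float(s) + eps), dtype=float)
        tangent = ahead - center
        if np.linalg.norm(tangent) == 0:
            tangent = np.array([0.0, 0.0, 1.0])
        u, v = _axis_frame(tangent)
        ring_radius = spec.radius_at(float(s)) + spec.atom_vdw_radius
        resname = spec.ring_residues[k % len(spec.ring_residues)]
        # stagger alternate rings by half an angular step to close gaps
        offset = (k % 2) * math.pi / spec.atoms_per_ring
        for j in range(spec.atoms_per_ring):
            phi = 2 * math.pi * j / spec.atoms_per_ring + offset
            pos = center + ring_radius * (math.cos(phi) * u + math.sin(phi) * v)
            atoms.append(
                Atom(
                    serial=serial,
                    name=f"{spec.element}{j + 1}",
                    element=spec.element,
                    residue_name=resname,
                    residue_seq=k + 1,
                    chain="A",
                    position=pos,
                    vdw_radius=spec.atom_vdw_radius,
                )
            )
            serial += 1

    path_s = np.arange(0.0, spec.axis_length + 1e-9, 1.0)
    points = np.array([axis(float(s)) for s in path_s])
    return Structure(atoms), TransferPath(points)


def make_rod_ligand(
    length: float = 18.0,
    n_atoms: int = 10,
    bond: tuple[str, str] = ("C10", "C19"),
    vdw_radius: float = 1.7,
) -> Structure:
    """A rigid linear 'cholesteryl-ester stand-in' rod along z.

    The two designated bond atoms are the rod ends, so the reference
    bond direction is the rod direction.
    """
    if n_atoms < 2:
        raise ValueError("rod needs at least 2 atoms")
    zs = np.linspace(-length / 2, length / 2, n_atoms)
    names = [f"C{i + 1}" for i in range(n_atoms)]
    names[0], names[-1] = bond
    atoms = [
        Atom(
            serial=i + 1,
            name=names[i],
            element="C",
            residue_name="CLR",
            residue_seq=1,
            chain="L",
            position=np.array([0.0, 0.0, z]),
            vdw_radius=vdw_radius,
        )
        for i, z in enumerate(zs)
    ]
    return Structure(atoms)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    c = float(a @ b)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180°: rotate about any axis perpendicular to a
        ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, ref)
        axis /= np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    v = np.cross(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def make_ligand_trajectory(
    path: TransferPath,
    ligand: Structure,
    orientation_schedule: Callable[[float], np.ndarray],
    bond: tuple[str, str] = ("C10", "C19"),
) -> LigandTrajectory:
    """Slide a rigid ligand along a path with a scheduled bond orientation.

    One frame per path point: the ligand centroid is placed on the point
    and the designated bond is rotated onto the scheduled unit vector.
    A schedule returning a non-unit vector is an error, as is a ligand
    missing the bond atoms.
    """
    try:
        a0 = ligand.atom_by_name(bond[0]).position
        b0 = ligand.atom_by_name(bond[1]).position
    except KeyError as exc:
        raise ValueError(f"ligand lacks designated bond atom: {exc}") from None
    v0 = b0 - a0
    n0 = np.linalg.norm(v0)
    if n0 == 0:
        raise ValueError("designated bond has zero length in the template ligand")
    v0 = v0 / n0
    centroid0 = ligand.centroid()

    frames: list[Structure] = []
    for i, p in enumerate(path.points):
        target = np.asarray(orientation_schedule(float(path.arclength[i])), dtype=float)
        if not math.isclose(float(np.linalg.norm(target)), 1.0, rel_tol=1e-6):
            raise ValueError(
                f"orientation schedule returned a non-unit vector at s={path.arclength[i]:.2f}"
            )
        R = _rotation_between(v0, target)
        frame = ligand.copy()
        for atom in frame.atoms:
            atom.position = R @ (atom.position - centroid0) + p
        frames.append(frame)
    return LigandTrajectory(frames, path.arclength.copy(), bond)


def sample_transfer_times(
    prefactor: float,
    exponent: float,
    forces: Sequence[float],
    n_rep: int,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Replicate transfer times drawn from Time = A·F^−b × exp(N(0, σ²)).

    Returns a tidy DataFrame with columns ``force_kcal_mol_A``,
    ``replicate``, ``time_ns`` — the same layout the kinetics fit
    consumes.  Deterministic under the noise model's seed.
    """
    forces = np.asarray(forces, dtype=float)
    if np.any(forces <= 0):
        raise ValueError("forces must be positive")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    rng = np.random.default_rng(noise.seed)
    rows = []
    for f in forces:
        base = prefactor * f ** (-exponent)
        eps = rng.normal(0.0, noise.sigma, size=n_rep) if noise.sigma > 0 else np.zeros(n_rep)
        for r in range(n_rep):
            rows.append(
                {"force_kcal_mol_A": f, "replicate": r + 1, "time_ns": base * math.exp(eps[r])}
            )
    return pd.DataFrame(rows)


def langevin_first_passage(spec: LangevinSpec, n_rep: int) -> LangevinResult:
    """First-passage times of overdamped walkers through a 1-D tunnel.

    Euler–Maruyama update ``x ← x + (F/γ)Δt + √(2kBTΔt/γ)·N(0,1)`` with a
    reflecting boundary at 0 and absorption at L.  Walkers still inside
    after ``max_steps`` are excluded and counted as non-passages.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dt = spec.time_step
    drift = spec.force / spec.friction * dt
    sigma = math.sqrt(2.0 * spec.kBT * dt / spec.friction)
    L = spec.tunnel_length

    x = np.zeros(n_rep)
    times = np.full(n_rep, np.nan)
    active = np.ones(n_rep, dtype=bool)
    for step in range(spec.max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        x[idx] += drift + sigma * rng.standard_normal(idx.size)
        np.abs(x, out=x)  # reflect at the entry
        crossed = idx[x[idx] >= L]
        if crossed.size:
            times[crossed] = (step + 1) * dt
            active[crossed] = False
    passed = ~np.isnan(times)
    return LangevinResult(times[passed], int((~passed).sum()))


def make_monolayer_lattice(
    spacing: float, n_per_side: int, jitter_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Jittered 2-D hexagonal lattice of phosphorus-like points.

    Emulates phosphate headgroup positions in a lipid monolayer whose
    nearest-neighbour distance (the RDF first peak) equals ``spacing``.
    Returns an (N, 2) array in Å.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if n_per_side < 2:
        raise ValueError("lattice needs at least 2 points per side")
    rng = np.random.default_rng(seed)
    pts = []
    for i in range(n_per_side):
        for j in range(n_per_side):
            x = j * spacing + (i % 2) * spacing / 2.0
            y = i * spacing * math.sqrt(3) / 2.0
            pts.append((x, y))
    arr = np.array(pts, dtype=float)
    if jitter_sd > 0:
        arr += rng.normal(0.0, jitter_sd, size=arr.shape)
    return arr
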