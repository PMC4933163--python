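"""Run configuration: sectioned key-value files with strict validation.

Every tunable cutoff and constant in the pipeline has a documented
default here; a config file (YAML — sectioned, diffable key-value text)
overrides them.  Unknown sections or keys are rejected outright so a
typo cannot silently fall back to a default.
"""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping, TextIO

import yaml

__all__ = ["RunConfig", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "barrel": {
        "axis_length_A": 60.0,
        "ring_spacing_A": 1.0,
        "inner_radius_A": 3.3,
        "atoms_per_ring": 24,
        "atom_vdw_radius_A": 1.7,
        "ring_residues": ["ILE", "LEU", "PHE", "VAL", "MET", "ALA"],
    },
    "ligand": {
        "length_A": 18.0,
        "n_atoms": 10,
        "bond": ["C10", "C19"],
        "turn_at_fraction": 0.5,  # arclength fraction of the 90° steroid-ring turn
    },
    "geometry": {
        "probe_radius_A": 3.0,
        "interior_threshold_A": 1.25,
        "contact_cutoff_A": 2.4,
        "include_hydrogens": True,
        "sasa_probe_radius_A": 1.4,
        "sasa_points_per_atom": 960,
        "profile_step_A": 1.0,
    },
    "kinetics": {
        "weighting": "auto",
        "prefactor_ns": 475.0,
        "exponent": 2.75,
        "forces_kcal_mol_A": list(range(6, 24)),
        "n_rep": 4,
        "noise_sigma": 0.3,
    },
    "langevin": {
        "enabled": False,
        "tunnel_length_A": 60.0,
        "friction_kcal_ps_mol_A2": 1.0,
        "temperature_K": 310.0,
        "forces_kcal_mol_A": [2.0, 4.0, 8.0, 16.0],
        "time_step_ps": 0.005,
        "max_steps": 2_000_000,
        "n_rep": 50,
    },
    "biophysics": {
        "surface_tension_low_N_per_m": 0.020,
        "surface_tension_high_N_per_m": 0.033,
        "hdl_radius_A": 50.0,
        "ldl_radius_A": 110.0,
        "tunnel_diameter_A": 6.0,
        "cetp_mass_Da": 73000.0,
        "ce_mass_Da": 651.0,
        "specific_activity_nmol_h_ug": 75.7,
        "plasma_flux_ug_h_ml": 64.0,
        "cetp_concentration_ug_ml": 1.75,
    },
}


def _validate(user: Mapping[str, Any], defaults: Mapping[str, Any], prefix: str = "") -> dict:
    merged = copy.deepcopy(dict(defaults))
    for key, value in user.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {prefix + str(key)!r}")
        if isinstance(defaults[key], Mapping):
            if not isinstance(value, Mapping):
                raise ValueError(f"config section {prefix + str(key)!r} must be a mapping")
            merged[key] = _validate(value, defaults[key], prefix=f"{prefix}{key}.")
        else:
            merged[key] = value
    return merged


class RunConfig:
    """Validated, default-complete pipeline configuration."""

    def __init__(self, overrides: Mapping[str, Any] | None = None):
        self._data = _validate(overrides or {}, DEFAULTS)

    @classmethod
    def from_yaml(cls, stream: TextIO | str | Path) -> "RunConfig":
        if isinstance(stream, (str, Path)):
            with open(stream) as handle:
                raw = yaml.safe_load(handle)
        else:
            raw = yaml.safe_load(stream)
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ValueError("config file must contain a top-level mapping")
        return cls(raw)

    def __getitem__(self, key: str) -> Any:
        return self._data[key]

    @property
    def seed(self) -> int:
        return int(self._data["seed"])

    def section(self, name: str) -> dict[str, Any]:
        return copy.deepcopy(self._data[name])

    def as_dict(self) -> dict[str, Any]:
        return copy.deepcopy(self._data)
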