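"""Pipeline orchestration: the profile / kinetics / predict / simulate runs.

Each command reads PDB/CSV inputs, drives the library modules, and
writes TSV profiles or key-value reports plus a machine-readable
manifest (inputs, parameters, seeds, output hashes) sufficient to
reproduce the run.  Manifests are deterministic: rerunning the same
config yields byte-identical outputs and manifests.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import biophysics as bp
from . import kinetics as kin
from .config import RunConfig
from .structure import Structure, read_pdb, read_pdb_models, write_pdb, write_pdb_models
from .synthetic import (
    BarrelSpec,
    LangevinSpec,
    NoiseModel,
    langevin_first_passage,
    make_barrel,
    make_ligand_trajectory,
    make_rod_ligand,
    sample_transfer_times,
)
from .tunnel import (
    LigandTrajectory,
    TransferPath,
    contact_profile,
    default_plane_normal,
    diameter_profile,
    hydrophobicity_profile,
    orientation_angle,
)

__all__ = ["cmd_profile", "cmd_kinetics", "cmd_predict", "cmd_simulate"]

log = logging.getLogger("cetptunnel")


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, command: str, inputs: dict, params: dict,
                    outputs: list[Path]) -> Path:
    manifest = {
        "command": command,
        "inputs": inputs,
        "parameters": params,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _strip_hydrogens(structure: Structure) -> Structure:
    atoms = [a for a in structure.atoms if a.element != "H"]
    if not atoms:
        raise ValueError("structure contains only hydrogens")
    return Structure(atoms)


def _path_from_trajectory(traj: LigandTrajectory) -> TransferPath:
    centroids = np.array([f.centroid() for f in traj.frames])
    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    if np.any(steps > 2.0):
        raise ValueError(
            "trajectory frames are more than 2 Å apart; supply a finer trajectory"
        )
    return TransferPath(centroids)


def cmd_profile(structure_file: str | Path, trajectory_file: str | Path,
                config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Geometry + chemistry profiles of a tunnel from a ligand trajectory.

    Writes diameter, hydrophobicity, contact and orientation TSVs along
    the arclength of the ligand's centroid path, plus the run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    geo = config.section("geometry")
    bond = tuple(config.section("ligand")["bond"])

    structure = read_pdb(structure_file)
    models = read_pdb_models(trajectory_file)
    if not models or all(len(m) == 0 for m in models):
        raise ValueError("empty trajectory")
    # fail before any heavy computation if the designated bond is absent
    for i, m in enumerate(models):
        names = {a.name for a in m.atoms}
        if bond[0] not in names or bond[1] not in names:
            raise ValueError(f"trajectory model {i + 1} lacks designated bond atoms {bond}")

    contact_structure = structure if geo["include_hydrogens"] else _strip_hydrogens(structure)
    centroids = np.array([m.centroid() for m in models])
    arclength = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(centroids, axis=0), axis=1))])
    traj = LigandTrajectory(models, arclength, bond)  # type: ignore[arg-type]
    path = _path_from_trajectory(traj)
    log.info("profiling %d frames over %.1f Å of pathway", len(traj), path.length)

    diam = diameter_profile(structure, path, geo["probe_radius_A"], geo["interior_threshold_A"])
    hydro = hydrophobicity_profile(
        contact_structure, traj, step=geo["profile_step_A"], cutoff=geo["contact_cutoff_A"],
        probe_radius=geo["sasa_probe_radius_A"], points_per_atom=geo["sasa_points_per_atom"],
    )
    contacts = contact_profile(contact_structure, traj, geo["contact_cutoff_A"])
    orient = orientation_angle(traj, default_plane_normal(path))

    outputs = []
    for name, obj in (
        ("diameter.tsv", diam), ("hydrophobicity.tsv", hydro), ("contacts.tsv", contacts),
    ):
        obj.to_tsv(outdir / name)
        outputs.append(outdir / name)
    orient.to_csv(outdir / "orientation.tsv", sep="\t", index=False, float_format="%.4f")
    outputs.append(outdir / "orientation.tsv")
    path.to_tsv(outdir / "path.tsv")
    outputs.append(outdir / "path.tsv")

    _write_manifest(outdir, "profile",
                    {"structure": str(structure_file), "trajectory": str(trajectory_file)},
                    {"geometry": geo, "bond": list(bond), "seed": config.seed}, outputs)
    open_diam = diam.diameter[diam.open_flag]
    return {
        "n_frames": len(traj),
        "path_length_A": path.length,
        "min_open_diameter_A": float(open_diam.min()) if open_diam.size else float("nan"),
        "mean_hydropathy": float(np.nanmean(hydro.value)),
        "outdir": outdir,
    }


def _biophysics_chain(bio: dict[str, Any]) -> dict[str, Any]:
    cross = bp.TunnelCrossSection(bio["tunnel_diameter_A"])
    forces = {}
    for tag, alpha in (("low", bio["surface_tension_low_N_per_m"]),
                       ("high", bio["surface_tension_high_N_per_m"])):
        hdl = bp.LipoproteinShell(alpha, bio["hdl_radius_A"])
        ldl = bp.LipoproteinShell(alpha, bio["ldl_radius_A"])
        forces[tag] = bp.driving_force(bp.pressure_difference(hdl, ldl), cross)
    rate_sa = bp.rate_from_specific_activity(
        bp.SpecificActivity(bio["specific_activity_nmol_h_ug"], bio["cetp_mass_Da"]))
    rate_pf = bp.rate_from_plasma_flux(
        bp.PlasmaFlux(bio["plasma_flux_ug_h_ml"], bio["cetp_concentration_ug_ml"],
                      bio["ce_mass_Da"], bio["cetp_mass_Da"]))
    return {
        "driving_force_low_kcal_mol_A": forces["low"],
        "driving_force_high_kcal_mol_A": forces["high"],
        "radiolabel_rate_specific_activity_per_s": rate_sa,
        "radiolabel_rate_plasma_flux_per_s": rate_pf,
        "radiolabel_time_specific_activity_s": bp.per_molecule_time(rate_sa),
        "radiolabel_time_plasma_flux_s": bp.per_molecule_time(rate_pf),
    }


def cmd_kinetics(table_file: str | Path, config: RunConfig,
                 outdir: str | Path) -> dict[str, Any]:
    """Power-law fit of a force-time table plus physiological extrapolation.

    Writes a key-value fit report, per-point log residuals, and — with
    the biophysics block — the predicted physiological force span,
    transfer times and per-second rates, each labelled as extrapolation
    when outside the fitted force range.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    table = kin.ForceTimeTable.from_csv(table_file)
    fit = kin.fit_power_law(table, config.section("kinetics")["weighting"])
    log.info("fitted Time = %.3g * F^-%.3f (r = %.3f, n = %d)",
             fit.prefactor, fit.exponent, fit.correlation, fit.n_points)

    summary = kin.summarize(table)
    pred = np.array([kin.predict_time(fit, f) for f in summary["force_kcal_mol_A"]])
    residuals = summary.assign(
        predicted_time_ns=pred,
        log_residual=np.log(summary["mean_time_ns"].to_numpy()) - np.log(pred),
    )
    residuals.to_csv(outdir / "residuals.tsv", sep="\t", index=False, float_format="%.6g")

    results: dict[str, Any] = {
        "prefactor_ns": fit.prefactor,
        "exponent": fit.exponent,
        "correlation": fit.correlation,
        "n_points": fit.n_points,
    }
    lines = [f"{k} = {v:.6g}" for k, v in results.items()]

    chain = _biophysics_chain(config.section("biophysics"))
    results.update(chain)
    for tag in ("low", "high"):
        force = chain[f"driving_force_{tag}_kcal_mol_A"]
        t_ns = kin.predict_time(fit, force)
        t_s = t_ns * 1e-9
        extrap = fit.is_extrapolation(force)
        results[f"predicted_time_{tag}_s"] = t_s
        results[f"predicted_rate_{tag}_per_s"] = 1.0 / t_s
        results[f"extrapolation_{tag}"] = extrap
        lines.append(
            f"physiological_{tag}: force = {force:.4g} kcal/mol/A, "
            f"time = {t_s:.3g} s, rate = {1.0 / t_s:.4g} /s"
            + (" [extrapolation]" if extrap else "")
        )
    for k in ("radiolabel_rate_specific_activity_per_s", "radiolabel_rate_plasma_flux_per_s",
              "radiolabel_time_specific_activity_s", "radiolabel_time_plasma_flux_s"):
        lines.append(f"{k} = {chain[k]:.6g}")

    (outdir / "fit_report.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(outdir, "kinetics", {"table": str(table_file)},
                    {"kinetics": config.section("kinetics"),
                     "biophysics": config.section("biophysics"), "seed": config.seed},
                    [outdir / "fit_report.txt", outdir / "residuals.tsv"])
    results["outdir"] = outdir
    return results


def cmd_predict(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Biophysics-only report: Laplace forces and radiolabel conversions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    chain = _biophysics_chain(config.section("biophysics"))
    lines = [f"{k} = {v:.6g}" for k, v in chain.items()]
    (outdir / "predict_report.txt").write_text("\n".join(lines) + "\n")
    _write_manifest(outdir, "predict", {},
                    {"biophysics": config.section("biophysics"), "seed": config.seed},
                    [outdir / "predict_report.txt"])
    chain = dict(chain)
    chain["outdir"] = outdir
    return chain


def cmd_simulate(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Generate the synthetic dataset bundle: barrel, trajectory, tables.

    Byte-identical on rerun with the same config (all randomness flows
    from the config seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    seed = config.seed
    bar = config.section("barrel")
    lig = config.section("ligand")
    kin_cfg = config.section("kinetics")

    spec = BarrelSpec(
        axis_length=bar["axis_length_A"], ring_spacing=bar["ring_spacing_A"],
        inner_radius=bar["inner_radius_A"], atoms_per_ring=bar["atoms_per_ring"],
        ring_residues=tuple(bar["ring_residues"]), atom_vdw_radius=bar["atom_vdw_radius_A"],
    )
    barrel, path = make_barrel(spec)
    write_pdb(barrel, outdir / "barrel.pdb")

    ligand = make_rod_ligand(lig["length_A"], lig["n_atoms"], tuple(lig["bond"]))
    turn_s = lig["turn_at_fraction"] * path.length
    axis, perp = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])

    def schedule(s: float) -> np.ndarray:
        # emulates the ~90° steroid-ring turn near the tunnel midpoint
        return axis if s < turn_s else perp

    traj = make_ligand_trajectory(path, ligand, schedule, tuple(lig["bond"]))
    write_pdb_models(traj.frames, outdir / "trajectory.pdb")
    path.to_tsv(outdir / "path.tsv")

    table = sample_transfer_times(
        kin_cfg["prefactor_ns"], kin_cfg["exponent"], kin_cfg["forces_kcal_mol_A"],
        kin_cfg["n_rep"], NoiseModel(kin_cfg["noise_sigma"], seed),
    )
    kin.ForceTimeTable.from_replicates(table).to_csv(outdir / "force_time.csv")

    outputs = [outdir / "barrel.pdb", outdir / "trajectory.pdb", outdir / "path.tsv",
               outdir / "force_time.csv"]

    lv = config.section("langevin")
    if lv["enabled"]:
        rows = []
        for i, force in enumerate(lv["forces_kcal_mol_A"]):
            lspec = LangevinSpec(
                tunnel_length=lv["tunnel_length_A"], friction=lv["friction_kcal_ps_mol_A2"],
                temperature=lv["temperature_K"], force=force, time_step=lv["time_step_ps"],
                max_steps=lv["max_steps"], seed=seed + 1000 + i,
            )
            result = langevin_first_passage(lspec, lv["n_rep"])
            log.info("langevin F=%.3g: %d passages, %d non-passages",
                     force, len(result.times), result.n_nonpassage)
            for r, t_ps in enumerate(result.times):
                rows.append({"force_kcal_mol_A": force, "replicate": r + 1,
                             "time_ns": t_ps / 1000.0})
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(outdir / "langevin_times.csv", index=False)
            outputs.append(outdir / "langevin_times.csv")

    _write_manifest(outdir, "simulate", {}, {**config.as_dict()}, outputs)
    return {"outdir": outdir, "n_atoms": len(barrel), "n_frames": len(traj),
            "n_table_rows": len(table)}
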