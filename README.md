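# cetptunnel

Desk-scale analysis of cholesteryl-ester (CE) transit through the tunnel
of the cholesteryl ester transfer protein (CETP).

CETP carries CE from high-density to low-density lipoprotein particles
(HDL → LDL), and one proposed mechanism is a continuous ~60-Å
hydrophobic tunnel through the protein.  Evaluating that mechanism
computationally involves three kinds of analysis, all implemented here
as a tested library:

1. **Tunnel geometry and chemistry** — a probe-sphere diameter profile
   along a transfer pathway (3.0-Å probe, 1.25-Å interior threshold for
   calling a point open channel), a greedy step-by-step pathway search,
   residue contacts under a strict 2.4-Å criterion (the diameter of a
   hydrogen van der Waals surface), Shrake–Rupley solvent-accessible
   surface areas, and a SASA-weighted Kyte–Doolittle hydrophobicity
   profile per 1-Å arclength step:
   H(s) = Σᵣ wᵣ·KD(r), wᵣ = SASA(r) / Σ SASA(contacts at s).
2. **Transfer kinetics** — steered-pulling transfer times follow a
   power law in the driving force, Time(ns) = A·Force^−b, fitted by
   log-log least squares (the published replicate-level fit is
   A = 475, b = 2.75, |r| = 0.96 over 18 forces of 6–23 kcal/mol/Å).
3. **Lipoprotein biophysics** — the Young-Laplace pressure P = 2α/R of
   each particle (α surface tension, R radius) gives a pressure
   difference ΔP = 2α(1/R_HDL − 1/R_LDL) that, pushed over the ~6-Å
   tunnel cross-section, yields the physiological driving force
   (~0.018–0.029 kcal/mol/Å); radiolabel transfer rates are converted
   to CE molecules/s per CETP molecule and per-molecule times.

Because all-atom steered MD cannot run at desk scale, a first-class
synthetic-data module generates every pipeline input with known ground
truth: hollow atomic barrels with exactly specified inner-radius
profiles (a construction oracle for the profiler), rigid-ligand
trajectories with scheduled bond orientations, power-law force–time
tables with log-normal replicate scatter, and overdamped 1-D Langevin
first-passage times with closed-form limits.

## Worked example

The four numbered scripts under `analysis/` run the whole study chain
and write their tables under `results/`:

```sh
python analysis/01_simulate.py        # synthetic barrel / trajectory / tables
python analysis/02_profile_tunnel.py  # geometry + chemistry profiles
python analysis/03_fit_kinetics.py    # power-law fits + extrapolation
python analysis/04_biophysics.py      # Laplace forces + radiolabel rates
```

Output of the last two steps:

```
published means : Time(ns) = 540 × F^-2.80 (r = -0.989, n = 18 forces)
  extrapolated physiological transfer time: 0.0105–0.0428 s/molecule
synthetic table : Time(ns) = 365 × F^-2.66 (r = -0.968; truth A = 475, b = 2.75)
langevin drift  : fitted b = 1.00 (drift-dominated surrogate: expected ≈ 1, not the all-atom 2.75)
physiological driving force: 0.018–0.029 kcal/mol/Å
radiolabel turnover: 1.14–1.54 CE molecules/s/CETP
per-molecule transfer time: 0.65–0.88 s
```

Reading those numbers: fitting only the 18 published per-force *means*
gives b ≈ 2.80 — close to, but not identical with, the replicate-level
2.75 (the 72 individual times are unpublished).  The synthetic
4-replicate table with realistic scatter recovers the truth within its
sampling noise.  The Langevin surrogate sits in the drift-dominated
regime where time ∝ 1/F, so its fitted exponent is ≈ 1 by construction
— a deliberate regime contrast with the all-atom value.  The
Young-Laplace chain puts the physiological driving force three decades
below the simulated forces, and the radiolabel conversions give the
experimental turnover of ~1.1–1.5 CE/s per CETP (0.65–0.88 s per
molecule).

The same pipeline is scriptable through a CLI
(`cetp-tunnel simulate|profile|kinetics|predict`), configured by a
strict YAML file; see `cetp-tunnel --help`.

## Layout

```
src/cetptunnel/   library: structure, tunnel, synthetic, trajmetrics,
                  kinetics, biophysics, config, pipeline, cli
analysis/         numbered narrative drivers (see worked example)
tests/            pytest suite incl. oracle and property tests
scripts/          acceptance recomputation
docs/methods.md   models, assumptions, parameters, limitations
```
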