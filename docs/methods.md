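# Methods

This note records the models implemented in `cetptunnel`, the
assumptions and defaults behind them, and what the synthetic-data
generators do and do not emulate.

## Structures and constants

Atoms carry Å coordinates, residue identity and a van der Waals radius.
Radii come from the Bondi set by default (C 1.70, H 1.20, N 1.55, O
1.52, S/P 1.80 Å, …), overridable via a two-column element→radius text
file; no radius set is canonical for this analysis, Bondi is simply the
de-facto standard.  The PDB reader handles fixed-column ATOM/HETATM
records (ligands are heteroatoms), skips altLoc codes other than
blank/'A', assigns radii at parse time, and reports malformed fields
with their line number.  The writer emits 3-decimal coordinates and
rejects values that overflow the 8-column field (|x| ≥ 10⁵ Å).
Wall chemistry uses the Kyte–Doolittle hydropathy scale (+4.5 ILE to
−4.5 ARG); lookup of a non-standard residue code is an error rather
than a silent default.

## Tunnel geometry

**Clearance.**  The channel radius at a path point p is
r(p) = max over centers c with |c − p| ≤ probe radius of
min over atoms i of (|c − xᵢ| − rᵢ), i.e. the largest ball fitting the
channel with its center near p.  The maximization is a deterministic
grid search (0.25-Å spacing, matching the grid used for molecular
volume) followed by one Nelder–Mead refinement pass, and never returns
less than the clearance at p itself.  Diameter = 2r clamped at zero; a
point is *open* when r reaches the 1.25-Å interior threshold (the
MOLE-style minimum sphere radius for a point to count as channel — an
interpretation, recorded here), and *outside* when no atom surface lies
within 50 Å.  Defaults: probe radius 3.0 Å, threshold 1.25 Å.

One consequence of the max-over-centers definition: a constriction
narrower (axially) than the probe radius can be dodged by moving the
center along the channel, so only necks wider than the probe diameter
register as closed.  The construction-oracle tests use such plateaus.

**Pathway search.**  A greedy step-by-step walk: from the current
point, candidate points one step (default 1 Å) away within a cone
(default half-angle 60°) about the previous direction are scored by
point clearance; the best is taken until the exit predicate holds or
every candidate falls below the interior threshold (dead end → partial
path flagged `terminated_early`).  The first step scans the full
sphere unless an initial direction is given.  This is the geometric
analog of iteratively pulling a ligand toward the deepest pore; it
makes no claim to Voronoi/alpha-sphere completeness.

**Contacts.**  A residue contacts the ligand when any of its atoms is
strictly closer than 2.4 Å (center-to-center) to any ligand atom — the
criterion is the diameter of a hydrogen vdW surface, i.e. touching
hydrogen spheres.  Whether hydrogens participate is exposed as a flag
(default: included) since the source convention is unstated.

**SASA.**  Shrake–Rupley with a deterministic Fibonacci-spiral point
set (default 960 points/atom, error floor at 50), water probe 1.4 Å.
Point counting quantizes areas at ~(sphere area)/n per point, so
per-residue convergence on doubling is ~1–2% for small areas while the
total converges below 0.5%; tests assert exactly that.

**Hydrophobicity profile.**  Per frame, contact residues are weighted
by their share of the contact set's total SASA and their hydropathy
values averaged; frame values are averaged within 1-Å arclength bins
per trajectory, and the mean/SD across repeated trajectories form the
profile.  SASA is computed once on the ligand-free structure — the
per-conformation alternative is possible but the reference convention
is unstated, and the ligand-free choice keeps weights
trajectory-independent.  Bins with no contact are flagged undefined;
values are convex combinations of contributing residues' scale values
by construction.

**Orientation.**  The designated ligand bond's angle against a
reference plane, arcsin(|v̂·n̂|), 0° in-plane to 90° along the normal.
The default plane contains the global path direction (its normal is a
deterministic perpendicular); any unit normal can be supplied.

## Trajectory metrics

RMSD uses the optimal proper rotation (reflections excluded — molecules
are chiral) via quaternion superposition; under three points the
rotation is underdetermined and rejected.  RMSF uses a two-pass scheme:
superpose all frames on the first, take the mean, re-superpose on the
mean, then RMS-deviate about the refreshed mean.  Radius of gyration is
mass-weighted with unit masses by default.  Molecular volume counts
0.25-Å grid cells whose centers fall inside any vdW sphere — monotone
in the radii and convergent on grid halving for protein-scale unions.
The RDF first peak normalizes the pair-distance histogram by the shell
measure (2πr·Δr in 2-D, 4πr²·Δr in 3-D) and returns the center of the
first local maximum above the mean density; only the peak location is
consumed downstream, so the overall normalization constant is
immaterial.

## Kinetics

Transfer times at constant pulling force follow Time = A·Force^−b.
The fit is ordinary least squares of ln T on ln F (the slope is
log-base invariant); b is the negated slope, A the exponentiated
intercept, and r the Pearson correlation of the log-log pairs.  With
replicates the default uses every row (matching the 72-simulation
convention); an aggregated table fits one point per force.  The fit is
scale-equivariant: scaling all times by c scales A by c and leaves b
and r untouched.  Predictions outside the fitted force range are
labelled extrapolations — the physiological evaluation sits three
decades below the fitted span and is never reported silently.

The bundled 18-force table carries only per-force means ± SD (n = 4);
the replicate-level constants (A = 475, b = 2.75, |r| = 0.96) are
therefore reproducible from published data only approximately — the
means-only fit gives b ≈ 2.80, |r| ≈ 0.99.

## Biophysics

Internal pressure of a lipoprotein particle: P = 2α/R (Young-Laplace),
with measured surface tensions α ≈ 0.020–0.033 N/m for both HDL and
LDL and mean diameters ~100 Å (HDL) and ~220 Å (LDL).  The HDL–LDL
pressure difference pushed over the tunnel cross-section gives the
driving force; the cross-section is modelled as a circular disc of the
~6-Å tunnel diameter (an inference — a 6×4-Å rectangular cross-section
does not reproduce the 0.018–0.029 kcal/mol/Å span, the disc does).
The force-unit conversion is exact: 1 kcal/mol/Å = 4184/(N_A·10⁻¹⁰) N
≈ 6.948×10⁻¹¹ N.  The span convention pairs the low tension (0.020)
for both particles at the low end and the high tension (0.033) at the
high end.

Radiolabel conversions: specific activity (nmol CE/h/µg CETP, CETP
73 kDa) and plasma flux (µg CE/h/ml over 1.75 µg/ml CETP, CE 651 Da)
both reduce to CE molecules/s per CETP molecule (1.54 and 1.14
respectively); the per-molecule time is the reciprocal.  Reports round
forces to two significant figures and times to one–two, keeping full
precision internally.

## Synthetic data: what it emulates, what it does not

The generators define the test-bed conditions:

* **Barrels** place atom rings (default 24 atoms, 1-Å ring spacing,
  staggered) at radial distance inner_radius(s) + atom radius, so the
  on-axis clearance *is* the specified profile; rings extend 3 Å past
  both path ends so the probe cannot escape the open mouths at the
  endpoints.  The 1-Å ring spacing keeps the axial clearance overshoot
  below 0.03 Å, inside the 0.1-Å oracle tolerance.  Default dimensions
  (60 Å × 6.6 Å, hydrophobic residues) emulate a protein tunnel's
  scale; nothing else about a real protein — side-chain packing,
  flexibility, electrostatics — is represented.
* **Ligand trajectories** slide a rigid rod along the path with a
  scheduled reference-bond orientation (default: a 90° turn at the
  mid-tunnel, emulating the observed steroid-ring flip near the neck).
  Real ligands are flexible and their conformations are not emulated.
* **Force–time tables** invert the fitted law with multiplicative
  log-normal noise (σ = 0.3, chosen because the printed SDs scale
  roughly with the means; 18 forces of 6–23 kcal/mol/Å, 4 replicates —
  the study's design).  Individual replicates cannot be matched to the
  real simulations, only the mean/SD structure.
* **Langevin first-passage** is a 1-D overdamped Euler–Maruyama walk
  (reflecting entry, absorbing exit — transfer through the whole
  tunnel) with kBT from CODATA kB (0.616 kcal/mol at 310 K).  It has
  closed-form limits used as oracles: mean time → γL/F when
  F·L ≫ kBT, and L²γ/(2kBT) at F = 0.  In the drift regime its
  time–force law has exponent b ≈ 1 — deliberately distinct from the
  all-atom 2.75, which encodes force-dependent barrier crossing the
  surrogate does not model.  Passing tests on these generators
  therefore validate the *analysis machinery*, not any all-atom
  observable.

Per-step first-passage detection biases times upward by
O(√Δt) (missed sub-step crossings); at the default steps this is ~1%,
well inside the stated tolerances.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed through
numpy's Generator; reruns are byte-identical, and the simulate command
writes a manifest with input hashes.  The shipped analyses use a
60-Å barrel (1608 atoms), 61-frame trajectories, 72-row force tables
and 30–2000 Langevin walkers — sizes chosen so the whole chain runs in
about a minute on one core while keeping sampling error well inside
the assertion tolerances.

## Known limitations

* No Voronoi/alpha-sphere cavity enumeration; the profiler measures
  clearance along a given or greedily found path only.
* The hydrophobicity weighting uses ligand-free SASA on the input
  structure; conformation-resolved weights would differ in flexible
  regions.
* All-atom observables (interaction-energy barriers, the measured
  6.0 ± 0.6 Å neck of the real protein, RMSF percentages of the real
  trajectories) are out of reach of the synthetic surrogates and are
  not asserted anywhere.
* The Young-Laplace model treats particles as ideal spheres with a
  single surface tension and ignores entropic contributions to the
  chemical-potential difference; it is a driving-force estimate, not a
  free-energy calculation.
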