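#!/usr/bin/env python
"""Young-Laplace driving force and radiolabel turnover conversions.

Computes the internal-pressure difference between HDL- (50 Å) and LDL-
(110 Å) sized particles at surface tensions 0.020–0.033 N/m, pushes it
over the 6-Å tunnel cross-section to get the physiological driving
force, and converts the two radiolabel measurements (specific activity
and bulk plasma flux) to per-CETP turnover rates and times.
"""
from pathlib import Path

from cetptunnel.config import RunConfig
from cetptunnel.pipeline import cmd_predict

OUT = Path(__file__).resolve().parent.parent / "results" / "biophysics"

res = cmd_predict(RunConfig({"seed": 2016}), OUT)
print(f"physiological driving force: "
      f"{res['driving_force_low_kcal_mol_A']:.3f}–"
      f"{res['driving_force_high_kcal_mol_A']:.3f} kcal/mol/Å")
print(f"radiolabel turnover: {res['radiolabel_rate_plasma_flux_per_s']:.2f}–"
      f"{res['radiolabel_rate_specific_activity_per_s']:.2f} CE molecules/s/CETP")
print(f"per-molecule transfer time: {res['radiolabel_time_specific_activity_s']:.2f}–"
      f"{res['radiolabel_time_plasma_flux_s']:.2f} s")
print(f"report -> {OUT}")
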