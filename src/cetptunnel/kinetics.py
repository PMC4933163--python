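"""Power-law kinetics of steered transfer time versus driving force.

Repeated pulling simulations at constant force F yield transfer times T
that follow Time = A·Force^−b over the simulated force range; on log-log
axes this is a straight line, so the fit is ordinary least squares of
log T on log F.  The fitted law is then extrapolated down to
physiological driving forces (three orders of magnitude below the
simulated ones — always labelled as extrapolation).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, TextIO

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ForceTimeTable",
    "PowerLawFit",
    "fit_power_law",
    "predict_time",
    "summarize",
    "load_reference_table",
]

REPLICATE_COLUMNS = ["force_kcal_mol_A", "replicate", "time_ns"]
AGGREGATED_COLUMNS = ["force_kcal_mol_A", "mean_time_ns", "sd_time_ns", "n"]


@dataclass
class ForceTimeTable:
    """Driving forces (kcal/mol/Å) with transfer times (ns).

    Either replicate-level (force, replicate, time) or aggregated
    (force, mean, sd, n) — the printed study table ships aggregated, the
    synthetic generator produces replicates.
    """

    data: pd.DataFrame
    aggregated: bool

    def __post_init__(self) -> None:
        cols = AGGREGATED_COLUMNS if self.aggregated else REPLICATE_COLUMNS
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
        if np.any(self.data["force_kcal_mol_A"].to_numpy() <= 0):
            raise ValueError("forces must be positive")
        tcol = "mean_time_ns" if self.aggregated else "time_ns"
        if np.any(self.data[tcol].to_numpy() <= 0):
            raise ValueError("times must be positive")

    @classmethod
    def from_replicates(cls, df: pd.DataFrame) -> "ForceTimeTable":
        return cls(df.reset_index(drop=True), aggregated=False)

    @classmethod
    def from_means(cls, df: pd.DataFrame) -> "ForceTimeTable":
        return cls(df.reset_index(drop=True), aggregated=True)

    @classmethod
    def from_csv(cls, stream: TextIO | str | Path, sep: str | None = None) -> "ForceTimeTable":
        """Load either layout from CSV/TSV, inferring which from the header."""
        try:
            df = pd.read_csv(stream, sep=sep, engine="python", comment="#")
        except Exception as exc:
            raise ValueError(f"malformed force-time table: {exc}") from None
        if set(REPLICATE_COLUMNS) <= set(df.columns):
            return cls.from_replicates(df[REPLICATE_COLUMNS])
        if set(AGGREGATED_COLUMNS) <= set(df.columns):
            return cls.from_means(df[AGGREGATED_COLUMNS])
        raise ValueError(
            f"unrecognized columns {list(df.columns)}; expected {REPLICATE_COLUMNS} "
            f"or {AGGREGATED_COLUMNS}"
        )

    def to_csv(self, stream: TextIO | str | Path) -> None:
        self.data.to_csv(stream, index=False)

    @property
    def forces(self) -> np.ndarray:
        return np.unique(self.data["force_kcal_mol_A"].to_numpy())

    def force_range(self) -> tuple[float, float]:
        f = self.forces
        return float(f.min()), float(f.max())


@dataclass
class PowerLawFit:
    """Time = prefactor · Force^−exponent with the log-log Pearson r.

    ``prefactor`` carries units ns·(kcal/mol/Å)^exponent; ``correlation``
    is the Pearson r of the (log F, log T) pairs (negative for a
    decreasing law).  ``force_range`` records the fitted span so
    predictions outside it can be labelled extrapolations.
    """

    prefactor: float
    exponent: float
    correlation: float
    n_points: int
    force_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")

    def is_extrapolation(self, force: float) -> bool:
        if self.force_range is None:
            return False
        lo, hi = self.force_range
        return not lo <= force <= hi


def fit_power_law(
    table: ForceTimeTable,
    weighting: Literal["auto", "per-replicate", "per-force-mean"] = "auto",
) -> PowerLawFit:
    """Least-squares power-law fit of transfer time versus force.

    Natural-log OLS of log(time) on log(force); the exponent is the
    negated slope, the prefactor the exponentiated intercept.
    ``per-replicate`` uses every row (the study's own convention when
    replicates exist), ``per-force-mean`` one point per force; ``auto``
    picks per-replicate whenever replicates are available.
    """
    if weighting == "auto":
        weighting = "per-force-mean" if table.aggregated else "per-replicate"
    if weighting == "per-replicate" and table.aggregated:
        raise ValueError("aggregated table has no replicates; use per-force-mean")

    if weighting == "per-replicate":
        f = table.data["force_kcal_mol_A"].to_numpy(dtype=float)
        t = table.data["time_ns"].to_numpy(dtype=float)
    else:
        if table.aggregated:
            f = table.data["force_kcal_mol_A"].to_numpy(dtype=float)
            t = table.data["mean_time_ns"].to_numpy(dtype=float)
        else:
            grouped = summarize(table)
            f = grouped["force_kcal_mol_A"].to_numpy(dtype=float)
            t = grouped["mean_time_ns"].to_numpy(dtype=float)

    if len(np.unique(f)) < 2:
        raise ValueError("need at least 2 distinct forces to fit")
    res = stats.linregress(np.log(f), np.log(t))
    return PowerLawFit(
        prefactor=float(math.exp(res.intercept)),
        exponent=float(-res.slope),
        correlation=float(res.rvalue),
        n_points=len(f),
        force_range=(float(f.min()), float(f.max())),
    )


def predict_time(fit: PowerLawFit, force: float) -> float:
    """Transfer time (ns) at a driving force (kcal/mol/Å): A·F^−b."""
    if force <= 0:
        raise ValueError("force must be positive")
    return fit.prefactor * force ** (-fit.exponent)


def summarize(table: ForceTimeTable) -> pd.DataFrame:
    """Per-force mean, sample SD (n−1 denominator) and replicate count.

    A single-replicate force carries NaN SD (flagged, not silently zero).
    """
    if table.aggregated:
        return table.data.copy()
    g = table.data.groupby("force_kcal_mol_A")["time_ns"]
    out = pd.DataFrame(
        {
            "force_kcal_mol_A": g.mean().index,
            "mean_time_ns": g.mean().to_numpy(),
            "sd_time_ns": g.std(ddof=1).to_numpy(),
            "n": g.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def load_reference_table() -> ForceTimeTable:
    """The bundled 18-force steered-transfer table (mean ± SD, n = 4 each).

    Published means and SDs of 72 all-atom pulling simulations (18
    forces from 6 to 23 kcal/mol/Å, four replicates each); only the
    per-force aggregates are available, so the table ships aggregated.
    """
    ref = resources.files("cetptunnel.data").joinpath("force_time_means.tsv")
    with ref.open("r") as handle:
        return ForceTimeTable.from_csv(handle, sep="\t")
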