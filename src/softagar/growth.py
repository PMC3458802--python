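"""Per-well growth metrics: colony calling, size change, doubling time.

The assay's operational definitions, applied to particle tables:

* a particle is a **colony** when its area strictly exceeds the mean day-2
  particle area plus two standard deviations (computed over a chip or a
  single well);
* **change in average cell size** and **relative colony-number change** are
  differenced against day 2 to cancel the cell clumps present at seeding;
* the growth rate constant k solves x = x0 * exp(k t) between the day-2
  total cell-covered area x0 and the fit-day area x, and the doubling time
  is t_d = ln 2 / k. Wells whose area did not increase do not fit the
  exponential model and are flagged ``no_fit`` rather than given a rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnalysisError

__all__ = [
    "ColonyThreshold",
    "GrowthFit",
    "colony_size_threshold",
    "count_colonies",
    "delta_mean_size",
    "relative_colony_change",
    "fit_growth",
    "plating_efficiency",
]


@dataclass(frozen=True)
class ColonyThreshold:
    """Colony-calling cutoff: day-2 mean particle area plus two sample SDs."""

    mean_day2_size: float
    sd_day2_size: float
    threshold: float
    scope: str = "per_chip"
    n_particles: int = 0


def _areas(tables: Iterable[pd.DataFrame] | pd.DataFrame) -> np.ndarray:
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    parts = [np.asarray(t["area_px2"], dtype=float) for t in tables]
    return np.concatenate(parts) if parts else np.empty(0)


def colony_size_threshold(
    day2_tables: Iterable[pd.DataFrame] | pd.DataFrame, scope: str = "per_chip"
) -> ColonyThreshold:
    """Pool day-2 particle areas over ``scope`` and return mean + 2*SD.

    Requires at least two particles (the sample SD is undefined otherwise).
    """
    areas = _areas(day2_tables)
    if areas.size < 2:
        raise AnalysisError(
            f"colony threshold needs >=2 day-2 particles in scope, got {areas.size}"
        )
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1))
    return ColonyThreshold(mean, sd, mean + 2.0 * sd, scope=scope, n_particles=areas.size)


def count_colonies(table: pd.DataFrame, thr: ColonyThreshold) -> int:
    """Number of particles strictly larger than the colony threshold.

    The rule is "larger than", so a particle exactly at the threshold is not
    a colony.
    """
    if len(table) == 0:
        return 0
    return int((np.asarray(table["area_px2"], dtype=float) > thr.threshold).sum())


def delta_mean_size(day2_table: pd.DataFrame, dayd_table: pd.DataFrame) -> float:
    """Mean particle area at the later day minus mean area at day 2 (px^2).

    Raw (pre-normalisation). An empty table at either day is recorded as a
    missing value with a warning, never as a silent zero.
    """
    if len(day2_table) == 0 or len(dayd_table) == 0:
        warnings.warn("empty particle table; size change recorded as missing", stacklevel=2)
        return float("nan")
    return float(dayd_table["area_px2"].mean() - day2_table["area_px2"].mean())


def relative_colony_change(
    day2_table: pd.DataFrame,
    dayd_table: pd.DataFrame,
    thr: ColonyThreshold,
    well_id: str = "?",
) -> float:
    """(colonies at day D - colonies at day 2) / day-2 total particle count."""
    n2 = len(day2_table)
    if n2 == 0:
        raise AnalysisError(f"well {well_id}: no day-2 particles to normalise colony change")
    return (count_colonies(dayd_table, thr) - count_colonies(day2_table, thr)) / n2


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit of one well's total cell-covered area."""

    x0: float
    x: float
    t: float
    k: float = float("nan")
    t_d: float = float("nan")
    status: str = "no_fit"
    well_id: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def fit_growth(
    total_area_by_day: Mapping[float, float],
    fit_day: float,
    baseline_day: float = 2.0,
    method: str = "two_point",
    well_id: str = "",
) -> GrowthFit:
    """Solve x = x0 * exp(k t) for a well and derive the doubling time.

    ``two_point`` (the assay-faithful default) uses only the baseline and
    ``fit_day`` areas: k = ln(x / x0) / (fit_day - baseline_day).
    ``regression`` fits ln(area) against day over every time point up to and
    including ``fit_day`` (>= 3 points required).

    A well with x <= x0 or x0 = 0 did not grow exponentially and is returned
    with ``status='no_fit'`` and k, t_d unset.
    """
    days = {float(d): float(a) for d, a in total_area_by_day.items()}
    if float(baseline_day) not in days or float(fit_day) not in days:
        raise AnalysisError(
            f"well {well_id or '?'}: total areas required at day {baseline_day} and day {fit_day}"
        )
    if fit_day <= baseline_day:
        raise AnalysisError("fit_day must be after the baseline day")
    x0 = days[float(baseline_day)]
    x = days[float(fit_day)]
    t = float(fit_day) - float(baseline_day)
    no_fit = GrowthFit(x0=x0, x=x, t=t, status="no_fit", well_id=well_id)

    if method == "two_point":
        if x0 <= 0 or x <= x0:
            return no_fit
        k = math.log(x / x0) / t
    elif method == "regression":
        pts = sorted((d, a) for d, a in days.items() if baseline_day <= d <= fit_day)
        if len(pts) < 3:
            raise AnalysisError("regression fit needs >=3 time points")
        if any(a <= 0 for _, a in pts) or x0 <= 0 or x <= x0:
            return no_fit
        ds = np.array([d - baseline_day for d, _ in pts])
        la = np.log([a for _, a in pts])
        k = float(np.polyfit(ds, la, 1)[0])
        if k <= 0:
            return no_fit
    else:
        raise ValueError(f"unknown fit method {method!r}")

    return GrowthFit(x0=x0, x=x, t=t, k=k, t_d=math.log(2.0) / k, status="ok", well_id=well_id)


def plating_efficiency(
    day2_table: pd.DataFrame,
    colony_day_table: pd.DataFrame,
    thr: ColonyThreshold,
    well_id: str = "?",
) -> float:
    """Fraction of day-2 cells that formed a colony by the first later day."""
    n2 = len(day2_table)
    if n2 == 0:
        raise AnalysisError(f"well {well_id}: no day-2 particles to normalise plating efficiency")
    return count_colonies(colony_day_table, thr) / n2
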