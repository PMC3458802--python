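"""Chip- and screen-level statistics.

Raw per-well metrics are expressed as percent of the negative controls of
the same chip (pooled "no siRNA" and non-targeting wells), summarised per
siRNA as mean +/- SEM over replicate wells, and tested against the pooled
controls with a one-way ANOVA followed by two-sided Welch t-tests. A
siRNA is a *hit* when its normalised mean lies beyond two standard
deviations of the per-well control values and the t-test is significant.
Assay quality is quantified by the screening-window coefficient
Z' = 1 - 3 (SD+ + SD-) / R, where R is the absolute difference between the
positive- and negative-control means, and reproducibility by the Pearson
correlation between per-siRNA means of two replicate screens. Transfection
efficiency is the fraction of cells whose fluorescence exceeds the
non-targeting control mean plus two SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONTROL_ROLES
from .errors import AnalysisError

__all__ = [
    "ScreenWindow",
    "TransfectionResult",
    "normalize_to_controls",
    "summarize_sirna",
    "hit_call",
    "z_factor",
    "replicate_correlation",
    "transfection_efficiency",
]


def _control_wells(plate_map: pd.DataFrame, chip_id: str | None = None) -> pd.Index:
    pm = plate_map if chip_id is None else plate_map[plate_map["chip_id"] == chip_id]
    return pd.Index(pm.loc[pm["role"].isin(CONTROL_ROLES), "well_id"])


def normalize_to_controls(
    values: pd.Series, plate_map: pd.DataFrame, chip_id: str | None = None
) -> pd.Series:
    """Express per-well raw metric values as percent of the chip's controls.

    ``values`` is indexed by well_id. Normalisation is done within each chip
    (each well is divided by the mean of the negative-control wells of its
    own chip and multiplied by 100). Missing values propagate as NaN.
    """
    pm = plate_map if chip_id is None else plate_map[plate_map["chip_id"] == chip_id]
    well_chip = pm.set_index("well_id")["chip_id"]
    unknown = values.index.difference(well_chip.index)
    if len(unknown) > 0:
        raise AnalysisError(f"wells absent from the plate map: {sorted(unknown)}")
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for chip, wells in well_chip.groupby(well_chip):
        ctrl = _control_wells(pm, chip).intersection(values.index)
        ctrl_vals = values.loc[ctrl].dropna()
        if len(ctrl_vals) == 0:
            raise AnalysisError(f"chip {chip}: no usable negative-control wells")
        mean = float(ctrl_vals.mean())
        if mean <= 0:
            raise AnalysisError(f"chip {chip}: control mean {mean:g} is not positive")
        here = values.index.intersection(wells.index)
        out.loc[here] = values.loc[here] / mean * 100.0
    return out


def summarize_sirna(values: pd.Series, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Per-siRNA mean, SEM and replicate count of a normalised metric.

    Wells with missing values (e.g. ``no_fit`` doubling times) are excluded
    from n; their number is reported as ``n_missing``. SEM is NaN for n < 2.
    """
    pm = plate_map.set_index("well_id")
    unknown = values.index.difference(pm.index)
    if len(unknown) > 0:
        raise AnalysisError(f"wells absent from the plate map: {sorted(unknown)}")
    df = pd.DataFrame({"value": values})
    df["sirna"] = pm.loc[df.index, "sirna"]
    df["role"] = pm.loc[df.index, "role"]
    rows = []
    for sirna, grp in df.groupby("sirna", sort=False):
        vals = grp["value"].dropna()
        n = len(vals)
        rows.append(
            {
                "sirna": sirna,
                "role": grp["role"].iloc[0],
                "n": n,
                "n_missing": len(grp) - n,
                "mean_pct": float(vals.mean()) if n else float("nan"),
                "sem_pct": float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def hit_call(
    values: pd.Series,
    plate_map: pd.DataFrame,
    alpha: float = 0.05,
    band_sd: float = 2.0,
    suppressed_when: str = "below",
    p_adjust: str | None = None,
) -> tuple[pd.DataFrame, float]:
    """Flag siRNAs whose normalised metric departs from the controls.

    Runs a one-way ANOVA across every siRNA group (controls included), then
    a two-sided Welch t-test of each non-control siRNA against the pooled
    per-well control values. A siRNA is a hit when its mean lies beyond
    ``band_sd`` standard deviations of the control well values *and* its
    t-test p-value is below ``alpha``. ``suppressed_when`` maps the sign of
    the departure onto a direction label: for size/colony metrics smaller
    means suppression (``below``); for doubling time larger does (``above``).
    ``p_adjust='bh'`` applies Benjamini-Hochberg across the non-control
    siRNAs (off by default; the assay reports raw p-values).

    Returns the summary table (with ``p_value``, ``hit``, ``direction``
    columns added) and the ANOVA p-value.
    """
    if suppressed_when not in ("below", "above"):
        raise ValueError("suppressed_when must be 'below' or 'above'")
    summary = summarize_sirna(values, plate_map)
    pm = plate_map.set_index("well_id")
    ctrl_wells = pm.index[pm["role"].isin(CONTROL_ROLES)].intersection(values.index)
    ctrl = values.loc[ctrl_wells].dropna()
    if len(ctrl) < 2:
        raise AnalysisError("hit calling needs >=2 usable control wells")
    ctrl_mean = float(ctrl.mean())
    ctrl_sd = float(ctrl.std(ddof=1))
    degenerate_controls = ctrl_sd == 0

    groups = []
    for _, grp in values.groupby(pm.loc[values.index, "sirna"].values):
        vals = grp.dropna().to_numpy()
        if len(vals) >= 2:
            groups.append(vals)
    anova_p = float("nan")
    if len(groups) >= 2:
        anova_p = float(stats.f_oneway(*groups).pvalue)

    p_values, hits, directions = [], [], []
    for _, row in summary.iterrows():
        if row["role"] in CONTROL_ROLES:
            p_values.append(np.nan)
            hits.append(False)
            directions.append("")
            continue
        sirna_wells = pm.index[pm["sirna"] == row["sirna"]].intersection(values.index)
        vals = values.loc[sirna_wells].dropna().to_numpy()
        if degenerate_controls or len(vals) < 2:
            if degenerate_controls:
                warnings.warn(
                    "control wells have zero variance; t-test skipped", stacklevel=2
                )
            p = np.nan
        else:
            p = float(stats.ttest_ind(vals, ctrl.to_numpy(), equal_var=False).pvalue)
        mean = row["mean_pct"]
        beyond = (
            not np.isnan(mean)
            and abs(mean - ctrl_mean) > band_sd * ctrl_sd
        )
        if degenerate_controls:
            significant = beyond
        else:
            significant = (not np.isnan(p)) and p < alpha
        p_values.append(p)
        hits.append(bool(beyond and significant))
        if np.isnan(mean) or mean == ctrl_mean:
            directions.append("")
        elif (mean < ctrl_mean) == (suppressed_when == "below"):
            directions.append("suppressor")
        else:
            directions.append("stimulator")

    summary["p_value"] = p_values
    if p_adjust == "bh":
        mask = summary["p_value"].notna().to_numpy()
        adj = np.full(len(summary), np.nan)
        if mask.any():
            adj[mask] = stats.false_discovery_control(summary.loc[mask, "p_value"].to_numpy())
        summary["p_adjusted"] = adj
        significant = summary["p_adjusted"] < alpha
        hits = [
            bool(h and s) if not np.isnan(p) else h
            for h, s, p in zip(hits, significant, summary["p_value"])
        ]
    summary["hit"] = hits
    summary["direction"] = directions
    summary["control_mean_pct"] = ctrl_mean
    summary["control_sd_pct"] = ctrl_sd
    return summary, anova_p


@dataclass(frozen=True)
class ScreenWindow:
    """Z'-factor decomposition: arm SDs, dynamic range R and Z' itself."""

    sd_plus: float
    sd_minus: float
    dynamic_range: float
    z_prime: float


def z_factor(positive_values: Sequence[float], negative_values: Sequence[float]) -> ScreenWindow:
    """Screening-window coefficient Z' = 1 - 3 (SD+ + SD-) / R."""
    pos = np.asarray(positive_values, dtype=float)
    neg = np.asarray(negative_values, dtype=float)
    pos, neg = pos[~np.isnan(pos)], neg[~np.isnan(neg)]
    if len(pos) < 2 or len(neg) < 2:
        raise AnalysisError("Z' needs >=2 values in each control arm")
    r = abs(float(pos.mean()) - float(neg.mean()))
    if r == 0:
        raise AnalysisError("Z' undefined: the dynamic range R is zero")
    sd_plus = float(pos.std(ddof=1))
    sd_minus = float(neg.std(ddof=1))
    return ScreenWindow(sd_plus, sd_minus, r, 1.0 - 3.0 * (sd_plus + sd_minus) / r)


def replicate_correlation(screen_a: pd.Series, screen_b: pd.Series) -> float:
    """Pearson r between per-siRNA means of two replicate screens.

    Series are indexed by siRNA name; the correlation is computed over the
    intersection (with a warning when the sets differ). Requires >= 3 shared
    siRNAs and non-zero variance in both screens.
    """
    a = screen_a.dropna()
    b = screen_b.dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < len(a) or len(shared) < len(b):
        warnings.warn(
            f"screens share only {len(shared)} siRNAs; correlating the intersection",
            stacklevel=2,
        )
    if len(shared) < 3:
        raise AnalysisError("replicate correlation needs >=3 siRNAs present in both screens")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise AnalysisError("replicate correlation undefined for zero-variance screens")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class TransfectionResult:
    """Fraction of cells above the non-targeting fluorescence threshold."""

    threshold: float
    nt_mean: float
    nt_sd: float
    per_well_fraction: dict = field(default_factory=dict)
    mean_pct: float = float("nan")
    sem_pct: float = float("nan")
    n_wells: int = 0


def transfection_efficiency(
    well_intensities: Mapping[str, Sequence[float]],
    non_targeting_wells: Sequence[str],
) -> TransfectionResult:
    """Measure siRNA uptake from per-cell fluorescence intensities.

    ``well_intensities`` maps well_id to the per-cell (per-particle) mean
    fluorescence values of that well. The labeling threshold is the mean of
    the pooled non-targeting control cells plus two SDs; a cell is labeled
    when its intensity is strictly greater. The summary mean +/- SEM is
    taken over the non-control wells; empty wells yield missing fractions.
    """
    nt = [np.asarray(well_intensities[w], dtype=float) for w in non_targeting_wells
          if w in well_intensities]
    pooled = np.concatenate([v[~np.isnan(v)] for v in nt]) if nt else np.empty(0)
    if pooled.size < 2:
        raise AnalysisError("transfection threshold needs >=2 non-targeting cells")
    nt_mean = float(pooled.mean())
    nt_sd = float(pooled.std(ddof=1))
    threshold = nt_mean + 2.0 * nt_sd

    fractions: dict[str, float] = {}
    for well, vals in well_intensities.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        fractions[well] = float((v > threshold).mean()) if v.size else float("nan")

    sample = [f for w, f in fractions.items()
              if w not in set(non_targeting_wells) and not np.isnan(f)]
    result = TransfectionResult(threshold, nt_mean, nt_sd, fractions, n_wells=len(sample))
    if sample:
        arr = np.asarray(sample) * 100.0
        result.mean_pct = float(arr.mean())
        if len(arr) >= 2:
            result.sem_pct = float(arr.std(ddof=1) / np.sqrt(len(arr)))
    return result
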