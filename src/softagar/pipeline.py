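"""End-to-end orchestration: images -> particle tables -> metrics -> report.

``quantify_images`` turns every well stack in a directory into a particle
table (projection, threshold, component extraction). ``analyze_particles``
computes the per-well growth metrics, normalises them to the negative
controls of each chip, summarises per siRNA, calls hits, and computes the
screening window when positive-control wells are present.

Wells are keyed internally by ``chip_id/well_id`` so that multiple chips
with overlapping well labels can be analysed together; normalisation is
always within-chip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import growth, io, screenstats
from .config import CONTROL_ROLES, RunConfig
from .errors import AnalysisError, FormatError, SoftAgarError
from .segment import segment_stack

__all__ = ["quantify_images", "analyze_particles", "run_pipeline"]

log = logging.getLogger("softagar")

_PARTICLE_FILE_RE = re.compile(r"^particles_(?P<chip>.+)_(?P<well>[^_]+)_d(?P<day>[0-9.]+)\.csv$")

#: metrics reported per siRNA, with the direction that means suppression
METRICS = {
    "delta_mean_size_pct": "below",
    "relative_colony_change_pct": "below",
    "doubling_time_pct": "above",
}


def _uid(chip: str, well: str) -> str:
    return f"{chip}/{well}"


def _augmented_plate_map(plate_map: pd.DataFrame) -> pd.DataFrame:
    pm = plate_map.copy()
    pm["well_id"] = [
        _uid(c, w) for c, w in zip(pm["chip_id"], plate_map["well_id"])
    ]
    return pm


def quantify_images(config: RunConfig, plate_map: pd.DataFrame | None = None):
    """Segment every recognised stack in ``config.images_dir``.

    Returns ``{(chip_id, well_id, day): particle DataFrame}``. A fluorescence
    frame ``{chip}_{well}_fluor.tif`` contributes per-particle mean
    fluorescence at the baseline day. Unreadable files raise
    :class:`FormatError`; wells listed in the plate map but absent from the
    directory are reported with a warning by the caller.
    """
    config.validate()
    images_dir = Path(config.images_dir)
    found = []
    for p in sorted(images_dir.iterdir()):
        parsed = io.parse_stack_filename(p.name)
        if parsed is not None:
            found.append((parsed, p))
    tables = {}
    for (chip, well, day), path in found:
        stack = io.read_stack(path, well_id=well, day=day, pixel_size_um=config.pixel_size_um)
        fluor = None
        if day == config.baseline_day:
            fpath = images_dir / io.fluor_filename(chip, well)
            if fpath.exists():
                fluor = tifffile.imread(str(fpath))
        table = segment_stack(
            stack,
            well_diameter_px=config.well_diameter_px,
            fluor_img=fluor,
            method=config.threshold_method,
            threshold=config.fixed_threshold,
            min_particle_area=config.min_particle_area,
        )
        tables[(chip, well, float(day))] = table
        log.info("quantified %s well %s day %g: %d particles", chip, well, day, len(table))
    return tables


def write_particle_tables(tables, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (chip, well, day), table in sorted(tables.items()):
        d = int(day) if float(day).is_integer() else day
        io.write_particles(outdir / f"particles_{chip}_{well}_d{d}.csv", table)


def read_particle_tables(tables_dir):
    tables = {}
    for p in sorted(Path(tables_dir).glob("particles_*.csv")):
        m = _PARTICLE_FILE_RE.match(p.name)
        if m is None:
            continue
        tables[(m.group("chip"), m.group("well"), float(m.group("day")))] = io.read_particles(p)
    if not tables:
        raise FormatError(f"no particle tables found in {tables_dir}")
    return tables


def _colony_day(days: list[float], config: RunConfig) -> float | None:
    """Latest usable day for colony counting: the fit day when it precedes
    the late-merging exclusion, else the first post-baseline day that does."""
    usable = [d for d in days
              if config.baseline_day < d < config.late_colony_exclusion_day]
    if not usable:
        return None
    if config.fit_day in usable:
        return config.fit_day
    return usable[0]


def analyze_particles(tables, plate_map: pd.DataFrame, config: RunConfig) -> dict:
    """Compute the full screen report from per-(well, day) particle tables."""
    config.validate()
    warnings_list: list[str] = []
    pm = _augmented_plate_map(plate_map)
    pm_idx = pm.set_index("well_id")
    area_scale = config.pixel_size_um**2 if config.report_units == "um2" else 1.0

    by_well: dict[str, dict[float, pd.DataFrame]] = {}
    for (chip, well, day), table in tables.items():
        by_well.setdefault(_uid(chip, well), {})[float(day)] = table
    for uid in pm_idx.index:
        if uid not in by_well or config.baseline_day not in by_well.get(uid, {}):
            warnings_list.append(f"well {uid}: no day-{config.baseline_day:g} data; skipped")
    missing_from_map = [u for u in by_well if u not in pm_idx.index]
    if missing_from_map:
        raise AnalysisError(f"wells not in the plate map: {sorted(missing_from_map)}")

    # colony thresholds from day-2 particles, pooled per chip (or per well)
    thresholds: dict[str, growth.ColonyThreshold] = {}
    if config.threshold_scope == "per_chip":
        for chip in sorted(pm["chip_id"].unique()):
            day2 = [t[config.baseline_day] for u, t in by_well.items()
                    if u.startswith(chip + "/") and config.baseline_day in t]
            if day2:
                thresholds[chip] = growth.colony_size_threshold(day2, scope="per_chip")

    # ---- per-well metrics -------------------------------------------------
    timepoint_rows, summary_rows = [], []
    raw = {m: {} for m in ("delta_mean_size", "relative_colony_change", "doubling_time")}
    plating = {}
    for uid in pm_idx.index:
        days_tables = by_well.get(uid, {})
        if config.baseline_day not in days_tables:
            continue
        chip = pm_idx.loc[uid, "chip_id"]
        if config.threshold_scope == "per_well":
            thr = growth.colony_size_threshold(days_tables[config.baseline_day], scope="per_well")
        else:
            thr = thresholds[chip]
        days = sorted(days_tables)
        for day in days:
            t = days_tables[day]
            timepoint_rows.append(
                {
                    "chip_id": chip,
                    "well_id": uid.split("/", 1)[1],
                    "sirna": pm_idx.loc[uid, "sirna"],
                    "role": pm_idx.loc[uid, "role"],
                    "day": day,
                    "cell_count": len(t),
                    "mean_size": float(t["area_px2"].mean()) * area_scale if len(t) else np.nan,
                    "colony_count": growth.count_colonies(t, thr),
                    "total_area": float(t["area_px2"].sum()) * area_scale,
                }
            )
        base = days_tables[config.baseline_day]
        row = {
            "chip_id": chip,
            "well_id": uid.split("/", 1)[1],
            "sirna": pm_idx.loc[uid, "sirna"],
            "role": pm_idx.loc[uid, "role"],
            "day2_cell_count": len(base),
        }
        # size change and colony change at the fit / colony day
        if config.fit_day in days_tables:
            row["delta_mean_size"] = growth.delta_mean_size(base, days_tables[config.fit_day]) * area_scale
        else:
            warnings_list.append(f"well {uid}: no day-{config.fit_day:g} data for size change")
            row["delta_mean_size"] = np.nan
        cday = _colony_day(days, config)
        if cday is not None:
            row["colony_day"] = cday
            row["relative_colony_change"] = growth.relative_colony_change(
                base, days_tables[cday], thr, well_id=uid
            )
        else:
            row["colony_day"] = np.nan
            row["relative_colony_change"] = np.nan
        # exponential fit on total area
        if config.fit_day in days_tables:
            fit = growth.fit_growth(
                {d: float(t["area_px2"].sum()) for d, t in days_tables.items()},
                fit_day=config.fit_day,
                baseline_day=config.baseline_day,
                well_id=uid,
            )
            row.update(k=fit.k, t_d=fit.t_d, fit_status=fit.status,
                       x0=fit.x0 * area_scale, x=fit.x * area_scale)
        else:
            row.update(k=np.nan, t_d=np.nan, fit_status="missing", x0=np.nan, x=np.nan)
        # plating efficiency at the first post-baseline imaging day
        post = [d for d in days if d > config.baseline_day]
        if post:
            row["plating_efficiency"] = growth.plating_efficiency(base, days_tables[post[0]], thr, uid)
            plating[uid] = row["plating_efficiency"]
        else:
            row["plating_efficiency"] = np.nan
        raw["delta_mean_size"][uid] = row["delta_mean_size"]
        raw["relative_colony_change"][uid] = row["relative_colony_change"]
        raw["doubling_time"][uid] = row["t_d"]
        summary_rows.append(row)

    timepoints = pd.DataFrame(timepoint_rows)
    well_summary = pd.DataFrame(summary_rows)

    # ---- normalisation, summaries, hits ----------------------------------
    report: dict = {
        "schema": io.REPORT_SCHEMA,
        "units": config.report_units,
        "n_wells": len(well_summary),
        "chips": sorted(pm["chip_id"].unique().tolist()),
        "colony_thresholds": {c: asdict(t) for c, t in thresholds.items()},
        "metrics": {},
        "warnings": warnings_list,
    }
    normalized: dict[str, pd.Series] = {}
    for metric, direction in METRICS.items():
        raw_name = metric.removesuffix("_pct")
        series = pd.Series(raw[raw_name], dtype=float)
        try:
            norm = screenstats.normalize_to_controls(series, pm)
            summary, anova_p = screenstats.hit_call(
                norm, pm, alpha=config.alpha, suppressed_when=direction,
                p_adjust=config.p_adjust,
            )
        except AnalysisError as exc:
            warnings_list.append(f"{metric}: {exc}")
            continue
        normalized[metric] = norm
        report["metrics"][metric] = {
            "anova_p": anova_p,
            "per_sirna": summary.sort_values("sirna").to_dict(orient="records"),
            "hits": sorted(summary.loc[summary["hit"], "sirna"].tolist()),
        }

    # plating efficiency per siRNA (fraction of day-2 cells forming colonies)
    if plating:
        pe = screenstats.summarize_sirna(pd.Series(plating, dtype=float) * 100.0, pm)
        report["plating_efficiency_pct"] = pe.sort_values("sirna").to_dict(orient="records")

    # screening window from size change, positive vs negative control wells
    report["z_prime"] = None
    if "delta_mean_size_pct" in normalized:
        norm = normalized["delta_mean_size_pct"]
        pos = norm[pm_idx.loc[norm.index, "role"].values == "positive_control"].dropna()
        neg = norm[pm_idx.loc[norm.index, "role"].isin(CONTROL_ROLES).values].dropna()
        if len(pos) >= 2 and len(neg) >= 2:
            try:
                report["z_prime"] = asdict(screenstats.z_factor(pos, neg))
            except AnalysisError as exc:
                warnings_list.append(f"z_prime: {exc}")

    # transfection efficiency from day-2 particle fluorescence
    report["transfection"] = None
    fluor_by_well = {}
    for uid, days_tables in by_well.items():
        base = days_tables.get(config.baseline_day)
        if base is not None and base["mean_fluor"].notna().any():
            fluor_by_well[uid] = base["mean_fluor"].dropna().to_numpy()
    nt_wells = [u for u in fluor_by_well
                if pm_idx.loc[u, "role"] == "non_targeting"]
    if fluor_by_well and nt_wells:
        try:
            res = screenstats.transfection_efficiency(fluor_by_well, nt_wells)
            report["transfection"] = {
                "threshold": res.threshold,
                "nt_mean": res.nt_mean,
                "nt_sd": res.nt_sd,
                "mean_pct": res.mean_pct,
                "sem_pct": res.sem_pct,
                "n_wells": res.n_wells,
                "per_well_pct": {w: f * 100.0 for w, f in sorted(res.per_well_fraction.items())},
            }
        except AnalysisError as exc:
            warnings_list.append(f"transfection: {exc}")

    report["_tables"] = {"timepoints": timepoints, "well_summary": well_summary}
    return report


def write_outputs(report: dict, outdir) -> dict:
    """Write the report JSON and tidy CSVs; returns the report without the
    in-memory table attachments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables", {})
    if "timepoints" in tables:
        io.write_table(outdir / "well_timepoints.csv", tables["timepoints"])
    if "well_summary" in tables:
        io.write_table(outdir / "well_metrics.csv", tables["well_summary"])
    io.write_report(outdir / "report.json", report)
    return report


def run_pipeline(config: RunConfig) -> dict:
    """images + plate map -> particle tables -> metrics -> report.

    Writes particle CSVs, metric CSVs and ``report.json`` under
    ``config.out_dir`` and returns the report dict. Missing wells are
    reported in the report's warnings; missing controls abort the run.
    """
    config.validate()
    plate_map = io.read_plate_map(config.plate_map)
    tables = quantify_images(config, plate_map)
    write_particle_tables(tables, Path(config.out_dir) / "particles")
    report = analyze_particles(tables, plate_map, config)
    metric_missing = not report["metrics"]
    report = write_outputs(report, config.out_dir)
    if metric_missing:
        raise AnalysisError(
            "no metric could be normalised (missing negative controls?): "
            + "; ".join(report["warnings"])
        )
    return report
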