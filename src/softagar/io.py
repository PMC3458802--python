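"""File formats: multi-page TIFF stacks, CSV tables, JSON reports, YAML config.

Filenames follow ``{chip}_{well}_d{day}.tif`` for brightfield stacks and
``{chip}_{well}_fluor.tif`` for fluorescence frames. All CSV tables carry a
schema-version comment header and 0-based pixel coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import RunConfig, SimulationConfig, SirnaCondition
from .errors import FormatError
from .segment import PARTICLE_COLUMNS
from .types import WellImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "stack_filename",
    "fluor_filename",
    "parse_stack_filename",
    "write_plate_map",
    "read_plate_map",
    "write_particles",
    "read_particles",
    "write_table",
    "read_table",
    "write_truths",
    "write_report",
    "load_sim_config",
    "load_run_config",
    "write_screen",
]

PLATE_MAP_SCHEMA = "softagar-plate-map v1"
PARTICLES_SCHEMA = "softagar-particles v1"
TABLE_SCHEMA = "softagar-table v1"
REPORT_SCHEMA = "softagar-report v1"

_STACK_RE = re.compile(r"^(?P<chip>.+)_(?P<well>[^_]+)_d(?P<day>\d+(?:\.\d+)?)\.tiff?$")


def stack_filename(chip_id: str, well_id: str, day: float) -> str:
    d = int(day) if float(day).is_integer() else day
    return f"{chip_id}_{well_id}_d{d}.tif"


def fluor_filename(chip_id: str, well_id: str) -> str:
    return f"{chip_id}_{well_id}_fluor.tif"


def parse_stack_filename(name: str) -> tuple[str, str, float] | None:
    """Return (chip_id, well_id, day) or None if the name is not a stack."""
    m = _STACK_RE.match(Path(name).name)
    if m is None:
        return None
    return m.group("chip"), m.group("well"), float(m.group("day"))


def write_stack(path, stack: WellImageStack) -> None:
    """Write a stack as a multi-page TIFF with JSON metadata in the header."""
    meta = {
        "well_id": stack.well_id,
        "day": float(stack.day),
        "pixel_size_um": float(stack.pixel_size_um),
    }
    tifffile.imwrite(str(path), stack.data, photometric="minisblack", metadata=meta)


def read_stack(
    path,
    well_id: str | None = None,
    day: float | None = None,
    pixel_size_um: float | None = None,
) -> WellImageStack:
    """Read a multi-page TIFF as a stack; slices come back in page order.

    Metadata (well id, day, pixel size) is taken from the embedded JSON when
    present, the filename pattern second, and the keyword fallbacks last.
    Unreadable or mixed-shape files raise :class:`FormatError` naming the
    file.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta: dict[str, Any] = {}
            if tf.shaped_metadata:
                meta = dict(tf.shaped_metadata[0])
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt/mixed-shape files
        raise FormatError(f"cannot read TIFF stack {path.name}: {exc}") from exc
    parsed = parse_stack_filename(path.name)
    if well_id is None:
        well_id = meta.get("well_id") or (parsed[1] if parsed else path.stem)
    if day is None:
        day = meta.get("day", parsed[2] if parsed else float("nan"))
    if pixel_size_um is None:
        pixel_size_um = meta.get("pixel_size_um", float("nan"))
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected 2-D pages, got array of shape {data.shape}")
    return WellImageStack(well_id=str(well_id), day=float(day), data=data,
                          pixel_size_um=float(pixel_size_um))


# ---------------------------------------------------------------------------
# CSV tables

def _write_csv(path, df: pd.DataFrame, schema: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {schema}\n")
        df.to_csv(fh, index=False)


def _read_csv(path, schema: str) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#") or schema.split()[0] not in first:
            raise FormatError(f"{Path(path).name}: missing schema header ({schema})")
        return pd.read_csv(fh)


def write_plate_map(path, plate_map: pd.DataFrame) -> None:
    _write_csv(path, plate_map[["chip_id", "well_id", "sirna", "role", "replicate"]],
               PLATE_MAP_SCHEMA)


def read_plate_map(path) -> pd.DataFrame:
    pm = _read_csv(path, PLATE_MAP_SCHEMA)
    missing = {"chip_id", "well_id", "sirna", "role"} - set(pm.columns)
    if missing:
        raise FormatError(f"plate map lacks columns: {sorted(missing)}")
    dup = pm.duplicated(subset=["chip_id", "well_id"])
    if dup.any():
        raise FormatError("plate map has duplicate (chip_id, well_id) entries")
    return pm


def write_particles(path, table: pd.DataFrame) -> None:
    _write_csv(path, table[PARTICLE_COLUMNS], PARTICLES_SCHEMA)


def read_particles(path) -> pd.DataFrame:
    t = _read_csv(path, PARTICLES_SCHEMA)
    missing = set(PARTICLE_COLUMNS) - set(t.columns)
    if missing:
        raise FormatError(f"particle table lacks columns: {sorted(missing)}")
    return t[PARTICLE_COLUMNS]


def write_table(path, df: pd.DataFrame) -> None:
    """Generic tidy table (well metrics, growth curves, summaries)."""
    _write_csv(path, df, TABLE_SCHEMA)


def read_table(path) -> pd.DataFrame:
    return _read_csv(path, TABLE_SCHEMA)


# ---------------------------------------------------------------------------
# JSON

class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, cls=_NumpyEncoder, allow_nan=True)
        fh.write("\n")


def write_truths(path, truths) -> None:
    """Ground truth as JSON, one record per well (arrays become lists)."""
    payload = []
    for t in truths:
        payload.append(
            {
                "well_id": t.well_id,
                "sirna": t.sirna,
                "day": t.day,
                "seeded_cell_count": t.seeded_cell_count,
                "true_colony_forming_fraction": t.true_colony_forming_fraction,
                "true_k": t.true_k,
                "centers": np.round(t.centers, 3),
                "areas_px2": np.round(t.areas_px2, 4),
                "rates_k": np.round(t.rates_k, 6),
                "colony_forming": t.colony_forming,
                "labeled": t.labeled,
                "fluor_intensity": np.round(t.fluor_intensity, 3),
                "focal_slice": t.focal_slice,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, cls=_NumpyEncoder)
        fh.write("\n")


# ---------------------------------------------------------------------------
# YAML configuration

def load_sim_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sirnas = [SirnaCondition(**s) for s in raw.pop("sirnas", [])]
    for key in ("cells_per_well", "imaging_days"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SimulationConfig(sirnas=sirnas, **raw)
    cfg.validate()
    return cfg


def load_run_config(path, **overrides) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Screen materialisation

def write_screen(screen, outdir) -> None:
    """Write a synthetic screen to ``outdir``: stacks, fluorescence frames,
    plate map and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = screen.config
    write_plate_map(outdir / "plate_map.csv", screen.plate_map)
    write_truths(outdir / "truth.json", screen.truths())
    for well_id in screen.plate_map["well_id"]:
        for day in cfg.imaging_days:
            write_stack(outdir / stack_filename(cfg.chip_id, well_id, day),
                        screen.stack(well_id, day))
        tifffile.imwrite(str(outdir / fluor_filename(cfg.chip_id, well_id)),
                         screen.fluorescence(well_id), photometric="minisblack")
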