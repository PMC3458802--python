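"""Synthetic end-to-end recovery experiments.

Because colony screens of this kind publish summary statistics rather than
raw image stacks, the pipeline is validated by parameter recovery: the
simulator is configured so that the analytically expected value of a screen
metric equals a known reference, and the full image -> segmentation ->
statistics chain must recover it. Each experiment returns
``{"value": <number on the reported scale>, "n": <problem size>}``.

Problem sizes are deliberately desk-scale (5 replicate wells per arm,
scaled-down well rasters) so that every experiment runs in seconds; the
expected values are scale-free ratios, so shrinking the raster does not move
them.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import growth, screenstats
from .config import SimulationConfig, SirnaCondition
from .segment import segment_stack
from .simulate import SyntheticScreen, simulate_screen

__all__ = [
    "doubling_time_recovery",
    "size_change_recovery",
    "colony_number_recovery",
    "size_change_recovery_day10",
    "replicate_correlation_recovery",
    "transfection_efficiency_recovery",
]


def _child_seed(seed: int, stream: int) -> int:
    """A reproducible sub-seed (< 2**31) for one experiment."""
    return int(np.random.SeedSequence(seed, spawn_key=(stream,)).generate_state(1)[0] >> 1)


def _quantify(screen: SyntheticScreen, with_fluor: bool = False):
    """Segment every (well, imaging day) of a synthetic screen."""
    cfg = screen.config
    tables: dict[str, dict[float, pd.DataFrame]] = {}
    for well in screen.plate_map["well_id"]:
        tables[well] = {}
        for day in cfg.imaging_days:
            fluor = screen.fluorescence(well) if (with_fluor and day == 2.0) else None
            tables[well][day] = segment_stack(
                screen.stack(well, day),
                well_diameter_px=cfg.well_diameter_px,
                fluor_img=fluor,
            )
    return tables


def _arm_wells(screen: SyntheticScreen, sirna: str) -> list[str]:
    pm = screen.plate_map
    return pm.loc[pm["sirna"] == sirna, "well_id"].tolist()


def doubling_time_recovery(seed: int = 1) -> dict:
    """Treated doubling time as percent of control, days 2 -> 8.

    Five control wells grow colonies at k = 0.2310/day (3-day area doubling)
    and five treated wells at k = 0.0873/day; 600 cells per well, 39% of
    them colony-forming, per-colony rate CV 0.1. The pipeline fits
    x = x0 exp(k t) on measured total particle area per well over t = 6 days
    and reports the treated-to-control ratio of mean doubling times.
    """
    cfg = SimulationConfig(
        sirnas=[
            SirnaCondition("control", "negative_control", 0.39, 0.2310),
            SirnaCondition("treated", "targeted", 0.39, 0.0873),
        ],
        replicates_per_sirna=5,
        cells_per_well=(600, 600),
        rate_cv=0.1,
        well_cv=0.05,
        imaging_days=(2.0, 8.0),
        seed=_child_seed(seed, 1),
    )
    screen = simulate_screen(cfg)
    tables = _quantify(screen)
    t_d = {}
    for well, per_day in tables.items():
        fit = growth.fit_growth(
            {d: float(t["area_px2"].sum()) for d, t in per_day.items()},
            fit_day=8.0, well_id=well,
        )
        t_d[well] = fit.t_d if fit.ok else math.nan
    ctrl = np.nanmean([t_d[w] for w in _arm_wells(screen, "control")])
    trt = np.nanmean([t_d[w] for w in _arm_wells(screen, "treated")])
    return {"value": float(trt / ctrl * 100.0), "n": cfg.n_wells}


def _size_change_experiment(seed: int, stream: int, fit_day: float,
                            control_factor: float, treated_factor: float) -> dict:
    """Shared machinery for the mean-size-change recovery experiments.

    All cells are colony-forming and per-arm rates are set so true colony
    areas multiply by the given factors between day 2 and ``fit_day``; wells
    are kept sparse (100 cells, single-cell founders) so late-day colony
    merging does not distort the mean-size ratio.
    """
    t = fit_day - 2.0
    cfg = SimulationConfig(
        sirnas=[
            SirnaCondition("control", "negative_control", 1.0, math.log(control_factor) / t),
            SirnaCondition("treated", "targeted", 1.0, math.log(treated_factor) / t),
        ],
        replicates_per_sirna=5,
        cells_per_well=(100, 100),
        founder_cell_multiple=1.0,
        rate_cv=0.05,
        well_cv=0.02,
        imaging_days=(2.0, fit_day),
        seed=_child_seed(seed, stream),
    )
    screen = simulate_screen(cfg)
    tables = _quantify(screen)
    delta = {w: growth.delta_mean_size(per_day[2.0], per_day[fit_day])
             for w, per_day in tables.items()}
    ctrl = float(np.mean([delta[w] for w in _arm_wells(screen, "control")]))
    trt = float(np.mean([delta[w] for w in _arm_wells(screen, "treated")]))
    return {"value": trt / ctrl * 100.0, "n": cfg.n_wells}


def size_change_recovery(seed: int = 2) -> dict:
    """Day 2 -> 7 mean-size change, treated (x2.8 area) vs control (x6.0)."""
    return _size_change_experiment(seed, 2, fit_day=7.0, control_factor=6.0, treated_factor=2.8)


def size_change_recovery_day10(seed: int = 4) -> dict:
    """Day 2 -> 10 mean-size change, treated (x2.8) vs control (x5.0)."""
    return _size_change_experiment(seed, 4, fit_day=10.0, control_factor=5.0, treated_factor=2.8)


def colony_number_recovery(seed: int = 3) -> dict:
    """Relative colony-number change (day 2 -> 7), treated vs control.

    Control wells have colony-forming probability 0.39, treated 0.16, and
    formed colonies grow identically at k = 0.3/day. 600 cells per well on a
    half-scale well raster (1150 px diameter): at the default scaled-down
    raster 234 colonies/well already merge heavily by day 7, which is
    precisely the artifact the assay avoids by excluding late counts.
    The pipeline pools day-2 particles for the colony threshold, computes
    (colonies_d7 - colonies_d2) / cells_d2 per well and normalises the
    treated mean to the control mean.
    """
    cfg = SimulationConfig(
        sirnas=[
            SirnaCondition("control", "negative_control", 0.39, 0.3),
            SirnaCondition("treated", "targeted", 0.16, 0.3),
        ],
        replicates_per_sirna=5,
        cells_per_well=(600, 600),
        rate_cv=0.1,
        well_cv=0.05,
        imaging_days=(2.0, 7.0),
        frame_px=1200,
        well_diameter_px=1150,
        seed=_child_seed(seed, 3),
    )
    screen = simulate_screen(cfg)
    tables = _quantify(screen)
    thr = growth.colony_size_threshold([per_day[2.0] for per_day in tables.values()])
    change = {
        w: growth.relative_colony_change(per_day[2.0], per_day[7.0], thr, well_id=w)
        for w, per_day in tables.items()
    }
    ctrl = float(np.mean([change[w] for w in _arm_wells(screen, "control")]))
    trt = float(np.mean([change[w] for w in _arm_wells(screen, "treated")]))
    return {"value": trt / ctrl * 100.0, "n": cfg.n_wells}


def replicate_correlation_recovery(seed: int = 5, n_pairs: int = 200, n_sirnas: int = 40) -> dict:
    """Mean Pearson r between replicate screens under a variance-component model.

    Per-siRNA true normalised effects have SD 20 (percent-of-control scale);
    each screen adds independent per-siRNA noise with SD 10, giving an
    expected correlation of 400 / (400 + 100) = 0.8.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))
    names = [f"sirna{i:02d}" for i in range(n_sirnas)]
    rs = []
    for _ in range(n_pairs):
        effects = 100.0 + rng.normal(0.0, 20.0, n_sirnas)
        a = pd.Series(effects + rng.normal(0.0, 10.0, n_sirnas), index=names)
        b = pd.Series(effects + rng.normal(0.0, 10.0, n_sirnas), index=names)
        rs.append(screenstats.replicate_correlation(a, b))
    return {"value": float(np.mean(rs)), "n": n_pairs}


def transfection_efficiency_recovery(seed: int = 6) -> dict:
    """Fluorescent-siRNA uptake measured against the non-targeting threshold.

    Five wells of 500 cells with 82% labeled (bright ~ N(150, 17), dim
    control ~ N(100, 10)); five non-targeting wells define the mean + 2 SD
    threshold. Expected percent above threshold: 82 * P(N(150,17) > thr) +
    18 * P(N(100,10) > thr) ~ 79%.
    """
    cfg = SimulationConfig(
        sirnas=[
            SirnaCondition("non_targeting", "non_targeting", 0.0, 0.0, labeled_fraction=0.0),
            SirnaCondition("accell_green", "targeted", 0.0, 0.0, labeled_fraction=0.82),
        ],
        replicates_per_sirna=5,
        cells_per_well=(500, 500),
        imaging_days=(2.0,),
        seed=_child_seed(seed, 6),
    )
    screen = simulate_screen(cfg)
    tables = _quantify(screen, with_fluor=True)
    intensities = {w: per_day[2.0]["mean_fluor"].to_numpy() for w, per_day in tables.items()}
    res = screenstats.transfection_efficiency(
        intensities, _arm_wells(screen, "non_targeting")
    )
    return {"value": res.mean_pct, "n": cfg.n_wells}
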