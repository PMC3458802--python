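"""Ground-truthed synthetic soft-agar screens.

The generator emulates the assay the analysis expects: each well of a chip
is seeded with 500-700 agar-embedded cells, a condition-specific fraction of
which found colonies whose area grows exponentially (area(t) =
area(2) * exp(k_i * (t - 2)) with per-colony rates k_i scattered
lognormally around the condition rate). Colony founders appear at the day-2
baseline as small clumps of a few cell areas - real day-2 images contain
clumped and overlapping cells, which is exactly why the assay differences
all metrics against day 2. Wells are rendered as brightfield z-stacks (dark
disks on a bright noisy background; every object is sharp in one focal
slice and strongly attenuated/blurred in the others, so the
minimum-intensity projection recovers all of them) plus an optional
fluorescence frame modelling Accell-Green-like siRNA uptake.

Everything is reproducible: one integer seed determines layouts, truths and
images byte-for-byte, and each (well, day) draws from its own seed stream so
stacks can be re-rendered lazily in any order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .config import SimulationConfig, SirnaCondition
from .errors import ConfigurationError
from .segment import circular_footprint
from .types import WellImageStack

__all__ = [
    "WellTruth",
    "SyntheticScreen",
    "simulate_screen",
    "build_plate_map",
    "grow_well",
    "render_well_stack",
    "render_fluorescence",
]


@dataclass
class WellTruth:
    """Ground truth for one well at one day.

    Arrays are parallel, one entry per seeded object. ``colony_forming``
    marks the objects whose area grows; the rest stay at single-cell area.
    """

    well_id: str
    sirna: str
    day: float
    seeded_cell_count: int
    centers: np.ndarray          # (n, 2) row/col pixel coordinates
    areas_px2: np.ndarray        # (n,) current true area
    rates_k: np.ndarray          # (n,) per-day growth rate (0 for non-forming)
    colony_forming: np.ndarray   # (n,) bool
    labeled: np.ndarray          # (n,) bool - fluorescent siRNA uptake
    fluor_intensity: np.ndarray  # (n,) per-cell fluorescence (arbitrary units)
    focal_slice: np.ndarray      # (n,) int - z-slice where the object is sharp
    alive: np.ndarray            # (n,) bool
    true_colony_forming_fraction: float = float("nan")
    true_k: float = float("nan")

    @property
    def n_colonies(self) -> int:
        return int(np.count_nonzero(self.colony_forming & self.alive))

    def total_area(self) -> float:
        return float(self.areas_px2[self.alive].sum())


def grow_well(truth: WellTruth, from_day: float, to_day: float) -> WellTruth:
    """Advance a well's true areas from ``from_day`` to ``to_day``.

    Colony-forming objects multiply their area by exp(k_i * dt); everything
    else is unchanged. The object list never gains members, so the colony
    count cannot increase.
    """
    dt = float(to_day) - float(from_day)
    if dt < 0:
        raise ValueError(f"cannot grow backwards: from day {from_day} to day {to_day}")
    if not math.isclose(float(from_day), float(truth.day)):
        raise ValueError(f"truth is at day {truth.day}, not day {from_day}")
    areas = truth.areas_px2.copy()
    growing = truth.colony_forming & truth.alive
    areas[growing] = areas[growing] * np.exp(truth.rates_k[growing] * dt)
    return replace(truth, day=float(to_day), areas_px2=areas)


def build_plate_map(config: SimulationConfig) -> pd.DataFrame:
    """Assign wells to siRNA conditions in replicate blocks.

    Returns a table with columns chip_id, well_id, sirna, role, replicate.
    Raises :class:`ConfigurationError` if the layout does not fit the chip.
    """
    config.validate()
    width = max(2, len(str(config.wells_per_chip)))
    rows = []
    w = 0
    for cond in config.sirnas:
        for rep in range(1, config.replicates_per_sirna + 1):
            w += 1
            rows.append(
                {
                    "chip_id": config.chip_id,
                    "well_id": f"W{w:0{width}d}",
                    "sirna": cond.name,
                    "role": cond.role,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def _unit_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _generate_day2_truth(
    config: SimulationConfig, cond: SirnaCondition, well_id: str, rng: np.random.Generator
) -> WellTruth:
    n = int(rng.integers(config.cells_per_well[0], config.cells_per_well[1] + 1))
    # uniform positions in the well disk, with a small margin for object radii
    margin = 4.0 * config.cell_radius_px
    r_max = max(config.well_radius_px - margin, 1.0)
    radii = r_max * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * math.pi
    c0 = (config.frame_px - 1) / 2.0
    centers = np.column_stack([c0 + radii * np.sin(theta), c0 + radii * np.cos(theta)])
    # colony fate is decided by the first uniform draw so that raising the
    # forming fraction (same seed) only converts non-formers into formers
    forming = rng.random(n) < cond.colony_forming_fraction
    well_factor = float(_unit_lognormal(rng, config.well_cv, ()))
    rates = cond.growth_rate_k * well_factor * _unit_lognormal(rng, config.rate_cv, n)
    rates[~forming] = 0.0
    areas = config.cell_area_px2 * _unit_lognormal(rng, config.size_cv, n)
    areas[forming] *= config.founder_cell_multiple
    labeled = rng.random(n) < cond.labeled_fraction
    fluor = np.where(
        labeled,
        rng.normal(config.labeled_intensity_mean, config.labeled_intensity_sd, n),
        rng.normal(config.unlabeled_intensity_mean, config.unlabeled_intensity_sd, n),
    )
    focal = rng.integers(0, config.z_slices, n)
    return WellTruth(
        well_id=well_id,
        sirna=cond.name,
        day=2.0,
        seeded_cell_count=n,
        centers=centers,
        areas_px2=areas,
        rates_k=rates,
        colony_forming=forming,
        labeled=labeled,
        fluor_intensity=fluor,
        focal_slice=focal,
        alive=np.ones(n, dtype=bool),
        true_colony_forming_fraction=cond.colony_forming_fraction,
        true_k=cond.growth_rate_k,
    )


def render_well_stack(
    truth: WellTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> WellImageStack:
    """Render a brightfield z-stack of a well.

    Objects are dark disks clipped to the circular well footprint. Each is
    drawn sharp in its focal slice; in the other slices it appears Gaussian-
    blurred (sigma grows with slice distance) and amplitude-attenuated, so
    its darkest appearance is in exactly one slice and defocused copies stay
    above any sensible segmentation threshold. The frame outside the well is
    a darker rim, which the analysis must exclude via the footprint.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.frame_px, config.frame_px)
    footprint = circular_footprint(shape, radius=config.well_radius_px)
    well_area = math.pi * config.well_radius_px**2
    if np.any(truth.areas_px2[truth.alive] > well_area):
        raise ConfigurationError(
            f"an object in well {truth.well_id} exceeds the well area ({well_area:.0f} px^2)"
        )
    slabs = [np.zeros(shape, dtype=bool) for _ in range(config.z_slices)]
    radii = np.sqrt(truth.areas_px2 / math.pi)
    for i in np.flatnonzero(truth.alive):
        rr, cc = draw_disk(tuple(truth.centers[i]), radii[i], shape=shape)
        keep = footprint[rr, cc]
        slabs[int(truth.focal_slice[i]) % config.z_slices][rr[keep], cc[keep]] = True

    depth = config.background_level - config.cell_level
    blurred: dict[tuple[int, int], np.ndarray] = {}
    slices = []
    for t in range(config.z_slices):
        dark = np.zeros(shape, dtype=np.float64)
        for s in range(config.z_slices):
            d = abs(t - s)
            if d == 0:
                contrib = slabs[s].astype(np.float64) * depth
            else:
                key = (s, d)
                if key not in blurred:
                    blurred[key] = gaussian_filter(
                        slabs[s].astype(np.float64), config.blur_sigma_per_slice * d
                    )
                contrib = blurred[key] * (depth * config.defocus_attenuation**d)
            np.maximum(dark, contrib, out=dark)
        img = np.where(footprint, config.background_level - dark, config.rim_level)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, shape)
        slices.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return WellImageStack(
        well_id=truth.well_id,
        day=truth.day,
        data=np.stack(slices),
        pixel_size_um=config.pixel_size_um,
    )


def render_fluorescence(
    truth: WellTruth, config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render the fluorescence channel of a well as a float32 frame.

    Each object's disk is filled with its per-cell intensity (labeled cells
    draw from the bright distribution, unlabeled from the dim control one) on
    a near-zero background; the spatial footprint matches the brightfield
    objects so brightfield particles can be used as measurement masks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = (config.frame_px, config.frame_px)
    footprint = circular_footprint(shape, radius=config.well_radius_px)
    img = np.full(shape, config.fluor_background, dtype=np.float64)
    radii = np.sqrt(truth.areas_px2 / math.pi)
    for i in np.flatnonzero(truth.alive):
        rr, cc = draw_disk(tuple(truth.centers[i]), radii[i], shape=shape)
        keep = footprint[rr, cc]
        rr, cc = rr[keep], cc[keep]
        img[rr, cc] = np.maximum(img[rr, cc], truth.fluor_intensity[i])
    if config.fluor_noise_sd > 0:
        img = img + rng.normal(0.0, config.fluor_noise_sd, shape)
    return np.clip(img, 0.0, None).astype(np.float32)


class SyntheticScreen:
    """A fully specified synthetic chip: plate map, truths and images.

    Stacks are rendered lazily from per-(well, day) seed streams, so a screen
    object is cheap to hold and bit-reproducible regardless of access order.
    """

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.plate_map = build_plate_map(config)
        self._conditions = {c.name: c for c in config.sirnas}
        self._well_index = {w: i for i, w in enumerate(self.plate_map["well_id"])}
        self._truth_cache: dict[str, WellTruth] = {}

    # -- seed streams -------------------------------------------------------
    def _rng(self, well_id: str, stream: int, day: float | None = None) -> np.random.Generator:
        key: tuple[int, ...] = (self._well_index[well_id], stream)
        if day is not None:
            key = key + (int(round(day * 10)),)
        return np.random.default_rng(np.random.SeedSequence(self.config.seed, spawn_key=key))

    # -- ground truth -------------------------------------------------------
    def truth_day2(self, well_id: str) -> WellTruth:
        if well_id not in self._truth_cache:
            row = self.plate_map.loc[self.plate_map["well_id"] == well_id].iloc[0]
            cond = self._conditions[row["sirna"]]
            self._truth_cache[well_id] = _generate_day2_truth(
                self.config, cond, well_id, self._rng(well_id, 0)
            )
        return self._truth_cache[well_id]

    def truth(self, well_id: str, day: float) -> WellTruth:
        t = grow_well(self.truth_day2(well_id), 2.0, day)
        if self.config.death_rate_per_day > 0 and day > 2.0:
            rng = self._rng(well_id, 3, day)
            survive = rng.random(t.seeded_cell_count) < math.exp(
                -self.config.death_rate_per_day * (day - 2.0)
            )
            t = replace(t, alive=t.alive & survive)
        return t

    def truths(self) -> list[WellTruth]:
        return [self.truth_day2(w) for w in self.plate_map["well_id"]]

    # -- images -------------------------------------------------------------
    def stack(self, well_id: str, day: float) -> WellImageStack:
        return render_well_stack(self.truth(well_id, day), self.config, self._rng(well_id, 1, day))

    def fluorescence(self, well_id: str) -> np.ndarray:
        return render_fluorescence(self.truth_day2(well_id), self.config, self._rng(well_id, 2))

    def stacks(self):
        """Yield (well_id, day, WellImageStack) over the imaging schedule."""
        for well_id in self.plate_map["well_id"]:
            for day in self.config.imaging_days:
                yield well_id, day, self.stack(well_id, day)

    def write(self, outdir) -> None:
        """Materialise the screen on disk (TIFF stacks, plate map, truth JSON)."""
        from . import io as _io

        _io.write_screen(self, outdir)


def simulate_screen(config: SimulationConfig) -> SyntheticScreen:
    """Validate ``config`` and build the corresponding synthetic screen."""
    return SyntheticScreen(config)
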