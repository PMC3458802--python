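"""Configuration objects for the simulator and the analysis pipeline.

The simulator emulates one chip: a 50-well slide in which each siRNA
condition occupies a block of replicate wells (default 5), each well seeded
with 500-700 cells embedded in soft agar and imaged as a short brightfield
z-stack on a fixed schedule of days post seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

__all__ = ["SirnaCondition", "SimulationConfig", "RunConfig", "ROLES", "CONTROL_ROLES"]

ROLES = ("negative_control", "non_targeting", "positive_control", "targeted")

#: roles pooled into the negative reference group ("no siRNA" + non-targeting)
CONTROL_ROLES = ("negative_control", "non_targeting")


@dataclass(frozen=True)
class SirnaCondition:
    """One siRNA condition and its ground-truth effect parameters.

    Parameters
    ----------
    name : str
        siRNA label as it appears in the plate map.
    role : str
        One of ``negative_control``, ``non_targeting``, ``positive_control``,
        ``targeted``.
    colony_forming_fraction : float
        Probability that a seeded cell founds a growing colony (the true
        plating efficiency of the condition).
    growth_rate_k : float
        Mean per-colony exponential area growth rate, per day.
    labeled_fraction : float
        Fraction of cells taking up the fluorescent siRNA (Accell-Green-like
        labeling); 0 for conditions without a fluorescent tracer.
    """

    name: str
    role: str = "targeted"
    colony_forming_fraction: float = 0.39
    growth_rate_k: float = 0.231
    labeled_fraction: float = 0.0

    def validate(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for siRNA {self.name!r}")
        for attr in ("colony_forming_fraction", "labeled_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{attr}={v} for siRNA {self.name!r} outside [0, 1]")
        if self.growth_rate_k < 0:
            raise ConfigurationError(f"growth_rate_k must be >= 0, got {self.growth_rate_k}")


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated chip.

    Geometry defaults render a scaled-down well: a 560 px circle inside a
    600 px frame standing in for the real 3 mm well (pixel_size_um is kept so
    areas can be reported in um^2). Intensity defaults put dark cells
    (``cell_level``) on a bright agar background (``background_level``) as in
    inverted-microscope brightfield.
    """

    sirnas: list[SirnaCondition] = field(default_factory=list)
    chip_id: str = "chip1"
    wells_per_chip: int = 50
    replicates_per_sirna: int = 5
    cells_per_well: tuple[int, int] = (500, 700)
    # biological noise
    rate_cv: float = 0.2            # per-colony growth-rate CV (lognormal)
    well_cv: float = 0.05           # well-level multiplicative rate noise
    size_cv: float = 0.1            # single-cell area CV
    founder_cell_multiple: float = 4.0  # day-2 area of a colony founder, in cell areas
    death_rate_per_day: float = 0.0     # per-object removal hazard (off by default)
    # imaging schedule (days post seeding; must include the day-2 baseline)
    imaging_days: tuple[float, ...] = (2.0, 7.0, 14.0)
    # geometry
    frame_px: int = 600
    well_diameter_px: int = 560
    pixel_size_um: float = 5.36
    z_slices: int = 3
    cell_radius_px: float = 2.0
    # brightfield intensity model (8-bit)
    background_level: float = 200.0
    cell_level: float = 80.0
    noise_sd: float = 5.0
    rim_level: float = 150.0
    blur_sigma_per_slice: float = 2.0
    defocus_attenuation: float = 0.35
    # fluorescence model (arbitrary units)
    fluor_background: float = 0.0
    fluor_noise_sd: float = 2.0
    unlabeled_intensity_mean: float = 100.0
    unlabeled_intensity_sd: float = 10.0
    labeled_intensity_mean: float = 150.0
    labeled_intensity_sd: float = 17.0
    seed: int = 0

    @property
    def well_radius_px(self) -> float:
        return self.well_diameter_px / 2.0

    @property
    def cell_area_px2(self) -> float:
        return math.pi * self.cell_radius_px**2

    @property
    def n_wells(self) -> int:
        return len(self.sirnas) * self.replicates_per_sirna

    def validate(self) -> None:
        if not self.sirnas:
            raise ConfigurationError("config needs at least one siRNA condition")
        names = [s.name for s in self.sirnas]
        if len(set(names)) != len(names):
            raise ConfigurationError("siRNA names must be unique")
        for s in self.sirnas:
            s.validate()
        if self.replicates_per_sirna < 1:
            raise ConfigurationError("replicates_per_sirna must be >= 1")
        if self.n_wells > self.wells_per_chip:
            raise ConfigurationError(
                f"layout needs {self.n_wells} wells but the chip has {self.wells_per_chip}"
            )
        lo, hi = self.cells_per_well
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid cells_per_well range {self.cells_per_well}")
        days = tuple(float(d) for d in self.imaging_days)
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("imaging_days must be strictly increasing")
        if 2.0 not in days:
            raise ConfigurationError("imaging_days must include the day-2 baseline")
        if self.well_diameter_px > self.frame_px:
            raise ConfigurationError("well_diameter_px must fit inside the frame")
        if self.z_slices < 1:
            raise ConfigurationError("z_slices must be >= 1")
        for attr in ("rate_cv", "well_cv", "size_cv", "noise_sd", "death_rate_per_day"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if self.founder_cell_multiple <= 0:
            raise ConfigurationError("founder_cell_multiple must be > 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class RunConfig:
    """Settings for the quantification/analysis pipeline.

    ``fit_day`` is the post-baseline time point used both for the two-point
    exponential fit and for the size/colony change metrics (the assay solves
    the growth equation at day 7 or 8 for MCF7-like schedules, day 10 for
    SK-BR-3-like ones). Colony counts taken on or after
    ``late_colony_exclusion_day`` are never used for colony-change metrics,
    because by then colonies merge and the counts are unreliable.
    """

    images_dir: str = "."
    plate_map: str = "plate_map.csv"
    out_dir: str = "out"
    baseline_day: float = 2.0
    fit_day: float = 7.0
    late_colony_exclusion_day: float = 14.0
    threshold_method: str = "otsu"      # or "fixed"
    fixed_threshold: float | None = None
    threshold_scope: str = "per_chip"   # or "per_well"
    min_particle_area: int = 4
    well_diameter_px: int | None = 560  # None -> no footprint restriction
    pixel_size_um: float = 5.36
    alpha: float = 0.05
    p_adjust: str | None = None         # None (raw p, assay-faithful) or "bh"
    report_units: str = "px2"           # or "um2"
    seed: int = 0

    def validate(self) -> None:
        if self.fit_day <= self.baseline_day:
            raise ConfigurationError("fit_day must be after baseline_day")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ConfigurationError("fixed_threshold required when threshold_method='fixed'")
        if self.threshold_scope not in ("per_chip", "per_well"):
            raise ConfigurationError(f"unknown threshold_scope {self.threshold_scope!r}")
        if self.min_particle_area < 1:
            raise ConfigurationError("min_particle_area must be >= 1")
        if self.report_units not in ("px2", "um2"):
            raise ConfigurationError(f"unknown report_units {self.report_units!r}")
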