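"""Simulator: layout, growth arithmetic, rendering, determinism."""

import math

import numpy as np
import pytest

from softagar import (
    ConfigurationError,
    SimulationConfig,
    SirnaCondition,
    build_plate_map,
    grow_well,
    render_well_stack,
    segment_stack,
    simulate_screen,
)
from softagar.simulate import _generate_day2_truth


def _cfg(**kw):
    base = dict(
        sirnas=[SirnaCondition("ctrl", "negative_control"), SirnaCondition("t1")],
        replicates_per_sirna=2,
        cells_per_well=(20, 25),
        imaging_days=(2.0, 7.0),
        frame_px=200,
        well_diameter_px=180,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestLayout:
    def test_full_chip_layout(self):
        """9 targeted siRNAs + 1 pooled control block, 5 replicates -> 50 wells."""
        sirnas = [SirnaCondition("no_sirna", "negative_control")] + [
            SirnaCondition(f"gene{i}") for i in range(9)
        ]
        pm = build_plate_map(_cfg(sirnas=sirnas, replicates_per_sirna=5, wells_per_chip=50))
        assert len(pm) == 50
        assert pm["well_id"].is_unique
        assert (pm["role"] == "negative_control").sum() == 5
        assert pm.groupby("sirna").size().eq(5).all()

    def test_layout_overflow_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="wells"):
            build_plate_map(_cfg(wells_per_chip=3))

    @pytest.mark.parametrize(
        "bad",
        [
            dict(imaging_days=(7.0, 2.0)),
            dict(imaging_days=(3.0, 7.0)),  # baseline day 2 missing
            dict(well_diameter_px=300, frame_px=200),
            dict(cells_per_well=(0, 10)),
            dict(sirnas=[SirnaCondition("x", colony_forming_fraction=1.5)]),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            _cfg(**bad).validate()


class TestGrowWell:
    def _truth(self, rng, **kw):
        cfg = _cfg(**kw)
        return _generate_day2_truth(cfg, cfg.sirnas[0], "W01", rng), cfg

    def test_one_doubling(self, rng):
        truth, _ = self._truth(rng)
        truth.areas_px2[:] = 100.0
        truth.colony_forming[:] = True
        truth.rates_k[:] = math.log(2.0)
        grown = grow_well(truth, 2.0, 3.0)
        assert np.allclose(grown.areas_px2, 200.0)

    def test_zero_rate_is_identity(self, rng):
        truth, _ = self._truth(rng)
        truth.rates_k[:] = 0.0
        grown = grow_well(truth, 2.0, 9.0)
        assert np.array_equal(grown.areas_px2, truth.areas_px2)

    def test_negative_interval_rejected(self, rng):
        truth, _ = self._truth(rng)
        with pytest.raises(ValueError, match="backwards"):
            grow_well(truth, 2.0, 1.0)

    def test_population_total_matches_per_colony_closed_form(self, rng):
        """Total area after growth equals the sum of per-object closed forms."""
        truth, _ = self._truth(rng, cells_per_well=(300, 300))
        grown = grow_well(truth, 2.0, 9.0)
        expected = np.where(
            truth.colony_forming,
            truth.areas_px2 * np.exp(truth.rates_k * 7.0),
            truth.areas_px2,
        ).sum()
        assert grown.total_area() == pytest.approx(expected, rel=1e-9)
        assert grown.n_colonies <= truth.n_colonies

    def test_monotone_in_colony_forming_fraction(self):
        """More permissive forming probability never loses true colonies."""
        counts = []
        for f in (0.1, 0.3, 0.5, 0.9):
            cfg = _cfg(sirnas=[SirnaCondition("a", colony_forming_fraction=f),
                               SirnaCondition("ctrl", "negative_control")], seed=5)
            truth = simulate_screen(cfg).truth_day2("W01")
            counts.append(truth.n_colonies)
        assert counts == sorted(counts)


class TestRendering:
    def test_same_seed_bit_identical(self, tiny_config):
        a, b = simulate_screen(tiny_config), simulate_screen(tiny_config)
        w = a.plate_map["well_id"].iloc[0]
        assert np.array_equal(a.stack(w, 5.0).data, b.stack(w, 5.0).data)
        assert np.array_equal(a.fluorescence(w), b.fluorescence(w))
        ta, tb = a.truth_day2(w), b.truth_day2(w)
        assert np.array_equal(ta.areas_px2, tb.areas_px2)
        assert np.array_equal(ta.centers, tb.centers)

    def test_single_imaging_day_yields_one_stack_per_well(self, tiny_config):
        cfg = tiny_config.with_(imaging_days=(2.0,))
        screen = simulate_screen(cfg)
        stacks = list(screen.stacks())
        assert len(stacks) == len(screen.plate_map)

    def test_object_darkest_well_below_background(self, rng):
        """The in-focus appearance must be detectable under the noise floor."""
        cfg = _cfg(noise_sd=3.0, z_slices=3)
        truth = _generate_day2_truth(cfg, cfg.sirnas[0], "W01", rng)
        # keep a single object
        for arr in ("areas_px2", "rates_k", "fluor_intensity"):
            setattr(truth, arr, getattr(truth, arr)[:1])
        for arr in ("centers", "colony_forming", "labeled", "focal_slice", "alive"):
            setattr(truth, arr, getattr(truth, arr)[:1])
        truth.seeded_cell_count = 1
        truth.centers[0] = (100.0, 100.0)
        stack = render_well_stack(truth, cfg, np.random.default_rng(0))
        r, c = 100, 100
        assert stack.data[:, r, c].min() < cfg.background_level - 2 * cfg.noise_sd

    def test_empty_well_segments_to_nothing(self, rng):
        cfg = _cfg(cells_per_well=(1, 1), noise_sd=4.0)
        truth = _generate_day2_truth(cfg, cfg.sirnas[0], "W01", rng)
        truth.alive[:] = False
        stack = render_well_stack(truth, cfg, np.random.default_rng(0))
        table = segment_stack(stack, well_diameter_px=cfg.well_diameter_px)
        assert len(table) == 0

    def test_roundtrip_recovers_separated_objects(self):
        """Noise-free rendering + segmentation returns every object with
        its area within the rasterisation tolerance (+-15%)."""
        cfg = _cfg(noise_sd=0.0, frame_px=300, well_diameter_px=280,
                   cells_per_well=(9, 9), size_cv=0.0, founder_cell_multiple=4.0,
                   cell_radius_px=2.5,
                   sirnas=[SirnaCondition("all", "negative_control", 1.0, 0.3),
                           SirnaCondition("t", colony_forming_fraction=1.0)])
        screen = simulate_screen(cfg)
        truth = screen.truth_day2("W01")
        # place objects on a wide grid: separation >> 2 disk diameters
        spots = [(r + 0.4, c + 0.7) for r in (60, 150, 240) for c in (60, 150, 240)][: truth.seeded_cell_count]
        truth.centers[:] = np.array(spots, dtype=float)
        stack = render_well_stack(truth, cfg, np.random.default_rng(0))
        table = segment_stack(stack, well_diameter_px=cfg.well_diameter_px)
        assert len(table) == truth.seeded_cell_count
        measured = table.sort_values(["centroid_row", "centroid_col"])["area_px2"].to_numpy()
        order = np.lexsort((truth.centers[:, 1], truth.centers[:, 0]))
        true_areas = truth.areas_px2[order]
        assert np.all(np.abs(measured - true_areas) / true_areas <= 0.15)

    def test_oversized_object_rejected(self, rng):
        cfg = _cfg()
        truth = _generate_day2_truth(cfg, cfg.sirnas[0], "W01", rng)
        truth.areas_px2[0] = math.pi * cfg.well_radius_px**2 * 2
        with pytest.raises(ConfigurationError, match="exceeds the well"):
            render_well_stack(truth, cfg, np.random.default_rng(0))


class TestFluorescence:
    def test_unlabeled_condition_draws_from_control_distribution(self):
        cfg = _cfg(sirnas=[SirnaCondition("nt", "non_targeting", labeled_fraction=0.0),
                           SirnaCondition("c", "negative_control")],
                   cells_per_well=(500, 500))
        truth = simulate_screen(cfg).truth_day2("W01")
        assert not truth.labeled.any()
        assert truth.fluor_intensity.mean() == pytest.approx(
            cfg.unlabeled_intensity_mean, abs=3 * cfg.unlabeled_intensity_sd / math.sqrt(500)
        )

    def test_fully_labeled_condition(self):
        cfg = _cfg(sirnas=[SirnaCondition("ag", labeled_fraction=1.0),
                           SirnaCondition("c", "negative_control")],
                   cells_per_well=(500, 500))
        truth = simulate_screen(cfg).truth_day2("W01")
        assert truth.labeled.all()
        assert truth.fluor_intensity.mean() == pytest.approx(
            cfg.labeled_intensity_mean, abs=3 * cfg.labeled_intensity_sd / math.sqrt(500)
        )

    def test_mixture_matches_gaussian_tail_expectation(self):
        """With overlapping intensity distributions, the fraction of cells
        above the control mean + 2SD cutoff matches the closed-form mixture
        tail probability."""
        from scipy.stats import norm

        cfg = _cfg(sirnas=[SirnaCondition("ag", labeled_fraction=0.5),
                           SirnaCondition("c", "negative_control")],
                   cells_per_well=(700, 700), seed=11)
        truth = simulate_screen(cfg).truth_day2("W01")
        thr = cfg.unlabeled_intensity_mean + 2 * cfg.unlabeled_intensity_sd
        expected = 0.5 * norm.sf(
            thr, cfg.labeled_intensity_mean, cfg.labeled_intensity_sd
        ) + 0.5 * norm.sf(thr, cfg.unlabeled_intensity_mean, cfg.unlabeled_intensity_sd)
        measured = (truth.fluor_intensity > thr).mean()
        assert measured == pytest.approx(expected, abs=0.05)
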