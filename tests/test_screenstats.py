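"""Control normalisation, siRNA summaries, hit calls, Z', correlation,
transfection efficiency."""

import math

import numpy as np
import pandas as pd
import pytest

from softagar import (
    AnalysisError,
    hit_call,
    normalize_to_controls,
    replicate_correlation,
    summarize_sirna,
    transfection_efficiency,
    z_factor,
)


def plate_map(groups):
    """groups: dict sirna -> (role, [well ids])"""
    rows = []
    for sirna, (role, wells) in groups.items():
        for i, w in enumerate(wells, 1):
            rows.append({"chip_id": "c1", "well_id": w, "sirna": sirna,
                         "role": role, "replicate": i})
    return pd.DataFrame(rows)


@pytest.fixture
def pm():
    return plate_map({
        "no_sirna": ("negative_control", ["A1", "A2", "A3"]),
        "non_targeting": ("non_targeting", ["B1", "B2"]),
        "geneX": ("targeted", ["C1", "C2", "C3", "C4", "C5"]),
        "esr1": ("positive_control", ["D1", "D2", "D3"]),
    })


class TestNormalize:
    def test_controls_average_to_100(self, pm):
        vals = pd.Series({"A1": 4.0, "A2": 5.0, "A3": 6.0, "B1": 5.0, "B2": 5.0,
                          "C1": 1.8})
        norm = normalize_to_controls(vals, pm)
        ctrl = norm[["A1", "A2", "A3", "B1", "B2"]]
        assert ctrl.mean() == pytest.approx(100.0)
        assert norm["C1"] == pytest.approx(36.0)

    def test_scale_invariance(self, pm):
        vals = pd.Series({"A1": 4.0, "A2": 6.0, "C1": 2.0})
        scaled = normalize_to_controls(vals * 7.3, pm)
        assert scaled.equals(normalize_to_controls(vals, pm))

    def test_missing_controls_abort(self, pm):
        with pytest.raises(AnalysisError, match="control"):
            normalize_to_controls(pd.Series({"C1": 2.0}), pm)

    def test_nonpositive_control_mean_rejected(self, pm):
        with pytest.raises(AnalysisError, match="not positive"):
            normalize_to_controls(pd.Series({"A1": -1.0, "A2": 1.0, "C1": 2.0}), pm)

    def test_per_chip_normalisation(self):
        pm2 = pd.concat([
            plate_map({"no_sirna": ("negative_control", ["A1"]), "g": ("targeted", ["C1"])}),
            plate_map({"no_sirna": ("negative_control", ["A1"]), "g": ("targeted", ["C1"])})
            .assign(chip_id="c2", well_id=["X1", "X2"]),
        ])
        vals = pd.Series({"A1": 2.0, "C1": 1.0, "X1": 8.0, "X2": 4.0})
        norm = normalize_to_controls(vals, pm2)
        assert norm["C1"] == pytest.approx(50.0)
        assert norm["X2"] == pytest.approx(50.0)


class TestSummaries:
    def test_mean_and_sem(self, pm):
        vals = pd.Series({"C1": 30.0, "C2": 35.0, "C3": 40.0, "C4": 35.0, "C5": 40.0})
        s = summarize_sirna(vals, pm).set_index("sirna").loc["geneX"]
        assert s["mean_pct"] == pytest.approx(36.0)
        assert s["sem_pct"] == pytest.approx(np.std([30, 35, 40, 35, 40], ddof=1) / np.sqrt(5))
        assert s["sem_pct"] == pytest.approx(1.9, abs=0.08)

    def test_single_replicate_has_no_sem(self, pm):
        s = summarize_sirna(pd.Series({"C1": 42.0}), pm).set_index("sirna").loc["geneX"]
        assert s["mean_pct"] == 42.0 and math.isnan(s["sem_pct"])

    def test_identical_replicates_zero_sem(self, pm):
        s = summarize_sirna(pd.Series({"C1": 50.0, "C2": 50.0}), pm).set_index("sirna").loc["geneX"]
        assert s["sem_pct"] == 0.0

    def test_unknown_well_rejected(self, pm):
        with pytest.raises(AnalysisError, match="absent"):
            summarize_sirna(pd.Series({"ZZ": 1.0}), pm)


class TestHitCall:
    def _values(self, target_mean, rng, pm, spread=3.0):
        vals = {w: 100 + v for w, v in zip(
            ["A1", "A2", "A3", "B1", "B2"], rng.normal(0, spread, 5))}
        vals.update({w: target_mean + v for w, v in zip(
            ["C1", "C2", "C3", "C4", "C5"], rng.normal(0, spread, 5))})
        vals.update({w: 40.0 + v for w, v in zip(["D1", "D2", "D3"], rng.normal(0, spread, 3))})
        return pd.Series(vals)

    def test_suppressor_flagged(self, pm, rng):
        summary, anova_p = hit_call(self._values(36.0, rng, pm), pm)
        row = summary.set_index("sirna").loc["geneX"]
        assert row["hit"] and row["direction"] == "suppressor"
        assert row["p_value"] < 0.05
        assert anova_p < 0.01

    def test_stimulator_flagged(self, pm, rng):
        summary, _ = hit_call(self._values(170.0, rng, pm), pm)
        row = summary.set_index("sirna").loc["geneX"]
        assert row["hit"] and row["direction"] == "stimulator"

    def test_doubling_time_direction_reversed(self, pm, rng):
        """For doubling time, longer than control means suppression."""
        summary, _ = hit_call(self._values(265.0, rng, pm), pm, suppressed_when="above")
        assert summary.set_index("sirna").loc["geneX", "direction"] == "suppressor"

    def test_null_sirna_not_flagged(self, pm, rng):
        summary, _ = hit_call(self._values(101.0, rng, pm), pm)
        assert not summary.set_index("sirna").loc["geneX", "hit"]

    def test_invariant_to_well_order(self, pm, rng):
        vals = self._values(36.0, rng, pm)
        a, _ = hit_call(vals, pm)
        b, _ = hit_call(vals.sample(frac=1, random_state=0), pm.sample(frac=1, random_state=1))
        a = a.sort_values("sirna").reset_index(drop=True)
        b = b.sort_values("sirna").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_controls_warn(self, pm):
        vals = pd.Series({"A1": 100.0, "A2": 100.0, "C1": 50.0, "C2": 51.0})
        with pytest.warns(UserWarning, match="zero variance"):
            summary, _ = hit_call(vals, pm)
        assert math.isnan(summary.set_index("sirna").loc["geneX", "p_value"])

    def test_power_for_strong_suppressor(self, pm):
        """An effect at 36% of control with assay-realistic replicate scatter
        is detected in nearly every simulated screen."""
        rng = np.random.default_rng(7)
        hits = 0
        n_screens = 200
        for _ in range(n_screens):
            vals = self._values(36.0, rng, pm, spread=12.0)
            summary, _ = hit_call(vals, pm)
            hits += bool(summary.set_index("sirna").loc["geneX", "hit"])
        assert hits / n_screens >= 0.95


class TestZFactor:
    def test_hand_evaluated_example(self):
        w = z_factor([38, 40, 42], [97, 100, 103])
        sd_p = np.std([38, 40, 42], ddof=1)
        sd_n = np.std([97, 100, 103], ddof=1)
        assert w.dynamic_range == pytest.approx(60.0)
        assert w.z_prime == pytest.approx(1 - 3 * (sd_p + sd_n) / 60.0, rel=1e-12)

    def test_perfect_assay(self):
        assert z_factor([40.0, 40.0], [100.0, 100.0]).z_prime == 1.0

    def test_symmetric_in_arm_labels(self, rng):
        a, b = rng.normal(40, 2, 5), rng.normal(100, 3, 5)
        assert z_factor(a, b).z_prime == pytest.approx(z_factor(b, a).z_prime)

    def test_zero_dynamic_range_rejected(self):
        with pytest.raises(AnalysisError, match="dynamic range"):
            z_factor([50.0, 50.0], [50.0, 50.0])

    def test_strictly_decreasing_in_arm_sd(self, rng):
        base = z_factor([40, 42, 38], [100, 103, 97]).z_prime
        wider = z_factor([30, 50, 40], [100, 103, 97]).z_prime
        assert wider < base


class TestReplicateCorrelation:
    def test_identical_screens(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert replicate_correlation(s, s) == pytest.approx(1.0)

    def test_negated_screen(self):
        s = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert replicate_correlation(s, -s) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        y = pd.Series(rng.normal(size=40), index=x.index)
        r = replicate_correlation(x, y)
        expected = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_partial_overlap_warns(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        b = pd.Series([1.0, 2, 3, 4], index=list("abce"))
        with pytest.warns(UserWarning, match="intersection"):
            replicate_correlation(a, b)

    def test_too_few_shared_sirnas(self):
        a = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(AnalysisError, match=">=3"):
            replicate_correlation(a, a)

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 1, 1], index=list("abc"))
        b = pd.Series([1.0, 2, 3], index=list("abc"))
        with pytest.raises(AnalysisError, match="variance"):
            replicate_correlation(a, b)


class TestTransfection:
    def test_threshold_and_strict_comparison(self):
        nt = {"N1": [90.0, 110.0], "N2": [100.0, 100.0]}  # mean 100
        sd = np.std([90, 110, 100, 100], ddof=1)
        thr = 100 + 2 * sd
        res = transfection_efficiency(
            {**nt, "T1": [thr + 5, thr - 1, thr]}, ["N1", "N2"]
        )
        assert res.threshold == pytest.approx(thr)
        assert res.per_well_fraction["T1"] == pytest.approx(1 / 3)

    def test_control_wells_sit_at_gaussian_false_positive_floor(self, rng):
        """Non-targeting wells measured against their own threshold show only
        the ~2.3% upper-tail mass - the no-cross-contamination check."""
        nt = {f"N{i}": rng.normal(100, 10, 4000) for i in range(3)}
        res = transfection_efficiency(nt, list(nt))
        for frac in res.per_well_fraction.values():
            assert frac == pytest.approx(0.02275, abs=0.012)

    def test_separated_distributions_recover_labeled_fraction(self, rng):
        nt = {"N1": rng.normal(100, 10, 2000)}
        labeled = np.where(rng.random(2000) < 0.75,
                           rng.normal(300, 10, 2000), rng.normal(100, 10, 2000))
        res = transfection_efficiency({"N1": nt["N1"], "T1": labeled}, ["N1"])
        assert res.mean_pct == pytest.approx(75.0, abs=3.0)

    def test_needs_nontargeting_cells(self):
        with pytest.raises(AnalysisError, match="non-targeting"):
            transfection_efficiency({"T1": [1.0, 2.0]}, [])
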