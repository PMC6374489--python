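import numpy as np
import pandas as pd
import pytest

import drugpath as dp


class TestSphereGeometry:
    @pytest.mark.parametrize("convention", ["area", "diameter", "volume"])
    def test_sav_times_radius_is_three(self, convention):
        readout = np.array([0.5, 1.0, 7.3, 100.0])
        r, v, sa = dp.sphere_from_readout(readout, convention)
        assert np.allclose((sa / v) * r, 3.0)

    def test_sav_examples(self):
        r, v, sa = dp.sphere_from_readout(np.array([6.0]), "diameter")  # r = 3
        assert (sa / v)[0] == pytest.approx(1.0)
        r, v, sa = dp.sphere_from_readout(np.array([2.0]), "diameter")  # r = 1
        assert (sa / v)[0] == pytest.approx(3.0)

    def test_volume_doubling_scales_sav_by_cuberoot_half(self):
        r1, v1, sa1 = dp.sphere_from_readout(np.array([5.0]), "volume")
        r2, v2, sa2 = dp.sphere_from_readout(np.array([10.0]), "volume")
        assert (sa2 / v2)[0] / (sa1 / v1)[0] == pytest.approx(2.0 ** (-1.0 / 3.0))

    def test_sav_monotone_decreasing_in_radius(self):
        r, v, sa = dp.sphere_from_readout(np.linspace(1, 50, 25), "diameter")
        assert (np.diff(sa / v) < 0).all()

    def test_nonpositive_readout_rejected(self):
        with pytest.raises(ValueError):
            dp.sphere_from_readout(np.array([1.0, 0.0]), "area")

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            dp.sphere_from_readout(np.array([1.0]), "mass")


class TestSizeRecords:
    def test_added_size_differences(self):
        sizes = pd.DataFrame(
            {
                "condition": ["a", "b"],
                "group": ["G", "G"],
                "size_g1": [1.0, 2.0],
                "size_g2m": [2.0, 2.0],
            }
        )
        rec, skipped = dp.size_records(sizes, convention="volume")
        assert skipped == []
        assert rec["delta_v"].iloc[0] == pytest.approx(1.0)
        assert rec["delta_v"].iloc[1] == pytest.approx(0.0)

    def test_phase_swap_antisymmetry(self):
        sizes = pd.DataFrame(
            {"condition": ["a"], "group": ["G"], "size_g1": [3.0], "size_g2m": [7.0]}
        )
        fwd, _ = dp.size_records(sizes, "volume")
        swapped = sizes.rename(columns={"size_g1": "size_g2m", "size_g2m": "size_g1"})
        rev, _ = dp.size_records(swapped, "volume")
        assert fwd["delta_v"].iloc[0] == pytest.approx(-rev["delta_v"].iloc[0])

    def test_missing_phase_skipped_with_record(self):
        sizes = pd.DataFrame(
            {
                "condition": ["a", "b"],
                "group": ["G", "G"],
                "size_g1": [1.0, np.nan],
                "size_g2m": [2.0, 2.0],
            }
        )
        rec, skipped = dp.size_records(sizes, "volume")
        assert len(rec) == 1
        assert skipped and "b" in skipped[0]


class TestFitSizeModel:
    def test_adder_slope_exactly_zero(self):
        births, divisions = dp.generate_size_population(
            dp.SizeSimConfig(model="adder", n=200, growth_param=2.0, seed=1)
        )
        fit = dp.fit_size_model(births, divisions - births)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.classification == "adder" and fit.qualifier == "perfect"

    def test_sizer_slope_exactly_minus_one(self):
        births, divisions = dp.generate_size_population(
            dp.SizeSimConfig(model="sizer", n=200, growth_param=8.0, seed=2)
        )
        fit = dp.fit_size_model(births, divisions - births)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.classification == "sizer" and fit.qualifier == "perfect"

    def test_timer_slope_exactly_plus_one(self):
        births, divisions = dp.generate_size_population(
            dp.SizeSimConfig(model="timer", n=200, growth_param=2.0, seed=3)
        )
        fit = dp.fit_size_model(births, divisions - births)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.classification == "timer" and fit.qualifier == "perfect"

    def test_zero_birth_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dp.fit_size_model([2.0, 2.0, 2.0], [1.0, 1.1, 0.9])

    @pytest.mark.parametrize(
        "model,param,true_slope",
        [("adder", 2.0, 0.0), ("sizer", 8.0, -1.0), ("timer", 2.0, 1.0)],
    )
    def test_noisy_slope_estimates_unbiased(self, model, param, true_slope):
        """Mean slope over 500 noisy simulations within +/- 0.05 of truth."""
        slopes = []
        for seed in range(500):
            births, divisions = dp.generate_size_population(
                dp.SizeSimConfig(
                    model=model, n=60, growth_param=param, noise_sd=0.4, seed=seed
                )
            )
            slopes.append(dp.fit_size_model(births, divisions - births).slope)
        assert np.mean(slopes) == pytest.approx(true_slope, abs=0.05)

    def test_qualifier_bands(self):
        x = np.linspace(1.0, 3.0, 30)
        fit = dp.fit_size_model(x, 0.2 * x + 1.0)  # slope 0.2 -> near adder
        assert (fit.classification, fit.qualifier) == ("adder", "near")
        fit2 = dp.fit_size_model(x, 0.6 * x)  # halfway -> moderate
        assert fit2.qualifier == "moderate"


class TestBirthDivisionCorrelation:
    def test_constant_offset_growth(self):
        g1 = np.array([1.0, 2.0, 3.0, 4.0])
        out = dp.birth_division_correlation(g1, g1 + 5.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["normal_doubling"]

    def test_constant_division_size(self):
        g1 = np.array([1.0, 2.0, 3.0])
        out = dp.birth_division_correlation(g1, np.full(3, 9.0))
        assert out["slope"] == pytest.approx(0.0)
        assert not out["normal_doubling"]

    def test_noisy_doubling_ci_contains_truth(self):
        rng = np.random.default_rng(6)
        slopes = []
        for _ in range(100):
            g1 = rng.uniform(1, 3, size=50)
            g2 = 2.0 * g1 + rng.normal(0, 0.2, size=50)
            slopes.append(dp.birth_division_correlation(g1, g2)["slope"])
        assert np.mean(slopes) == pytest.approx(2.0, abs=0.05)


class TestAddedSizeVariance:
    def test_identical_distributions_ratio_one(self):
        v = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        out = dp.added_size_variance({"A": v, "B": v.copy()})
        assert out["f_statistic"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_f_statistic_matches_definition(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(scale=2.0, size=25)
        out = dp.added_size_variance({"A": a, "B": b})
        assert out["f_statistic"].iloc[0] == pytest.approx(
            np.var(a, ddof=1) / np.var(b, ddof=1)
        )

    def test_sizer_added_variance_exceeds_adder(self):
        """With equal division noise, a sizer spreads added sizes by the
        full birth-size spread on top; an adder does not."""
        exceed = 0
        for seed in range(30):
            ba, da = dp.generate_size_population(
                dp.SizeSimConfig(model="adder", n=100, growth_param=2.0, noise_sd=0.2, seed=seed)
            )
            bs, ds_ = dp.generate_size_population(
                dp.SizeSimConfig(model="sizer", n=100, growth_param=4.0, noise_sd=0.2, seed=seed)
            )
            out = dp.added_size_variance({"sizer": ds_ - bs, "adder": da - ba})
            if out["f_statistic"].iloc[0] > 1:
                exceed += 1
        assert exceed == 30

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            dp.added_size_variance({"A": [1.0, 2.0, 3.0], "B": [1.0, 1.0, 1.0]})


class TestSavShift:
    def _records(self, ctrl_readout, treated_readout, group="ESC"):
        sizes = pd.DataFrame(
            {
                "condition": ["vehicle", "drug"],
                "group": [group, group],
                "size_g1": [ctrl_readout, treated_readout],
                "size_g2m": [ctrl_readout * 2, treated_readout * 2],
            }
        )
        rec, _ = dp.size_records(sizes, convention="diameter")
        return rec

    def test_radius_shrink_scales_sav_inversely(self):
        f = 0.8
        rec = self._records(10.0, 10.0 * f)
        out = dp.sav_shift(rec, ["drug"], ["vehicle"])
        assert out["ratio"].iloc[0] == pytest.approx(1.0 / f)

    def test_no_treatment_effect_zero_shift(self):
        rec = self._records(10.0, 10.0)
        out = dp.sav_shift(rec, ["drug"], ["vehicle"])
        assert out["shift"].iloc[0] == pytest.approx(0.0)

    def test_missing_arm_rejected(self):
        rec = self._records(10.0, 9.0)
        with pytest.raises(ValueError, match="arm"):
            dp.sav_shift(rec, ["absent_drug"], ["vehicle"])

    def test_group_restricted_shrinkage_detected_only_there(self):
        """A 10% G1 radius reduction planted in one group only is detected
        in that group and not in the unaffected one, across seeds."""
        rng = np.random.default_rng(12)
        n = 12
        for _ in range(20):
            rows = []
            for group, factor in (("ESC", 0.9), ("AFSC", 1.0)):
                for j in range(n):
                    base = rng.uniform(9.5, 10.5)
                    rows.append(
                        {"condition": f"ctl_{j}", "group": group,
                         "size_g1": base, "size_g2m": 2 * base}
                    )
                    treated = rng.uniform(9.5, 10.5) * factor
                    rows.append(
                        {"condition": f"trt_{j}", "group": group,
                         "size_g1": treated, "size_g2m": 2 * treated}
                    )
            rec, _ = dp.size_records(pd.DataFrame(rows), "diameter")
            out = dp.sav_shift(
                rec, [f"trt_{j}" for j in range(n)], [f"ctl_{j}" for j in range(n)]
            ).set_index("group")
            assert out.loc["ESC", "shift"] > 0.02 > out.loc["AFSC", "shift"]
            assert out.loc["ESC", "p"] < 0.01 < out.loc["AFSC", "p"]
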