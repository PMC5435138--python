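"""Threshold derivation, dose normalization and exposure assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pacudesat import phenotyping as ph

from oracles import naive_quantile


class TestQuantile:
    def test_uniform_grid(self):
        assert ph.quantile(range(101), 0.10) == pytest.approx(10.0)

    def test_boundaries(self):
        vals = [3.0, 1.0, 2.0]
        assert ph.quantile(vals, 0.0) == 1.0
        assert ph.quantile(vals, 1.0) == 3.0

    def test_matches_sort_based_oracle(self, rng):
        vals = rng.normal(0, 10, 10_000)
        for p in (0.025, 0.1, 0.25, 0.5, 0.75, 0.9, 0.99):
            assert ph.quantile(vals, p) == pytest.approx(naive_quantile(vals, p))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ph.quantile([], 0.5)


def _measures_frame(median=None, duration=None, nadir=None, frac=None, n=100):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "median_spo2": median if median is not None else rng.normal(97, 2, n),
            "minutes_below_level_per_hour": duration if duration is not None else rng.gamma(2, 2, n),
            "nadir_spo2": nadir if nadir is not None else rng.normal(90, 4, n),
            "o2_fraction": frac if frac is not None else rng.uniform(0, 1, n),
            "o2_duration_min": rng.uniform(0, 120, n),
        }
    )


class TestThresholds:
    def test_nadir_cut_on_uniform_grid(self):
        m = _measures_frame(nadir=np.arange(101.0), n=101)
        th = ph.derive_thresholds(m)
        assert th.nadir_cut == pytest.approx(10.0)

    def test_permutation_invariance(self, rng):
        m = _measures_frame()
        th1 = ph.derive_thresholds(m)
        th2 = ph.derive_thresholds(m.sample(frac=1.0, random_state=1))
        assert th1.median_cut == th2.median_cut
        assert th1.nadir_cut == th2.nadir_cut
        assert th1.o2_quartile_bounds == th2.o2_quartile_bounds

    def test_duplication_invariance(self):
        m = _measures_frame()
        th1 = ph.derive_thresholds(m)
        th2 = ph.derive_thresholds(pd.concat([m, m], ignore_index=True))
        assert th1.nadir_cut == pytest.approx(th2.nadir_cut)
        assert th1.duration_cut == pytest.approx(th2.duration_cut)

    def test_all_missing_measure_leaves_cut_absent(self):
        m = _measures_frame()
        m["nadir_spo2"] = np.nan
        th = ph.derive_thresholds(m)
        assert th.nadir_cut is None
        exp = ph.assign_exposures(m, th)
        assert exp["nadir_low"].isna().all()

    def test_tie_free_calibration_is_exact(self, rng):
        """On continuous tie-free data the cuts classify exactly 10% low
        medians, 10% low nadirs, 10% high durations and 25% per oxygen
        quartile (n divisible by 10/4 keeps interpolation exact)."""
        n = 1000
        m = _measures_frame(
            median=rng.normal(97, 2, n),
            duration=rng.gamma(2, 2, n),
            nadir=rng.normal(90, 4, n),
            frac=rng.uniform(0, 1, n),
            n=n,
        )
        th = ph.derive_thresholds(m)
        exp = ph.assign_exposures(m, th)
        assert exp["nadir_low"].sum() == n * 0.10
        assert exp["median_low"].sum() == n * 0.10
        assert exp["duration_high"].sum() == n * 0.10
        assert exp["o2_quartile"].value_counts().tolist() == [250, 250, 250, 250]


class TestIdealBodyWeight:
    def test_male_71_inches(self):
        assert ph.ideal_body_weight(180.34, "male") == pytest.approx(75.3)

    def test_female_base_case(self):
        assert ph.ideal_body_weight(152.4, "female") == pytest.approx(45.5)

    def test_sex_difference_constant(self):
        for h in (155.0, 170.0, 190.0):
            diff = ph.ideal_body_weight(h, "male") - ph.ideal_body_weight(h, "female")
            assert diff == pytest.approx(4.5)

    def test_out_of_range_height_rejected(self):
        with pytest.raises(ValueError):
            ph.ideal_body_weight(90.0, "male")


class TestDoseNormalization:
    def test_nmba_arithmetic(self):
        assert ph.normalize_nmba_dose(10, 70, 120) == pytest.approx(0.0714, abs=1e-4)

    def test_zero_dose(self):
        assert ph.normalize_nmba_dose(0, 70, 120) == 0.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            ph.normalize_nmba_dose(10, 0, 120)

    def test_morphine_equivalents_arithmetic(self):
        val = ph.morphine_equivalents([("morphine", 10.0)], 70, 60)
        assert val == pytest.approx(10 / 70, abs=1e-4)

    def test_empty_list_is_zero(self):
        assert ph.morphine_equivalents([], 70, 60) == 0.0

    def test_fentanyl_path_equals_morphine_path(self):
        # 0.1 mg fentanyl at factor 100 == 10 mg morphine at factor 1
        a = ph.morphine_equivalents([("fentanyl", 0.1)], 70, 60)
        b = ph.morphine_equivalents([("morphine", 10.0)], 70, 60)
        assert a == pytest.approx(b)

    def test_unknown_agent_named_in_error(self):
        with pytest.raises(ValueError, match="pethidine"):
            ph.morphine_equivalents([("pethidine", 50.0)], 70, 60)


class TestComplexityScore:
    def _records(self, rates, n_per=400, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for region, rate in rates.items():
            for _ in range(n_per):
                rows.append({"procedure_region": region, "early_prc": int(rng.random() < rate)})
        return pd.DataFrame(rows)

    def test_riskier_region_scores_higher(self):
        rec = self._records({"a": 0.01, "b": 0.05})
        score, high, cut = ph.surgical_complexity_score(rec)
        assert score[rec["procedure_region"] == "b"].mean() > score[rec["procedure_region"] == "a"].mean()

    def test_single_region_degenerate_warns(self):
        rec = self._records({"only": 0.02})
        with pytest.warns(UserWarning):
            score, high, cut = ph.surgical_complexity_score(rec)
        assert (~high).all()

    def test_label_permutation_equivalence(self):
        rec = self._records({"a": 0.01, "b": 0.05, "c": 0.10})
        score1, _, _ = ph.surgical_complexity_score(rec)
        swapped = rec.copy()
        swapped["procedure_region"] = swapped["procedure_region"].map({"a": "b", "b": "a", "c": "c"})
        score2, _, _ = ph.surgical_complexity_score(swapped)
        assert np.allclose(np.sort(score1), np.sort(score2), atol=1e-6)


class TestAssignExposures:
    def test_boundary_conventions(self):
        m = _measures_frame(n=4)
        m.loc[:, "nadir_spo2"] = [88.0, 89.0, 90.0, 85.0]
        m.loc[:, "minutes_below_level_per_hour"] = [18.0, 17.9, 20.0, 0.0]
        th = ph.PopulationThresholds(nadir_cut=89.0, duration_cut=18.0)
        exp = ph.assign_exposures(m, th)
        assert exp["nadir_low"].tolist() == [1.0, 0.0, 0.0, 1.0]   # strict <
        assert exp["duration_high"].tolist() == [1.0, 0.0, 1.0, 0.0]  # >= at the cut

    def test_o2_fraction_half_lands_in_third_category(self):
        assert ph.o2_quartile(0.50, (0.25, 0.50, 0.75)) == 3

    def test_o2_minute_bins(self):
        assert [ph.o2_minute_bin(x) for x in (10, 30, 45, 60, 75, 90, 100)] == [1, 2, 2, 3, 3, 4, 4]
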