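"""Dose integration, organ doses, percentage-difference statistics."""

import numpy as np
import pandas as pd
import pytest

from deepdose import (
    TimeDoseRateSeries,
    Volume,
    integrate_series,
    load_published_organ_errors,
    load_reference_masses,
    organ_doses,
    organ_percent_diff,
    paired_ttest_bonferroni,
    voxel_percent_diff,
)
from deepdose.volumes import DoseMap

VOXEL = (2.67, 2.67, 5.0)
SCHEDULE = (1.0, 4.0, 7.0, 10.0, 15.0, 30.0, 46.0, 62.0)


def rate_map(value, dims=(3, 3, 3)):
    return DoseMap(np.full(dims, float(value)), VOXEL, "Gy/s")


class TestIntegrateSeries:
    def test_constant_rate_gives_r_times_t(self):
        # huge lambda suppresses the tail; zero-head avoids the [0, t1) term
        series = TimeDoseRateSeries((0.001, 10.0), [rate_map(2.0), rate_map(2.0)],
                                    decay_constant_per_min=1e9)
        dose = integrate_series(series, head="zero")
        expected = 2.0 * (10.0 - 0.001) * 60.0  # Gy/s x minutes->seconds
        np.testing.assert_allclose(dose.data, expected, rtol=1e-6)

    def test_tail_term_is_rate_over_lambda(self):
        # R_last / lambda: 1 Gy/min at lambda = 0.01 /min -> 100 Gy
        r_gy_per_s = 1.0 / 60.0
        series = TimeDoseRateSeries((0.5, 1.0), [rate_map(0.0), rate_map(r_gy_per_s)],
                                    decay_constant_per_min=0.01)
        dose = integrate_series(series, head="zero")
        trapezoid = 0.5 * r_gy_per_s * 0.5 * 60.0
        np.testing.assert_allclose(dose.data, 100.0 + trapezoid, rtol=1e-9)

    def test_exponential_closed_form_within_3_percent(self):
        lam = np.log(2.0) / 67.7  # per min
        r0 = 5e-4
        maps = [rate_map(r0 * np.exp(-lam * t)) for t in SCHEDULE]
        series = TimeDoseRateSeries(SCHEDULE, maps, decay_constant_per_min=lam)
        dose = integrate_series(series)
        closed = r0 / (lam / 60.0)
        assert dose.data[0, 0, 0] == pytest.approx(closed, rel=0.03)

    def test_refinement_reduces_error_monotonically(self):
        lam = 0.02
        closed = 1.0 / (lam / 60.0)
        errs = []
        for n in (4, 8, 16, 32):
            times = np.linspace(1.0, 62.0, n)
            maps = [rate_map(np.exp(-lam * t)) for t in times]
            series = TimeDoseRateSeries(tuple(times), maps, decay_constant_per_min=lam)
            # compare only the trapezoid segment against its exact integral
            dose = integrate_series(series, head="zero").data[0, 0, 0]
            tail = np.exp(-lam * 62.0) / (lam / 60.0)
            exact_seg = (np.exp(-lam * 1.0) - np.exp(-lam * 62.0)) / (lam / 60.0)
            errs.append(abs((dose - tail) - exact_seg))
        assert errs == sorted(errs, reverse=True)

    def test_negative_rates_rejected(self):
        series = TimeDoseRateSeries((1.0, 2.0), [rate_map(-1.0), rate_map(1.0)])
        with pytest.raises(ValueError, match="negative"):
            integrate_series(series)

    def test_two_time_points_required(self):
        with pytest.raises(ValueError):
            TimeDoseRateSeries((1.0,), [rate_map(1.0)])


class TestOrganDoses:
    def _setup(self):
        dims = (4, 4, 4)
        labels = Volume(np.zeros(dims, dtype=np.int32), VOXEL, "label")
        labels.data[0, 0, :3] = 1
        density = Volume(np.ones(dims), VOXEL, "g/cm3")
        dose = DoseMap(np.ones(dims), VOXEL, "Gy")
        return dose, labels, density

    def test_uniform_dose_mean_is_value(self):
        dose, labels, density = self._setup()
        dose.data[:] = 2.5
        ref = pd.DataFrame({"organ": ["o"], "reference_mass_g": [1.0]})
        table = organ_doses(dose, labels, density, {1: "o"}, ref)
        assert table.loc[0, "mean_dose_gy"] == pytest.approx(2.5)

    def test_identity_correction_when_masses_match(self):
        dose, labels, density = self._setup()
        patient_mass = 3 * density.voxel_volume_ml
        ref = pd.DataFrame({"organ": ["o"], "reference_mass_g": [patient_mass]})
        table = organ_doses(dose, labels, density, {1: "o"}, ref)
        assert table.loc[0, "mass_corrected_dose_gy"] == pytest.approx(
            table.loc[0, "mean_dose_gy"])

    def test_hand_computed_weighted_mean(self):
        dose, labels, density = self._setup()
        density.data[0, 0, 0] = 1.0
        density.data[0, 0, 1] = 0.5
        density.data[0, 0, 2] = 2.0
        dose.data[0, 0, 0] = 1.0
        dose.data[0, 0, 1] = 2.0
        dose.data[0, 0, 2] = 3.0
        ref = pd.DataFrame({"organ": ["o"], "reference_mass_g": [1.0]})
        table = organ_doses(dose, labels, density, {1: "o"}, ref)
        expected = (1.0 * 1.0 + 2.0 * 0.5 + 3.0 * 2.0) / 3.5
        assert table.loc[0, "mean_dose_gy"] == pytest.approx(expected)

    def test_absent_organ_flagged(self):
        dose, labels, density = self._setup()
        table = organ_doses(dose, labels, density, {1: "o", 9: "ghost"})
        ghost = table.set_index("organ").loc["ghost"]
        assert not ghost["present"]

    def test_organ_energy_bounded_by_whole_body(self):
        dose, labels, density = self._setup()
        labels.data[1, 1, :2] = 2
        table = organ_doses(dose, labels, density, {1: "a", 2: "b"})
        organ_energy = (table["mean_dose_gy"] * table["organ_mass_g"]).sum()
        body_energy = (dose.data * density.data * density.voxel_volume_ml).sum()
        assert organ_energy <= body_energy + 1e-12

    def test_packaged_reference_masses_load(self):
        table = load_reference_masses()
        assert set(table.columns) == {"organ", "reference_mass_g"}
        assert (table["reference_mass_g"] > 0).all()
        assert "lungs" in set(table["organ"])


class TestVoxelPercentDiff:
    def test_identical_maps_zero(self):
        r = np.ones((3, 3, 3))
        assert voxel_percent_diff(r, r) == (0.0, 0.0)

    def test_ten_percent_uniform(self):
        r = np.ones((3, 3, 3))
        mean, std = voxel_percent_diff(1.1 * r, r)
        assert mean == pytest.approx(10.0)
        assert std == pytest.approx(0.0, abs=1e-9)

    def test_four_voxel_hand_case(self):
        ref = np.array([1.0, 2.0, 4.0, 5.0]).reshape(4, 1, 1)
        method = np.array([1.1, 1.8, 4.4, 5.0]).reshape(4, 1, 1)
        mean, _ = voxel_percent_diff(method, ref, floor=0.0)
        assert mean == pytest.approx((10 + 10 + 10 + 0) / 4)

    def test_asymmetric_in_reference(self):
        r = np.full((2, 2, 2), 2.0)
        m = np.full((2, 2, 2), 1.0)
        assert voxel_percent_diff(m, r)[0] != voxel_percent_diff(r, m)[0]

    def test_floor_excludes_near_zero_reference(self):
        ref = np.array([1.0, 1e-9]).reshape(2, 1, 1)
        method = np.array([1.0, 1.0]).reshape(2, 1, 1)
        mean, _ = voxel_percent_diff(method, ref)
        assert mean == pytest.approx(0.0)

    def test_all_below_floor_errors(self):
        ref = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            voxel_percent_diff(ref, ref)


class TestOrganPercentDiff:
    def _table(self, values):
        return pd.DataFrame({"organ": list("abc"),
                             "mass_corrected_dose_gy": values})

    def test_identical_tables_zero(self):
        t = self._table([1.0, 2.0, 3.0])
        out = organ_percent_diff(t, t)
        assert np.allclose(out[out["organ"].isin(list("abc"))]["mean_pct_diff"], 0.0)

    def test_two_subject_average(self):
        m = [self._table([1.02, 1.0, 1.0]), self._table([1.04, 1.0, 1.0])]
        r = [self._table([1.0, 1.0, 1.0])] * 2
        out = organ_percent_diff(m, r).set_index("organ")
        assert out.loc["a", "mean_pct_diff"] == pytest.approx(3.0)

    def test_missing_organ_errors(self):
        m = self._table([1.0, 2.0, 3.0])
        r = m.copy()
        r.loc[0, "organ"] = "zzz"
        with pytest.raises(ValueError, match="organ sets"):
            organ_percent_diff(m, r)

    def test_published_benchmark_row_averages(self):
        # cross-organ averages of the published per-organ values reproduce the
        # published row averages at printed precision (voxel-kernel and CNN rows)
        pub = load_published_organ_errors()
        no_panc = pub[pub["organ"] != "pancreas"]
        assert round(no_panc["vsv_mean"].mean(), 2) == 9.43
        assert round(no_panc["cnn_mean"].mean(), 2) == 1.07
        assert round(pub["vsv_mean"].mean(), 2) == 8.47
        assert round(pub["cnn_mean"].mean(), 2) == 1.09


class TestPairedTTest:
    def test_identical_samples_degenerate(self):
        res = paired_ttest_bonferroni([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.status == "degenerate"
        assert not res.significant

    def test_closed_form_t_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_ttest_bonferroni(a + np.array([1.0, 2.0, 3.0, 4.0]), a)
        # differences {1,2,3,4}: t = 2.5 / (1.29099/2)
        assert res.t == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2), rel=1e-6)

    def test_bonferroni_threshold(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res1 = paired_ttest_bonferroni(a + np.array([1.0, 2.0, 3.0, 4.0]), a, m_tests=1)
        res8 = paired_ttest_bonferroni(a + np.array([1.0, 2.0, 3.0, 4.0]), a, m_tests=8)
        assert res8.alpha_adjusted == pytest.approx(0.05 / 8)
        # raw p ~= 0.0305: significant alone, not after correction
        assert res1.significant and not res8.significant

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_bonferroni([1.0, 2.0], [1.0])
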