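import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from gatedlung import (
    LesionSpec,
    LungMeasurement,
    PhantomSpec,
    compute_frc,
    compute_vt,
    ct_histogram,
    generate_phantom,
    group_percent_change,
    longitudinal_change,
    lung_function,
    measure_lung,
    refs_from_image,
    rescale_to_hu,
)
from .conftest import hu_image


def meas(phase, volume_ml, mean_ct_hu, n=1000):
    return LungMeasurement(phase=phase, volume_ml=volume_ml, mean_ct_hu=mean_ct_hu,
                           voxel_count=n)


class TestMeasureLung:
    def test_volume_from_voxel_count(self):
        vals = np.full((10, 10, 10), -700.0)
        img = hu_image(vals, phase="expiration")
        m = measure_lung(img, np.ones(vals.shape, bool))
        assert m.voxel_count == 1000
        assert m.volume_ml == pytest.approx(1000 * 0.075**3 / 1000.0)  # 4.21875e-4
        assert m.mean_ct_hu == -700.0

    def test_bimodal_mean(self):
        vals = np.full((2, 2, 2), -600.0)
        vals[1] = -800.0
        m = measure_lung(hu_image(vals), np.ones(vals.shape, bool))
        assert m.mean_ct_hu == -700.0

    def test_empty_mask_rejected(self):
        img = hu_image(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            measure_lung(img, np.zeros((4, 4, 4), bool))

    def test_misaligned_mask_rejected(self):
        img = hu_image(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="aligned"):
            measure_lung(img, np.ones((5, 4, 4), bool))


class TestFRC:
    def test_pure_air_limit(self):
        assert compute_frc(meas("expiration", 0.5, -1000.0)) == pytest.approx(0.5)

    def test_water_limit(self):
        assert compute_frc(meas("expiration", 0.5, 0.0)) == 0.0

    def test_mixture(self):
        assert compute_frc(meas("expiration", 0.5, -600.0)) == pytest.approx(0.30)

    def test_zero_ct_air_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_frc(meas("expiration", 0.5, -600.0), ct_air_hu=0.0)

    def test_wrong_phase_rejected(self):
        with pytest.raises(ValueError, match="end-expiration"):
            compute_frc(meas("inspiration", 0.5, -600.0))

    def test_positive_mean_ct_warns_unclamped(self):
        with pytest.warns(UserWarning, match="positive"):
            frc = compute_frc(meas("expiration", 0.5, 100.0))
        assert frc == pytest.approx(-0.05)  # raw value, not clamped


class TestVT:
    def test_identical_phases_give_zero(self):
        frc = compute_frc(meas("expiration", 0.5, -600.0))
        assert compute_vt(meas("inspiration", 0.5, -600.0), frc) == pytest.approx(0.0)

    def test_mixture(self):
        vt = compute_vt(meas("inspiration", 0.7, -650.0), frc_ml=0.30)
        assert vt == pytest.approx(0.155)

    def test_negative_vt_warns(self):
        with pytest.warns(UserWarning, match="misassignment"):
            vt = compute_vt(meas("inspiration", 0.4, -500.0), frc_ml=0.30)
        assert vt == pytest.approx(-0.10)

    def test_lung_function_flags(self):
        fun = lung_function(meas("expiration", 0.5, -600.0),
                            meas("inspiration", 0.4, -500.0))
        assert fun.negative_vt
        assert fun.frc_ml == pytest.approx(0.30)

    @settings(max_examples=60, derandomize=True)
    @given(
        v_exp=hst.floats(0.01, 1.0),
        v_extra=hst.floats(0.0, 0.5),
        ct_exp=hst.floats(-1000.0, 0.0),
        ct_insp=hst.floats(-1000.0, 0.0),
    )
    def test_bounds_when_hu_in_air_water_range(self, v_exp, v_extra, ct_exp, ct_insp):
        """0 <= FRC <= V_exp and FRC + VT <= V_insp for HU in [-1000, 0]."""
        v_insp = v_exp + v_extra
        frc = compute_frc(meas("expiration", v_exp, ct_exp))
        vt = compute_vt(meas("inspiration", v_insp, ct_insp), frc)
        assert 0.0 <= frc <= v_exp + 1e-12
        assert frc + vt <= v_insp + 1e-12


class TestHistogram:
    def test_uniform_single_bin(self):
        vals = np.full((5, 5, 5), -700.0)
        h = ct_histogram(hu_image(vals), np.ones(vals.shape, bool))
        assert h.counts.sum() == 125
        assert h.counts.max() == 125

    def test_normalized_sums_to_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-1000, 200, (6, 6, 6))
        h = ct_histogram(hu_image(vals), np.ones(vals.shape, bool), normalize=True)
        assert h.counts.sum() == pytest.approx(1.0)

    @settings(max_examples=30, derandomize=True)
    @given(
        vals=hnp.arrays(
            float, (4, 4, 4),
            elements=hst.floats(-2000, 2000, allow_nan=False),
        )
    )
    def test_conservation_with_clipping(self, vals):
        """Out-of-range values land in end bins; counts sum to voxel count."""
        h = ct_histogram(hu_image(vals), np.ones(vals.shape, bool))
        assert h.counts.sum() == 64
        assert np.all(np.diff(h.bin_edges_hu) > 0)

    def test_bad_bin_width_rejected(self):
        vals = np.zeros((4, 4, 4))
        with pytest.raises(ValueError, match="positive"):
            ct_histogram(hu_image(vals), np.ones(vals.shape, bool), bin_width_hu=0)

    def test_fibrosis_shifts_histogram_mean_toward_zero(self):
        """The lesion's air-fraction reduction appears as the expected
        density shift of the masked CT-number distribution."""
        clean_spec = PhantomSpec(grid_shape=(64, 64, 64))
        lesion = LesionSpec("fibrosis", clean_spec.lung_centers_mm[0], 0.8, 0.7)
        sick_spec = PhantomSpec(grid_shape=(64, 64, 64), lesions=(lesion,))
        hists = {}
        means = {}
        for name, spec in (("clean", clean_spec), ("sick", sick_spec)):
            exp, _, truth = generate_phantom(spec)
            hu = rescale_to_hu(exp, refs_from_image(exp))
            hists[name] = ct_histogram(hu, truth.lung_mask_true)
            means[name] = -1000.0 * float(
                truth.air_fraction_expiration[truth.lung_mask_true].mean()
            )
        shift_hist = hists["sick"].mean_hu - hists["clean"].mean_hu
        shift_true = means["sick"] - means["clean"]
        assert shift_hist > 0  # toward 0 HU
        assert shift_hist == pytest.approx(shift_true, abs=25.0)  # within a bin


def _study(rows):
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "week", "phase", "volume_ml",
                 "mean_ct_hu", "frc_ml", "vt_ml", "leak_flag"],
    )


def _animal_rows(aid, group, week, frc, vt, v_exp=0.5, v_insp=0.7):
    return [
        (aid, group, week, "expiration", v_exp, -600.0, frc, vt, False),
        (aid, group, week, "inspiration", v_insp, -650.0, frc, vt, False),
    ]


class TestLongitudinal:
    def test_identical_weeks_give_zero_deltas(self):
        rows = _animal_rows("m1", "g", 12, 0.30, 0.15) + _animal_rows(
            "m1", "g", 24, 0.30, 0.15
        )
        d = longitudinal_change(_study(rows))
        assert float(d["delta_frc_ml"].iloc[0]) == 0.0
        assert float(d["delta_vt_ml"].iloc[0]) == 0.0

    def test_halved_frc(self):
        rows = _animal_rows("m1", "g", 12, 0.30, 0.15) + _animal_rows(
            "m1", "g", 24, 0.15, 0.15
        )
        d = longitudinal_change(_study(rows))
        assert float(d["delta_frc_ml"].iloc[0]) == pytest.approx(-0.15)
        assert float(d["pct_change_frc_ml"].iloc[0]) == pytest.approx(-50.0)

    def test_animal_missing_baseline_excluded(self, caplog):
        rows = (
            _animal_rows("m1", "g", 12, 0.30, 0.15)
            + _animal_rows("m1", "g", 24, 0.25, 0.15)
            + _animal_rows("m2", "g", 24, 0.40, 0.2)  # no week 12
        )
        d = longitudinal_change(_study(rows))
        assert list(d["animal_id"]) == ["m1"]

    def test_no_complete_animal_rejected(self):
        rows = _animal_rows("m1", "g", 24, 0.30, 0.15)
        with pytest.raises(ValueError, match="both week"):
            longitudinal_change(_study(rows))

    def test_endpoint_is_per_animal_latest_week(self):
        rows = (
            _animal_rows("m1", "g", 12, 0.4, 0.2)
            + _animal_rows("m1", "g", 18, 0.2, 0.2)
            + _animal_rows("m2", "g", 12, 0.4, 0.2)
            + _animal_rows("m2", "g", 24, 0.3, 0.2)
        )
        d = longitudinal_change(_study(rows))
        by = d.set_index("animal_id")
        assert by.loc["m1", "week_b"] == 18
        assert by.loc["m2", "week_b"] == 24


class TestGroupPercentChange:
    def test_halved_group_mean(self):
        rows = []
        for i, (a, b) in enumerate([(0.38, 0.19), (0.42, 0.21)]):
            rows += _animal_rows(f"m{i}", "t", 12, a, 0.1)
            rows += _animal_rows(f"m{i}", "t", 24, b, 0.1)
        for i, v in enumerate([0.30, 0.40]):
            rows += _animal_rows(f"c{i}", "ctl", 12, v, 0.1)
            rows += _animal_rows(f"c{i}", "ctl", 24, v, 0.1)
        out = group_percent_change(_study(rows), "frc_ml")
        by = out.set_index("group")
        assert by.loc["t", "pct_change_of_mean"] == pytest.approx(-50.0)
        assert by.loc["ctl", "pct_change_of_mean"] == pytest.approx(0.0)
        assert by.loc["t", "n"] == 2

    def test_unknown_metric_rejected(self):
        rows = _animal_rows("m1", "g", 12, 0.3, 0.1) + _animal_rows("m1", "g", 24, 0.3, 0.1)
        with pytest.raises(ValueError, match="metric"):
            group_percent_change(_study(rows), "nope")


class TestEquationExactnessOnPhantom:
    def test_frc_exact_with_perfect_segmentation(self, small_phantom):
        """With the truth mask and exact calibration, the FRC formula
        reproduces the generator's air content to float precision."""
        exp, insp, truth = small_phantom
        for img, true_air in (
            (exp, truth.air_volume_expiration_ml),
            (insp, truth.air_volume_inspiration_ml),
        ):
            hu = rescale_to_hu(img, refs_from_image(img))
            m = measure_lung(hu, truth.lung_mask_true)
            est = m.volume_ml * m.mean_ct_hu / -1000.0
            assert est == pytest.approx(true_air, rel=1e-9)
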