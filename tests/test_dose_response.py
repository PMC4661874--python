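"""Normalization, curve building and IC50 estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from combindex import (
    DoseEffectCurve,
    HillGroundTruth,
    PlateDesign,
    WellRecord,
    aggregate_experiments,
    build_curve,
    ic50_4pl,
    ic50_interpolate,
    normalize_viability,
    simulate_plate,
)
from combindex.dose_response import make_condition
from combindex.errors import DataError, InsufficientDataError


def _well(exp="E1", dose=1.0, rep=1, viability=1.0, agent="A"):
    return WellRecord(
        experiment_id=exp, varied_agent=agent, dose=dose, dose_unit="ng/mL",
        replicate=rep, viability=viability,
    )


def _curve(doses, fa, cond=None):
    cond = cond or make_condition("A", "ng/mL")
    return DoseEffectCurve(
        condition=cond, doses=np.asarray(doses), fa=np.asarray(fa),
        n_replicates=np.full(len(doses), 3),
    )


class TestNormalizeViability:
    def test_divides_by_in_experiment_control_mean(self):
        raws = [_well(viability=0.4), _well(viability=0.6, rep=2)]
        controls = [_well(dose=0.0, viability=0.5)]
        out = normalize_viability(raws, controls)
        assert [w.viability for w in out] == pytest.approx([0.8, 1.2])

    def test_reading_equal_to_control_gives_unity(self):
        out = normalize_viability(
            [_well(viability=0.5)], [_well(dose=0.0, viability=0.5)]
        )
        assert out[0].viability == pytest.approx(1.0)

    def test_zero_control_mean_is_a_data_error(self):
        with pytest.raises(DataError):
            normalize_viability([_well()], [_well(dose=0.0, viability=0.0)])

    def test_missing_control_experiment_is_a_data_error(self):
        with pytest.raises(DataError):
            normalize_viability([_well(exp="E2")], [_well(exp="E1", dose=0.0)])


class TestBuildCurve:
    def test_fa_is_complement_of_mean_viability(self):
        wells = [_well(dose=10.0, rep=r, viability=v) for r, v in enumerate((0.9, 0.8, 0.7))]
        wells += [_well(dose=100.0, viability=0.5)]
        curve = build_curve(wells, wells[0].condition)
        assert curve.fa[0] == pytest.approx(0.2)
        assert list(curve.n_replicates) == [3, 1]

    def test_doses_come_out_sorted(self):
        wells = [_well(dose=d) for d in (100.0, 1.0, 10.0)]
        curve = build_curve(wells, wells[0].condition)
        assert list(curve.doses) == [1.0, 10.0, 100.0]

    def test_single_dose_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            build_curve([_well(dose=1.0)], _well().condition)

    def test_negative_fa_is_flagged_not_fatal(self):
        curve = _curve([1.0, 10.0], [-0.1, 0.6])
        assert "negative_fa" in curve.flags


class TestIC50Interpolate:
    def test_symmetric_bracket_gives_log_midpoint(self):
        est = ic50_interpolate(_curve([10.0, 100.0], [0.4, 0.6]))
        assert est.status == "ok"
        assert est.value == pytest.approx(10**1.5)

    def test_exact_crossing_returns_that_dose(self):
        est = ic50_interpolate(_curve([10.0, 50.0, 100.0], [0.3, 0.5, 0.7]))
        assert est.value == pytest.approx(50.0)

    def test_never_reaching_half_is_above_range(self):
        est = ic50_interpolate(_curve([1.0, 10.0, 100.0], [0.1, 0.3, 0.45]))
        assert est.status == "above_range"
        assert est.value is None

    def test_starting_above_half_is_below_range_with_min_dose(self):
        est = ic50_interpolate(_curve([1.0, 10.0], [0.7, 0.9]))
        assert est.status == "below_range"
        assert est.value == 1.0
        assert "ic50_below_tested_range" in est.flags

    def test_multiple_crossings_use_first_and_flag(self):
        est = ic50_interpolate(
            _curve([1.0, 10.0, 100.0, 1000.0], [0.4, 0.6, 0.4, 0.7])
        )
        assert "multiple_crossings" in est.flags
        assert est.value == pytest.approx(10**0.5)  # between 1 and 10

    @given(shift=st.floats(min_value=0.001, max_value=0.3))
    def test_positive_fa_shift_never_increases_ic50(self, shift):
        doses = [1.0, 10.0, 100.0, 1000.0]
        fa = np.array([0.1, 0.35, 0.6, 0.8])
        base = ic50_interpolate(_curve(doses, fa)).value
        shifted = ic50_interpolate(_curve(doses, np.minimum(fa + shift, 1.0))).value
        assert shifted <= base + 1e-12

    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    def test_normalization_scale_invariance(self, scale):
        # rescaling all raw readings and controls by the same factor leaves
        # the interpolated IC50 unchanged
        raw_v = [0.9, 0.7, 0.45, 0.2]
        doses = [1.0, 10.0, 100.0, 1000.0]
        def estimate(factor):
            raws = [_well(dose=d, viability=v * factor) for d, v in zip(doses, raw_v)]
            controls = [_well(dose=0.0, viability=1.0 * factor)]
            wells = normalize_viability(raws, controls)
            return ic50_interpolate(build_curve(wells, wells[0].condition)).value
        assert estimate(scale) == pytest.approx(estimate(1.0), rel=1e-9)


class TestIC504PL:
    def test_recovers_noise_free_hill_within_one_percent(self):
        truth = HillGroundTruth("A", ic50=100.0, hill_slope=1.0)
        doses = np.logspace(0, 4, 9)
        fa = truth.inhibition(doses)
        est = ic50_4pl(_curve(doses, fa))
        assert est.method == "four_parameter_logistic"
        assert est.value == pytest.approx(100.0, rel=0.01)

    def test_constant_fa_falls_back_to_interpolation(self):
        est = ic50_4pl(_curve([1.0, 10.0, 100.0, 1000.0], [0.3, 0.3, 0.3, 0.3]))
        assert est.method == "interpolation"
        assert any(f.startswith("4pl_nonconvergence") for f in est.flags)

    def test_requires_four_doses(self):
        with pytest.raises(InsufficientDataError):
            ic50_4pl(_curve([1.0, 10.0, 100.0], [0.2, 0.5, 0.8]))

    def test_crossing_curve_yields_in_range_value(self):
        est = ic50_4pl(_curve([1.0, 10.0, 100.0, 1000.0], [0.05, 0.3, 0.7, 0.95]))
        assert est.status == "ok"
        assert 1.0 <= est.value <= 1000.0

    @given(
        log_ic50=st.floats(min_value=1.2, max_value=2.8),
        slope=st.floats(min_value=0.7, max_value=2.5),
    )
    def test_agrees_with_interpolation_on_noise_free_hill(self, log_ic50, slope):
        # four doses per decade bracketing the IC50 with >= 2 points per
        # side: at this grid density log-linear interpolation and the 4PL
        # fit agree within 2% even for steep slopes
        truth = HillGroundTruth("A", ic50=10**log_ic50, hill_slope=slope)
        doses = np.logspace(0, 4, 17)
        fa = truth.inhibition(doses)
        interp = ic50_interpolate(_curve(doses, fa)).value
        fitted = ic50_4pl(_curve(doses, fa)).value
        assert fitted == pytest.approx(interp, rel=0.02)


class TestAggregateExperiments:
    def _est(self, value, status="ok"):
        cond = make_condition("A", "ng/mL")
        from combindex.dose_response import IC50Estimate
        return IC50Estimate(cond, value, "interpolation", status)

    def test_mean_and_sample_sd(self):
        agg = aggregate_experiments([self._est(v) for v in (20.0, 22.0, 24.0)])
        assert agg.mean == pytest.approx(22.0)
        assert agg.sd == pytest.approx(2.0)
        assert agg.n_used == 3

    def test_single_experiment_has_no_sd(self):
        agg = aggregate_experiments([self._est(15.0)])
        assert agg.mean == 15.0
        assert agg.sd is None

    def test_out_of_range_experiments_are_masked_and_counted(self):
        ests = [self._est(v) for v in (14.0, 16.0, 18.0)]
        ests.append(self._est(None, status="above_range"))
        agg = aggregate_experiments(ests)
        assert agg.mean == pytest.approx(16.0)
        assert agg.n_used == 3
        assert agg.n_excluded == 1

    def test_all_out_of_range_propagates_status(self):
        agg = aggregate_experiments(
            [self._est(None, "above_range"), self._est(None, "above_range")]
        )
        assert agg.status == "above_range"
        assert agg.mean is None

    def test_mixed_conditions_rejected(self):
        from combindex.dose_response import IC50Estimate
        a = self._est(1.0)
        b = IC50Estimate(make_condition("B", "nM"), 2.0, "interpolation", "ok")
        with pytest.raises(DataError):
            aggregate_experiments([a, b])


def test_noise_free_plate_roundtrip_recovers_ground_truth():
    # parameter-recovery oracle: simulate -> curve -> 4PL, no noise
    truth = HillGroundTruth("A", ic50=250.0, hill_slope=1.3)
    design = PlateDesign(
        "A", tuple(np.logspace(0, 4, 9)), replicates_per_dose=3,
        n_experiments=2, noise_cv=0.0, seed=0,
    )
    wells = simulate_plate([truth], design)
    curve = build_curve(wells, wells[0].condition)
    assert ic50_4pl(curve).value == pytest.approx(250.0, rel=0.01)
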