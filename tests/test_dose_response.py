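"""Curve fitting, percent effects, validity gates and unit conversion."""

import math

import numpy as np
import pytest

from ecotoxrisk.datasets import Endpoint, ExposureDesign
from ecotoxrisk.dose_response import (
    CannotEvaluateError,
    InvalidControlError,
    MonotonicityError,
    check_validity,
    ec50_to_analyte_concentration,
    fit_log_logistic,
    log_logistic,
    percent_effect,
    read_curves_json,
    write_curves_json,
)
from ecotoxrisk.synthetic_data import (
    GroundTruth,
    make_default_design,
    simulate_dose_response,
)
from ecotoxrisk.units import AnalyteConcentration, UnitError


class TestPercentEffect:
    def test_growth_equal_to_control_is_zero_effect(self, continuous_dataset_factory):
        ds = continuous_dataset_factory([0.1, 1.0], [[2.0, 2.0], [2.0, 2.0]],
                                        controls=[2.0, 2.0, 2.0])
        eff = percent_effect(ds)
        np.testing.assert_allclose(eff.mean_effect, [0.0, 0.0], atol=1e-12)

    def test_quarter_growth_is_75_percent_inhibition(
        self, continuous_dataset_factory
    ):
        ds = continuous_dataset_factory([0.1, 1.0], [[2.0], [0.5]],
                                        controls=[2.0, 2.0])
        eff = percent_effect(ds)
        assert eff.mean_effect[1] == pytest.approx(75.0)

    def test_all_daphnids_immobilised_is_100_percent(self, quantal_dataset_factory):
        ds = quantal_dataset_factory([0.1, 1.0], [[0, 0, 0], [5, 5, 5]],
                                     control_counts=[0, 0, 0])
        eff = percent_effect(ds)
        assert eff.mean_effect[1] == pytest.approx(100.0)

    def test_stimulation_reported_raw_but_clipped_copy_floors_at_zero(
        self, continuous_dataset_factory
    ):
        ds = continuous_dataset_factory([0.1, 1.0], [[2.4], [1.0]],
                                        controls=[2.0, 2.0])
        eff = percent_effect(ds)
        assert eff.mean_effect[0] == pytest.approx(-20.0)
        assert eff.mean_effect_clipped[0] == 0.0

    def test_nonpositive_control_raises(self, continuous_dataset_factory):
        ds = continuous_dataset_factory([0.1, 1.0], [[1.0], [1.0]],
                                        controls=[0.0, 0.0])
        with pytest.raises(InvalidControlError):
            percent_effect(ds)


class TestValidityGates:
    @pytest.mark.parametrize("growth, expected", [(15.0, True), (14.9, False)])
    def test_algal_fold_growth_threshold_is_16(
        self, continuous_dataset_factory, growth, expected
    ):
        # t0 = 1.0, so fold growth = 1 + control growth increment
        ds = continuous_dataset_factory(
            [0.1, 1.0], [[1.0], [1.0]], controls=[growth] * 3, control_t0=1.0
        )
        report = check_validity(ds)
        assert report.passed is expected
        assert report.threshold == 16.0

    def test_algae_without_time0_cannot_be_evaluated(
        self, continuous_dataset_factory
    ):
        ds = continuous_dataset_factory([0.1, 1.0], [[1.0], [1.0]],
                                        controls=[20.0] * 3)
        with pytest.raises(CannotEvaluateError):
            check_validity(ds)

    @pytest.mark.parametrize("area, expected", [(10.0, True), (9.8, False)])
    def test_duckweed_mean_frond_growth_threshold_is_10_mm2(
        self, continuous_dataset_factory, area, expected
    ):
        ds = continuous_dataset_factory(
            [0.1, 1.0], [[5.0], [5.0]], controls=[area] * 8,
            endpoint=Endpoint.frond_area_growth,
        )
        assert check_validity(ds).passed is expected

    @pytest.mark.parametrize(
        "control_counts, expected",
        [([1, 0, 0], True),    # 1/15 = 6.7 %
         ([1, 1, 0], False),   # 2/15 = 13.3 %
         ([1, 1, 1, 0, 0, 0], True)],  # 3/30 = 10 % boundary passes
    )
    def test_daphnid_control_immobilisation_at_most_10_percent(
        self, quantal_dataset_factory, control_counts, expected
    ):
        ds = quantal_dataset_factory([0.1, 1.0], [[0, 0, 0], [5, 5, 5]],
                                     control_counts=control_counts)
        assert check_validity(ds).passed is expected


class TestFitLogLogistic:
    @pytest.mark.parametrize("ec50, hill", [(1.0, 2.0), (0.3, 1.0), (12.0, 3.5)])
    def test_noiseless_recovery_continuous(self, ec50, hill):
        design = make_default_design(Endpoint.algal_growth, 72)
        truth = GroundTruth(ec50_true=ec50, hill_slope=hill, noise_cv=0.0, seed=1)
        ds = simulate_dose_response(design, truth)
        curve = fit_log_logistic(ds, n_bootstrap=0)
        assert curve.converged
        assert curve.ec50 == pytest.approx(ec50, rel=1e-6)
        assert curve.hill_slope == pytest.approx(hill, rel=1e-6)
        assert curve.effect_at(curve.ec50) == pytest.approx(50.0, abs=1e-9)

    def test_symmetric_bracketing_data_gives_geometric_midpoint(
        self, continuous_dataset_factory
    ):
        # effects 20/50/80 % at 0.1/1/10 are symmetric in log-concentration:
        # the exact solution is EC50 = 1 (geometric midpoint), h = log(4)/log(10)
        ds = continuous_dataset_factory(
            [0.1, 1.0, 10.0], [[0.8], [0.5], [0.2]], controls=[1.0, 1.0]
        )
        curve = fit_log_logistic(ds, n_bootstrap=0)
        assert curve.ec50 == pytest.approx(1.0, rel=1e-6)
        assert curve.hill_slope == pytest.approx(math.log(4) / math.log(10),
                                                 rel=1e-6)

    def test_scale_equivariance(self):
        base = GroundTruth(ec50_true=1.0, hill_slope=2.0, noise_cv=0.0, seed=1)
        for k in (1e-3, 1e-1, 1.0, 1e1, 1e3):
            design = ExposureDesign(
                levels=tuple(k * np.array([0.01, 0.1, 1.0, 10.0, 100.0])),
                n_replicates=3, organisms_per_replicate=1,
                endpoint=Endpoint.algal_growth, duration_h=72,
            )
            truth = GroundTruth(ec50_true=k, hill_slope=2.0, noise_cv=0.0, seed=1)
            ds = simulate_dose_response(design, truth)
            curve = fit_log_logistic(ds, n_bootstrap=0)
            assert curve.ec50 == pytest.approx(k * base.ec50_true, rel=1e-6)

    def test_noiseless_quantal_recovery(self, quantal_dataset_factory):
        design = make_default_design(Endpoint.immobilisation, 48)
        truth = GroundTruth(ec50_true=1.0, hill_slope=2.0, seed=9)
        ds = simulate_dose_response(design, truth)
        curve = fit_log_logistic(ds, n_bootstrap=0)
        assert curve.converged
        assert 0.2 < curve.ec50 < 5.0  # ML estimate from 15 animals/level

    def test_decreasing_effects_refused(self, continuous_dataset_factory):
        ds = continuous_dataset_factory(
            [0.1, 1.0, 10.0], [[0.2], [0.5], [0.9]], controls=[1.0, 1.0]
        )
        with pytest.raises(MonotonicityError):
            fit_log_logistic(ds, n_bootstrap=0)

    def test_unbracketed_effects_flagged_extrapolated(
        self, continuous_dataset_factory
    ):
        ds = continuous_dataset_factory(
            [0.1, 1.0, 10.0], [[0.99], [0.97], [0.9]], controls=[1.0, 1.0]
        )
        curve = fit_log_logistic(ds, n_bootstrap=0)
        assert curve.extrapolated

    def test_bootstrap_ci_is_seeded_and_brackets_estimate(self):
        design = make_default_design(Endpoint.algal_growth, 72)
        truth = GroundTruth(ec50_true=1.0, hill_slope=2.0, noise_cv=0.1, seed=4)
        ds = simulate_dose_response(design, truth)
        a = fit_log_logistic(ds, n_bootstrap=100, seed=42)
        b = fit_log_logistic(ds, n_bootstrap=100, seed=42)
        assert a.ec50_ci95 == b.ec50_ci95
        lo, hi = a.ec50_ci95
        assert lo <= a.ec50 <= hi

    def test_ci_narrows_with_replication(self):
        truth = GroundTruth(ec50_true=1.0, hill_slope=2.0, noise_cv=0.15, seed=0)
        widths = {}
        for n_rep in (3, 24):
            design = ExposureDesign(
                levels=(0.01, 0.1, 1.0, 10.0, 100.0), n_replicates=n_rep,
                organisms_per_replicate=1,
                endpoint=Endpoint.algal_growth, duration_h=72,
            )
            ratios = []
            for seed in range(8):
                t = GroundTruth(ec50_true=1.0, hill_slope=2.0, noise_cv=0.15,
                                seed=100 + seed)
                ds = simulate_dose_response(design, t)
                cv = fit_log_logistic(ds, n_bootstrap=120, seed=seed)
                lo, hi = cv.ec50_ci95
                ratios.append(hi / lo)
            widths[n_rep] = np.median(ratios)
        assert widths[24] < widths[3]


class TestUnitConversion:
    def test_full_strength_is_identity(self):
        stock = AnalyteConcentration("SAN1", "Ag", "na", 950.0, "ug_per_L")
        value, unit = ec50_to_analyte_concentration(100.0, stock)
        assert value == pytest.approx(950.0)
        assert unit == "ug_per_L"

    def test_ten_percent_dilution(self):
        stock = AnalyteConcentration("SUN1", "Ti", "light", 6.99, "mg_per_L")
        value, unit = ec50_to_analyte_concentration(10.0, stock)
        assert value == pytest.approx(0.699)
        assert unit == "mg_per_L"

    def test_fractional_dilution_against_direct_multiplication(self):
        # 0.1384 % of a 950 µg/L stock: oracle is plain multiplication
        stock = AnalyteConcentration("SAN1", "Ag", "na", 950.0, "ug_per_L")
        value, _ = ec50_to_analyte_concentration(0.1384, stock)
        assert value == pytest.approx(0.001384 * 950.0, rel=1e-12)
        assert value == pytest.approx(1.315, abs=5e-4)

    def test_out_of_range_percent_rejected(self):
        stock = AnalyteConcentration("SAN1", "Ag", "na", 950.0, "ug_per_L")
        for bad in (0.0, -1.0, 101.0):
            with pytest.raises(ValueError):
                ec50_to_analyte_concentration(bad, stock)

    def test_missing_unit_rejected(self):
        with pytest.raises(UnitError):
            AnalyteConcentration("SAN1", "Ag", "na", 950.0, "parts")


def test_curves_json_roundtrip(tmp_path):
    design = make_default_design(Endpoint.algal_growth, 72)
    truth = GroundTruth(ec50_true=1.0, hill_slope=2.0, noise_cv=0.0, seed=1)
    ds = simulate_dose_response(design, truth, label="rt")
    curve = fit_log_logistic(ds, n_bootstrap=50, seed=1)
    path = tmp_path / "curves.json"
    write_curves_json([curve], path)
    back = read_curves_json(path)[0]
    assert back.ec50 == pytest.approx(curve.ec50)
    assert back.ec50_ci95 == pytest.approx(curve.ec50_ci95)
    assert back.label == "rt"
    assert back.organism == curve.organism
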