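"""Monte Carlo propagation: reproducibility, trimming, both error schemes."""

import numpy as np
import pytest

from streamco2 import (
    FluxEnsemble,
    PerturbationSpec,
    apply_filters,
    run_ensemble,
    total_dependent,
    total_independent,
    trim_outliers,
)
from streamco2.co2model import DEFAULT_CO2_MODEL
from streamco2.pipeline import compute_fluxes
from conftest import make_segment_row, make_segments


def zero_noise_spec(n_iter=50):
    return PerturbationSpec(
        co2_residual_sd=0.0,
        k600_residual_sd=0.0,
        width_residual_sd=0.0,
        velocity_residual_sd=0.0,
        tw_residual_sd=0.0,
        n_iter=n_iter,
    )


@pytest.fixture
def five_segments():
    rows = [
        make_segment_row(f"s{i}", 2 * i, 2 * i + 1, discharge_m3s=0.1 + 0.2 * i,
                         elevation_m=1400.0 + 100 * i, slope_mm=0.03 + 0.01 * i)
        for i in range(5)
    ]
    return make_segments(rows)


class TestRunEnsemble:
    def test_zero_noise_reproduces_deterministic_chain(self, five_segments):
        ens = run_ensemble(five_segments, DEFAULT_CO2_MODEL, zero_noise_spec(), seed=1)
        det = compute_fluxes(five_segments)
        for i in range(len(five_segments)):
            np.testing.assert_allclose(
                ens.total[i], det["total_gC_yr"].iloc[i], rtol=1e-12
            )
            np.testing.assert_allclose(
                ens.areal_daily[i], det["areal_gC_m2_d"].iloc[i], rtol=1e-12
            )

    def test_same_seed_bitwise_identical(self, five_segments):
        spec = PerturbationSpec(n_iter=200)
        a = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=9)
        b = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=9)
        np.testing.assert_array_equal(a.total, b.total)
        np.testing.assert_array_equal(a.co2, b.co2)

    def test_different_seed_differs(self, five_segments):
        spec = PerturbationSpec(n_iter=50)
        a = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=9)
        b = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=10)
        assert not np.array_equal(a.total, b.total)

    def test_draws_independent_of_segment_order(self, five_segments):
        # per-segment substreams: dropping trailing segments leaves the
        # leading segments' draws untouched
        spec = PerturbationSpec(n_iter=64)
        full = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=3)
        head = run_ensemble(five_segments.iloc[:2], DEFAULT_CO2_MODEL, spec, seed=3)
        np.testing.assert_array_equal(full.total[:2], head.total)

    def test_concentration_channel_lognormal_scale(self):
        # only the CO2 channel perturbed: reconstructing the concentration
        # from areal flux, kCO2 and saturation recovers the ln-scale sd
        seg = make_segments([make_segment_row()])
        spec = PerturbationSpec(
            co2_residual_sd=0.5,
            k600_residual_sd=0.0,
            width_residual_sd=0.0,
            velocity_residual_sd=0.0,
            tw_residual_sd=0.0,
            n_iter=10_000,
        )
        ens = run_ensemble(seg, DEFAULT_CO2_MODEL, spec, seed=21)
        from streamco2 import (
            barometric_pressure,
            co2_saturation,
            henry_constant,
            water_temperature,
        )

        c_sat = co2_saturation(
            barometric_pressure(1500.0), henry_constant(water_temperature(5.0))
        )
        # concentration rebuilt through the flux chain: delta / M_C + sat
        delta = ens.areal_daily[0] * 1000.0 / ens.kco2[0]  # mg C m^-3
        c_stream = delta / 12.011 + c_sat
        np.testing.assert_allclose(c_stream, ens.co2[0], rtol=1e-9)
        sd = np.log(c_stream).std(ddof=1)
        assert sd == pytest.approx(0.5, rel=0.05)

    def test_missing_sds_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(co2_residual_sd=-0.1)


class TestTrimOutliers:
    def test_pooled_linear_interpolation_threshold(self):
        # 1000 pooled values 1..1000: the 99.5th percentile is 995.005,
        # so exactly the 5 values above it are removed
        totals = np.arange(1.0, 1001.0).reshape(1, 1000)
        ens = FluxEnsemble.from_total_draws(totals)
        trimmed = trim_outliers(ens, variables=("areal_flux",), trim_quantile=0.995)
        assert int(trimmed.trimmed.sum()) == 5
        assert trimmed.trimmed[0, -5:].all()

    def test_quantile_one_removes_nothing(self):
        ens = FluxEnsemble.from_total_draws(np.random.default_rng(0).normal(size=(3, 100)))
        trimmed = trim_outliers(ens, trim_quantile=1.0)
        assert trimmed.trimmed.sum() == 0

    def test_all_equal_removes_nothing(self):
        ens = FluxEnsemble.from_total_draws(np.full((4, 50), 7.0))
        trimmed = trim_outliers(ens, trim_quantile=0.995)
        assert trimmed.trimmed.sum() == 0

    def test_trimmed_fraction_bounded(self, five_segments):
        spec = PerturbationSpec(n_iter=2000)
        ens = run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=2)
        trimmed = trim_outliers(ens)
        # at most three trimmed variables, each removing <= 0.5% of draws
        assert trimmed.trimmed_fraction <= 3 * (1 - spec.trim_quantile) + 1e-9


class TestTotalSchemes:
    @pytest.fixture
    def iid_normal_ensemble(self):
        rng = np.random.default_rng(12)
        draws = rng.normal(1.0, 0.2, size=(100, 10_000))
        ens = FluxEnsemble.from_total_draws(draws)
        return trim_outliers(ens, trim_quantile=1.0)

    def test_independent_interval_closed_form(self, iid_normal_ensemble):
        # sum of 100 iid N(1, 0.2) is N(100, 2): 5-95% width = 2*1.645*2
        est = total_independent(iid_normal_ensemble)
        assert est.mean == pytest.approx(100.0, rel=0.01)
        assert est.interval_width == pytest.approx(6.58, rel=0.10)

    def test_dependent_interval_closed_form(self, iid_normal_ensemble):
        # per-segment width 2*1.645*0.2 = 0.658, summed over 100 segments
        est = total_dependent(iid_normal_ensemble)
        assert est.mean == pytest.approx(100.0, rel=0.01)
        assert est.interval_width == pytest.approx(65.8, rel=0.10)

    def test_dependent_is_sqrt_n_wider(self, iid_normal_ensemble):
        ratio = (
            total_dependent(iid_normal_ensemble).interval_width
            / total_independent(iid_normal_ensemble).interval_width
        )
        assert ratio == pytest.approx(10.0, rel=0.10)

    def test_single_segment_schemes_agree(self):
        draws = np.random.default_rng(3).lognormal(0.0, 0.4, size=(1, 5000))
        ens = trim_outliers(FluxEnsemble.from_total_draws(draws), trim_quantile=1.0)
        ind, dep = total_independent(ens), total_dependent(ens)
        assert ind.mean == pytest.approx(dep.mean, rel=1e-12)
        assert ind.p5 == pytest.approx(dep.p5, rel=1e-12)
        assert ind.p95 == pytest.approx(dep.p95, rel=1e-12)

    def test_zero_noise_gives_zero_width(self, five_segments):
        ens = run_ensemble(five_segments, DEFAULT_CO2_MODEL, zero_noise_spec(), seed=0)
        ens = trim_outliers(ens, trim_quantile=1.0)
        est = total_independent(ens)
        assert est.interval_width == pytest.approx(0.0, abs=1e-9)
        det_sum = compute_fluxes(five_segments)["total_gC_yr"].sum()
        assert est.mean == pytest.approx(det_sum, rel=1e-12)

    def test_dependent_contains_independent(self):
        # bracketing property over randomized ensembles
        rng = np.random.default_rng(77)
        for _ in range(10):
            n_seg = rng.integers(2, 30)
            mu = rng.uniform(-1.0, 3.0, size=(int(n_seg), 1))
            sd = rng.uniform(0.05, 1.0, size=(int(n_seg), 1))
            draws = rng.normal(mu, sd, size=(int(n_seg), 2000))
            ens = trim_outliers(FluxEnsemble.from_total_draws(draws), trim_quantile=1.0)
            ind, dep = total_independent(ens), total_dependent(ens)
            assert dep.p5 <= ind.p5 + 1e-9
            assert dep.p95 >= ind.p95 - 1e-9

    def test_means_of_both_schemes_agree(self, five_segments):
        spec = PerturbationSpec(n_iter=4000)
        ens = trim_outliers(
            run_ensemble(five_segments, DEFAULT_CO2_MODEL, spec, seed=8),
            trim_quantile=1.0,
        )
        ind, dep = total_independent(ens), total_dependent(ens)
        assert ind.mean == pytest.approx(dep.mean, rel=1e-9)

    def test_mean_converges_with_iterations(self, small_network):
        segments, _ = apply_filters(small_network.segments)
        spec_a = PerturbationSpec(n_iter=10_000)
        spec_b = PerturbationSpec(n_iter=20_000)
        a = total_independent(
            trim_outliers(run_ensemble(segments, DEFAULT_CO2_MODEL, spec_a, seed=4))
        )
        b = total_independent(
            trim_outliers(run_ensemble(segments, DEFAULT_CO2_MODEL, spec_b, seed=4))
        )
        assert abs(b.mean - a.mean) / abs(a.mean) < 0.01
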