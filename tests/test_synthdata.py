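"""Synthetic network generator, calibration sets and mass balances."""

import numpy as np
import pandas as pd
import pytest

from streamco2 import NetworkTopology, apply_filters
from streamco2.co2model import DEFAULT_CO2_MODEL, PUBLISHED_R2, fit_co2_model, residual_sd_for_r2
from streamco2.synthdata import (
    NetworkSpec,
    generate_calibration_set,
    generate_network,
    simulate_groundwater_forward,
)
from conftest import make_segment_row, make_segments


class TestGenerateNetwork:
    def test_single_headwater_is_a_chain(self):
        topo = generate_network(NetworkSpec(n_headwaters=1, chain_segments=5, seed=0))
        assert len(topo) == 5
        assert (topo.segments["strahler"] == 1).all()
        assert len(topo.headwaters()) == 1
        assert len(topo.outlets()) == 1

    def test_full_pairwise_merging_strahler(self):
        topo = generate_network(
            NetworkSpec(n_headwaters=4, merge_probability=1.0, gw_inflow_fraction=0.0, seed=1)
        )
        seg = topo.segments
        outlet = seg[seg["segment_id"].isin(topo.outlets())].iloc[0]
        assert outlet["strahler"] == 3
        headwaters = seg[seg["segment_id"].isin(topo.headwaters())]
        assert outlet["discharge_m3s"] == pytest.approx(
            headwaters["discharge_m3s"].sum()
        )

    def test_water_balance_with_groundwater_increments(self):
        topo = generate_network(NetworkSpec(n_headwaters=12, seed=3))
        seg = topo.segments
        outlet_q = seg[seg["segment_id"].isin(topo.outlets())]["discharge_m3s"].iloc[0]
        assert outlet_q == pytest.approx(seg["q_gw_m3s"].sum(), rel=1e-12)

    def test_discharge_nondecreasing_downstream(self):
        topo = generate_network(NetworkSpec(n_headwaters=10, seed=4))
        q = dict(zip(topo.segments["segment_id"], topo.segments["discharge_m3s"]))
        for sid in topo.segments["segment_id"]:
            down = topo.downstream_of(sid)
            if down is not None:
                assert q[down] >= q[sid]

    def test_elevations_strictly_decrease_downstream(self):
        topo = generate_network(NetworkSpec(n_headwaters=10, seed=6))
        elev = dict(zip(topo.segments["segment_id"], topo.segments["elevation_m"]))
        for sid in topo.segments["segment_id"]:
            down = topo.downstream_of(sid)
            if down is not None:
                assert elev[down] < elev[sid]

    def test_soc_and_tair_decrease_with_elevation(self):
        topo = generate_network(NetworkSpec(n_headwaters=64, seed=7))
        seg = topo.segments
        assert seg["soc_gkg"].corr(seg["elevation_m"]) < 0
        assert seg["tair_c"].corr(seg["elevation_m"]) < -0.9

    def test_reproducible_by_seed(self):
        a = generate_network(NetworkSpec(seed=11)).segments
        b = generate_network(NetworkSpec(seed=11)).segments
        pd.testing.assert_frame_equal(a, b)

    def test_alpine_regime_mostly_passes_filters(self, swiss_regime_spec):
        # statistical check across 100 seeded networks: the generator's
        # default regime lies almost entirely inside the retention filters
        total = kept = 0
        for seed in range(100):
            spec = NetworkSpec(
                n_headwaters=16, elevation_range=(1200.0, 4938.0), seed=seed
            )
            topo = generate_network(spec)
            retained, _ = apply_filters(topo.segments)
            total += len(topo)
            kept += len(retained)
        assert kept / total >= 0.95

    def test_inverted_elevation_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            NetworkSpec(elevation_range=(2000.0, 1000.0))


class TestGenerateCalibrationSet:
    def test_noiseless_refit_is_perfect(self):
        truth = DEFAULT_CO2_MODEL.with_residual_sd(0.0)
        obs = generate_calibration_set(100, truth, seed=1)
        _, report = fit_co2_model(obs)
        assert report.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noise_calibrated_to_published_r2(self):
        sd = residual_sd_for_r2(PUBLISHED_R2)
        truth = DEFAULT_CO2_MODEL.with_residual_sd(sd)
        r2s = [
            fit_co2_model(generate_calibration_set(323, truth, seed=s))[1].r_squared
            for s in range(20)
        ]
        assert np.mean(r2s) == pytest.approx(PUBLISHED_R2, abs=0.05)

    def test_covariates_within_ranges(self):
        truth = DEFAULT_CO2_MODEL.with_residual_sd(0.3)
        obs = generate_calibration_set(500, truth, seed=2)
        assert obs["elevation_m"].between(500.0, 4938.0).all()
        assert obs["discharge_m3s"].between(0.001, 2.26).all()
        assert obs["soc_gkg"].between(10.0, 200.0).all()

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_set(0, DEFAULT_CO2_MODEL.with_residual_sd(0.1))


class TestForwardGroundwaterSimulator:
    def test_equilibrium_fixed_point(self):
        # groundwater at the (uniform) saturation concentration keeps every
        # reach at saturation with zero evasion
        rows = [
            make_segment_row("a", 0, 1, discharge_m3s=0.10, elevation_m=1500.0, tair_c=5.0),
            make_segment_row("b", 1, 2, discharge_m3s=0.12, elevation_m=1500.0, tair_c=5.0),
        ]
        topo = NetworkTopology(make_segments(rows))
        probe = simulate_groundwater_forward(topo, 1.0)
        c_sat_umol_l = probe["c_sat_umol_m3"].iloc[0] / 1000.0
        forward = simulate_groundwater_forward(topo, c_sat_umol_l)
        np.testing.assert_allclose(forward["f_umol_s"], 0.0, atol=1e-9)
        np.testing.assert_allclose(
            forward["c_umol_m3"], forward["c_sat_umol_m3"], rtol=1e-12
        )

    def test_zero_groundwater_inflow_gives_degenerate_pairs(self):
        from streamco2 import network_groundwater_survey

        topo = generate_network(
            NetworkSpec(n_headwaters=4, merge_probability=1.0, gw_inflow_fraction=0.0, seed=9)
        )
        forward = simulate_groundwater_forward(topo, 100.0)
        c = dict(zip(forward["segment_id"], forward["c_umol_m3"]))
        f = dict(zip(forward["segment_id"], forward["f_umol_s"]))
        table, summary = network_groundwater_survey(topo, c, f)
        assert summary["n_gaining"] == 0

    def test_carbon_mass_balance_closes(self):
        topo = generate_network(NetworkSpec(n_headwaters=16, seed=13))
        truth = 150.0
        forward = simulate_groundwater_forward(topo, truth)
        q = dict(zip(forward["segment_id"], forward["q_m3s"]))
        c = dict(zip(forward["segment_id"], forward["c_umol_m3"]))
        mass_in = (forward["q_gw_m3s"] * truth * 1000.0).sum()
        outlet = topo.outlets()[0]
        mass_out = q[outlet] * c[outlet] + forward["f_umol_s"].sum()
        assert mass_out == pytest.approx(mass_in, rel=1e-8)

    def test_losing_topology_rejected(self):
        rows = [
            make_segment_row("a", 0, 1, discharge_m3s=0.20),
            make_segment_row("b", 1, 2, discharge_m3s=0.10),
        ]
        topo = NetworkTopology(make_segments(rows))
        with pytest.raises(ValueError, match="gaining"):
            simulate_groundwater_forward(topo, 100.0)
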