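"""Kinetic-model unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phloempet as pp
from phloempet.model import PRIMARY_SHOOT_PARAMS, SECONDARY_SHOOT_PARAMS

from oracles import advection_cascade_closed_form, euler_simulate


class TestAdvectiveRate:
    @pytest.mark.parametrize(
        "s_ph,l,expected",
        [(128.0, 4.0, 0.032), (70.0, 10.0, 0.007)],
    )
    def test_unit_conversion(self, s_ph, l, expected):
        params = pp.ModelParameters(s_ph=s_ph, a12=0.01, b=0.01, c=0.01)
        geom = pp.RoiGeometry(roi_length_mm=l)
        assert pp.advective_rate_constant(params, geom) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            pp.ModelParameters(s_ph=0.0, a12=0.01, b=0.01, c=0.01)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            pp.RoiGeometry(roi_length_mm=0.0)


class TestInputClosure:
    @pytest.mark.parametrize(
        "total,c2,c3,expected",
        [(1.0, 0.3, 0.2, 0.5), (0.0, 0.0, 0.0, 0.0), (0.1, 0.15, 0.0, 0.0)],
    )
    def test_examples(self, total, c2, c3, expected):
        assert pp.input_c1(total, c2, c3) == pytest.approx(expected)

    @given(
        total=st.floats(0, 10), c2=st.floats(0, 10), c3=st.floats(0, 10)
    )
    @settings(derandomize=True, max_examples=200)
    def test_floor_property(self, total, c2, c3):
        v = pp.input_c1(total, c2, c3)
        assert v >= 0.0
        if total - c2 - c3 >= 0:
            assert v == pytest.approx(total - c2 - c3)


class TestDerivatives:
    def test_zero_state_zero_input_is_equilibrium(self, paper_params, primary_geom):
        d = pp.derivatives(0.0, np.zeros(11), paper_params, primary_geom, lambda t: 0.0)
        assert np.all(d == 0.0)

    def test_shape_validated(self, paper_params, primary_geom):
        with pytest.raises(ValueError):
            pp.derivatives(0.0, np.zeros(7), paper_params, primary_geom, lambda t: 0.0)

    def test_storage_pools_stay_empty_without_unloading(self, primary_geom, constant_input_tac):
        params = pp.ModelParameters(s_ph=128.0, a12=0.0, b=0.3 / 60, c=0.2 / 60)
        sim = pp.simulate(params, primary_geom, constant_input_tac)
        for roi in ("input", "roi1", "roi2", "roi3"):
            assert np.all(sim.conc[roi]["C2"] == 0.0)
            assert np.all(sim.conc[roi]["C3"] == 0.0)

    def test_single_stage_exponential_approach(self, primary_geom, constant_input_tac):
        # constant upstream A, no exchange: ROI-1 C1 follows A(1 - e^{-kt})
        params = pp.ModelParameters(s_ph=128.0, a12=0.0, b=0.0, c=0.0)
        k = pp.advective_rate_constant(params, primary_geom)
        sim = pp.simulate(params, primary_geom, constant_input_tac)
        expected = 1.5 * (1.0 - np.exp(-k * sim.t_min * 60.0))
        assert np.allclose(sim.conc["roi1"]["C1"], expected, atol=1.5e-6)


class TestSimulate:
    def test_zero_input_gives_zero_output(self, primary_geom, paper_params):
        t = pp.TacTable.default_grid()
        tab = pp.TacTable(t, np.zeros((24, 4)))
        sim = pp.simulate(paper_params, primary_geom, tab)
        assert np.all(sim.totals == 0.0)
        assert np.all(sim.frame_totals == 0.0)

    def test_linearity_in_input(self, primary_geom, paper_params, noiseless_tac):
        sim1 = pp.simulate(paper_params, primary_geom, noiseless_tac, dense=False)
        sim10 = pp.simulate(paper_params, primary_geom, noiseless_tac.scaled(10.0), dense=False)
        assert np.allclose(sim10.frame_totals, 10.0 * sim1.frame_totals, rtol=1e-6)

    def test_downstream_peaks_strictly_decrease(self, roi_set):
        noiseless = roi_set[0]
        peaks = noiseless.values.max(axis=0)
        assert peaks[0] > peaks[1] > peaks[2] > peaks[3]

    def test_non_decay_corrected_rejected(self, primary_geom, paper_params, noiseless_tac):
        bad = pp.TacTable(
            noiseless_tac.time_min, noiseless_tac.values, decay_corrected=False
        )
        with pytest.raises(ValueError, match="decay"):
            pp.simulate(paper_params, primary_geom, bad)

    def test_frame_average_consistent_with_dense_trajectory(
        self, primary_geom, paper_params, noiseless_tac
    ):
        # declared aggregation rule: average of the dense trajectory over
        # each 5-min frame window
        sim = pp.simulate(
            paper_params, primary_geom, noiseless_tac,
            solver=pp.SolverConfig(dense_dt_min=0.05),
        )
        edges = noiseless_tac.frame_edges_min
        for f in range(noiseless_tac.n_frames):
            sel = (sim.t_min >= edges[f]) & (sim.t_min <= edges[f + 1])
            trap = np.trapezoid(sim.totals[sel, 1:], sim.t_min[sel], axis=0) / (
                edges[f + 1] - edges[f]
            )
            assert np.allclose(trap, sim.frame_totals[f, 1:], rtol=2e-3, atol=1e-9)

    def test_midpoint_aggregation_option(self, primary_geom, paper_params, noiseless_tac):
        sim = pp.simulate(
            paper_params, primary_geom, noiseless_tac,
            solver=pp.SolverConfig(frame_aggregation="midpoint"), dense=False,
        )
        dense = pp.simulate(paper_params, primary_geom, noiseless_tac)
        mid_idx = np.searchsorted(dense.t_min, noiseless_tac.time_min)
        assert np.allclose(sim.frame_totals, dense.totals[mid_idx], rtol=1e-5, atol=1e-10)

    @pytest.mark.parametrize("params", [PRIMARY_SHOOT_PARAMS, SECONDARY_SHOOT_PARAMS])
    def test_nonnegativity_and_monotone_storage(self, primary_geom, noiseless_tac, params):
        sim = pp.simulate(params, primary_geom, noiseless_tac)
        assert sim.totals.min() >= 0.0
        for roi in ("input", "roi1", "roi2", "roi3"):
            c3 = sim.conc[roi]["C3"]
            assert np.all(np.diff(c3) >= -1e-12)

    def test_distributed_initialization_close_to_default(
        self, primary_geom, paper_params, noiseless_tac
    ):
        # results should be insensitive to how frame-1 activity is split
        a = pp.simulate(paper_params, primary_geom, noiseless_tac, dense=False)
        b = pp.simulate(
            paper_params, primary_geom, noiseless_tac,
            solver=pp.SolverConfig(init_mode="distributed"), dense=False,
        )
        scale = np.abs(noiseless_tac.values).max()
        assert np.abs(a.frame_totals - b.frame_totals).max() / scale < 0.005


class TestOracleEquivalence:
    def test_adaptive_rk_matches_fixed_step_euler(
        self, paper_params, primary_geom, noiseless_tac
    ):
        t_e, euler = euler_simulate(
            paper_params.s_ph, paper_params.a12, paper_params.b, paper_params.c,
            paper_params.h, primary_geom.roi_length_mm,
            noiseless_tac.time_min, noiseless_tac.input,
            dt_min=0.001, t_end_min=120.0,
        )
        sim = pp.simulate(
            paper_params, primary_geom, noiseless_tac,
            solver=pp.SolverConfig(dense_dt_min=0.5),
        )
        idx = np.round(sim.t_min / 0.001).astype(int)
        err = np.abs(sim.totals[:, 1:] - euler[idx]) / np.abs(euler).max()
        assert err.max() < 1e-3

    def test_advection_cascade_closed_form(self, primary_geom, constant_input_tac):
        params = pp.ModelParameters(s_ph=128.0, a12=0.0, b=0.0, c=0.0)
        k = pp.advective_rate_constant(params, primary_geom)
        sim = pp.simulate(params, primary_geom, constant_input_tac)
        expected = advection_cascade_closed_form(1.5, k, sim.t_min * 60.0)
        assert np.abs(sim.totals[:, 1:] - expected).max() / 1.5 < 1e-4


class TestMassBalance:
    @pytest.mark.parametrize(
        "params",
        [
            PRIMARY_SHOOT_PARAMS,
            SECONDARY_SHOOT_PARAMS,
            pp.ModelParameters(s_ph=128.0, a12=0.0, b=0.0, c=0.0),
            pp.ModelParameters(s_ph=216.0, a12=0.35 / 60, b=0.30 / 60, c=0.45 / 60),
        ],
    )
    def test_residual_small(self, primary_geom, noiseless_tac, params):
        sim = pp.simulate(params, primary_geom, noiseless_tac)
        assert pp.mass_balance(sim) < 1e-4

    def test_zero_inflow_returns_zero(self, primary_geom, paper_params):
        t = pp.TacTable.default_grid()
        tab = pp.TacTable(t, np.zeros((24, 4)))
        sim = pp.simulate(paper_params, primary_geom, tab)
        assert pp.mass_balance(sim) == 0.0
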