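"""Calibration objective and SCE-UA parameter estimation."""

import numpy as np
import pytest

import phloempet as pp


class TestRmseObjective:
    def test_self_consistency_at_truth(self, paper_params, primary_geom, noiseless_tac):
        assert pp.rmse_objective(paper_params, noiseless_tac, primary_geom) < 1e-6

    def test_constant_offset_residual(self, paper_params, primary_geom, noiseless_tac):
        delta = 0.037
        shifted = noiseless_tac.values.copy()
        shifted[:, 1:] += delta
        tab = pp.TacTable(noiseless_tac.time_min, shifted)
        assert pp.rmse_objective(paper_params, tab, primary_geom) == pytest.approx(
            delta, rel=1e-4
        )

    def test_noisy_rmse_matches_injected_residual_norm(
        self, paper_params, primary_geom, roi_set
    ):
        # perturb only the downstream ROIs (the input column is forcing:
        # noise there changes the simulation itself)
        noiseless, _, _ = roi_set
        rng = np.random.default_rng(123)
        vals = noiseless.values.copy()
        noise = rng.standard_normal(vals[:, 1:].shape) * 0.05 * vals[:, 1:]
        vals[:, 1:] += noise
        tab = pp.TacTable(noiseless.time_min, vals)
        injected = np.sqrt(np.mean(noise**2))
        assert pp.rmse_objective(paper_params, tab, primary_geom) == pytest.approx(
            injected, rel=1e-3
        )


class TestCalibrationConfig:
    def test_five_param_complex_count_rule(self):
        cfg = pp.CalibrationConfig(
            free_parameters=("s_ph", "a12", "b", "c", "h"), n_complexes=11
        )
        assert cfg.effective_n_complexes == 11

    def test_default_complex_count_is_two_n_plus_one(self):
        assert pp.CalibrationConfig().effective_n_complexes == 9

    def test_exchange_bounds_must_stay_physical(self):
        with pytest.raises(ValueError):
            pp.CalibrationConfig(bounds={"a12": (0.0, 1.5)})

    def test_default_coupling_constant(self):
        assert pp.CalibrationConfig().h_fixed == pytest.approx(0.68759)


class TestCalibrate:
    def test_noiseless_recovery_at_reported_means(
        self, paper_params, primary_geom, noiseless_tac
    ):
        res = pp.calibrate(noiseless_tac, primary_geom, pp.CalibrationConfig(seed=1))
        for name in ("s_ph", "a12", "b", "c"):
            rel = abs(getattr(res.params, name) - getattr(paper_params, name)) / getattr(
                paper_params, name
            )
            assert rel < 0.02, name
        assert res.params.h == paper_params.h  # fixed, not fitted
        assert res.params.a21 == pytest.approx(res.params.h * res.params.a12)

    def test_degenerate_truth_pins_a12_at_lower_bound(self, primary_geom):
        truth = pp.ModelParameters(s_ph=100.0, a12=1e-9, b=0.002, c=0.003)
        cfg = pp.SyntheticConfig(params=truth, noise=pp.NoiseModel(cv=0.0, floor=0.0))
        noiseless, _, _ = pp.generate_roi_set(cfg)
        res = pp.calibrate(
            noiseless, primary_geom, pp.CalibrationConfig(seed=2, max_evaluations=4000)
        )
        assert res.params.a12 < 0.005

    def test_reproducible_for_fixed_seed(self, primary_geom, noiseless_tac):
        cfg = pp.CalibrationConfig(seed=7, max_evaluations=1500)
        r1 = pp.calibrate(noiseless_tac, primary_geom, cfg)
        r2 = pp.calibrate(noiseless_tac, primary_geom, cfg)
        assert r1.params == r2.params
        assert r1.rmse == r2.rmse
        assert r1.n_evaluations == r2.n_evaluations

    def test_objective_scales_with_data(self, paper_params, primary_geom, noiseless_tac):
        r1 = pp.rmse_objective(paper_params, noiseless_tac, primary_geom)
        r10 = pp.rmse_objective(paper_params, noiseless_tac.scaled(10.0), primary_geom)
        assert r10 == pytest.approx(10.0 * r1, rel=1e-6)

    def test_budget_exhaustion_sets_converged_false(self, primary_geom, noiseless_tac):
        res = pp.calibrate(
            noiseless_tac, primary_geom, pp.CalibrationConfig(seed=0, max_evaluations=300)
        )
        assert not res.converged

    def test_too_few_frames_rejected(self, primary_geom, noiseless_tac):
        short = pp.TacTable(noiseless_tac.time_min[:5], noiseless_tac.values[:5])
        with pytest.raises(ValueError, match="8 frames"):
            pp.calibrate(short, primary_geom)

    def test_result_serializes_to_json(self, tmp_path, primary_geom, noiseless_tac):
        res = pp.calibrate(
            noiseless_tac, primary_geom, pp.CalibrationConfig(seed=0, max_evaluations=400)
        )
        path = tmp_path / "fit.json"
        res.to_json(path)
        import json

        d = json.loads(path.read_text())
        assert d["params"]["a21"] == pytest.approx(d["params"]["h"] * d["params"]["a12"])
        assert d["config"]["n_complexes"] == 9


class TestFiveParamModel:
    def test_h_recovered_on_clean_data(self, paper_params, primary_geom, noiseless_tac):
        res = pp.calibrate_five_param(
            noiseless_tac, primary_geom, pp.CalibrationConfig(seed=3, max_evaluations=30000)
        )
        assert res.config.effective_n_complexes == 11
        assert abs(res.params.h - paper_params.h) / paper_params.h < 0.05

    def test_average_h_reporting(self):
        assert pp.average_h([0.6, 0.7, 0.76]) == pytest.approx(0.6867)

    def test_average_h_accepts_results(self, primary_geom, noiseless_tac):
        res = pp.calibrate(
            noiseless_tac, primary_geom, pp.CalibrationConfig(seed=0, max_evaluations=300)
        )
        assert pp.average_h([res]) == pytest.approx(round(res.params.h, 4))
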