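"""Sensitivity matrices and collinearity-index identifiability."""

import itertools

import numpy as np
import pytest

import phloempet as pp

from oracles import gamma_via_svd


@pytest.fixture(scope="module")
def sens_traj(paper_params, primary_geom, noiseless_tac):
    return pp.relative_sensitivities(
        paper_params, primary_geom, noiseless_tac, output_surface="trajectories"
    )


@pytest.fixture(scope="module")
def sens_frames(paper_params, primary_geom, noiseless_tac):
    return pp.relative_sensitivities(
        paper_params, primary_geom, noiseless_tac, output_surface="frames"
    )


class TestCollinearityIndex:
    def test_orthonormal_columns_give_unity(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).random((30, 4)))
        assert pp.collinearity_index(q) == pytest.approx(1.0, abs=1e-10)

    def test_identical_columns_flagged_infinite(self):
        col = np.arange(1.0, 11.0)
        assert pp.collinearity_index(np.column_stack([col, col])) == np.inf

    def test_zero_column_flagged_infinite(self):
        M = np.column_stack([np.arange(10.0), np.zeros(10)])
        assert pp.collinearity_index(M) == np.inf

    def test_single_column_convention(self):
        assert pp.collinearity_index(np.arange(1.0, 5.0)[:, None]) == 1.0

    def test_matches_svd_oracle(self, sens_traj):
        gamma = pp.collinearity_index(sens_traj)
        assert gamma == pytest.approx(gamma_via_svd(sens_traj.matrix), abs=1e-8)

    def test_invariant_to_column_scaling_and_row_permutation(self, sens_traj):
        M = sens_traj.matrix
        gamma = pp.collinearity_index(M)
        scaled = M * np.array([7.0, 0.01, 3.0, 100.0])
        assert pp.collinearity_index(scaled) == pytest.approx(gamma, rel=1e-10)
        rng = np.random.default_rng(1)
        perm = rng.permutation(M.shape[0])
        assert pp.collinearity_index(M[perm]) == pytest.approx(gamma, rel=1e-10)

    def test_subset_gamma_bounded_by_superset(self, sens_traj):
        names = sens_traj.parameter_names
        full = pp.collinearity_index(sens_traj)
        for r in (2, 3):
            for sub in itertools.combinations(names, r):
                assert pp.collinearity_index(sens_traj, sub) <= full + 1e-9


class TestSensitivities:
    def test_all_columns_active_at_reported_means(self, sens_traj):
        norms = np.linalg.norm(sens_traj.matrix, axis=0)
        assert np.all(norms > 0.0)

    def test_structurally_dead_parameter_gives_zero_column(
        self, primary_geom, noiseless_tac
    ):
        # without unloading the storage pools never fill, so b has no effect
        params = pp.ModelParameters(s_ph=128.0, a12=0.0, b=0.002, c=0.003)
        with pytest.warns(UserWarning, match="one-sided"):
            S = pp.relative_sensitivities(
                params, primary_geom, noiseless_tac, free=("s_ph", "a12", "b", "c")
            )
        assert np.allclose(S.column("b"), 0.0, atol=1e-12)
        assert pp.collinearity_index(S, ("s_ph", "b")) == np.inf

    def test_finite_difference_step_robustness(
        self, paper_params, primary_geom, noiseless_tac, sens_traj
    ):
        S2 = pp.relative_sensitivities(
            paper_params, primary_geom, noiseless_tac, rel_perturbation=2e-4
        )
        g1 = pp.collinearity_index(sens_traj)
        g2 = pp.collinearity_index(S2)
        assert abs(g2 - g1) / g1 < 0.01

    def test_trajectory_surface_below_threshold_at_reported_means(self, sens_traj):
        gamma = pp.collinearity_index(sens_traj)
        assert gamma < 15.0

    def test_frame_surface_is_stricter(self, sens_traj, sens_frames):
        assert pp.collinearity_index(sens_frames) > pp.collinearity_index(sens_traj)


class TestAssess:
    def test_report_structure(self, paper_params, primary_geom, noiseless_tac, sens_traj):
        rep = pp.assess(
            paper_params, primary_geom, noiseless_tac, sensitivities=sens_traj
        )
        assert rep.threshold == 15.0
        assert rep.gamma("a12") == 1.0  # singleton convention
        full = tuple(sorted(("s_ph", "a12", "b", "c")))
        assert rep.identifiable[full] == (rep.gammas[full] <= 15.0)
        d = rep.to_dict()
        assert d["threshold"] == 15.0
        assert "a12+b+c+s_ph" in d["gammas"]

    def test_report_is_json_serializable(
        self, paper_params, primary_geom, noiseless_tac, sens_traj
    ):
        import json

        rep = pp.assess(
            paper_params, primary_geom, noiseless_tac, sensitivities=sens_traj
        )
        json.dumps(rep.to_dict())
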