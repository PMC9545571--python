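"""Tests for the grid-search inversion and its sensitivity diagnostics."""

import numpy as np
import pytest

from lidarpol import (
    AxisSpec,
    GridSpec,
    ModelParams,
    compare_models,
    grid_search,
    predict_delta,
    ridge_profile,
    rmse,
)

from conftest import make_field


def small_single_grid():
    return GridSpec("single", {
        "m22_p": AxisSpec(0.5, 1.0, 0.05),
        "phi_p": AxisSpec(0.0, 0.4, 0.05),
    })


class TestRmse:
    def test_perfect_prediction(self):
        assert rmse([0.1, 0.2, 0.3], [0.1, 0.2, 0.3], k=0) == 0.0

    def test_hand_evaluation(self):
        assert rmse([0.1, 0.3], [0.2, 0.2], k=0) == pytest.approx(0.1)

    def test_dof_correction(self):
        # same residuals, k=1 halves the denominator
        assert rmse([0.1, 0.3], [0.2, 0.2], k=1) == pytest.approx(
            np.sqrt(0.02))

    def test_degenerate_denominator(self):
        with pytest.raises(ValueError, match="N > k"):
            rmse([0.1, 0.3], [0.2, 0.2], k=2)


class TestGridSearch:
    def test_single_node_grid(self, single_truth):
        observations = make_field(single_truth, n_obs=10, seed=3)
        grid = GridSpec("single", {
            "m22_p": AxisSpec(0.66, 0.66, 0.01),
            "phi_p": AxisSpec(0.02, 0.02, 0.01),
        })
        result = grid_search(observations, grid)
        assert result.rmse_surface.shape == (1, 1)
        params = result.optimum
        predicted = [predict_delta(s, params) for s, _ in observations]
        direct = rmse(predicted, [d for _, d in observations], k=2)
        assert result.optimum_rmse == pytest.approx(direct, abs=1e-12)

    def test_noise_free_node_recovery(self):
        grid = small_single_grid()
        axes = grid.axis_values()
        truth = ModelParams("single", m22_p=float(axes["m22_p"][4]),
                            phi_p=float(axes["phi_p"][2]))
        observations = make_field(truth, n_obs=100, seed=11)
        result = grid_search(observations, grid)
        assert result.optimum.m22_p == truth.m22_p
        assert result.optimum.phi_p == truth.phi_p
        assert result.optimum_rmse == pytest.approx(0.0, abs=1e-12)

    def test_surface_matches_bruteforce_oracle(self, single_truth, constants):
        """Vectorized surface equals per-node scalar re-evaluation."""
        observations = make_field(single_truth, n_obs=40, noise_sd=0.01,
                                  seed=5)
        grid = small_single_grid()
        result = grid_search(observations, grid, constants)
        axes = result.axes()
        rng = np.random.default_rng(0)
        deltas_obs = [d for _, d in observations]
        for _ in range(20):
            i = rng.integers(len(axes["m22_p"]))
            j = rng.integers(len(axes["phi_p"]))
            params = ModelParams("single", m22_p=float(axes["m22_p"][i]),
                                 phi_p=float(axes["phi_p"][j]))
            predicted = [predict_delta(s, params, constants)
                         for s, _ in observations]
            expected = rmse(predicted, deltas_obs, k=result.k)
            assert result.rmse_surface[i, j] == pytest.approx(expected,
                                                              abs=1e-12)

    def test_two_particle_surface_matches_oracle(self, constants):
        truth = ModelParams("two", m22_acid=0.9, phi_labile=0.2,
                            phi_acid=0.05)
        observations = make_field(truth, n_obs=25, noise_sd=0.01, seed=9)
        grid = GridSpec("two", {
            "m22_acid": AxisSpec(0.5, 1.0, 0.1),
            "phi_labile": AxisSpec(0.0, 0.4, 0.1),
            "phi_acid": AxisSpec(0.0, 0.4, 0.1),
        })
        result = grid_search(observations, grid, constants)
        axes = result.axes()
        deltas_obs = [d for _, d in observations]
        rng = np.random.default_rng(1)
        for _ in range(15):
            idx = tuple(int(rng.integers(len(v))) for v in axes.values())
            params = ModelParams(
                "two",
                m22_acid=float(axes["m22_acid"][idx[0]]),
                phi_labile=float(axes["phi_labile"][idx[1]]),
                phi_acid=float(axes["phi_acid"][idx[2]]),
                m22_labile=constants.m22_labile_fixed,
            )
            predicted = [predict_delta(s, params, constants)
                         for s, _ in observations]
            expected = rmse(predicted, deltas_obs, k=result.k)
            assert result.rmse_surface[idx] == pytest.approx(expected,
                                                             abs=1e-12)

    def test_bit_identical_reproducibility(self, single_truth):
        observations = make_field(single_truth, n_obs=30, noise_sd=0.005,
                                  seed=2)
        a = grid_search(observations, small_single_grid())
        b = grid_search(observations, small_single_grid())
        assert np.array_equal(a.rmse_surface, b.rmse_surface)
        assert a.optimum_index == b.optimum_index

    def test_noise_shrinks_recovery_error(self):
        """Recovered parameters approach truth as observation noise -> 0."""
        grid = GridSpec("single", {
            "m22_p": AxisSpec(0.5, 1.0, 0.01),
            "phi_p": AxisSpec(0.0, 0.4, 0.005),
        })
        axes = grid.axis_values()
        truth = ModelParams("single", m22_p=float(axes["m22_p"][20]),
                            phi_p=float(axes["phi_p"][20]))
        errors = []
        for sd in (0.02, 0.005, 0.001):
            observations = make_field(truth, n_obs=300, noise_sd=sd, seed=13)
            opt = grid_search(observations, grid).optimum
            errors.append(abs(opt.m22_p - truth.m22_p)
                          + abs(opt.phi_p - truth.phi_p))
        assert errors[2] <= errors[0]
        assert errors[2] <= 0.015  # within a step or two at the lowest noise

    def test_constant_surface_tie_break(self):
        # particle-free water: every node predicts delta = 0 exactly, so the
        # whole surface ties and the deterministic rule must pick
        # (smallest phi, largest m22)
        truth = ModelParams("single", m22_p=0.8, phi_p=0.1)
        observations = make_field(
            truth, n_obs=10, seed=1,
            b_p_range=(1e-12, 1e-12), bbp_over_bp_range=(0.0, 0.0),
            labile_fraction_range=(0.0, 0.0),
        )
        observations = [(s, 0.0) for s, _ in observations]
        grid = small_single_grid()
        r1 = grid_search(observations, grid)
        r2 = grid_search(observations, grid)
        assert r1.optimum.phi_p == 0.0
        assert r1.optimum.m22_p == 1.0
        assert r1.optimum_index == r2.optimum_index


class TestRidgeProfile:
    def test_single_axis_profile_is_surface(self, single_truth):
        observations = make_field(single_truth, n_obs=10, seed=3)
        grid = GridSpec("single", {
            "m22_p": AxisSpec(0.5, 1.0, 0.1),
            "phi_p": AxisSpec(0.1, 0.1, 0.1),
        })
        result = grid_search(observations, grid)
        profile = ridge_profile(result, "m22_p")
        surface = result.rmse_surface[:, 0]
        assert [p["rmse"] for p in profile] == pytest.approx(list(surface))

    def test_compensation_ridge_monotone(self):
        """More multiple-scattering depolarization (phi) is compensated by
        less single-scattering depolarization (larger conditional M22)."""
        grid = GridSpec("single", {
            "m22_p": AxisSpec(0.5, 1.0, 0.01),
            "phi_p": AxisSpec(0.0, 0.06, 0.005),
        })
        axes = grid.axis_values()
        truth = ModelParams("single", m22_p=float(axes["m22_p"][16]),
                            phi_p=float(axes["phi_p"][4]))
        observations = make_field(truth, n_obs=200, seed=21)
        result = grid_search(observations, grid)
        profile = ridge_profile(result, "phi_p")
        m22_opt = [p["conditional_optimum"]["m22_p"] for p in profile]
        assert all(b >= a - 1e-12 for a, b in zip(m22_opt, m22_opt[1:]))

    def test_unknown_axis(self, single_truth):
        observations = make_field(single_truth, n_obs=10, seed=3)
        result = grid_search(observations, small_single_grid())
        with pytest.raises(ValueError, match="unknown axis"):
            ridge_profile(result, "phi_acid")


class TestCompareModels:
    def _aligned_grids(self, step=0.05, k=None):
        single = GridSpec("single", {
            "m22_p": AxisSpec(0.5, 1.0, step),
            "phi_p": AxisSpec(0.0, 0.4, step),
        }, k=k)
        two = GridSpec("two", {
            "m22_acid": AxisSpec(0.5, 1.0, step),
            "phi_labile": AxisSpec(0.0, 0.4, step),
            "phi_acid": AxisSpec(0.0, 0.4, step),
        }, k=k)
        return single, two

    def test_degenerate_calcite_makes_models_coincide(self):
        # with no acid-labile backscatter the two-particle family nests the
        # single-particle family on aligned grids; the grids share k so the
        # RMSE scoring is comparable node-for-node
        truth = ModelParams("single", m22_p=0.75, phi_p=0.1)
        observations = make_field(truth, n_obs=60, noise_sd=0.01, seed=17,
                                  labile_fraction_range=(0.0, 0.0))
        single, two = self._aligned_grids(k=0)
        rs = grid_search(observations, single)
        rt = grid_search(observations, two)
        comparison = compare_models(rs, rt)
        assert rt.optimum_rmse <= rs.optimum_rmse + 1e-12
        assert comparison["delta_rmse"] == pytest.approx(
            rs.optimum_rmse - rt.optimum_rmse)

    def test_two_particle_truth_favors_two_particle_model(self, constants):
        single, two = self._aligned_grids()
        axes = two.axis_values()
        truth = ModelParams(
            "two",
            m22_acid=float(axes["m22_acid"][8]),
            phi_labile=float(axes["phi_labile"][4]),
            phi_acid=float(axes["phi_acid"][1]),
            m22_labile=constants.m22_labile_fixed,
        )
        observations = make_field(truth, n_obs=80, seed=23,
                                  labile_fraction_range=(0.3, 0.8))
        rs = grid_search(observations, single)
        rt = grid_search(observations, two)
        comparison = compare_models(rs, rt)
        assert rt.optimum_rmse == pytest.approx(0.0, abs=1e-12)
        assert comparison["improved"]

    def test_single_truth_no_spurious_improvement(self):
        truth = ModelParams("single", m22_p=0.75, phi_p=0.1)
        observations = make_field(truth, n_obs=150, noise_sd=0.005, seed=29)
        single, two = self._aligned_grids()
        comparison = compare_models(grid_search(observations, single),
                                    grid_search(observations, two))
        assert abs(comparison["delta_rmse"]) < 0.005  # within the noise floor

    def test_mismatched_observation_counts(self, single_truth):
        single, two = self._aligned_grids(step=0.1)
        obs_a = make_field(single_truth, n_obs=10, seed=1)
        obs_b = make_field(single_truth, n_obs=12, seed=1)
        with pytest.raises(ValueError, match="observation counts"):
            compare_models(grid_search(obs_a, single),
                           grid_search(obs_b, two))


class TestGridSpecValidation:
    def test_axis_names_checked(self):
        with pytest.raises(ValueError, match="axes"):
            GridSpec("single", {"m22_acid": AxisSpec(0.5, 1.0, 0.1),
                                "phi_p": AxisSpec(0.0, 0.4, 0.1)})

    def test_step_positive(self):
        with pytest.raises(ValueError):
            AxisSpec(0.5, 1.0, 0.0)

    def test_default_k_counts_free_parameters(self):
        assert GridSpec.single().k_effective == 2
        assert GridSpec.two().k_effective == 3
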