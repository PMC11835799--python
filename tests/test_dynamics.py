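import numpy as np
import pytest

from dirswarm.dynamics import (
    attraction_velocity,
    auditory_phase_rate,
    evaluate_derivatives,
    fused_rates,
    gaze_rate,
    phase_gaze_velocity,
    repulsion_velocity,
    total_phase_rate,
    total_velocity,
    visual_phase_rate,
)
from dirswarm.model_core import ModelParams, SwarmState, pairwise_geometry, wrap_angle

from conftest import random_state
from reference import naive_derivatives


def single_agent(x=(1.0, 0.0), theta=0.0, delta=0.0, omega=4 * np.pi, phi=0.0):
    return SwarmState(
        positions=np.array([x]),
        phases=[theta],
        gazes=[delta],
        spontaneous_freqs=[omega],
        stimulus_phases=[phi],
        group_ids=[1],
    )


def pair(x1, x2, theta1=0.0, theta2=0.0, delta1=0.0, delta2=0.0):
    return SwarmState(
        positions=np.array([x1, x2], dtype=float),
        phases=[theta1, theta2],
        gazes=[delta1, delta2],
        spontaneous_freqs=[4 * np.pi, 4 * np.pi],
        stimulus_phases=[0.0, 0.0],
        group_ids=[1, 2],
    )


class TestAttraction:
    def test_linear_attraction_at_unit_distance(self):
        state = single_agent(x=(1.0, 0.0))
        v = attraction_velocity(state, ModelParams(attraction_strength=0.1, attraction_exponent=1.0))
        np.testing.assert_allclose(v, [[-0.1, 0.0]], atol=1e-15)

    def test_zero_at_origin(self):
        v = attraction_velocity(single_agent(x=(0.0, 0.0)), ModelParams())
        np.testing.assert_allclose(v, [[0.0, 0.0]])

    def test_quadratic_exponent(self):
        state = single_agent(x=(0.0, 2.0))
        v = attraction_velocity(state, ModelParams(attraction_strength=0.1, attraction_exponent=2.0))
        np.testing.assert_allclose(v, [[0.0, -0.4]], atol=1e-15)


class TestRepulsion:
    def test_hand_computed_pair(self):
        state = pair((0.0, 0.0), (1.0, 0.0))
        geom = pairwise_geometry(state.positions)
        v = repulsion_velocity(state, geom, ModelParams(repulsion_strength=1.5, repulsion_decay=2.0))
        np.testing.assert_allclose(v[0], [-0.75, 0.0], atol=1e-14)
        np.testing.assert_allclose(v[1], [0.75, 0.0], atol=1e-14)

    def test_single_agent_zero(self):
        state = single_agent()
        v = repulsion_velocity(state, pairwise_geometry(state.positions), ModelParams())
        np.testing.assert_allclose(v, [[0.0, 0.0]])

    def test_inverse_square_decay(self):
        state = pair((0.0, 0.0), (2.0, 0.0))
        geom = pairwise_geometry(state.positions)
        v = repulsion_velocity(state, geom, ModelParams(repulsion_strength=1.5, repulsion_decay=2.0))
        np.testing.assert_allclose(v[0], [-0.1875, 0.0], atol=1e-14)


class TestPhaseGazeAttraction:
    def test_panoramic_in_phase_pair(self):
        state = pair((0.0, 0.0), (1.0, 0.0), delta1=0.0)  # gaze along +x, at partner
        geom = pairwise_geometry(state.positions)
        params = ModelParams(pg_attraction_strength=0.5, pg_spatial_decay=1.0, constriction=0.0)
        v = phase_gaze_velocity(state, geom, params)
        assert np.linalg.norm(v[0]) == pytest.approx(0.25 / (2 * np.pi), rel=1e-12)
        assert v[0, 0] > 0  # toward the partner

    def test_antiphase_pair_no_attraction(self):
        state = pair((0.0, 0.0), (1.0, 0.0), theta2=np.pi)
        geom = pairwise_geometry(state.positions)
        v = phase_gaze_velocity(state, geom, ModelParams(constriction=0.0))
        np.testing.assert_allclose(v[0], [0.0, 0.0], atol=1e-15)

    def test_target_dead_behind_invisible(self):
        state = pair((0.0, 0.0), (1.0, 0.0), delta1=np.pi)  # facing away
        geom = pairwise_geometry(state.positions)
        v = phase_gaze_velocity(state, geom, ModelParams(constriction=1.0))
        np.testing.assert_allclose(v[0], [0.0, 0.0], atol=1e-15)


class TestGazeRate:
    def test_target_dead_ahead_no_rotation(self):
        state = pair((0.0, 0.0), (1.0, 0.0), delta1=0.0)
        geom = pairwise_geometry(state.positions)
        assert gaze_rate(state, geom, ModelParams(constriction=1.0))[0] == pytest.approx(0.0)

    def test_hand_computed_quarter_turn_target(self):
        state = pair((0.0, 0.0), (0.0, 1.0), delta1=0.0)  # target at +y, gaze +x
        geom = pairwise_geometry(state.positions)
        params = ModelParams(gaze_strength=0.25, gaze_spatial_decay=1.0, constriction=1.0)
        assert gaze_rate(state, geom, params)[0] == pytest.approx(0.0625, rel=1e-12)

    def test_antiphase_target_no_rotation(self):
        state = pair((0.0, 0.0), (0.0, 1.0), theta2=np.pi, delta1=0.0)
        geom = pairwise_geometry(state.positions)
        assert gaze_rate(state, geom, ModelParams(constriction=1.0))[0] == pytest.approx(0.0)


class TestPhaseRates:
    def test_auditory_at_lock_is_zero(self):
        state = single_agent(theta=0.3, phi=0.3)
        assert auditory_phase_rate(state, ModelParams())[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("diff,expected", [(np.pi / 2, 0.8), (-np.pi / 2, -0.8)])
    def test_auditory_quarter_cycle(self, diff, expected):
        state = single_agent(theta=0.0, phi=diff)
        assert auditory_phase_rate(state, ModelParams(auditory_strength=0.8))[0] == pytest.approx(
            expected
        )

    def test_visual_quarter_cycle_panoramic(self):
        state = pair((0.0, 0.0), (1.0, 0.0), theta2=np.pi / 2, delta1=0.0)
        geom = pairwise_geometry(state.positions)
        params = ModelParams(visual_strength=0.4, visual_spatial_decay=1.0, constriction=0.0)
        assert visual_phase_rate(state, geom, params)[0] == pytest.approx(
            0.2 / (2 * np.pi), rel=1e-12
        )

    def test_equal_phases_no_visual_entrainment(self, rng):
        state = random_state(rng, n=5)
        state.phases[:] = 1.0
        geom = pairwise_geometry(state.positions)
        np.testing.assert_allclose(
            visual_phase_rate(state, geom, ModelParams()), np.zeros(5), atol=1e-15
        )

    def test_uncoupled_phase_rate_is_spontaneous(self, rng):
        state = random_state(rng, n=4)
        params = ModelParams(auditory_strength=0.0, visual_strength=0.0)
        geom = pairwise_geometry(state.positions)
        np.testing.assert_allclose(
            total_phase_rate(state, geom, params), state.spontaneous_freqs, atol=1e-15
        )


class TestTotals:
    def test_all_strengths_zero(self, rng):
        state = random_state(rng, n=4)
        params = ModelParams(
            attraction_strength=0.0, repulsion_strength=0.0, pg_attraction_strength=0.0
        )
        geom = pairwise_geometry(state.positions)
        np.testing.assert_allclose(total_velocity(state, geom, params), 0.0, atol=1e-15)

    def test_components_sum_exactly(self, rng):
        state = random_state(rng, n=6)
        params = ModelParams()
        der = evaluate_derivatives(state, params)
        np.testing.assert_array_equal(
            der.velocity, der.v_attraction + der.v_repulsion + der.v_phase_gaze
        )
        np.testing.assert_array_equal(
            der.phase_rate, der.spontaneous + der.phase_auditory + der.phase_visual
        )


class TestOracleEquivalence:
    def test_vectorized_matches_naive_double_loop(self, rng):
        for _ in range(50):
            state = random_state(rng)
            params = ModelParams(
                constriction=rng.uniform(0.0, 2.0),
                gaze_strength=rng.uniform(0.0, 1.0),
                repulsion_decay=rng.choice([1.0, 2.0, 2.5]),
            )
            ref_v, ref_d, ref_p = naive_derivatives(state, params)
            der = evaluate_derivatives(state, params)
            np.testing.assert_allclose(der.velocity, ref_v, atol=1e-12)
            np.testing.assert_allclose(der.gaze_rate, ref_d, atol=1e-12)
            np.testing.assert_allclose(der.phase_rate, ref_p, atol=1e-12)

    def test_fused_fast_path_matches_modular_terms(self, rng):
        for _ in range(20):
            state = random_state(rng)
            params = ModelParams(constriction=rng.uniform(0.0, 2.0))
            der = evaluate_derivatives(state, params)
            vel, drate, prate = fused_rates(state, params)
            np.testing.assert_allclose(vel, der.velocity, atol=1e-13)
            np.testing.assert_allclose(drate, der.gaze_rate, atol=1e-13)
            np.testing.assert_allclose(prate, der.phase_rate, atol=1e-13)


def _rotate(xy, beta):
    rot = np.array([[np.cos(beta), -np.sin(beta)], [np.sin(beta), np.cos(beta)]])
    return xy @ rot.T


class TestEquivariance:
    def test_rotation_equivariance(self, rng):
        state = random_state(rng, n=6)
        params = ModelParams()
        der = evaluate_derivatives(state, params)
        beta = 1.1
        rotated = state.copy()
        rotated.positions = _rotate(state.positions, beta)
        rotated.gazes = wrap_angle(state.gazes + beta)
        der_rot = evaluate_derivatives(rotated, params)
        np.testing.assert_allclose(der_rot.velocity, _rotate(der.velocity, beta), atol=1e-12)
        np.testing.assert_allclose(der_rot.gaze_rate, der.gaze_rate, atol=1e-12)
        np.testing.assert_allclose(der_rot.phase_rate, der.phase_rate, atol=1e-12)

    def test_translation_leaves_pairwise_terms_unchanged(self, rng):
        state = random_state(rng, n=6)
        params = ModelParams()
        der = evaluate_derivatives(state, params)
        shifted = state.copy()
        shifted.positions = state.positions + np.array([3.0, -7.0])
        der_s = evaluate_derivatives(shifted, params)
        np.testing.assert_allclose(der_s.v_repulsion, der.v_repulsion, atol=1e-12)
        np.testing.assert_allclose(der_s.v_phase_gaze, der.v_phase_gaze, atol=1e-12)
        np.testing.assert_allclose(der_s.gaze_rate, der.gaze_rate, atol=1e-12)
        np.testing.assert_allclose(der_s.phase_rate, der.phase_rate, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        state = random_state(rng, n=7)
        params = ModelParams()
        der = evaluate_derivatives(state, params)
        perm = rng.permutation(7)
        permuted = SwarmState(
            positions=state.positions[perm],
            phases=state.phases[perm],
            gazes=state.gazes[perm],
            spontaneous_freqs=state.spontaneous_freqs[perm],
            stimulus_phases=state.stimulus_phases[perm],
            group_ids=state.group_ids[perm],
        )
        der_p = evaluate_derivatives(permuted, params)
        np.testing.assert_allclose(der_p.velocity, der.velocity[perm], atol=1e-12)
        np.testing.assert_allclose(der_p.gaze_rate, der.gaze_rate[perm], atol=1e-12)
        np.testing.assert_allclose(der_p.phase_rate, der.phase_rate[perm], atol=1e-12)
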