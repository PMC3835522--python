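"""Smoothed step functions, memberships, curvature and the gradient flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapseg.levelset import (
    EvolutionParams,
    LevelSetState,
    compute_memberships,
    curvature,
    evolve_multiphase,
    evolve_two_phase,
    hard_labels,
    indicator_memberships,
    initialize_level_set,
    laplacian,
    membership_gradients,
    smoothed_delta,
    smoothed_heaviside,
)


class TestHeavisideDelta:
    def test_analytic_anchors(self):
        assert smoothed_heaviside(0.0, 1.0) == pytest.approx(0.5)
        assert smoothed_heaviside(1.0, 1.0) == pytest.approx(0.75)  # arctan(1) = pi/4
        assert smoothed_delta(0.0, 1.0) == pytest.approx(1.0 / np.pi)
        assert smoothed_delta(0.0, 2.0) == pytest.approx(1.0 / (2 * np.pi))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 5))
    def test_symmetries(self, x, eps):
        assert smoothed_heaviside(x, eps) + smoothed_heaviside(-x, eps) == pytest.approx(1.0)
        assert smoothed_delta(x, eps) == pytest.approx(smoothed_delta(-x, eps))

    def test_delta_integrates_to_one(self):
        # quadrature over [-100 eps, 100 eps] captures ~99.4% of the mass
        for eps in (0.5, 1.0, 3.0):
            x = np.linspace(-100 * eps, 100 * eps, 200001)
            integral = np.trapezoid(smoothed_delta(x, eps), x)
            assert integral == pytest.approx(1.0, abs=0.01)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            smoothed_heaviside(0.0, 0.0)
        with pytest.raises(ValueError):
            smoothed_delta(0.0, -1.0)


class TestMemberships:
    def test_two_phase_values(self):
        state = LevelSetState(np.full((1, 4, 4), 10.0), epsilon=1.0, phase_count=2)
        m = compute_memberships(state)
        np.testing.assert_allclose(m[0], smoothed_heaviside(10.0, 1.0), atol=1e-12)
        assert m[0, 0, 0] == pytest.approx(0.9683, abs=1e-4)
        np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_three_phase_at_zero(self):
        state = LevelSetState(np.zeros((2, 3, 3)), epsilon=1.0, phase_count=3)
        m = compute_memberships(state)
        np.testing.assert_allclose(m[0], 0.25, atol=1e-12)
        np.testing.assert_allclose(m[1], 0.25, atol=1e-12)
        np.testing.assert_allclose(m[2], 0.5, atol=1e-12)

    @pytest.mark.parametrize("n_phases,n_funcs", [(2, 1), (3, 2), (4, 2)])
    def test_partition_of_unity(self, rng, n_phases, n_funcs):
        state = LevelSetState(
            rng.normal(0, 3, (n_funcs, 8, 8)), epsilon=1.0, phase_count=n_phases
        )
        np.testing.assert_allclose(compute_memberships(state).sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(indicator_memberships(state).sum(axis=0), 1.0)

    def test_membership_gradients_sum_to_zero(self, rng):
        for n in (2, 3, 4):
            funcs = rng.normal(0, 2, ((1 if n == 2 else 2), 6, 6))
            state = LevelSetState(funcs, epsilon=1.0, phase_count=n)
            grads = membership_gradients(state)
            np.testing.assert_allclose(grads.sum(axis=1), 0.0, atol=1e-14)

    def test_unsupported_combination_rejected(self):
        with pytest.raises(ValueError):
            LevelSetState(np.zeros((2, 4, 4)), epsilon=1.0, phase_count=2)
        with pytest.raises(ValueError):
            LevelSetState(np.zeros((1, 4, 4)), epsilon=1.0, phase_count=4)


class TestCurvature:
    def test_circle_signed_distance(self):
        # curvature of a circle's signed distance is 1/R at the zero set
        n, R = 128, 20.0
        rows, cols = np.indices((n, n))
        phi = np.sqrt((rows - 63.5) ** 2 + (cols - 63.5) ** 2) - R
        kappa = curvature(phi)
        band = np.abs(phi) < 1.0
        assert np.median(kappa[band]) == pytest.approx(1.0 / R, rel=0.1)

    def test_planar_field_is_flat(self):
        rows, cols = np.indices((32, 32))
        phi = 0.7 * rows + 0.3 * cols - 10.0
        kappa = curvature(phi)
        np.testing.assert_allclose(kappa[2:-2, 2:-2], 0.0, atol=1e-10)

    def test_sign_flip_is_odd(self, rng):
        phi = rng.standard_normal((16, 16))
        np.testing.assert_allclose(curvature(-phi), -curvature(phi), atol=1e-10)


def _rhs_two_phase_oracle(phi, e1, e2, eps, dt, nu, mu):
    """Independent finite-difference evaluation of the two-phase flow RHS."""
    guard = 1e-10
    p = np.pad(phi, 1, mode="edge")
    gy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    gx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    norm = np.sqrt(gy**2 + gx**2) + guard
    ny, nx = gy / norm, gx / norm
    py = np.pad(ny, 1, mode="edge")
    px = np.pad(nx, 1, mode="edge")
    kappa = 0.5 * (py[2:, 1:-1] - py[:-2, 1:-1]) + 0.5 * (px[1:-1, 2:] - px[1:-1, :-2])
    lap = (
        p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * phi
    )
    delta = (eps / np.pi) / (eps**2 + phi**2)
    return phi + dt * (-delta * (e1 - e2) + nu * delta * kappa + mu * (lap - kappa))


class TestEvolution:
    def test_stationary_for_flat_interface_and_equal_evidence(self):
        rows = np.indices((16, 16))[0].astype(float)
        phi = rows - 7.5  # signed distance to a horizontal line
        state = LevelSetState(phi[None], epsilon=1.0, phase_count=2)
        e = np.stack([np.ones((16, 16)), np.ones((16, 16))])
        new = evolve_two_phase(state, e, EvolutionParams(nu=1.0, mu=1.0))
        np.testing.assert_allclose(new.functions[0][1:-1], phi[1:-1], atol=1e-12)

    def test_region_grows_where_its_evidence_is_lower(self):
        phi = np.zeros((8, 8))
        state = LevelSetState(phi[None], epsilon=1.0, phase_count=2)
        e1 = np.zeros((8, 8))
        e2 = np.ones((8, 8))
        new = evolve_two_phase(state, e1[None].repeat(2, 0) * 0 + np.stack([e1, e2]),
                               EvolutionParams(nu=0.0, mu=0.0))
        assert np.all(new.functions[0] > phi)  # e1 < e2 -> region 1 grows

    def test_pure_data_step_is_exact(self, rng):
        phi = rng.normal(0, 2, (8, 8))
        state = LevelSetState(phi[None], epsilon=1.0, phase_count=2)
        e = rng.normal(0, 1, (2, 8, 8))
        params = EvolutionParams(nu=0.0, mu=0.0, dt=0.1)
        new = evolve_two_phase(state, e, params)
        want = phi - 0.1 * smoothed_delta(phi, 1.0) * (e[0] - e[1])
        np.testing.assert_allclose(new.functions[0], want, atol=1e-15)

    def test_single_step_matches_direct_rhs(self, rng):
        phi = rng.normal(0, 2, (8, 8))
        e = rng.normal(0, 1, (2, 8, 8))
        params = EvolutionParams(dt=0.1, nu=0.5, mu=1.0)
        state = LevelSetState(phi[None], epsilon=1.0, phase_count=2)
        got = evolve_two_phase(state, e, params).functions[0]
        want = _rhs_two_phase_oracle(phi, e[0], e[1], 1.0, 0.1, 0.5, 1.0)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_multiphase_equal_evidence_has_no_data_force(self, rng):
        funcs = rng.normal(0, 2, (2, 8, 8))
        state = LevelSetState(funcs, epsilon=1.0, phase_count=4)
        e = np.ones((4, 8, 8)) * 3.7
        params = EvolutionParams(nu=0.0, mu=0.0)
        new = evolve_multiphase(state, e, params)
        np.testing.assert_allclose(new.functions, funcs, atol=1e-13)

    def test_three_phase_cheap_region_expands(self):
        # region 3 is {phi_1 < 0}; when its evidence is much lower, phi_1
        # must decrease near its zero set
        funcs = np.zeros((2, 8, 8))
        state = LevelSetState(funcs, epsilon=1.0, phase_count=3)
        e = np.stack([np.full((8, 8), 5.0), np.full((8, 8), 5.0), np.zeros((8, 8))])
        new = evolve_multiphase(state, e, EvolutionParams(nu=0.0, mu=0.0))
        assert np.all(new.functions[0] < 0)

    def test_regularizer_drives_gradient_magnitude_to_one(self):
        state = initialize_level_set((64, 64), ("circle", 31.5, 31.5, 15.0), c0=2.0)
        e = np.zeros((2, 64, 64))
        params = EvolutionParams(nu=0.0, mu=1.0, dt=0.1)
        for _ in range(200):
            state = evolve_two_phase(state, e, params)
        phi = state.functions[0]
        p = np.pad(phi, 1, mode="edge")
        gy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
        gx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
        mag = np.sqrt(gy**2 + gx**2)
        rows, cols = np.indices(phi.shape)
        dist = np.sqrt((rows - 31.5) ** 2 + (cols - 31.5) ** 2)
        band = np.abs(dist - 15.0) <= 3.0  # band around the zero set
        assert 0.8 <= np.median(mag[band]) <= 1.2


class TestInitialization:
    def test_square_seed_binary_step(self):
        state = initialize_level_set((64, 64), ("rect", 22, 22, 42, 42), c0=2.0)
        phi = state.functions[0]
        assert set(np.unique(phi)) == {-2.0, 2.0}
        assert (phi == -2.0).sum() == 400
        labels = hard_labels(state)
        assert (labels == 2).sum() == 400  # region 2 is {phi < 0}, the seed

    def test_seed_covering_whole_image(self):
        state = initialize_level_set((32, 32), ("rect", 0, 0, 32, 32), c0=2.0)
        np.testing.assert_array_equal(state.functions[0], -2.0)

    def test_two_disjoint_circle_seeds_for_two_functions(self):
        seeds = [("circle", 16.0, 16.0, 8.0), ("circle", 48.0, 48.0, 8.0)]
        state = initialize_level_set((64, 64), seeds, c0=2.0, phase_count=4)
        for j in range(2):
            assert set(np.unique(state.functions[j])) == {-2.0, 2.0}

    def test_union_seed(self):
        state = initialize_level_set(
            (64, 64),
            [[("circle", 16.0, 16.0, 5.0), ("circle", 40.0, 40.0, 5.0)]],
            c0=2.0,
        )
        inside = state.functions[0] < 0
        assert inside[16, 16] and inside[40, 40] and not inside[28, 28]

    def test_bad_seeds_rejected(self):
        with pytest.raises(ValueError):
            initialize_level_set((32, 32), ("rect", 10, 10, 10, 20), c0=2.0)
        with pytest.raises(ValueError):
            initialize_level_set((32, 32), ("rect", 0, 0, 40, 40), c0=2.0)
        with pytest.raises(ValueError):
            initialize_level_set((32, 32), ("circle", 5, 5, 3), c0=0.0)
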