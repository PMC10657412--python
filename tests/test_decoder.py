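"""Vector field, integration oracles, reducer, homogeneity diagnostic."""

import numpy as np
import pytest

from tdnode._autodiff import Tensor
from tdnode.config import ModelDims
from tdnode.decoder import (
    Reducer,
    VectorField,
    homogeneity_defect,
    integrate,
    rk4_batch,
    hermite_sample,
    reduce_to_sld,
)

DIMS = ModelDims.reduced()


def _random_field(seed, scale=0.3):
    """A vector field with generic (non-zero) weights.

    Undoes the null-field initialization to probe a generic dynamical law;
    ``scale`` keeps the dynamics non-stiff over the test horizons.
    """
    rng = np.random.default_rng(seed)
    vf = VectorField(rng, DIMS)
    vf.net.out.w.data = scale * rng.standard_normal(vf.net.out.w.data.shape)
    vf.net.out.b.data = (scale / 3.0) * rng.standard_normal(vf.net.out.b.data.shape)
    return vf


def _rk4_oracle(vf, y0, t_grid):
    """Independent dense fixed-step RK4 reference."""
    y = np.asarray(y0, float).copy()
    out = [y.copy()]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        f = lambda v: vf.numpy_eval(v[None, :])[0]
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(y.copy())
    return np.array(out)


class TestVectorField:
    def test_parameter_channels_exactly_zero(self):
        vf = _random_field(0)
        state = np.random.default_rng(1).standard_normal((4, 6))
        out = vf.numpy_eval(state)
        np.testing.assert_array_equal(out[:, 4:], 0.0)
        out_t = vf(Tensor(state))
        np.testing.assert_array_equal(out_t.data[:, 4:], 0.0)

    def test_finite_in_finite_out(self):
        vf = _random_field(2)
        out = vf.numpy_eval(np.random.default_rng(0).standard_normal((8, 6)) * 5)
        assert np.all(np.isfinite(out))

    def test_non_finite_state_rejected(self):
        vf = _random_field(0)
        bad = np.full((1, 6), np.nan)
        with pytest.raises(ValueError):
            vf.numpy_eval(bad)


class _LinearInP:
    """Hand-built field f(z, p) = (B + z1 * C) p: homogeneous of degree 1 in p."""

    def __init__(self, seed=0):
        rng = np.random.default_rng(seed)
        self.B = rng.standard_normal((4, 2))
        self.C = rng.standard_normal((4, 2))

    def numpy_eval(self, state):
        state = np.atleast_2d(state)
        coeff = self.B[None, :, :] + state[:, 0, None, None] * self.C[None, :, :]
        dz = np.einsum("nij,nj->ni", coeff, state[:, 4:])
        return np.concatenate([dz, np.zeros((state.shape[0], 2))], axis=1)


class _LinearHomogeneous:
    """f(z, p) = diag(p) acting on the first two latent coordinates.

    Homogeneous of degree one in p (f(z, p*T) = f(z, p)*T identically).
    """

    def numpy_eval(self, state):
        state = np.atleast_2d(state)
        dz = np.zeros((state.shape[0], 4))
        dz[:, 0] = state[:, 4] * state[:, 0]
        dz[:, 1] = state[:, 5] * state[:, 1]
        return np.concatenate([dz, np.zeros((state.shape[0], 2))], axis=1)


class TestHomogeneity:
    @pytest.mark.parametrize("field_cls", [_LinearInP, _LinearHomogeneous])
    def test_p_linear_field_has_zero_defect(self, field_cls):
        vf = field_cls()
        rng = np.random.default_rng(3)
        for _ in range(10):
            z = rng.standard_normal(4)
            p = rng.standard_normal(2)
            T = float(rng.uniform(0.1, 20.0))
            assert homogeneity_defect(vf, z, p, T) <= 1e-12

    def test_defect_nonnegative_for_generic_field(self):
        vf = _random_field(5)
        rng = np.random.default_rng(0)
        defects = [
            homogeneity_defect(vf, rng.standard_normal(4), rng.standard_normal(2),
                               float(rng.uniform(0.5, 5.0)))
            for _ in range(20)
        ]
        assert all(d >= 0 for d in defects)
        assert any(d > 0 for d in defects)  # generic fields are not homogeneous


class TestIntegrate:
    def test_origin_only_returns_initial_state(self):
        vf = _random_field(0)
        z0 = np.array([0.1, -0.2, 0.3, 0.0])
        p = np.array([0.5, -0.5])
        traj = integrate(vf, z0, p, np.array([0.0]))
        np.testing.assert_array_equal(traj.states[0], np.concatenate([z0, p]))

    def test_zero_field_constant_trajectory(self):
        rng = np.random.default_rng(0)
        vf = VectorField(rng, DIMS)  # output layer zero-initialized: null field
        z0 = rng.standard_normal(4)
        p = rng.standard_normal(2)
        traj = integrate(vf, z0, p, np.array([0.0, 0.5, 1.0, 2.0]))
        np.testing.assert_allclose(traj.states, np.tile(np.concatenate([z0, p]), (4, 1)))

    def test_adaptive_agrees_with_dense_rk4_oracle(self):
        # ten random weight draws; adaptive tol 1e-4 vs fixed-step h=1e-3
        times = np.linspace(0.0, 1.5, 7)
        for seed in range(10):
            vf = _random_field(seed + 10, scale=0.15)
            rng = np.random.default_rng(seed)
            z0 = 0.5 * rng.standard_normal(4)
            p = 0.5 * rng.standard_normal(2)
            traj = integrate(vf, z0, p, times, tol=1e-4)
            grid = np.arange(0.0, 1.5 + 1e-12, 1e-3)
            ref = _rk4_oracle(vf, np.concatenate([z0, p]), grid)
            idx = np.searchsorted(grid, times)
            assert np.max(np.abs(traj.states - ref[idx])) <= 1e-3

    def test_parameter_channels_constant_along_trajectory(self):
        vf = _random_field(3)
        p = np.array([0.7, -0.4])
        traj = integrate(vf, np.zeros(4), p, np.linspace(0, 2, 9))
        assert np.max(np.abs(traj.states[:, 4:] - p)) == 0.0

    def test_tolerance_refinement_sanity(self):
        vf = _random_field(7, scale=0.15)
        z0 = np.array([0.2, 0.1, -0.1, 0.0])
        p = np.array([0.3, -0.3])
        times = np.linspace(0, 1.5, 5)
        coarse = integrate(vf, z0, p, times, tol=1e-4).states
        fine = integrate(vf, z0, p, times, tol=5e-5).states
        assert np.max(np.abs(coarse - fine)) <= 10 * 1e-4


class TestReducer:
    def test_length_preserved_and_deterministic(self):
        red = Reducer(np.random.default_rng(0), DIMS)
        states = np.random.default_rng(1).standard_normal((5, 6))
        out = reduce_to_sld(red, states)
        assert out.shape == (5,)
        np.testing.assert_array_equal(out, reduce_to_sld(red, states))

    def test_ignores_parameter_channels(self):
        red = Reducer(np.random.default_rng(0), DIMS)
        rng = np.random.default_rng(2)
        states = rng.standard_normal((5, 6))
        altered = states.copy()
        altered[:, 4:] = rng.standard_normal((5, 2)) * 100
        np.testing.assert_array_equal(reduce_to_sld(red, states), reduce_to_sld(red, altered))


class TestTrainingIntegrator:
    def test_rk4_batch_matches_dense_oracle(self):
        vf = _random_field(21)
        rng = np.random.default_rng(4)
        state0 = 0.5 * rng.standard_normal((3, 6))
        horizons = np.array([0.8, 1.7, 2.5])
        states, derivs, h, n_steps = rk4_batch(
            vf, Tensor(state0), horizons, dtau=0.05, min_steps=8, max_steps=128
        )
        taus = np.array([0.4, 1.1, 2.2])
        member = np.array([0, 1, 2])
        sampled = hermite_sample(states, derivs, h, n_steps, member, taus)
        for i in range(3):
            grid = np.arange(0.0, horizons[i] + 1e-12, 1e-3)
            ref = _rk4_oracle(vf, state0[i], grid)
            j = np.searchsorted(grid, taus[i])
            np.testing.assert_allclose(sampled.data[i], ref[j], atol=5e-4)

    def test_hermite_exact_at_grid_nodes(self):
        vf = _random_field(22)
        state0 = 0.3 * np.random.default_rng(5).standard_normal((2, 6))
        horizons = np.array([1.0, 2.0])
        states, derivs, h, n_steps = rk4_batch(vf, Tensor(state0), horizons, dtau=0.25)
        sampled = hermite_sample(
            states, derivs, h, n_steps, np.array([0, 1]), np.array([3 * h[0], 5 * h[1]])
        )
        np.testing.assert_allclose(sampled.data[0], states[3].data[0], atol=1e-12)
        np.testing.assert_allclose(sampled.data[1], states[5].data[1], atol=1e-12)
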