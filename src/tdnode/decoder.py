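"""The learned dynamical law and its numerical integration.

The decoder integrates a 6-dimensional *augmented state* — the
4-dimensional latent tumor state z concatenated with the 2-dimensional
kinetic metrics p — in normalized time from tau = 0. The vector field is a
residual SELU network whose last two output components are forced to
exactly 0, so p is constant along every trajectory by construction. A
small SELU *reducer* maps the first 4 state components to the scalar
(normalized) SLD.

Two integration routes exist:

* :func:`integrate` — adaptive Dormand–Prince 5(4) via
  :func:`scipy.integrate.solve_ivp` (``RK45``), used at inference.
* :func:`rk4_batch` — a fixed-grid fourth-order Runge–Kutta scheme on the
  autodiff tape, used during training (discretize-then-optimize). Each
  batch member is advanced with its *own* uniform step (its horizon divided
  by a member-specific step count), so the states a member visits are
  bit-identical whether it is integrated alone or inside any batch; labels
  at off-grid times are read off with cubic Hermite interpolation, which is
  also member-local.

The generalized-homogeneity condition f(z, p) * T = f(z, p * T) is what
gives p the meaning of kinetic rates; it is encouraged by the prefix
augmentation rather than enforced architecturally, and
:func:`homogeneity_defect` measures how far a trained field is from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._autodiff import Tensor
from ._nn import Linear, Module, ResidualMLP
from .config import ModelDims

__all__ = [
    "AugmentedState",
    "Trajectory",
    "IntegrationError",
    "VectorField",
    "Reducer",
    "integrate",
    "reduce_to_sld",
    "homogeneity_defect",
    "rk4_batch",
    "hermite_sample",
]

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _selu_np(x: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(np.minimum(x, 0.0)) - 1.0))


@dataclass(frozen=True)
class AugmentedState:
    """Concatenation [z (c), p (k)]; the trailing k components are frozen."""

    vec: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.vec)):
            raise ValueError("augmented state must be finite")


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the augmented system."""

    eval_times: np.ndarray  # normalized, ascending
    states: np.ndarray  # len x (c + k); trailing k columns constant
    sld: np.ndarray | None = None  # reduced normalized SLD, len
    sld_mm: np.ndarray | None = None  # denormalized, len

    @property
    def latent(self) -> np.ndarray:
        return self.states[:, :4]


class IntegrationError(RuntimeError):
    def __init__(self, message: str, state: np.ndarray | None = None):
        super().__init__(message)
        self.state = state


class VectorField(Module):
    """Residual SELU network f(z, p) with frozen parameter channels."""

    def __init__(self, rng: np.random.Generator, dims: ModelDims):
        super().__init__()
        self.dims = dims
        d = dims.c + dims.k
        self.net = self.add_module(
            "net", ResidualMLP(rng, d, dims.vf_width, d, n_blocks=dims.vf_blocks)
        )
        # start from the null field: long-horizon prefix trajectories would
        # otherwise explode under a random residual field before the first
        # optimizer step
        self.net.out.w.data[:] = 0.0
        self.net.out.b.data[:] = 0.0
        self._freeze = np.concatenate([np.ones(dims.c), np.zeros(dims.k)])

    def __call__(self, state: Tensor) -> Tensor:
        """Autodiff path: state B x (c+k) -> derivative B x (c+k)."""
        return self.net(state) * Tensor(self._freeze)

    def numpy_eval(self, state: np.ndarray) -> np.ndarray:
        """Tape-free evaluation for inference-time solvers."""
        state = np.atleast_2d(np.asarray(state, dtype=float))
        if not np.all(np.isfinite(state)):
            raise ValueError("non-finite state passed to vector field")
        h = _selu_np(state @ self.net.inp.w.data + self.net.inp.b.data)
        for blk in self.net.blocks:
            h = h + _selu_np(h @ blk.w.data + blk.b.data)
        out = h @ self.net.out.w.data + self.net.out.b.data
        return out * self._freeze


class Reducer(Module):
    """Two fully connected SELU layers mapping the c latent components to SLD."""

    def __init__(self, rng: np.random.Generator, dims: ModelDims):
        super().__init__()
        self.dims = dims
        self.fc1 = self.add_module("fc1", Linear(rng, dims.c, dims.reducer_width))
        self.fc2 = self.add_module("fc2", Linear(rng, dims.reducer_width, 1))

    def __call__(self, latent: Tensor) -> Tensor:
        return self.fc2(self.fc1(latent).selu())

    def numpy_eval(self, states: np.ndarray) -> np.ndarray:
        """states: n x (c+k) or n x c -> n normalized SLD values."""
        latent = np.atleast_2d(states)[:, : self.dims.c]
        h = _selu_np(latent @ self.fc1.w.data + self.fc1.b.data)
        return (h @ self.fc2.w.data + self.fc2.b.data)[:, 0]


def integrate(
    vf: VectorField,
    z0: np.ndarray,
    p: np.ndarray,
    eval_times: np.ndarray,
    tol: float = 1e-4,
) -> Trajectory:
    """Adaptive Dormand–Prince 5(4) solution of the augmented system.

    Integrates from tau = 0 through max(eval_times) — which may exceed 1,
    the extrapolation region — and samples at ``eval_times``. The trailing
    parameter channels stay exactly constant because the field's
    corresponding outputs are exactly zero.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.size == 0:
        raise ValueError("eval_times must be non-empty")
    if eval_times[0] < 0 or np.any(np.diff(eval_times) < 0):
        raise ValueError("eval_times must be ascending and start at >= 0")
    if not tol > 0:
        raise ValueError("tol must be positive")
    y0 = np.concatenate([np.asarray(z0, float).ravel(), np.asarray(p, float).ravel()])
    t_end = float(eval_times[-1])
    if t_end == 0.0:
        states = np.tile(y0, (eval_times.size, 1))
        return Trajectory(eval_times=eval_times, states=states)

    def rhs(_t, y):
        return vf.numpy_eval(y[None, :])[0]

    # integrate segment-by-segment so every requested time is an exact step
    # endpoint (no dense-output interpolation error between large steps)
    grid = np.unique(np.concatenate([[0.0], eval_times]))
    states_at = {0.0: y0}
    y = y0
    for t0, t1 in zip(grid[:-1], grid[1:]):
        sol = solve_ivp(rhs, (t0, t1), y, method="RK45", rtol=tol, atol=tol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}]: {sol.message}",
                state=sol.y[:, -1] if sol.y.size else None,
            )
        y = sol.y[:, -1]
        states_at[t1] = y
    states = np.stack([states_at[t] for t in eval_times])
    return Trajectory(eval_times=eval_times, states=states)


def reduce_to_sld(reducer: Reducer, states: np.ndarray) -> np.ndarray:
    """Apply the reducer to trajectory states (uses only the c latent columns)."""
    return reducer.numpy_eval(np.asarray(states, dtype=float))


def homogeneity_defect(
    vf: VectorField, z: np.ndarray, p: np.ndarray, T: float, eps: float = 1e-12
) -> float:
    """Relative defect of f(z, p*T) = f(z, p)*T; zero for p-linear fields.

    Diagnostic only: the training scheme encourages this identity through
    augmentation but does not enforce it architecturally.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    z = np.asarray(z, float).ravel()
    p = np.asarray(p, float).ravel()
    lhs = vf.numpy_eval(np.concatenate([z, p * T])[None, :])[0]
    rhs = vf.numpy_eval(np.concatenate([z, p])[None, :])[0] * T
    return float(np.linalg.norm(lhs - rhs) / (np.linalg.norm(rhs) + eps))


# ---------------------------------------------------------------------------
# training-time fixed-grid integration (differentiable)
# ---------------------------------------------------------------------------

def plan_steps(horizons: np.ndarray, dtau: float, min_steps: int, max_steps: int):
    """Member-specific uniform step plan: counts and step sizes."""
    horizons = np.asarray(horizons, dtype=float)
    n = np.clip(np.ceil(horizons / dtau).astype(int), min_steps, max_steps)
    h = np.where(horizons > 0, horizons / n, 0.0)
    return n, h


def rk4_batch(
    vf: VectorField,
    state0: Tensor,
    horizons: np.ndarray,
    dtau: float = 0.25,
    min_steps: int = 8,
    max_steps: int = 64,
):
    """Fixed-grid RK4 over a batch, each member on its own uniform grid.

    ``state0``: B x (c+k) tensor of initial augmented states. Returns
    (states, derivs, h, n_steps) where states/derivs are lists of B x (c+k)
    tensors at grid nodes 0..K (K = max step count in batch) and ``derivs``
    holds f at each node for Hermite interpolation. Members that have
    exhausted their own step count are frozen via a gate, so their node
    states never depend on other batch members.
    """
    n_steps, h = plan_steps(horizons, dtau, min_steps, max_steps)
    K = int(n_steps.max())
    hcol = Tensor(h[:, None])
    states = [state0]
    derivs = [vf(state0)]
    y = state0
    for k in range(K):
        active = Tensor((k < n_steps).astype(float)[:, None])
        k1 = derivs[-1]
        k2 = vf(y + (0.5 * hcol) * k1)
        k3 = vf(y + (0.5 * hcol) * k2)
        k4 = vf(y + hcol * k3)
        incr = (hcol * (1.0 / 6.0)) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        y = y + active * incr
        states.append(y)
        derivs.append(vf(y))
    return states, derivs, h, n_steps


def hermite_sample(
    states: list,
    derivs: list,
    h: np.ndarray,
    n_steps: np.ndarray,
    member_idx: np.ndarray,
    taus: np.ndarray,
):
    """Cubic-Hermite read-out of per-member off-grid times.

    ``member_idx[j]`` is the batch row of query ``taus[j]`` (normalized
    time within that member's own grid). Returns an (n_queries) x (c+k)
    tensor. Exact at grid nodes; member-local, so packing-invariant.
    """
    from ._autodiff import stack_rows

    member_idx = np.asarray(member_idx, dtype=int)
    taus = np.asarray(taus, dtype=float)
    hq = h[member_idx]
    # segment index for each query, clamped to the member's own grid
    seg = np.floor_divide(taus, np.where(hq > 0, hq, 1.0)).astype(int)
    seg = np.clip(seg, 0, np.maximum(n_steps[member_idx] - 1, 0))
    theta = np.where(hq > 0, (taus - seg * hq) / np.where(hq > 0, hq, 1.0), 0.0)

    big_states = stack_rows(states)  # (K+1) x B x d
    big_derivs = stack_rows(derivs)
    y0 = big_states[seg, member_idx]
    y1 = big_states[seg + 1, member_idx]
    f0 = big_derivs[seg, member_idx]
    f1 = big_derivs[seg + 1, member_idx]
    th = theta[:, None]
    h00 = 2 * th**3 - 3 * th**2 + 1
    h10 = th**3 - 2 * th**2 + th
    h01 = -2 * th**3 + 3 * th**2
    h11 = th**3 - th**2
    hcol = hq[:, None]
    return (
        y0 * Tensor(h00)
        + f0 * Tensor(h10 * hcol)
        + y1 * Tensor(h01)
        + f1 * Tensor(h11 * hcol)
    )
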