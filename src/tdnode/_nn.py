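"""Neural-network building blocks used by the encoders and the decoder.

Layers are thin containers of :class:`~tdnode._autodiff.Tensor` parameters
with a functional ``__call__``. Recurrent layers (GRU, LSTM) advance their
state only where a per-step binary mask is 1, so left-padded batch members
produce exactly the states they would produce when processed alone; this is
what makes mask-aware packing an exact operation rather than an
approximation.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "ResidualMLP",
    "GRU",
    "LSTM",
    "SingleHeadAttention",
    "Adam",
]


class Module:
    """Base class: parameter registry plus recursive collection."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._subs: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_module(self, name: str, module: "Module") -> "Module":
        self._subs[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, sub in self._subs.items():
            out.update(sub.parameters(prefix + name + "."))
        return out

    def zero_grad(self):
        for p in self.parameters().values():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            if params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            params[k].data = np.asarray(v, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        super().__init__()
        self.w = self.add_param("w", _glorot(rng, n_in, n_out))
        self.b = self.add_param("b", np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class ResidualMLP(Module):
    """Input projection, ``n_blocks`` SELU residual blocks, output projection."""

    def __init__(self, rng, n_in: int, width: int, n_out: int, n_blocks: int):
        super().__init__()
        self.inp = self.add_module("inp", Linear(rng, n_in, width))
        self.blocks = [
            self.add_module(f"block{i}", Linear(rng, width, width))
            for i in range(n_blocks)
        ]
        self.out = self.add_module("out", Linear(rng, width, n_out))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.inp(x).selu()
        for blk in self.blocks:
            h = h + blk(h).selu()
        return self.out(h)


class GRU(Module):
    """Multi-layer gated recurrent unit with mask-gated state updates."""

    def __init__(self, rng, n_in: int, hidden: int, n_layers: int = 2):
        super().__init__()
        self.hidden = hidden
        self.n_layers = n_layers
        self.cells = []
        for layer in range(n_layers):
            d = n_in if layer == 0 else hidden
            cell = {
                "wx": self.add_param(f"l{layer}.wx", _glorot(rng, d, 3 * hidden)),
                "wh": self.add_param(f"l{layer}.wh", _glorot(rng, hidden, 3 * hidden)),
                "b": self.add_param(f"l{layer}.b", np.zeros(3 * hidden)),
            }
            self.cells.append(cell)

    def __call__(self, xs: list[Tensor], mask: np.ndarray) -> Tensor:
        """Run over timesteps ``xs`` (each B x d); mask is B x len(xs).

        Returns the final hidden state of the top layer (B x hidden).
        """
        b = xs[0].shape[0]
        h = [Tensor(np.zeros((b, self.hidden))) for _ in range(self.n_layers)]
        for t, x in enumerate(xs):
            m = Tensor(mask[:, t : t + 1])
            inp = x
            for layer, cell in enumerate(self.cells):
                gates = inp @ cell["wx"] + cell["b"]
                rec = h[layer] @ cell["wh"]
                n_h = self.hidden
                r = (gates[:, :n_h] + rec[:, :n_h]).sigmoid()
                z = (gates[:, n_h : 2 * n_h] + rec[:, n_h : 2 * n_h]).sigmoid()
                n = (gates[:, 2 * n_h :] + r * rec[:, 2 * n_h :]).tanh()
                h_new = (1.0 - z) * n + z * h[layer]
                h[layer] = m * h_new + (1.0 - m) * h[layer]
                inp = h[layer]
        return h[-1]


class LSTM(Module):
    """Single-layer LSTM with mask-gated state updates; returns final hidden."""

    def __init__(self, rng, n_in: int, hidden: int):
        super().__init__()
        self.hidden = hidden
        self.wx = self.add_param("wx", _glorot(rng, n_in, 4 * hidden))
        self.wh = self.add_param("wh", _glorot(rng, hidden, 4 * hidden))
        self.b = self.add_param("b", np.zeros(4 * hidden))

    def __call__(self, xs: list[Tensor], mask: np.ndarray) -> Tensor:
        b = xs[0].shape[0]
        h = Tensor(np.zeros((b, self.hidden)))
        c = Tensor(np.zeros((b, self.hidden)))
        n_h = self.hidden
        for t, x in enumerate(xs):
            m = Tensor(mask[:, t : t + 1])
            gates = x @ self.wx + h @ self.wh + self.b
            i = gates[:, :n_h].sigmoid()
            f = gates[:, n_h : 2 * n_h].sigmoid()
            g = gates[:, 2 * n_h : 3 * n_h].tanh()
            o = gates[:, 3 * n_h :].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
        return h


class SingleHeadAttention(Module):
    """Scaled dot-product attention with one head and padded-row masking."""

    def __init__(self, rng, d_key_in: int, d_value_in: int, d_query_in: int, dim: int):
        super().__init__()
        self.dim = dim
        self.wk = self.add_module("wk", Linear(rng, d_key_in, dim))
        self.wv = self.add_module("wv", Linear(rng, d_value_in, dim))
        self.wq = self.add_module("wq", Linear(rng, d_query_in, dim))

    def __call__(self, query: Tensor, kv_rows: Tensor, rows: int, row_mask: np.ndarray) -> Tensor:
        """query: B x dq; kv_rows: (B*rows) x d_in; row_mask: B x rows."""
        k = self.wk(kv_rows).fold_rows(rows)
        v = self.wv(kv_rows).fold_rows(rows)
        q = self.wq(query)
        scores = q.bdot_qk(k) * (1.0 / np.sqrt(self.dim))
        scores = scores + Tensor((row_mask - 1.0) * 1e9)
        alpha = scores.softmax(axis=1)
        return alpha.bdot_av(v)


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to grads."""

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
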