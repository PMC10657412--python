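"""The two encoders: initial latent state and kinetic metrics.

The *initial-condition encoder* maps a patient's pre-treatment
(time, SLD) pairs through a multi-layer GRU and a fully connected head to
the 4-dimensional latent tumor state at treatment start, z(0). Patients
with no pre-treatment visit contribute their first measurement as the sole
pre-treatment input.

The *parameter encoder* maps the partitioned seen post-treatment pairs
through small width-4 linear preprocessors (keys/values), a residual
stack + LSTM (query), single-head scaled dot-product attention, and a
residual postprocessor to a 2-vector ``raw``. Multiplying ``raw`` by the
patient's temporal scale T (the last seen measurement time, in weeks)
yields the kinetic metrics ``p`` — the quantity that is simultaneously the
decoder's ODE parameter and the per-patient feature used for survival
modelling. Because the encoder consumes only dimensionless inputs, ``p``
scales exactly linearly with the unit of time: measure time in days
instead of weeks and every metric is multiplied by 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import GRU, LSTM, Linear, Module, ResidualMLP, SingleHeadAttention
from .config import ModelDims

__all__ = [
    "InitialState",
    "KineticMetrics",
    "InitialStateEncoder",
    "ParameterEncoder",
    "rescale_kinetics",
]


@dataclass(frozen=True)
class InitialState:
    """4-dimensional latent tumor state at treatment start."""

    z0: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.z0)):
            raise ValueError("initial state must be finite")


@dataclass(frozen=True)
class KineticMetrics:
    """Parameter-encoder output before and after temporal rescaling.

    ``p = raw * T`` elementwise; both are retained because ``raw`` is
    dimensionless while ``p`` carries the patient's time scale.
    """

    raw: np.ndarray  # 2-vector, dimensionless
    p: np.ndarray  # 2-vector, rescaled by T
    T: float  # weeks

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("temporal scale T must be > 0")


def rescale_kinetics(raw: np.ndarray, T: float) -> KineticMetrics:
    """Apply the temporal rescaling p = raw * T."""
    if not T > 0:
        raise ValueError(f"temporal scale T must be > 0, got {T}")
    raw = np.asarray(raw, dtype=float)
    return KineticMetrics(raw=raw, p=raw * T, T=float(T))


class InitialStateEncoder(Module):
    """GRU over pre-treatment (tau, y) pairs -> z(0) in R^c."""

    def __init__(self, rng: np.random.Generator, dims: ModelDims):
        super().__init__()
        self.dims = dims
        self.gru = self.add_module("gru", GRU(rng, 2, dims.gru_hidden, dims.gru_layers))
        self.head = self.add_module("head", Linear(rng, dims.gru_hidden, dims.c))

    def __call__(self, pre_inputs: np.ndarray, pre_mask: np.ndarray,
                 pad_mode: str = "pack") -> Tensor:
        """pre_inputs: B x M x 2 left-padded; returns B x c."""
        if pre_inputs.size == 0:
            raise ValueError("empty pre-treatment input")
        b, m, _ = pre_inputs.shape
        mask = pre_mask if pad_mode == "pack" else np.ones_like(pre_mask)
        xs = [Tensor(pre_inputs[:, t, :]) for t in range(m)]
        h = self.gru(xs, mask)
        return self.head(h)


class ParameterEncoder(Module):
    """Attention-LSTM encoder of partitioned post-treatment pairs -> raw in R^k."""

    def __init__(self, rng: np.random.Generator, dims: ModelDims):
        super().__init__()
        self.dims = dims
        w = dims.pre_width
        self.pre_kv = self.add_module("pre_kv", Linear(rng, 4, w))
        self.pre_q = self.add_module("pre_q", ResidualMLP(rng, 4, w, w, n_blocks=2))
        self.lstm = self.add_module("lstm", LSTM(rng, w, dims.lstm_hidden))
        self.attn = self.add_module(
            "attn", SingleHeadAttention(rng, w, w, dims.lstm_hidden, dims.attn_dim)
        )
        self.post = self.add_module(
            "post",
            ResidualMLP(
                rng, dims.attn_dim + dims.lstm_hidden, dims.post_width, dims.k,
                n_blocks=dims.post_blocks,
            ),
        )

    def __call__(self, part_inputs: np.ndarray, part_mask: np.ndarray,
                 pad_mode: str = "pack") -> Tensor:
        """part_inputs: B x R x 4 left-padded; returns B x k (raw metrics)."""
        b, r, _ = part_inputs.shape
        if r == 0 or not np.any(part_mask):
            raise ValueError("parameter encoder needs >= 1 partition row per member")
        mask = part_mask if pad_mode == "pack" else np.ones_like(part_mask)
        flat = Tensor(part_inputs.reshape(b * r, 4))
        kv = self.pre_kv(flat).selu()
        q_rows = self.pre_q(flat).selu()
        xs = [q_rows.fold_rows(r)[:, t, :] for t in range(r)]
        query = self.lstm(xs, mask)
        attended = self.attn(query, kv, r, mask)
        return self.post(concat([attended, query], axis=1))
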