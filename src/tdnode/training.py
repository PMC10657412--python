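"""End-to-end training of the encoder–decoder on masked RMSE.

All four network modules (both encoders, the vector field, the reducer)
are optimized jointly with Adam on the root-mean-squared error over the
labelled positions of each batch, pooled across batch members. Training
integrates the neural ODE on a fixed per-member grid (see
:mod:`tdnode.decoder`) so gradients flow through the solver; inference
uses the adaptive Dormand–Prince route.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Adam, Module
from .augmentation import (
    AugmentedProfile,
    Batch,
    as_training_profile,
    assemble_batch,
    augment_prefixes,
)
from .cohort import Cohort, NormStats, PatientRecord, fit_norm_stats, normalize_profile
from .config import ModelDims, TrainConfig
from .decoder import Reducer, VectorField, hermite_sample, integrate, rk4_batch
from .encoders import InitialStateEncoder, KineticMetrics, ParameterEncoder, rescale_kinetics

logger = logging.getLogger(__name__)

__all__ = [
    "TDNODENetwork",
    "ModelCheckpoint",
    "masked_rmse",
    "train",
    "predict_profile",
    "encode_record",
]


def masked_rmse(pred: np.ndarray, labels: np.ndarray, mask: np.ndarray) -> float:
    """RMSE over mask-1 positions, pooled across the whole batch."""
    pred, labels, mask = (np.asarray(a, dtype=float) for a in (pred, labels, mask))
    if pred.shape != labels.shape or pred.shape != mask.shape:
        raise ValueError("pred, labels and mask must share a shape")
    n = mask.sum()
    if n == 0:
        raise ValueError("mask selects no positions")
    return float(np.sqrt(np.sum(mask * (pred - labels) ** 2) / n))


class TDNODENetwork(Module):
    """The four trainable modules plus the forward pass used in training."""

    def __init__(self, rng: np.random.Generator, dims: ModelDims):
        super().__init__()
        self.dims = dims
        self.init_enc = self.add_module("init_enc", InitialStateEncoder(rng, dims))
        self.param_enc = self.add_module("param_enc", ParameterEncoder(rng, dims))
        self.vf = self.add_module("vf", VectorField(rng, dims))
        self.reducer = self.add_module("reducer", Reducer(rng, dims))

    def encode(self, batch: Batch) -> tuple[Tensor, Tensor]:
        """Returns (z0: B x c, raw: B x k)."""
        z0 = self.init_enc(batch.pre_inputs, batch.pre_mask, batch.pad_mode)
        raw = self.param_enc(batch.part_inputs, batch.part_mask, batch.pad_mode)
        return z0, raw

    def predict_pairs(self, batch: Batch, cfg: TrainConfig):
        """Differentiable predictions at every labelled (member, time) pair.

        Returns (pred: n_pairs tensor, member_idx, label_values).
        """
        z0, raw = self.encode(batch)
        # the decoder works in per-patient rescaled time, where the relevant
        # parameter group is dimensionless: the raw encoding plays the role
        # of p*T in the rescaled-time field, while the reported kinetic
        # metrics are raw*T (units of the original time axis)
        state0 = concat([z0, raw], axis=1)
        states, derivs, h, n_steps = rk4_batch(
            self.vf, state0, batch.horizon, cfg.train_dtau,
            cfg.train_min_steps, cfg.train_max_steps,
        )
        rows, cols = np.nonzero(batch.mask)
        taus = batch.union_times[cols]
        sampled = hermite_sample(states, derivs, h, n_steps, rows, taus)
        pred = self.reducer(sampled[:, : self.dims.c])
        return pred.reshape(len(rows)), rows, batch.labels[rows, cols]

    def loss(self, batch: Batch, cfg: TrainConfig) -> Tensor:
        pred, _, labels = self.predict_pairs(batch, cfg)
        err = pred - Tensor(labels)
        return (err * err).mean().sqrt()


@dataclass
class ModelCheckpoint:
    """Weights + normalization statistics + configuration + loss history."""

    network: TDNODENetwork
    stats: NormStats
    config: TrainConfig
    loss_history: list = field(default_factory=list)
    n_optimizer_steps: int = 0  # actual Adam steps taken during training

    def save(self, directory: str | Path) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.network.state_dict())
        manifest = {
            "config": self.config.to_dict(),
            "norm_stats": {"mu": self.stats.mu, "sigma": self.stats.sigma},
            "loss_history": [float(x) for x in self.loss_history],
            "n_optimizer_steps": self.n_optimizer_steps,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return d

    @classmethod
    def load(cls, directory: str | Path) -> "ModelCheckpoint":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        config = TrainConfig.from_dict(manifest["config"])
        network = TDNODENetwork(np.random.default_rng(0), config.dims)
        with np.load(d / "weights.npz") as z:
            network.load_state_dict({k: z[k] for k in z.files})
        stats = NormStats(**manifest["norm_stats"])
        return cls(network=network, stats=stats, config=config,
                   loss_history=manifest["loss_history"],
                   n_optimizer_steps=manifest.get("n_optimizer_steps", 0))


def _augment_cohort(cohort: Cohort, stats: NormStats) -> list[AugmentedProfile]:
    """Deterministic augmentation order: subject id, then prefix length."""
    out: list[AugmentedProfile] = []
    for record in sorted(cohort, key=lambda r: r.subject_id):
        out.extend(augment_prefixes(record, stats))
    return out


def train(
    train_cohort: Cohort,
    config: TrainConfig,
    callback=None,
) -> ModelCheckpoint:
    """Fit the network on an eligible cohort with the prefix-augmented loss.

    Shuffling, initialization and therefore the entire loss history are
    determined by ``config.seed``. Raises on a non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    network = TDNODENetwork(rng, config.dims)
    stats = fit_norm_stats(train_cohort)
    profiles = _augment_cohort(train_cohort, stats)
    if not profiles:
        raise ValueError("augmentation produced no training profiles")
    optimizer = Adam(network.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history = []
    n_steps = 0
    n = len(profiles)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            members = [profiles[i] for i in order[start : start + config.batch_size]]
            batch = assemble_batch(members, pad_mode=config.pad_mode)
            network.zero_grad()
            loss = network.loss(batch, config)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={value}"
                )
            loss.backward()
            optimizer.step()
            n_steps += 1
            epoch_losses.append(value)
        history.append(float(np.mean(epoch_losses)))
        logger.info("epoch %d/%d: masked RMSE %.4f", epoch + 1, config.epochs, history[-1])
        if callback is not None:
            callback(epoch, history[-1])
    return ModelCheckpoint(network=network, stats=stats, config=config,
                           loss_history=history, n_optimizer_steps=n_steps)


def encode_record(
    network: TDNODENetwork,
    stats: NormStats,
    record: PatientRecord,
    window: float,
    pad_mode: str = "pack",
) -> tuple[np.ndarray, KineticMetrics]:
    """Encode one record: returns (z0, kinetic metrics with p = raw * T)."""
    profile = normalize_profile(record, stats, window)
    batch = assemble_batch([as_training_profile(profile)], pad_mode=pad_mode)
    z0, raw = network.encode(batch)
    metrics = rescale_kinetics(raw.data[0], profile.T)
    return z0.data[0], metrics


def predict_profile(
    checkpoint: ModelCheckpoint,
    record: PatientRecord,
    window: float | None = None,
    query_times: np.ndarray | None = None,
) -> np.ndarray:
    """Predicted SLD (mm) at ``query_times`` (weeks, >= 0).

    Normalizes with the checkpoint statistics, encodes the record truncated
    to the observation window, integrates the learned dynamics adaptively
    to the last query time (estimates inside the window, extrapolations
    beyond it) and denormalizes the reduced solution.
    """
    window = checkpoint.config.window if window is None else window
    if query_times is None:
        query_times = record.times[record.times >= 0]
    query_times = np.asarray(query_times, dtype=float)
    if np.any(query_times < 0):
        raise ValueError("query times must be >= 0 (treatment start)")
    profile = normalize_profile(record, checkpoint.stats, window)
    z0, metrics = encode_record(
        checkpoint.network, checkpoint.stats, record, window, checkpoint.config.pad_mode
    )
    order = np.argsort(query_times, kind="stable")
    taus = query_times[order] / profile.T
    traj = integrate(checkpoint.network.vf, z0, metrics.raw, taus, tol=checkpoint.config.ode_tol)
    sld_norm = checkpoint.network.reducer.numpy_eval(traj.states)
    out = np.empty_like(sld_norm)
    out[order] = checkpoint.stats.denormalize(sld_norm)
    return out
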