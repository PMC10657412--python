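"""Training-distribution construction: prefix augmentation, partitioning, batching.

Augmentation generates, for each patient, every truncation of their series
to its first ``j`` measurements (j = 2..m), each renormalized by its own
temporal scale T = time of the j-th measurement, while the training labels
still span the *full* parent horizon. Because the kinetic encoding is
multiplied by T, each prefix presents the same dynamics under a different
time scaling, which both teaches extrapolation and imposes the
time-rescaling (generalized homogeneity) structure on the learned field.

Partitioning turns the seen post-treatment points (indices beta..l) into
rows of adjacent (time, SLD) pairs — the parameter encoder's input format.
Batching left-pads heterogeneous members and carries binary masks; in the
default ``pack`` mode the masks gate recurrent-state updates so batched
computation is exactly equal to per-patient computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .cohort import NormalizedProfile, NormStats, PatientRecord

logger = logging.getLogger(__name__)

PadMode = Literal["pack", "repeat-first"]

__all__ = [
    "AugmentedProfile",
    "PartitionedInput",
    "Batch",
    "augment_prefixes",
    "as_training_profile",
    "partition_post_treatment",
    "assemble_batch",
]


@dataclass(frozen=True)
class AugmentedProfile:
    """One prefix-truncated, prefix-rescaled view of a parent record.

    ``profile`` holds all m parent measurements normalized by this prefix's
    T, with ``l == prefix_length``; labels are the measurements from index
    beta onward (the decoder's domain starts at tau = 0, and the last
    pre-treatment point is assigned tau = 0 by convention).
    """

    parent_id: str
    prefix_length: int  # j: number of measurements fed to the parameter encoder
    profile: NormalizedProfile
    label_tau: np.ndarray  # prefix-normalized label times, first entry 0
    label_y: np.ndarray  # Z-scored label SLD values

    def __post_init__(self):
        if self.prefix_length < 2:
            raise ValueError("prefix_length must be >= 2")

    @property
    def n_labels(self) -> int:
        return len(self.label_tau)

    @property
    def horizon(self) -> float:
        """Normalized integration end time (may exceed 1: extrapolation)."""
        return float(self.label_tau[-1])


@dataclass(frozen=True)
class PartitionedInput:
    """(s-1) x 4 matrix of adjacent seen (time, SLD) pairs, tau[beta] := 0."""

    rows: np.ndarray

    def __post_init__(self):
        if self.rows.ndim != 2 or self.rows.shape[1] != 4:
            raise ValueError("partitioned input must have shape (s-1, 4)")


@dataclass
class Batch:
    """Padded stacks + masks for a list of augmented profiles."""

    pre_inputs: np.ndarray  # B x M_pre_max x 2, left-padded
    pre_mask: np.ndarray  # B x M_pre_max
    part_inputs: np.ndarray  # B x (S_max - 1) x 4, left-padded
    part_mask: np.ndarray  # B x (S_max - 1)
    union_times: np.ndarray  # ascending union of all members' label times
    labels: np.ndarray  # B x L
    mask: np.ndarray  # B x L binary
    T: np.ndarray  # B, per-member temporal scale (weeks)
    horizon: np.ndarray  # B, per-member normalized integration end
    pad_mode: PadMode = "pack"

    @property
    def size(self) -> int:
        return self.labels.shape[0]


def _prefix_profile(record: PatientRecord, stats: NormStats, j: int) -> NormalizedProfile | None:
    """Normalize ``record`` as if its j-th measurement were the last seen one."""
    times = record.times
    T = float(times[j - 1])
    if T <= 0:
        return None
    pre = np.nonzero(times <= 0)[0]
    beta = int(pre[-1]) + 1 if pre.size else 1
    tau = times / T
    tau[j - 1] = 1.0
    return NormalizedProfile(
        subject_id=record.subject_id,
        tau_tilde=tau,
        y_tilde=stats.normalize(record.sld),
        beta=min(beta, j),
        l=j,
        T=T,
        window=T,
        m=record.m,
    )


def _labels_for(profile: NormalizedProfile) -> tuple[np.ndarray, np.ndarray]:
    tau = profile.tau_tilde[profile.beta - 1 :].copy()
    tau[0] = 0.0  # tau_tilde[beta] := 0 convention
    return tau, profile.y_tilde[profile.beta - 1 :].copy()


def augment_prefixes(record: PatientRecord, stats: NormStats) -> list[AugmentedProfile]:
    """All prefix truncations j = 2..m of one eligible record.

    Prefixes whose last time is <= 0 (temporal scale would be non-positive)
    are skipped with a warning; they cannot occur when post-treatment visits
    have strictly positive times.
    """
    if record.m < 2:
        raise ValueError(f"{record.subject_id}: need >= 2 measurements to augment")
    out = []
    for j in range(2, record.m + 1):
        profile = _prefix_profile(record, stats, j)
        if profile is None:
            logger.warning(
                "%s: prefix j=%d has non-positive scale; skipped", record.subject_id, j
            )
            continue
        tau, y = _labels_for(profile)
        out.append(
            AugmentedProfile(
                parent_id=record.subject_id,
                prefix_length=j,
                profile=profile,
                label_tau=tau,
                label_y=y,
            )
        )
    return out


def as_training_profile(profile: NormalizedProfile) -> AugmentedProfile:
    """Wrap a window-normalized profile as a single full-horizon member."""
    tau, y = _labels_for(profile)
    return AugmentedProfile(
        parent_id=profile.subject_id,
        prefix_length=profile.l,
        profile=profile,
        label_tau=tau,
        label_y=y,
    )


def partition_post_treatment(profile: NormalizedProfile) -> PartitionedInput:
    """Adjacent-pair rows over the seen range beta..l, with tau[beta] -> 0."""
    s = profile.n_seen
    if s < 2:
        raise ValueError(f"{profile.subject_id}: need >= 2 seen points, got {s}")
    tau = profile.tau_tilde[profile.beta - 1 : profile.l].copy()
    y = profile.y_tilde[profile.beta - 1 : profile.l]
    tau[0] = 0.0
    rows = np.column_stack([tau[:-1], y[:-1], tau[1:], y[1:]])
    return PartitionedInput(rows=rows)


def _pre_pairs(profile: NormalizedProfile) -> np.ndarray:
    """Pre-treatment (tau, y) pairs, indices 1..beta (>= 1 by the beta fallback)."""
    b = profile.beta
    return np.column_stack([profile.tau_tilde[:b], profile.y_tilde[:b]])


def assemble_batch(
    profiles: Sequence[AugmentedProfile], pad_mode: PadMode = "pack"
) -> Batch:
    """Stack members into left-padded tensors with masks and a union time grid.

    With ``pad_mode="pack"`` pad entries are zeros and are screened out of
    every downstream computation exactly. ``repeat-first`` replicates each
    member's first observation pair into the pads (and lets recurrent
    encoders consume them), trading exact batch invariance for fidelity to
    the padding scheme the architecture was originally described with.
    """
    if len(profiles) == 0:
        raise ValueError("cannot assemble an empty batch")
    b = len(profiles)
    pre = [_pre_pairs(p.profile) for p in profiles]
    parts = [partition_post_treatment(p.profile).rows for p in profiles]
    m_pre = max(x.shape[0] for x in pre)
    m_part = max(x.shape[0] for x in parts)

    pre_inputs = np.zeros((b, m_pre, 2))
    pre_mask = np.zeros((b, m_pre))
    part_inputs = np.zeros((b, m_part, 4))
    part_mask = np.zeros((b, m_part))
    for i, (pp, pr) in enumerate(zip(pre, parts)):
        pre_inputs[i, m_pre - pp.shape[0] :] = pp
        pre_mask[i, m_pre - pp.shape[0] :] = 1.0
        part_inputs[i, m_part - pr.shape[0] :] = pr
        part_mask[i, m_part - pr.shape[0] :] = 1.0
        if pad_mode == "repeat-first":
            pre_inputs[i, : m_pre - pp.shape[0]] = pp[0]
            part_inputs[i, : m_part - pr.shape[0]] = pr[0]

    union_times = np.unique(np.concatenate([p.label_tau for p in profiles]))
    L = len(union_times)
    labels = np.zeros((b, L))
    mask = np.zeros((b, L))
    for i, p in enumerate(profiles):
        idx = np.searchsorted(union_times, p.label_tau)
        labels[i, idx] = p.label_y
        mask[i, idx] = 1.0
    return Batch(
        pre_inputs=pre_inputs,
        pre_mask=pre_mask,
        part_inputs=part_inputs,
        part_mask=part_mask,
        union_times=union_times,
        labels=labels,
        mask=mask,
        T=np.array([p.profile.T for p in profiles]),
        horizon=np.array([p.horizon for p in profiles]),
        pad_mode=pad_mode,
    )
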