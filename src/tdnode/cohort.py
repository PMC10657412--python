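"""Longitudinal tumor-size cohorts: reading, eligibility, splitting, normalization.

The raw data are long-format tables of sum-of-longest-diameters (SLD, mm)
measurements per subject, with measurement time in weeks relative to
treatment start (negative = pre-treatment). This module turns them into
validated :class:`PatientRecord` collections and produces the per-patient
quantities the rest of the pipeline depends on:

* Z-scored SLD using training-cohort mean/sd (``y_tilde``),
* per-patient time rescaling by the last *seen* measurement time ``T``
  (``tau_tilde``, dimensionless, equal to 1 at the last seen point),
* the semantic indices ``beta`` (last pre-treatment measurement, 1-based)
  and ``l`` (last measurement inside the observation window, 1-based).

The observation window ``w`` (default 32 weeks) divides measurements into
*seen* (time <= w, model input) and *unseen* (extrapolation targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 32.0

__all__ = [
    "PatientRecord",
    "NormStats",
    "NormalizedProfile",
    "Cohort",
    "CohortFormatError",
    "CohortValidationError",
    "EmptyCohortError",
    "DegenerateCohortError",
    "UnscalableProfileError",
    "read_cohort",
    "filter_eligible",
    "split_train_test",
    "fit_norm_stats",
    "normalize_profile",
    "DEFAULT_WINDOW",
]


class CohortFormatError(ValueError):
    """Input table is structurally malformed (e.g. missing columns)."""


class CohortValidationError(ValueError):
    """Input table violates a record invariant (duplicates, bad values)."""


class EmptyCohortError(ValueError):
    """An operation produced or received a cohort with no usable patients."""


class DegenerateCohortError(ValueError):
    """Training cohort carries no SLD variance; Z-scoring is undefined."""


class UnscalableProfileError(ValueError):
    """Patient has no strictly positive seen time, so the time scale T <= 0."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject's measurement series plus optional survival/covariates."""

    subject_id: str
    times: np.ndarray  # weeks, strictly increasing; treatment start = 0
    sld: np.ndarray  # mm, same length
    arm: str = "arm1"
    os_time: Optional[float] = None  # weeks
    os_event: Optional[int] = None  # 1 = death observed
    covariates: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        sld = np.asarray(self.sld, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "sld", sld)
        if times.shape != sld.shape or times.ndim != 1:
            raise CohortValidationError(
                f"{self.subject_id}: times and sld must be 1-D and equal length"
            )
        if len(times) and np.any(np.diff(times) <= 0):
            raise CohortValidationError(f"{self.subject_id}: times must be strictly increasing")
        if np.any(sld < 0) or np.any(~np.isfinite(sld)):
            raise CohortValidationError(f"{self.subject_id}: SLD must be finite and >= 0")
        if self.os_time is not None and self.os_time < 0:
            raise CohortValidationError(f"{self.subject_id}: os_time must be >= 0")

    @property
    def m(self) -> int:
        """Number of measurements."""
        return len(self.times)

    def n_post_treatment(self) -> int:
        return int(np.sum(self.times >= 0))

    def with_times(self, times: np.ndarray) -> "PatientRecord":
        return replace(self, times=np.asarray(times, dtype=float))


@dataclass(frozen=True)
class NormStats:
    """Training-cohort SLD mean and sample standard deviation (mm)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise DegenerateCohortError("sigma must be > 0")

    def normalize(self, sld: np.ndarray) -> np.ndarray:
        return (np.asarray(sld, dtype=float) - self.mu) / self.sigma

    def denormalize(self, y_tilde: np.ndarray) -> np.ndarray:
        return np.asarray(y_tilde, dtype=float) * self.sigma + self.mu


@dataclass(frozen=True)
class NormalizedProfile:
    """A patient's series in normalized coordinates.

    ``beta`` and ``l`` are 1-based semantic indices (matching the way they
    are reported); array access uses ``beta - 1`` / ``l - 1``.
    """

    subject_id: str
    tau_tilde: np.ndarray  # dimensionless times, tau_tilde[l-1] == 1
    y_tilde: np.ndarray  # Z-scored SLD
    beta: int  # last pre-treatment index (1-based); 1 if no pre-treatment data
    l: int  # last seen index (1-based)
    T: float  # temporal scale: last seen measurement time (weeks)
    window: float  # observation window (weeks)
    m: int  # total measurement count

    @property
    def n_seen(self) -> int:
        """Number of points fed to the parameter encoder (indices beta..l)."""
        return self.l - self.beta + 1


@dataclass
class Cohort:
    """A collection of patient records with unique subject ids."""

    records: list[PatientRecord] = field(default_factory=list)
    tag: str = "cohort"

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, subject_id: str) -> PatientRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for t, y in zip(r.times, r.sld):
                rows.append({"subject_id": r.subject_id, "time_weeks": t, "sld_mm": y})
        return pd.DataFrame(rows)


_MEAS_COLS = ["subject_id", "time_weeks", "sld_mm"]
_SURV_COLS = ["subject_id", "os_weeks", "event"]


def read_cohort(
    path: str | Path,
    survival_path: str | Path | None = None,
    covariate_path: str | Path | None = None,
    tag: str = "cohort",
) -> Cohort:
    """Read a measurement table (CSV), optionally joining survival/covariates.

    Required measurement columns: ``subject_id,time_weeks,sld_mm``. Rows may
    be in any order; each record's series is sorted by time. Duplicate
    (subject, time) pairs and non-numeric SLD values raise
    :class:`CohortValidationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MEAS_COLS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    for col in ("time_weeks", "sld_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad = df.loc[coerced.isna() & df[col].notna(), "subject_id"].unique()
            raise CohortValidationError(f"non-numeric {col} for subjects {list(bad)}")
        df[col] = coerced
    dup = df.duplicated(subset=["subject_id", "time_weeks"], keep=False)
    if dup.any():
        bad = sorted(df.loc[dup, "subject_id"].unique())
        raise CohortValidationError(f"duplicate (subject_id, time) rows for {bad}")

    surv = None
    if survival_path is not None:
        surv = pd.read_csv(survival_path)
        missing = [c for c in _SURV_COLS if c not in surv.columns]
        if missing:
            raise CohortFormatError(f"{survival_path}: missing columns {missing}")
        surv = surv.set_index("subject_id")
    cov = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path)
        if "subject_id" not in cov.columns:
            raise CohortFormatError(f"{covariate_path}: missing subject_id column")
        cov = cov.set_index("subject_id")

    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_weeks")
        os_time = os_event = None
        if surv is not None and sid in surv.index:
            os_time = float(surv.loc[sid, "os_weeks"])
            os_event = int(surv.loc[sid, "event"])
        covariates = None
        if cov is not None and sid in cov.index:
            covariates = {k: float(v) for k, v in cov.loc[sid].items()}
        arm = str(grp["arm"].iloc[0]) if "arm" in grp.columns else "arm1"
        records.append(
            PatientRecord(
                subject_id=str(sid),
                times=grp["time_weeks"].to_numpy(),
                sld=grp["sld_mm"].to_numpy(),
                arm=arm,
                os_time=os_time,
                os_event=os_event,
                covariates=covariates,
            )
        )
    return Cohort(records=records, tag=tag)


def filter_eligible(cohort: Cohort) -> Cohort:
    """Drop patients with <= 1 post-treatment (time >= 0) measurement.

    Longitudinal modelling needs at least two on-treatment points; the
    filter is idempotent.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot filter an empty cohort")
    kept = [r for r in cohort if r.n_post_treatment() >= 2]
    removed = len(cohort) - len(kept)
    if removed:
        logger.info("filter_eligible: removed %d of %d patients", removed, len(cohort))
    if not kept:
        raise EmptyCohortError("all patients excluded by eligibility filter")
    return Cohort(records=kept, tag=cohort.tag)


def split_train_test(
    cohort: Cohort, train_fraction: float = 0.8, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Random subject-level train/test partition; deterministic given seed."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(cohort)
    if n < 2:
        raise EmptyCohortError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    train_idx = set(order[:n_train].tolist())
    train = [cohort.records[i] for i in sorted(train_idx)]
    test = [cohort.records[i] for i in range(n) if i not in train_idx]
    return Cohort(records=train, tag="train"), Cohort(records=test, tag="test")


def fit_norm_stats(train: Cohort) -> NormStats:
    """Mean and sample sd (n-1) of all training SLD values, pre and post."""
    values = np.concatenate([r.sld for r in train]) if len(train) else np.array([])
    if values.size < 2:
        raise EmptyCohortError("need >= 2 measurements to fit normalization stats")
    sigma = float(np.std(values, ddof=1))
    if sigma == 0.0:
        raise DegenerateCohortError("all training SLD values identical (sigma = 0)")
    return NormStats(mu=float(np.mean(values)), sigma=sigma)


def normalize_profile(
    record: PatientRecord, stats: NormStats, window: float = DEFAULT_WINDOW
) -> NormalizedProfile:
    """Normalize one record: Z-score SLD and rescale times by the last seen time.

    ``l`` is the largest index with time <= window; ``T`` is the largest
    seen time, and every time (seen or not) is divided by ``T``, so unseen
    measurements map beyond 1. Raises :class:`UnscalableProfileError` when
    the patient has no strictly positive seen time (T would be <= 0).
    """
    times = record.times
    if record.m < 2:
        raise CohortValidationError(f"{record.subject_id}: need >= 2 measurements")
    seen = np.nonzero(times <= window)[0]
    if seen.size == 0:
        raise UnscalableProfileError(
            f"{record.subject_id}: no measurement inside window {window}"
        )
    l = int(seen[-1]) + 1  # 1-based
    T = float(np.max(times[:l]))
    if T <= 0:
        raise UnscalableProfileError(
            f"{record.subject_id}: last seen time {T} <= 0; cannot rescale"
        )
    pre = np.nonzero(times <= 0)[0]
    beta = int(pre[-1]) + 1 if pre.size else 1
    tau_tilde = times / T
    tau_tilde[l - 1] = 1.0  # exact by construction (times[l-1] == T)
    return NormalizedProfile(
        subject_id=record.subject_id,
        tau_tilde=tau_tilde,
        y_tilde=stats.normalize(record.sld),
        beta=beta,
        l=l,
        T=T,
        window=float(window),
        m=record.m,
    )
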