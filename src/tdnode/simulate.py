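"""Synthetic clinical-trial generator with known kinetic ground truth.

Tumor trajectories follow the classical biexponential tumor-growth-
inhibition (TGI) model

    y(t) = y0 * (exp(KG * t) + exp(-KS * t) - 1),   t >= 0
    y(t) = y0 * exp(KG * t),                        t < 0

with growth rate KG and shrinkage rate KS (1/week) — exactly the kinetic
quantities classical TGI analyses estimate, which makes parameter-recovery
experiments against the learned metrics meaningful. Overall survival is
linked to the kinetics through a proportional-hazards (exponential) model
with log hazard b0 + bG*log KG + bS*log KS, administratively censored.

A cohort consists of three treatment arms differing in their (KG, KS)
log-normal medians, visits at a fixed interval with uniform jitter, one
pre-treatment visit, proportional + additive measurement noise, and
synthetic baseline covariates correlated with the kinetics (stand-ins for
real trial covariates). Every emitted patient has at least two
post-treatment visits, and all randomness derives from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientRecord

__all__ = [
    "TGIParams",
    "ArmSpec",
    "SimConfig",
    "tgi_trajectory",
    "simulate_patient",
    "nadir_time",
    "simulate_os_time",
    "simulate_trial",
]


@dataclass(frozen=True)
class TGIParams:
    """Patient-level kinetic parameters of the biexponential TGI model."""

    y0: float  # baseline SLD, mm
    KG: float  # growth rate, 1/week
    KS: float  # shrinkage rate, 1/week

    def __post_init__(self):
        if not self.y0 > 0:
            raise ValueError("y0 must be > 0")
        if self.KG < 0 or self.KS < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """Log-normal (median, CV) for each kinetic rate in one treatment arm."""

    name: str
    kg_median: float
    ks_median: float
    kg_cv: float = 0.4
    ks_cv: float = 0.4


@dataclass(frozen=True)
class SimConfig:
    """Trial-level simulation settings (defaults emulate a three-arm trial)."""

    n_patients: int = 300
    arms: tuple = (
        ArmSpec("arm1", kg_median=0.02, ks_median=0.02),
        ArmSpec("arm2", kg_median=0.01, ks_median=0.04),
        ArmSpec("arm3", kg_median=0.005, ks_median=0.08),
    )
    y0_median: float = 60.0  # mm
    y0_cv: float = 0.4
    noise_prop: float = 0.10  # proportional measurement noise SD
    noise_add: float = 2.0  # additive noise SD, mm
    visit_interval: float = 6.0  # weeks
    visit_jitter: float = 1.0  # uniform +- jitter, weeks
    max_follow_up: float = 104.0  # weeks
    pre_treatment_offset: float = -4.0  # weeks
    beta0: float = -4.3  # baseline log hazard
    beta_g: float = 1.0  # effect of log KG on log hazard
    beta_s: float = -1.0  # effect of log KS on log hazard
    censor_time: float = 130.0  # administrative censoring, weeks
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("y0_median", "visit_interval", "max_follow_up", "censor_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def tgi_trajectory(params: TGIParams, times: np.ndarray) -> np.ndarray:
    """Noiseless biexponential SLD at the given times (weeks)."""
    t = np.asarray(times, dtype=float)
    post = params.y0 * (np.exp(params.KG * t) + np.exp(-params.KS * t) - 1.0)
    pre = params.y0 * np.exp(params.KG * t)
    return np.where(t >= 0, post, pre)


def nadir_time(params: TGIParams) -> Optional[float]:
    """Time of the interior trajectory minimum: ln(KS/KG)/(KG+KS).

    Defined only when KS > KG > 0 (otherwise the post-treatment derivative
    never changes sign and there is no interior nadir). Raises when both
    rates are zero.
    """
    if params.KG == 0 and params.KS == 0:
        raise ValueError("nadir undefined for KG = KS = 0")
    if params.KG > 0 and params.KS > params.KG:
        return float(np.log(params.KS / params.KG) / (params.KG + params.KS))
    return None


def log_hazard(params: TGIParams, config: SimConfig) -> float:
    return config.beta0 + config.beta_g * np.log(params.KG) + config.beta_s * np.log(params.KS)


def simulate_os_time(
    params: TGIParams, config: SimConfig, rng: np.random.Generator
) -> tuple[float, int]:
    """Exponential proportional-hazards draw with administrative censoring."""
    rate = float(np.exp(log_hazard(params, config)))
    t = rng.exponential(1.0 / rate)
    if t > config.censor_time:
        return config.censor_time, 0
    return float(t), 1


def _visit_times(config: SimConfig, rng: np.random.Generator, horizon: float) -> np.ndarray:
    """One pre-treatment visit plus jittered post-treatment visits < horizon."""
    post = []
    k = 1
    while k * config.visit_interval <= config.max_follow_up:
        t = k * config.visit_interval + rng.uniform(-config.visit_jitter, config.visit_jitter)
        if t < horizon:
            post.append(t)
        k += 1
    return np.concatenate([[config.pre_treatment_offset], np.sort(post)])


def simulate_patient(
    params: TGIParams,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    arm: str = "arm1",
    os_time: Optional[float] = None,
    os_event: Optional[int] = None,
    covariates=None,
) -> PatientRecord:
    """One patient: jittered visit schedule, noisy SLD, clamped at zero.

    Visits stop at min(max follow-up, survival time). Note the visit draw
    consumes rng state even for visits beyond the horizon, so schedules are
    comparable across patients with different survival times.
    """
    horizon = config.max_follow_up if os_time is None else min(config.max_follow_up, os_time)
    times = _visit_times(config, rng, horizon)
    clean = tgi_trajectory(params, times)
    noisy = clean * (1.0 + config.noise_prop * rng.standard_normal(times.size))
    noisy = noisy + config.noise_add * rng.standard_normal(times.size)
    return PatientRecord(
        subject_id=subject_id,
        times=times,
        sld=np.maximum(noisy, 0.0),
        arm=arm,
        os_time=os_time,
        os_event=os_event,
        covariates=covariates,
    )


def _lognormal(rng, median: float, cv: float) -> float:
    sigma = float(np.sqrt(np.log(1.0 + cv**2)))
    return float(median * np.exp(sigma * rng.standard_normal()))


def _draw_covariates(params: TGIParams, lh: float, rng) -> dict[str, float]:
    """Synthetic baseline covariates, noisily correlated with the kinetics."""
    return {
        "baseline_sld": params.y0 * (1.0 + 0.05 * rng.standard_normal()),
        "growth_marker": float(np.log(params.KG) + 0.5 * rng.standard_normal()),
        "inflam_marker": float(lh + 0.7 * rng.standard_normal()),
        "age": float(rng.uniform(35.0, 85.0)),
        "ecog": float(rng.random() < 1.0 / (1.0 + np.exp(-(lh + 3.0)))),
    }


def simulate_trial(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a full cohort; returns (cohort, ground-truth table).

    Patients are assigned round-robin to arms; draws that would fail the
    eligibility rule (fewer than two post-treatment visits, e.g. very early
    deaths) are redrawn, so every emitted record is eligible. When
    ``out_dir`` is given, writes ``measurements.csv``, ``survival.csv``,
    ``covariates.csv`` and ``truth.csv``.
    """
    rng = np.random.default_rng(config.seed)
    records, truth_rows = [], []
    max_attempts = 200 * config.n_patients
    attempts = 0
    i = 0
    while len(records) < config.n_patients:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("simulation config yields too few eligible patients")
        arm = config.arms[i % len(config.arms)]
        params = TGIParams(
            y0=_lognormal(rng, config.y0_median, config.y0_cv),
            KG=_lognormal(rng, arm.kg_median, arm.kg_cv),
            KS=_lognormal(rng, arm.ks_median, arm.ks_cv),
        )
        os_time, os_event = simulate_os_time(params, config, rng)
        lh = log_hazard(params, config)
        sid = f"sim{len(records):04d}"
        rec = simulate_patient(
            params, config, rng, subject_id=sid, arm=arm.name,
            os_time=os_time, os_event=os_event,
            covariates=_draw_covariates(params, lh, rng),
        )
        if rec.n_post_treatment() < 2:
            continue  # redraw; this subject would be excluded by eligibility
        records.append(rec)
        nd = nadir_time(params)
        truth_rows.append(
            {
                "subject_id": sid,
                "arm": arm.name,
                "y0": params.y0,
                "KG": params.KG,
                "KS": params.KS,
                "nadir_weeks": np.nan if nd is None else nd,
                "log_hazard": lh,
            }
        )
        i += 1
    cohort = Cohort(records=records, tag="synthetic")
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        meas = []
        for r in records:
            for t, y in zip(r.times, r.sld):
                meas.append({"subject_id": r.subject_id, "time_weeks": t, "sld_mm": y, "arm": r.arm})
        pd.DataFrame(meas).to_csv(d / "measurements.csv", index=False)
        pd.DataFrame(
            [
                {"subject_id": r.subject_id, "os_weeks": r.os_time, "event": r.os_event}
                for r in records
            ]
        ).to_csv(d / "survival.csv", index=False)
        pd.DataFrame(
            [{"subject_id": r.subject_id, **r.covariates} for r in records]
        ).to_csv(d / "covariates.csv", index=False)
        truth.to_csv(d / "truth.csv", index=False)
    return cohort, truth
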