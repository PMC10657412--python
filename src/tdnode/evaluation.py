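"""Goodness-of-fit protocol: bootstrapped RMSE/R², residual bias curves,
window-sweep extrapolation reports.

Predictions are compared to observations only at post-treatment
measurement times; metrics are computed in mm (denormalized). Measurements
inside the observation window are *seen* (estimates), beyond it *unseen*
(extrapolations). Variability is summarized as median ± median absolute
deviation (MAD) over bootstrap resamples of prediction–label pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import Cohort, UnscalableProfileError
from .training import ModelCheckpoint, predict_profile

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSummary",
    "ResidualCurve",
    "build_prediction_set",
    "bootstrap_fit_metrics",
    "residual_time_curve",
    "windowed_extrapolation_report",
]


@dataclass(frozen=True)
class MetricSummary:
    """Bootstrap median ± MAD of RMSE and R² for one stratum."""

    stratum: str
    n_rows: int
    rmse_median: float
    rmse_mad: float
    r2_median: float
    r2_mad: float


@dataclass(frozen=True)
class ResidualCurve:
    """LOWESS-smoothed residual (predicted - observed) vs time with 95% band."""

    grid: np.ndarray
    median: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def covers_zero(self) -> float:
        """Fraction of grid points whose band contains zero."""
        return float(np.mean((self.lo <= 0.0) & (self.hi >= 0.0)))


def build_prediction_set(
    checkpoint: ModelCheckpoint, cohort: Cohort, window: float
) -> pd.DataFrame:
    """One row per post-treatment measurement: observed vs predicted SLD (mm).

    Patients that cannot be normalized under this window (no usable seen
    point, or a single seen point) are skipped with a log message.
    """
    rows = []
    for record in cohort:
        post = record.times >= 0
        if post.sum() == 0:
            continue
        try:
            pred = predict_profile(checkpoint, record, window, record.times[post])
        except (UnscalableProfileError, ValueError) as exc:
            logger.info("skipping %s under window %s: %s", record.subject_id, window, exc)
            continue
        for t, obs, pr in zip(record.times[post], record.sld[post], pred):
            rows.append(
                {
                    "subject_id": record.subject_id,
                    "arm": record.arm,
                    "time_weeks": float(t),
                    "observed": float(obs),
                    "predicted": float(pr),
                    "seen": bool(t <= window),
                }
            )
    return pd.DataFrame(rows)


def _rmse_r2(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return rmse, r2


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def bootstrap_fit_metrics(
    preds: pd.DataFrame, n_boot: int = 1000, seed: int = 0, stratum: str = "all"
) -> MetricSummary:
    """Median ± MAD of RMSE and R² over pair resamples with replacement."""
    if len(preds) < 2:
        raise ValueError("need >= 2 prediction rows")
    obs = preds["observed"].to_numpy()
    pred = preds["predicted"].to_numpy()
    rng = np.random.default_rng(seed)
    n = len(obs)
    rmses = np.empty(n_boot)
    r2s = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rmses[b], r2s[b] = _rmse_r2(obs[idx], pred[idx])
    return MetricSummary(
        stratum=stratum,
        n_rows=n,
        rmse_median=float(np.median(rmses)),
        rmse_mad=_mad(rmses),
        r2_median=float(np.median(r2s)),
        r2_mad=_mad(r2s),
    )


def residual_time_curve(
    preds: pd.DataFrame,
    n_boot: int = 200,
    frac: float = 0.3,
    seed: int = 0,
    n_grid: int = 50,
) -> ResidualCurve:
    """Bootstrapped LOWESS of residual vs time with a pointwise 95% band."""
    if len(preds) < 10:
        raise ValueError("need >= 10 rows for a residual curve")
    t = preds["time_weeks"].to_numpy()
    resid = (preds["predicted"] - preds["observed"]).to_numpy()
    grid = np.linspace(t.min(), t.max(), n_grid)
    rng = np.random.default_rng(seed)
    curves = np.empty((n_boot, n_grid))
    n = len(t)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        curves[b] = lowess(resid[idx], t[idx], frac=frac, xvals=grid)
    return ResidualCurve(
        grid=grid,
        median=np.median(curves, axis=0),
        lo=np.percentile(curves, 2.5, axis=0),
        hi=np.percentile(curves, 97.5, axis=0),
    )


def windowed_extrapolation_report(
    checkpoint: ModelCheckpoint,
    cohort: Cohort,
    windows=(16.0, 24.0, 32.0),
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Seen/unseen fit summaries per window and per arm (plus pooled).

    Returns a tidy table with one row per (window, stratum, subset); the
    pooled unseen row counts per window mirror the per-arm counts exactly
    (they partition the same prediction set).
    """
    tables = []
    for w in windows:
        preds = build_prediction_set(checkpoint, cohort, w)
        if preds.empty:
            raise ValueError(f"window {w} excludes every patient")
        strata = [("all", preds)] + [(arm, g) for arm, g in preds.groupby("arm")]
        for name, df in strata:
            for subset, sub in (("seen", df[df["seen"]]), ("unseen", df[~df["seen"]]), ("all", df)):
                if len(sub) < 2:
                    continue
                s = bootstrap_fit_metrics(sub, n_boot=n_boot, seed=seed, stratum=name)
                tables.append(
                    {
                        "window": w,
                        "stratum": name,
                        "subset": subset,
                        "n_rows": s.n_rows,
                        "rmse_median": s.rmse_median,
                        "rmse_mad": s.rmse_mad,
                        "r2_median": s.r2_median,
                        "r2_mad": s.r2_mad,
                    }
                )
    return pd.DataFrame(tables)
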