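"""High-level modelling interface.

:class:`TumorDynamicsModel` is built from a cohort (or a long-format
DataFrame), ``fit()`` trains the encoder–decoder and returns a
:class:`TumorDynamicsResults` carrying the checkpoint, the loss history,
per-patient kinetic metrics, prediction/evaluation methods, plotting and a
``summary()`` table. The survival layer hangs off the results object via
:meth:`TumorDynamicsResults.survival_analysis`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, survival as surv
from .cohort import Cohort, PatientRecord, filter_eligible
from .config import TrainConfig
from .training import ModelCheckpoint, predict_profile, train

__all__ = ["TumorDynamicsModel", "TumorDynamicsResults", "cohort_from_frame"]


def cohort_from_frame(
    df: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    tag: str = "cohort",
) -> Cohort:
    """Build a cohort from long-format measurements (+ optional joins)."""
    surv_ix = survival.set_index("subject_id") if survival is not None else None
    cov_ix = covariates.set_index("subject_id") if covariates is not None else None
    records = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_weeks")
        os_time = os_event = None
        if surv_ix is not None and sid in surv_ix.index:
            os_time = float(surv_ix.loc[sid, "os_weeks"])
            os_event = int(surv_ix.loc[sid, "event"])
        cov = None
        if cov_ix is not None and sid in cov_ix.index:
            cov = {k: float(v) for k, v in cov_ix.loc[sid].items()}
        records.append(
            PatientRecord(
                subject_id=str(sid),
                times=grp["time_weeks"].to_numpy(dtype=float),
                sld=grp["sld_mm"].to_numpy(dtype=float),
                arm=str(grp["arm"].iloc[0]) if "arm" in grp.columns else "arm1",
                os_time=os_time,
                os_event=os_event,
                covariates=cov,
            )
        )
    return Cohort(records=records, tag=tag)


class TumorDynamicsModel:
    """Encoder–decoder tumor-dynamics model bound to a training cohort."""

    def __init__(self, cohort: Cohort, config: TrainConfig | None = None):
        self.cohort = filter_eligible(cohort)
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframe(
        cls,
        measurements: pd.DataFrame,
        survival: pd.DataFrame | None = None,
        covariates: pd.DataFrame | None = None,
        config: TrainConfig | None = None,
    ) -> "TumorDynamicsModel":
        return cls(cohort_from_frame(measurements, survival, covariates), config)

    def fit(self, callback=None) -> "TumorDynamicsResults":
        checkpoint = train(self.cohort, self.config, callback=callback)
        return TumorDynamicsResults(checkpoint, train_cohort=self.cohort)


class TumorDynamicsResults:
    """Fitted model: checkpoint plus estimation, evaluation and explanation."""

    def __init__(self, checkpoint: ModelCheckpoint, train_cohort: Cohort | None = None):
        self.checkpoint = checkpoint
        self.train_cohort = train_cohort

    # -- persistence ----------------------------------------------------------
    def save(self, directory) -> Path:
        return self.checkpoint.save(directory)

    @classmethod
    def load(cls, directory) -> "TumorDynamicsResults":
        return cls(ModelCheckpoint.load(directory))

    # -- core quantities -------------------------------------------------------
    @property
    def loss_history(self) -> list:
        return self.checkpoint.loss_history

    def predict(
        self,
        record: PatientRecord,
        query_times: np.ndarray | None = None,
        window: float | None = None,
    ) -> np.ndarray:
        """Predicted SLD (mm) at post-treatment query times (weeks)."""
        return predict_profile(self.checkpoint, record, window, query_times)

    def kinetic_metrics(self, cohort: Cohort, window: float | None = None) -> pd.DataFrame:
        """Per-patient (p1, p2, T) table."""
        return surv.extract_metrics(self.checkpoint, cohort, window)

    # -- evaluation ------------------------------------------------------------
    def prediction_set(self, cohort: Cohort, window: float | None = None) -> pd.DataFrame:
        window = self.checkpoint.config.window if window is None else window
        return evaluation.build_prediction_set(self.checkpoint, cohort, window)

    def fit_metrics(self, cohort: Cohort, window: float | None = None,
                    n_boot: int = 1000, seed: int = 0):
        return evaluation.bootstrap_fit_metrics(
            self.prediction_set(cohort, window), n_boot=n_boot, seed=seed
        )

    def residual_curve(self, cohort: Cohort, window: float | None = None, **kw):
        return evaluation.residual_time_curve(self.prediction_set(cohort, window), **kw)

    def window_report(self, cohort: Cohort, windows=(16.0, 24.0, 32.0), **kw) -> pd.DataFrame:
        return evaluation.windowed_extrapolation_report(self.checkpoint, cohort, windows, **kw)

    # -- survival layer --------------------------------------------------------
    def survival_analysis(
        self,
        cohort: Cohort,
        feature_set: str = "metrics",
        covariates: pd.DataFrame | None = None,
        os_params: dict | None = None,
        cv_folds: int = 5,
        seed: int = 0,
        window: float | None = None,
    ) -> dict:
        """Fit the OS layer on a cohort's metrics; returns model + c-indices."""
        metrics = self.kinetic_metrics(cohort, window)
        data = surv.assemble_features(metrics, feature_set, covariates)
        model = surv.fit_os_model(data, os_params)
        out = {
            "data": data,
            "model": model,
            "train_cindex": surv.concordance(model, data),
        }
        if cv_folds and cv_folds >= 2:
            out["cv"] = surv.cross_validate_os(data, os_params, k=cv_folds, seed=seed)
        return out

    # -- plots -----------------------------------------------------------------
    def plot_patient(self, record: PatientRecord, window: float | None = None, ax=None):
        """Observed SLD and the continuous predicted curve for one patient."""
        import matplotlib.pyplot as plt

        window = self.checkpoint.config.window if window is None else window
        if ax is None:
            _, ax = plt.subplots()
        t_max = float(record.times.max())
        grid = np.linspace(0.0, max(t_max, window), 120)
        ax.plot(grid, self.predict(record, grid, window), label="predicted")
        ax.plot(record.times, record.sld, "o", label="observed")
        ax.axvline(window, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("time (weeks)")
        ax.set_ylabel("SLD (mm)")
        ax.set_title(record.subject_id)
        ax.legend()
        return ax

    def plot_residual_band(self, cohort: Cohort, window: float | None = None, ax=None, **kw):
        import matplotlib.pyplot as plt

        curve = self.residual_curve(cohort, window, **kw)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(curve.grid, curve.lo, curve.hi, alpha=0.3, label="95% band")
        ax.plot(curve.grid, curve.median, label="median residual")
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("time (weeks)")
        ax.set_ylabel("predicted - observed (mm)")
        ax.legend()
        return ax

    # -- summary ---------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.checkpoint.config
        stats = self.checkpoint.stats
        lines = [
            "Tumor Dynamics Neural-ODE Results",
            "=" * 44,
            f"{'epochs':<28}{cfg.epochs}",
            f"{'learning rate':<28}{cfg.lr}",
            f"{'weight decay (L2)':<28}{cfg.weight_decay}",
            f"{'batch size':<28}{cfg.batch_size}",
            f"{'observation window (wk)':<28}{cfg.window}",
            f"{'ODE tolerance':<28}{cfg.ode_tol}",
            f"{'latent dim c / metric dim k':<28}{cfg.dims.c} / {cfg.dims.k}",
            f"{'SLD mean mu (mm)':<28}{stats.mu:.3f}",
            f"{'SLD sd sigma (mm)':<28}{stats.sigma:.3f}",
        ]
        if self.loss_history:
            lines += [
                f"{'initial masked RMSE':<28}{self.loss_history[0]:.4f}",
                f"{'final masked RMSE':<28}{self.loss_history[-1]:.4f}",
            ]
        if self.train_cohort is not None:
            lines.append(f"{'training patients':<28}{len(self.train_cohort)}")
        lines.append("=" * 44)
        return "\n".join(lines)
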