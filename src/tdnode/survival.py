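"""The kinetics-to-survival layer: metric extraction, PCA, gradient-boosted
Cox modelling, concordance, cross-validation, Shapley attributions, and
principal-component perturbation of decoded trajectories.

The learned 2-dimensional kinetic metrics (p = raw encoder output × T, in
the patient's time units) take the role that classical TGI growth/shrink
rates play in established tumor-size-to-survival analyses. A gradient-
boosted proportional-hazards model (xgboost ``survival:cox``) maps a
chosen feature set to a risk score (higher score = higher hazard =
shorter expected survival); a Breslow baseline cumulative hazard turns
risk scores into per-patient survival curves. Shapley attributions come
from exact TreeSHAP on the boosted trees and are additive on the
log-hazard margin. Perturbing a patient's metrics along the first
principal component and decoding each perturbed vector links the survival
feature axis back to the tumor dynamics it encodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .cohort import Cohort, PatientRecord, UnscalableProfileError, normalize_profile
from .decoder import integrate
from .training import ModelCheckpoint, encode_record

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "PCResult",
    "OSModel",
    "extract_metrics",
    "pca_first_component",
    "assemble_features",
    "fit_os_model",
    "concordance",
    "cross_validate_os",
    "shap_summary",
    "perturb_along_pc",
    "km_vs_predicted_curves",
    "DEFAULT_OS_PARAMS",
]

# gradient-boosting defaults: modest trees, standard shrinkage
DEFAULT_OS_PARAMS = {
    "n_rounds": 100,
    "max_depth": 3,
    "eta": 0.1,
    "subsample": 1.0,
    "lambda": 1.0,
    "seed": 0,
}


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-patient features plus right-censored survival outcome."""

    X: pd.DataFrame  # n x p features, indexed by subject_id
    time: np.ndarray  # weeks, > 0
    event: np.ndarray  # 1 = death observed

    def __post_init__(self):
        if len(self.X) != len(self.time) or len(self.X) != len(self.event):
            raise ValueError("features and outcomes must align")
        if np.any(self.time <= 0):
            raise ValueError("os_time must be > 0")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(self.X.iloc[idx], self.time[idx], self.event[idx])


@dataclass(frozen=True)
class PCResult:
    """Principal axes of the kinetic-metric cloud (mean-centered, unscaled)."""

    loadings: np.ndarray  # n_components x 2, unit rows
    scores: np.ndarray  # n x n_components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


@dataclass
class OSModel:
    """Fitted gradient-boosted Cox model; higher risk = higher hazard."""

    booster: xgb.Booster
    feature_names: list[str]
    baseline_times: np.ndarray  # event times, ascending
    baseline_cumhaz: np.ndarray  # Breslow H0 at those times
    params: dict = field(default_factory=dict)
    _trees: list | None = None
    _margin_offset: float = 0.0

    def _dmatrix(self, X: pd.DataFrame) -> xgb.DMatrix:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: expected {self.feature_names}, got {list(X.columns)}"
            )
        return xgb.DMatrix(X.to_numpy(dtype=float), feature_names=self.feature_names)

    def _ensure_trees(self):
        if self._trees is None:
            self._trees = _tree_tables(self.booster, self.feature_names)

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Log-hazard-ratio margin; higher = shorter expected survival.

        Evaluated as the double-precision sum of per-tree leaf values plus
        the constant margin offset (the library's own predict rounds the
        sum to single precision, which matters for Shapley additivity).
        """
        if list(X.columns) != self.feature_names:
            raise ValueError(
                f"feature mismatch: expected {self.feature_names}, got {list(X.columns)}"
            )
        self._ensure_trees()
        xs = X.to_numpy(dtype=float)
        out = np.full(xs.shape[0], self._margin_offset)
        for i in range(xs.shape[0]):
            out[i] += sum(_tree_leaf_value(t, xs[i]) for t in self._trees)
        return out

    def predict_survival(self, X: pd.DataFrame, times: np.ndarray) -> np.ndarray:
        """n x len(times) survival probabilities S_i(t); S(0) = 1."""
        times = np.asarray(times, dtype=float)
        margins = self.predict_risk(X)
        h0 = np.concatenate([[0.0], self.baseline_cumhaz])
        grid = np.concatenate([[0.0], self.baseline_times])
        h_at = h0[np.searchsorted(grid, times, side="right") - 1]
        return np.exp(-np.outer(np.exp(margins), h_at))


def extract_metrics(
    checkpoint: ModelCheckpoint, cohort: Cohort, window: float | None = None
) -> pd.DataFrame:
    """Per-patient kinetic metrics table: subject_id, p1, p2, T (+ arm, OS).

    Deterministic given the checkpoint; unscalable patients are logged and
    omitted.
    """
    window = checkpoint.config.window if window is None else window
    rows = []
    for record in cohort:
        try:
            _, metrics = encode_record(
                checkpoint.network, checkpoint.stats, record, window,
                checkpoint.config.pad_mode,
            )
        except (UnscalableProfileError, ValueError) as exc:
            logger.info("metrics: skipping %s: %s", record.subject_id, exc)
            continue
        rows.append(
            {
                "subject_id": record.subject_id,
                "arm": record.arm,
                "p1": float(metrics.p[0]),
                "p2": float(metrics.p[1]),
                "T": metrics.T,
                "os_weeks": record.os_time,
                "event": record.os_event,
            }
        )
    return pd.DataFrame(rows)


def pca_first_component(metrics: np.ndarray) -> PCResult:
    """PCA of the n x 2 metric cloud: mean-centered, no variance scaling.

    Loadings are sign-fixed so each component's first non-zero coordinate
    is nonnegative (for points on the line y = x the first loading is
    (0.7071, 0.7071)).
    """
    metrics = np.asarray(metrics, dtype=float)
    if metrics.ndim != 2 or metrics.shape[0] < 3:
        raise ValueError("need an n x k matrix with n >= 3")
    if np.allclose(np.var(metrics, axis=0), 0.0):
        raise ValueError("degenerate covariance: metrics carry no variance")
    pca = PCA(n_components=metrics.shape[1])
    scores = pca.fit_transform(metrics)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        lead = loadings[i][np.nonzero(np.abs(loadings[i]) > 1e-12)[0][0]]
        if lead < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )


_FEATURE_SETS = ("metrics", "metrics+cov", "pc1", "pc1+cov", "pcs", "pcs+cov")


def assemble_features(
    metrics: pd.DataFrame,
    feature_set: str = "metrics",
    covariates: pd.DataFrame | None = None,
) -> SurvivalDataset:
    """Build the survival design matrix for one of the six feature sets.

    ``metrics`` is the table from :func:`extract_metrics` and must carry
    ``os_weeks``/``event``. Principal-component features are computed from
    the (p1, p2) cloud of the patients present.
    """
    if feature_set not in _FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {_FEATURE_SETS}")
    df = metrics.dropna(subset=["os_weeks", "event"]).set_index("subject_id")
    base = df[["p1", "p2"]]
    if feature_set.startswith("pc"):
        pc = pca_first_component(base.to_numpy())
        n_pc = 1 if feature_set.startswith("pc1") else 2
        X = pd.DataFrame(
            pc.scores[:, :n_pc], index=base.index,
            columns=[f"pc{i+1}" for i in range(n_pc)],
        )
    else:
        X = base.copy()
    if feature_set.endswith("+cov"):
        if covariates is None:
            raise ValueError("covariates required for a +cov feature set")
        cov = covariates.set_index("subject_id") if "subject_id" in covariates.columns else covariates
        X = X.join(cov, how="inner")
    time = df.loc[X.index, "os_weeks"].to_numpy(dtype=float)
    event = df.loc[X.index, "event"].to_numpy(dtype=int)
    return SurvivalDataset(X=X, time=time, event=event)


def _breslow(time, event, margin):
    """Breslow baseline cumulative hazard at distinct event times."""
    order = np.argsort(time, kind="stable")
    t, e, m = time[order], event[order], margin[order]
    risk = np.exp(m)
    event_times = np.unique(t[e == 1])
    cumhaz = np.empty_like(event_times)
    h = 0.0
    for i, et in enumerate(event_times):
        d = np.sum((t == et) & (e == 1))
        at_risk = risk[t >= et].sum()
        h += d / at_risk
        cumhaz[i] = h
    return event_times, cumhaz


def fit_os_model(data: SurvivalDataset, params: dict | None = None) -> OSModel:
    """Gradient-boosted Cox fit of the feature set to overall survival.

    Requires at least one observed event. The xgboost label convention is
    time for events and -time for censored subjects.
    """
    if data.event.sum() == 0:
        raise ValueError("all patients censored: Cox partial likelihood undefined")
    p = dict(DEFAULT_OS_PARAMS, **(params or {}))
    n_rounds = p.pop("n_rounds")
    label = np.where(data.event == 1, data.time, -data.time)
    dtrain = xgb.DMatrix(
        data.X.to_numpy(dtype=float), label=label, feature_names=data.feature_names
    )
    booster = xgb.train(
        {"objective": "survival:cox", "max_depth": p["max_depth"], "eta": p["eta"],
         "subsample": p["subsample"], "lambda": p["lambda"], "seed": p["seed"],
         "nthread": 1},
        dtrain,
        num_boost_round=n_rounds,
    )
    model = OSModel(
        booster=booster, feature_names=data.feature_names,
        baseline_times=np.array([]), baseline_cumhaz=np.array([]), params=p,
    )
    # calibrate the constant margin offset (base_score in margin space)
    # against the library's own prediction, then use the double-precision
    # leaf-sum route everywhere
    model._ensure_trees()
    lib_margin = booster.predict(model._dmatrix(data.X), output_margin=True).astype(float)
    leaf_sum = model.predict_risk(data.X)
    model._margin_offset = float(np.median(lib_margin - leaf_sum))
    margin = model.predict_risk(data.X)
    bt, bh = _breslow(data.time, data.event, margin)
    model.baseline_times, model.baseline_cumhaz = bt, bh
    return model


def concordance(model: OSModel, data: SurvivalDataset) -> float:
    """Harrell's c-index of the model's risk score on a dataset."""
    risk = model.predict_risk(data.X)
    return concordance_from_risk(risk, data.time, data.event)


def concordance_from_risk(risk: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """c-index of an arbitrary risk score (higher risk = earlier death)."""
    return float(concordance_index(time, -np.asarray(risk, float), event))


def cross_validate_os(
    data: SurvivalDataset,
    params: dict | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Patient-level random k-fold CV; per-fold test c-index, median ± MAD.

    If a fold has no events the split is redrawn with a shifted seed, up
    to 5 attempts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(data.time)
    for attempt in range(5):
        folds = list(KFold(n_splits=k, shuffle=True, random_state=seed + attempt).split(np.arange(n)))
        if all(data.event[test].sum() > 0 and data.event[train].sum() > 0
               for train, test in folds):
            break
    else:
        raise ValueError("could not produce folds with events in every fold")
    scores = []
    for train_idx, test_idx in folds:
        model = fit_os_model(data.subset(train_idx), params)
        scores.append(concordance(model, data.subset(test_idx)))
    scores = np.array(scores)
    return {
        "fold_scores": scores,
        "median": float(np.median(scores)),
        "mad": float(np.median(np.abs(scores - np.median(scores)))),
        "folds": [(train.copy(), test.copy()) for train, test in folds],
    }


def _tree_tables(booster: xgb.Booster, feature_names: list[str]):
    """Parse each boosted tree into flat arrays for fast descent."""
    df = booster.trees_to_dataframe()
    name_to_idx = {n: i for i, n in enumerate(feature_names)}
    trees = []
    for _, tree in df.groupby("Tree", sort=True):
        tree = tree.set_index("ID")
        ids = list(tree.index)
        pos = {i: k for k, i in enumerate(ids)}
        is_leaf = (tree["Feature"] == "Leaf").to_numpy()
        feat = np.array(
            [-1 if lf else name_to_idx[f] for lf, f in zip(is_leaf, tree["Feature"])]
        )
        # split decisions happen in single precision inside the library
        split = np.where(is_leaf, 0.0, tree["Split"].to_numpy(dtype=float)).astype(np.float32)
        value = np.where(is_leaf, tree["Gain"].to_numpy(dtype=float), 0.0)
        cover = tree["Cover"].to_numpy(dtype=float)
        yes = np.array([-1 if lf else pos[y] for lf, y in zip(is_leaf, tree["Yes"])])
        no = np.array([-1 if lf else pos[n] for lf, n in zip(is_leaf, tree["No"])])
        trees.append((feat, split, value, cover, yes, no))
    return trees


def _tree_leaf_value(tree, x: np.ndarray) -> float:
    """Plain descent: the tree's leaf value for one sample."""
    feat, split, value, cover, yes, no = tree
    node = 0
    while feat[node] >= 0:
        node = yes[node] if np.float32(x[feat[node]]) < split[node] else no[node]
    return float(value[node])


def _tree_expectation(tree, x: np.ndarray, subset: frozenset, node: int = 0) -> float:
    """E[tree(x_S, X_notS)] with the cover-weighted conditional expectation."""
    feat, split, value, cover, yes, no = tree
    f = feat[node]
    if f < 0:
        return value[node]
    if f in subset:
        child = yes[node] if np.float32(x[f]) < split[node] else no[node]
        return _tree_expectation(tree, x, subset, child)
    cy, cn = cover[yes[node]], cover[no[node]]
    return (
        cy * _tree_expectation(tree, x, subset, yes[node])
        + cn * _tree_expectation(tree, x, subset, no[node])
    ) / (cy + cn)


def _exact_shap(model: OSModel, X: pd.DataFrame) -> pd.DataFrame:
    """Double-precision Shapley values by subset enumeration over features."""
    from itertools import combinations
    from math import factorial

    names = model.feature_names
    p = len(names)
    trees = _tree_tables(model.booster, names)
    xs = X.to_numpy(dtype=float)
    n = xs.shape[0]
    weights = {k: factorial(k) * factorial(p - 1 - k) / factorial(p) for k in range(p)}
    phi = np.zeros((n, p))
    v_empty = np.empty(n)
    v_full = np.empty(n)
    all_feats = list(range(p))
    subsets = [frozenset(s) for k in range(p + 1) for s in combinations(all_feats, k)]
    for i in range(n):
        v = {
            s: sum(_tree_expectation(t, xs[i], s) for t in trees)
            for s in subsets
        }
        v_empty[i] = v[frozenset()]
        v_full[i] = v[frozenset(all_feats)]
        for j in all_feats:
            for s in subsets:
                if j in s:
                    continue
                phi[i, j] += weights[len(s)] * (v[s | {j}] - v[s])
    out = pd.DataFrame(phi, index=X.index, columns=names)
    out["base_value"] = v_empty + model._margin_offset
    return out


# exact enumeration is exponential in the feature count; beyond this many
# features fall back to the boosting library's single-precision TreeSHAP
_EXACT_SHAP_MAX_FEATURES = 8


def shap_summary(model: OSModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-patient Shapley attributions on the log-hazard margin.

    For the small feature sets this layer uses (metrics, principal
    components, a handful of covariates) the attributions are computed
    exactly in double precision by subset enumeration with the
    cover-weighted conditional expectation — the same convention as
    TreeSHAP, against which they are cross-checked in the test suite.
    Returns one row per patient with a column per feature plus
    ``base_value``; attributions + base value sum to the model margin
    (local additivity).
    """
    if list(X.columns) != model.feature_names:
        raise ValueError(
            f"feature mismatch: expected {model.feature_names}, got {list(X.columns)}"
        )
    if len(model.feature_names) <= _EXACT_SHAP_MAX_FEATURES:
        return _exact_shap(model, X)
    contribs = model.booster.predict(model._dmatrix(X), pred_contribs=True)
    out = pd.DataFrame(
        contribs, index=X.index, columns=model.feature_names + ["base_value"]
    )
    return out.astype(float)


def perturb_along_pc(
    checkpoint: ModelCheckpoint,
    record: PatientRecord,
    loading: np.ndarray,
    magnitude_range: tuple[float, float] = (-2.0, 2.0),
    n_perturb: int = 500,
    window: float | None = None,
    n_times: int = 60,
) -> dict:
    """Decode a family of trajectories with metrics shifted along a PC axis.

    The perturbation acts in metric (data) space: p' = p + delta * loading
    for ``n_perturb`` evenly spaced deltas over ``magnitude_range``; the
    patient's own initial state is reused and the original (delta = 0)
    curve is always included first. Because the decoder consumes the
    dimensionless encoding, each p' is divided by the patient's T before
    integration.
    """
    loading = np.asarray(loading, dtype=float)
    if not np.isclose(np.linalg.norm(loading), 1.0, atol=1e-6):
        raise ValueError("loading must have unit norm")
    if n_perturb < 1:
        raise ValueError("n_perturb must be >= 1")
    window = checkpoint.config.window if window is None else window
    profile = normalize_profile(record, checkpoint.stats, window)
    z0, metrics = encode_record(
        checkpoint.network, checkpoint.stats, record, window, checkpoint.config.pad_mode
    )
    horizon = max(1.0, float(np.max(profile.tau_tilde)))
    taus = np.linspace(0.0, horizon, n_times)
    deltas = np.concatenate([[0.0], np.linspace(*magnitude_range, n_perturb)])
    curves = np.empty((deltas.size, n_times))
    for i, d in enumerate(deltas):
        p_shift = metrics.p + d * loading
        traj = integrate(
            checkpoint.network.vf, z0, p_shift / metrics.T, taus,
            tol=checkpoint.config.ode_tol,
        )
        curves[i] = checkpoint.stats.denormalize(
            checkpoint.network.reducer.numpy_eval(traj.states)
        )
    return {"deltas": deltas, "times_weeks": taus * metrics.T, "curves_mm": curves}


def km_vs_predicted_curves(
    model: OSModel,
    data: SurvivalDataset,
    arms: np.ndarray,
    n_grid: int = 100,
) -> dict:
    """Per-arm Kaplan–Meier curve vs model-predicted survival band.

    For each arm: the product-limit estimate of the data, and the
    pointwise median and 2.5/97.5 percentiles of the per-patient predicted
    survival curves. Arms with no subjects are skipped with a warning.
    """
    arms = np.asarray(arms)
    grid = np.linspace(0.0, float(data.time.max()), n_grid)
    out = {}
    for arm in pd.unique(arms):
        sel = np.nonzero(arms == arm)[0]
        if sel.size == 0:
            logger.warning("arm %s has no subjects; skipped", arm)
            continue
        km = KaplanMeierFitter()
        km.fit(data.time[sel], data.event[sel])
        km_surv = km.survival_function_at_times(grid).to_numpy()
        pred = model.predict_survival(data.X.iloc[sel], grid)
        out[str(arm)] = {
            "grid_weeks": grid,
            "km": km_surv,
            "pred_median": np.median(pred, axis=0),
            "pred_lo": np.percentile(pred, 2.5, axis=0),
            "pred_hi": np.percentile(pred, 97.5, axis=0),
            "n": int(sel.size),
        }
    return out
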