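"""Gestational-age prediction: feature assembly, regressors and importance.

Three feature families feed the same regression interface:

* segmentation-encoder deep features — per view, every slice's bottleneck
  tensor is globally average-pooled and mapped by a fixed (seeded, untrained)
  linear projection to 256 dimensions; slice vectors are mean-pooled over the
  volume and the three view vectors concatenated to one 768-vector;
* 3D-autoencoder latents (:mod:`fetalbrain.autoencoder`);
* radiomics features (:mod:`fetalbrain.radiomics`).

Regressors: random forest (``rf``), a single regression tree (``rt``),
linear regression (``lr``) and gradient-boosted trees (``xgb``), all seeded.
Evaluation reports RMSE in weeks and the concordance index.  Feature
importance is the mean increase in RMSE when one column is permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .metrics import RegEvalReport, evaluate_regression, rmse
from .model import SegNet, normalize_volume, _pad_to_multiple
from .volume import VIEWS, extract_slices

ALGOS = ("rf", "rt", "lr", "xgb")

ENCODER_FEATURE_DIM = 256  # per view; three views concatenate to 768
_PROJECTION_SEED = 20330   # fixed: the projection is part of the feature definition


@dataclass
class GARecord:
    """Per-subject gestational-age target, in weeks."""

    subject_id: str
    ga_weeks: float

    def __post_init__(self) -> None:
        if not (20.0 <= self.ga_weeks <= 33.0):
            raise ValueError(f"ga_weeks must lie in [20, 33], got {self.ga_weeks}")


@dataclass
class FeatureMatrix:
    """Named subjects-by-features matrix with its provenance tag."""

    subject_ids: list
    feature_names: list
    values: np.ndarray
    source: str  # radiomics | encoder_deep | autoencoder_latent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise ValueError("values shape disagrees with ids/names")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.feature_names)


def _fixed_projection(c_in: int, dim: int = ENCODER_FEATURE_DIM) -> np.ndarray:
    rng = np.random.default_rng(_PROJECTION_SEED + c_in)
    return rng.normal(0.0, 1.0 / np.sqrt(c_in), size=(dim, c_in)).astype(np.float32)


def encoder_features(models: dict, vol, batch_size: int = 32) -> np.ndarray:
    """768-vector of encoder deep features from the three view models."""
    missing = [v for v in VIEWS if v not in models]
    if missing:
        raise ValueError(f"missing view models: {missing}")
    voxels = normalize_volume(vol.voxels if hasattr(vol, "voxels") else np.asarray(vol))
    parts = []
    for view in ("axial", "sagittal", "coronal"):
        model: SegNet = models[view]
        model.eval()
        div = 2 ** model.cfg.stages
        padded = [_pad_to_multiple(s, div)[0] for s in extract_slices(voxels, view).slices]
        xs = np.stack([p[None] for p in padded])
        feats = []
        for start in range(0, len(xs), batch_size):
            feats.append(model.bottleneck_features(xs[start : start + batch_size]))
        pooled = np.concatenate(feats, axis=0)      # (n_slices, C)
        proj = _fixed_projection(pooled.shape[1])
        per_slice = pooled @ proj.T                  # (n_slices, 256)
        parts.append(per_slice.mean(axis=0))         # combine slices: mean pool
    return np.concatenate(parts).astype(np.float32)


def fit_regressor(x: np.ndarray, y, algo: str = "rf", seed: int = 0,
                  n_trees: int = 500):
    """Fit one of the four regression algorithms; returns the fitted model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if algo == "rf":
        n_trees = int(np.clip(n_trees, 100, 1000))
        model = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    elif algo == "rt":
        model = DecisionTreeRegressor(random_state=seed)
    elif algo == "lr":
        if np.linalg.matrix_rank(np.column_stack([x, np.ones(len(x))])) <= x.shape[1]:
            warnings.warn("singular design matrix; falling back to ridge regression")
            model = Ridge(alpha=1e-6, random_state=seed)
        else:
            model = LinearRegression()
    elif algo == "xgb":
        model = XGBRegressor(
            n_estimators=300, objective="reg:squarederror", random_state=seed,
            n_jobs=1, verbosity=0,
        )
    else:
        raise ValueError(f"unknown algo {algo!r}; expected one of {ALGOS}")
    model.fit(x, y)
    return model


def evaluate_ga(model, x_test, y_test) -> RegEvalReport:
    x_test = np.asarray(x_test, dtype=float)
    if len(x_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(x_test)
    return evaluate_regression(np.asarray(y_test, dtype=float), pred)


def cross_validate_ga(x, y, algo: str = "rf", n_splits: int = 5,
                      seed: int = 0) -> RegEvalReport:
    """K-fold CV with out-of-fold predictions pooled for one report."""
    from sklearn.model_selection import KFold

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pred = np.empty_like(y)
    for train_idx, test_idx in KFold(n_splits=n_splits, shuffle=True,
                                     random_state=seed).split(x):
        model = fit_regressor(x[train_idx], y[train_idx], algo=algo, seed=seed)
        pred[test_idx] = model.predict(x[test_idx])
    return evaluate_regression(y, pred)


def permutation_importance(model, x, y, feature_names=None, n_repeats: int = 5,
                           seed: int = 0) -> dict:
    """name -> mean RMSE increase when that column is shuffled (descending)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(x.shape[1])]
    base = rmse(model.predict(x), y)
    rng = np.random.default_rng(seed)
    importances = {}
    for j, name in enumerate(feature_names):
        deltas = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            deltas.append(rmse(model.predict(xp), y) - base)
        importances[name] = float(np.mean(deltas))
    return dict(sorted(importances.items(), key=lambda kv: -kv[1]))
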