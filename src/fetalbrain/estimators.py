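"""Scikit-learn-style estimators wrapping the pipeline stages.

These classes follow the sklearn conventions (``get_params``/``set_params``
via ``BaseEstimator``, fitted attributes with a trailing underscore, fit /
predict / transform verbs) so they compose with sklearn model selection.
The functional interfaces in :mod:`fetalbrain.model`,
:mod:`fetalbrain.autoencoder`, :mod:`fetalbrain.radiomics` and
:mod:`fetalbrain.ga` remain the thin underlying layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import autoencoder as ae
from . import ga as ga_mod
from . import radiomics as rad
from .fusion import FusedVolume, fuse_views
from .model import (
    ModelConfig, TrainConfig, ViewProbabilities, build_model, predict_view,
    sample_training_slices, slice_dataset, train_view_model,
)
from .volume import VIEWS, ImageVolume, LabelVolume


class SliceSegmenter(BaseEstimator):
    """Single-view 2D slice segmentation network.

    Parameters mirror :class:`fetalbrain.model.ModelConfig` and
    :class:`fetalbrain.model.TrainConfig`.  ``fit`` takes lists of image and
    label volumes (or raw arrays) and trains on the slices of ``view``.
    """

    def __init__(self, view="coronal", variant="full", base_width=32,
                 n_classes=8, loss="combo", alpha=0.5, beta=0.5, lr=1e-4,
                 epochs=10, batch_size=16, head="sigmoid", bg_stride=1,
                 rare_boost=1, seed=0):
        self.view = view
        self.variant = variant
        self.base_width = base_width
        self.n_classes = n_classes
        self.loss = loss
        self.alpha = alpha
        self.beta = beta
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.head = head
        self.bg_stride = bg_stride
        self.rare_boost = rare_boost
        self.seed = seed

    def _configs(self):
        mc = ModelConfig(n_classes=self.n_classes, base_width=self.base_width,
                         variant=self.variant, head=self.head)
        tc = TrainConfig(lr=self.lr, epochs=self.epochs,
                         batch_size=self.batch_size, loss_name=self.loss,
                         alpha=self.alpha, beta=self.beta, seed=self.seed)
        return mc, tc

    def fit(self, X, y):
        mc, tc = self._configs()
        self.model_ = build_model(mc, seed=self.seed)
        images, targets = slice_dataset(list(zip(X, y)), self.view, mc.n_classes)
        images, targets = sample_training_slices(images, targets,
                                                 self.bg_stride, self.rare_boost)
        _, self.history_ = train_view_model(self.model_, images, targets, tc)
        return self

    def predict_proba_volume(self, vol) -> ViewProbabilities:
        return predict_view(self.model_, vol, self.view)

    def predict(self, vol) -> np.ndarray:
        return self.predict_proba_volume(vol).argmax_labels()


class MultiViewSegmenter(BaseEstimator):
    """Three per-view networks fused into one 3D multi-tissue labelling."""

    def __init__(self, variant="full", base_width=32, n_classes=8,
                 loss="combo", alpha=0.5, beta=0.5, lr=1e-4, epochs=10,
                 batch_size=16, fusion_mode="score_sum", head="sigmoid",
                 bg_stride=1, rare_boost=1, seed=0):
        self.variant = variant
        self.base_width = base_width
        self.n_classes = n_classes
        self.loss = loss
        self.alpha = alpha
        self.beta = beta
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.fusion_mode = fusion_mode
        self.head = head
        self.bg_stride = bg_stride
        self.rare_boost = rare_boost
        self.seed = seed

    def fit(self, X, y):
        self.segmenters_ = {}
        for i, view in enumerate(VIEWS):
            seg = SliceSegmenter(
                view=view, variant=self.variant, base_width=self.base_width,
                n_classes=self.n_classes, loss=self.loss, alpha=self.alpha,
                beta=self.beta, lr=self.lr, epochs=self.epochs,
                batch_size=self.batch_size, head=self.head,
                bg_stride=self.bg_stride, rare_boost=self.rare_boost,
                seed=self.seed + i,
            )
            seg.fit(X, y)
            self.segmenters_[view] = seg
        return self

    @property
    def models_(self):
        return {v: s.model_ for v, s in self.segmenters_.items()}

    def fuse(self, vol) -> FusedVolume:
        pa = self.segmenters_["axial"].predict_proba_volume(vol)
        ps = self.segmenters_["sagittal"].predict_proba_volume(vol)
        pc = self.segmenters_["coronal"].predict_proba_volume(vol)
        spacing = vol.spacing if isinstance(vol, ImageVolume) else (1.0, 1.0, 1.0)
        return fuse_views(pa, ps, pc, mode=self.fusion_mode, spacing=spacing)

    def predict(self, vol) -> np.ndarray:
        return self.fuse(vol).labels.labels


class VolumeAutoencoder(BaseEstimator, TransformerMixin):
    """3D autoencoder; ``transform`` yields per-volume latent vectors."""

    def __init__(self, latent_dim=256, depth=4, base_width=8,
                 input_shape=(32, 32, 32), lr=1e-3, epochs=12, batch_size=4,
                 seed=0):
        self.latent_dim = latent_dim
        self.depth = depth
        self.base_width = base_width
        self.input_shape = input_shape
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    def _config(self) -> ae.AEConfig:
        return ae.AEConfig(latent_dim=self.latent_dim, depth=self.depth,
                           base_width=self.base_width,
                           input_shape=tuple(self.input_shape), lr=self.lr,
                           epochs=self.epochs, batch_size=self.batch_size,
                           seed=self.seed)

    def fit(self, X, y=None):
        cfg = self._config()
        self.model_ = ae.build_autoencoder(cfg)
        _, self.history_ = ae.train_autoencoder(self.model_, list(X), cfg)
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([ae.encode_volume(self.model_, v) for v in X])


class RadiomicsExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: (image, mask) pairs -> 18-feature DataFrame.

    ``label`` selects the mask region: ``"all"`` uses the union of tissue
    labels 1-7, an integer restricts to that tissue.
    """

    def __init__(self, n_bins=32, label="all"):
        self.n_bins = n_bins
        self.label = label

    def fit(self, X, y=None):
        return self

    def _mask(self, lab) -> np.ndarray:
        arr = lab.labels if isinstance(lab, LabelVolume) else np.asarray(lab)
        if self.label == "all":
            return arr > 0
        return arr == int(self.label)

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for img, lab in X:
            spacing = img.spacing if isinstance(img, ImageVolume) else (1.0, 1.0, 1.0)
            voxels = img.voxels if isinstance(img, ImageVolume) else np.asarray(img)
            rows.append(rad.extract_features(voxels, self._mask(lab),
                                             spacing=spacing, n_bins=self.n_bins))
        return pd.DataFrame(rows, columns=list(rad.SELECTED_FEATURE_NAMES))


class CorrelationFeatureSelector(BaseEstimator, TransformerMixin):
    """Keep features ranked by |r| with the target, dropping near-duplicates."""

    def __init__(self, r_thresh=0.95):
        self.r_thresh = r_thresh

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names, values = list(X.columns), X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"f{j}" for j in range(values.shape[1])]
        self.selected_ = rad.select_features(values, y, names, self.r_thresh)
        self._names = names
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.selected_]
        idx = [self._names.index(n) for n in self.selected_]
        return np.asarray(X, dtype=float)[:, idx]


class GAPredictor(BaseEstimator, RegressorMixin):
    """Gestational-age regressor over any assembled feature matrix."""

    def __init__(self, algo="rf", n_trees=500, seed=0):
        self.algo = algo
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        self.model_ = ga_mod.fit_regressor(X, y, algo=self.algo,
                                           seed=self.seed, n_trees=self.n_trees)
        return self

    def predict(self, X):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        return self.model_.predict(X)
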