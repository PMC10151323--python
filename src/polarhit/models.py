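"""Scikit-learn-style estimators for the discrete-time competing-risks model.

:class:`DeepHitSurvival` learns the joint distribution of (event type,
hitting time) from polar-map stacks plus clinical features; with
``use_images=False`` it becomes the clinical-only comparator sharing the
same output contract.  ``X`` is a ``(maps, clinical)`` tuple (or just the
clinical table for the clinical-only model); ``y`` is either an outcomes
DataFrame with ``event_kind``/``time_days`` columns or an ``(n, 2)`` array
of (event code, time in days).

Training follows the repeated hold-out protocol: within each training set,
a randomly selected 20% of cases is held out for early stopping and model
selection; imputation and normalization statistics are estimated on the
training rows only and stored for exact reuse at prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (
    CLINICAL_FEATURES,
    Imputer,
    Normalizer,
    outcomes_to_arrays,
    stratified_kfold,
)
from .grid import TimeGrid
from .io import Cohort
from .losses import LossConfig, total_loss
from .nn import Adam, ArchitectureConfig, DeepHitNetwork
from .surface import RiskSurface

__all__ = [
    "DeepHitSurvival",
    "build_clinical_model",
    "CVResult",
    "train_cv",
    "predict_external",
]


def _as_outcome_arrays(y, grid: TimeGrid):
    if isinstance(y, pd.DataFrame):
        return outcomes_to_arrays(y, grid)
    y = np.asarray(y)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be an outcomes frame or an (n, 2) array")
    event = y[:, 0].astype(np.int64)
    days = y[:, 1].astype(np.int64)
    bins = np.minimum(
        np.ceil(days / grid.bin_width_days).astype(np.int64), grid.n_bins - 1
    )
    return event, days, bins


class DeepHitSurvival(BaseEstimator):
    """Two-branch convolutional/dense competing-risks survival network.

    Parameters mirror the architecture and training protocol; all fitted
    state lives in trailing-underscore attributes (``net_``, ``imputer_``,
    ``normalizer_``, ``grid_``, ``history_``).
    """

    def __init__(
        self,
        *,
        horizon_days: int = 3_900,
        bin_width_days: int = 30,
        n_events: int = 3,
        conv_channels: tuple = (16, 32),
        dropout: float = 0.3,
        leaky_slope: float = 0.01,
        image_dense_width: int = 512,
        clinical_dense_width: int = 32,
        shared_width: int = 256,
        head_width: int = 256,
        use_images: bool = True,
        alpha: float = 0.5,
        sigma: float = 0.1,
        lr: float = 1e-3,
        lr_decay: float = 1.0,
        weight_decay: float = 0.0,
        clip_norm: float | None = 5.0,
        batch_size: int = 256,
        max_epochs: int = 100,
        patience: int = 10,
        val_fraction: float = 0.2,
        binary_features=None,
        random_state: int = 0,
    ):
        self.horizon_days = horizon_days
        self.bin_width_days = bin_width_days
        self.n_events = n_events
        self.conv_channels = conv_channels
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        self.image_dense_width = image_dense_width
        self.clinical_dense_width = clinical_dense_width
        self.shared_width = shared_width
        self.head_width = head_width
        self.use_images = use_images
        self.alpha = alpha
        self.sigma = sigma
        self.lr = lr
        self.lr_decay = lr_decay
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.binary_features = binary_features
        self.random_state = random_state

    # -- input plumbing -----------------------------------------------------
    def _split_X(self, X):
        if self.use_images:
            if not (isinstance(X, (tuple, list)) and len(X) == 2):
                raise ValueError(
                    "X must be a (maps, clinical) tuple for the image model"
                )
            maps, clinical = X
        else:
            maps, clinical = (X[0], X[1]) if isinstance(X, (tuple, list)) else (None, X)
        if not isinstance(clinical, pd.DataFrame):
            clinical = np.asarray(clinical, dtype=np.float64)
            names = (
                list(CLINICAL_FEATURES)
                if clinical.shape[1] == len(CLINICAL_FEATURES)
                else [f"x{j}" for j in range(clinical.shape[1])]
            )
            clinical = pd.DataFrame(clinical, columns=names)
        if maps is not None:
            maps = np.asarray(maps, dtype=np.float64)
        return maps, clinical

    def _preprocess(self, maps, clinical):
        clin = self.imputer_.transform(clinical.reset_index(drop=True))
        xc = self.normalizer_.transform_clinical(clin)
        xm = Normalizer.transform_maps(maps) if self.use_images else None
        return xm, xc

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y):
        maps, clinical = self._split_X(X)
        self.grid_ = TimeGrid(self.bin_width_days, self.horizon_days)
        event, _, bins = _as_outcome_arrays(y, self.grid_)
        n = len(clinical)
        if maps is not None and len(maps) != n:
            raise ValueError("maps and clinical tables disagree on n_patients")

        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")

        # hold out a stratified validation subset for early stopping
        k_inner = max(2, round(1.0 / self.val_fraction))
        inner = stratified_kfold(
            pd.DataFrame({"event_kind": event}), k=k_inner, seed=self.random_state
        )
        val_idx = np.flatnonzero(inner == 0)
        tr_idx = np.flatnonzero(inner != 0)

        self.imputer_ = Imputer(binary_features=self.binary_features).fit(
            clinical.iloc[tr_idx]
        )
        self.normalizer_ = Normalizer(binary_features=self.binary_features).fit(
            self.imputer_.transform(clinical.iloc[tr_idx])
        )
        self.feature_names_in_ = list(clinical.columns)
        self.n_features_in_ = clinical.shape[1]

        xm, xc = self._preprocess(maps, clinical)
        arch = ArchitectureConfig(
            n_events=self.n_events,
            n_bins=self.grid_.n_bins,
            n_clinical=xc.shape[1],
            image_shape=tuple(xm.shape[1:]) if xm is not None else (5, 28, 36),
            conv_channels=tuple(self.conv_channels),
            dropout=self.dropout,
            leaky_slope=self.leaky_slope,
            image_dense_width=self.image_dense_width,
            clinical_dense_width=self.clinical_dense_width,
            shared_width=self.shared_width,
            head_width=self.head_width,
            use_images=self.use_images,
        )
        self.arch_ = arch
        self.net_ = DeepHitNetwork(arch, seed=self.random_state)
        loss_cfg = LossConfig(alpha=self.alpha, sigma=self.sigma)
        opt = Adam(
            self.net_, lr=self.lr, clip_norm=self.clip_norm,
            weight_decay=self.weight_decay,
        )
        rng = np.random.default_rng(self.random_state + 1)

        best_val = np.inf
        best_weights = self.net_.get_weights()
        best_epoch = -1
        decay_at = int(0.7 * self.max_epochs)
        self.history_ = []
        for epoch in range(self.max_epochs):
            if self.lr_decay != 1.0 and epoch == decay_at:
                opt.lr *= self.lr_decay
            order = rng.permutation(tr_idx)
            tr_losses = []
            for lo in range(0, len(order), self.batch_size):
                b = order[lo : lo + self.batch_size]
                if len(b) < 2:
                    continue  # batch normalization needs >1 sample
                pmf = self.net_.forward(
                    xm[b] if xm is not None else None, xc[b], train=True, rng=rng
                )
                loss, grad = total_loss(
                    pmf, event[b], bins[b], loss_cfg, return_grad=True
                )
                self.net_.backward(grad)
                opt.step()
                tr_losses.append(loss)
            val_pmf = self._forward_batched(xm, xc, val_idx)
            val_loss = total_loss(val_pmf, event[val_idx], bins[val_idx], loss_cfg)
            self.history_.append(
                {"epoch": epoch, "train_loss": float(np.mean(tr_losses)),
                 "val_loss": float(val_loss)}
            )
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = self.net_.get_weights()
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        self.net_.set_weights(best_weights)
        self.best_val_loss_ = float(best_val)
        self.n_parameters_ = self.net_.n_parameters()
        return self

    def _forward_batched(self, xm, xc, idx=None, batch=512):
        if idx is None:
            idx = np.arange(len(xc))
        out = np.empty((len(idx), self.n_events, self.grid_.n_bins))
        for lo in range(0, len(idx), batch):
            b = idx[lo : lo + batch]
            out[lo : lo + len(b)] = self.net_.forward(
                xm[b] if xm is not None else None, xc[b], train=False
            )
        return out

    # -- prediction ---------------------------------------------------------
    def predict_pmf(self, X) -> np.ndarray:
        """Joint (event, bin) probability grids, shape (n, K, T)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        maps, clinical = self._split_X(X)
        xm, xc = self._preprocess(maps, clinical)
        return self._forward_batched(xm, xc)

    def predict_surface(self, X) -> RiskSurface:
        return RiskSurface(self.predict_pmf(X))

    def predict_cif(self, X, event: int | None = None) -> np.ndarray:
        """Cumulative incidence curves; optionally restricted to one cause
        (0-based index)."""
        cif = self.predict_surface(X).cif()
        return cif if event is None else cif[:, event, :]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights + architecture + preprocessing."""
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "imputer": {
                "statistics": self.imputer_.statistics_,
                "kinds": self.imputer_.kinds_,
            },
            "normalizer": {
                "mean": self.normalizer_.mean_.to_dict(),
                "scale": self.normalizer_.scale_.to_dict(),
            },
            "feature_names": self.feature_names_in_,
            "schema_version": 1,
        }
        weights = self.net_.get_weights()
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path) -> "DeepHitSurvival":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        if meta.get("schema_version") != 1:
            raise ValueError("unrecognized checkpoint schema")
        params = dict(meta["params"])
        for key in ("conv_channels",):
            if isinstance(params.get(key), list):
                params[key] = tuple(params[key])
        est = cls(**params)
        est.grid_ = TimeGrid(est.bin_width_days, est.horizon_days)
        est.feature_names_in_ = meta["feature_names"]
        est.n_features_in_ = len(est.feature_names_in_)
        est.imputer_ = Imputer(binary_features=est.binary_features)
        est.imputer_.statistics_ = meta["imputer"]["statistics"]
        est.imputer_.kinds_ = meta["imputer"]["kinds"]
        est.normalizer_ = Normalizer(binary_features=est.binary_features)
        est.normalizer_.mean_ = pd.Series(meta["normalizer"]["mean"])
        est.normalizer_.scale_ = pd.Series(meta["normalizer"]["scale"])
        est.arch_ = ArchitectureConfig(
            n_events=est.n_events,
            n_bins=est.grid_.n_bins,
            n_clinical=est.n_features_in_,
            conv_channels=tuple(est.conv_channels),
            dropout=est.dropout,
            leaky_slope=est.leaky_slope,
            image_dense_width=est.image_dense_width,
            clinical_dense_width=est.clinical_dense_width,
            shared_width=est.shared_width,
            head_width=est.head_width,
            use_images=est.use_images,
        )
        est.net_ = DeepHitNetwork(est.arch_, seed=est.random_state)
        est.net_.set_weights(weights)
        return est


def build_clinical_model(**kwargs) -> DeepHitSurvival:
    """Clinical-only comparator: identical network minus the image branch
    and its 512-node layer; shares every contract of the full model."""
    kwargs["use_images"] = False
    return DeepHitSurvival(**kwargs)


# ---------------------------------------------------------------------------
# Cross-validated training protocol


@dataclass
class CVResult:
    """Outputs of the repeated hold-out protocol."""

    models: list
    oof_pmf: np.ndarray  # (n, K, T), each patient predicted by its held-out model
    fold_id: np.ndarray
    grid: TimeGrid

    def oof_surface(self) -> RiskSurface:
        return RiskSurface(self.oof_pmf)


def train_cv(
    cohort: Cohort,
    estimator: DeepHitSurvival | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold repeated hold-out training.

    For each fold, a fresh clone of ``estimator`` is fitted on the other
    k-1 folds (fitting its own imputer/normalizer and inner validation
    split) and predicts the held-out fold.  Returns all k models plus the
    concatenated out-of-fold predictions covering every patient exactly
    once.
    """
    from sklearn.base import clone

    if estimator is None:
        estimator = DeepHitSurvival(random_state=seed)
    fold = stratified_kfold(cohort.outcomes, k=k, seed=seed)
    grid = TimeGrid(estimator.bin_width_days, estimator.horizon_days)
    n = len(cohort)
    oof = np.full((n, estimator.n_events, grid.n_bins), np.nan)
    models = []
    covered = np.zeros(n, dtype=bool)
    for f in range(k):
        test_idx = np.flatnonzero(fold == f)
        train_idx = np.flatnonzero(fold != f)
        if np.intersect1d(test_idx, train_idx).size:
            raise RuntimeError("leakage: test patients present in training set")
        est = clone(estimator)
        est.set_params(random_state=seed + f)
        tr = cohort.subset(train_idx)
        X_tr = (tr.maps, tr.clinical) if estimator.use_images else tr.clinical
        est.fit(X_tr, tr.outcomes)
        te = cohort.subset(test_idx)
        X_te = (te.maps, te.clinical) if estimator.use_images else te.clinical
        oof[test_idx] = est.predict_pmf(X_te)
        if covered[test_idx].any():
            raise RuntimeError("a patient received two out-of-fold predictions")
        covered[test_idx] = True
        models.append(est)
    if not covered.all():
        raise RuntimeError("some patients received no out-of-fold prediction")
    return CVResult(models=models, oof_pmf=oof, fold_id=fold, grid=grid)


def predict_external(models: list, cohort: Cohort) -> list[np.ndarray]:
    """Evaluate every cross-validation model on an external cohort.

    Each model applies its own stored imputer/normalizer; returns one pmf
    array (m, K, T) per model.  Downstream metrics are computed per set and
    summarized as mean with bootstrap confidence intervals.
    """
    out = []
    for est in models:
        if not hasattr(est, "imputer_"):
            raise ValueError("model lacks stored preprocessing state")
        X = (cohort.maps, cohort.clinical) if est.use_images else cohort.clinical
        out.append(est.predict_pmf(X))
    return out
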