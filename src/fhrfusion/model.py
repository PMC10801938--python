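"""End-to-end fetal-acidosis classifier: assembly, training, evaluation.

The network couples the expert-feature embedding, the SE-TCN signal
backbone and cross-modal attention fusion, topped by a two-layer softmax
head.  :class:`CTGFusionClassifier` wraps it as a scikit-learn estimator
(fit / predict_proba / predict) over raw 30-minute windows;
:func:`train_cv` trains a stratified k-fold ensemble whose test prediction
is the mean of the fold probabilities, and :func:`evaluate` computes the
clinical metrics (accuracy, specificity, sensitivity, precision, F1, as
percentages, pathological positive).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .backbone import BackboneConfig, SETCNBackbone
from .features import FEATURE_NAMES, ExpertFeatureExtractor
from .fusion import FUSION_MODES, CrossModalFusion, ExpertEmbedding
from .nn import (
    Adam,
    Dropout,
    Linear,
    Module,
    Tensor,
    concat,
    cosine_annealing_lr,
    cross_entropy_with_logits,
)

__all__ = [
    "Metrics",
    "evaluate",
    "FusionNet",
    "build_model",
    "CTGFusionClassifier",
    "FoldEnsemble",
    "train_cv",
    "stack_modalities",
    "split_modalities",
]

N_FEATURES = len(FEATURE_NAMES)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class Metrics:
    """Clinical classification metrics in percent (pathological = positive)."""

    accuracy: float
    specificity: float
    sensitivity: float
    precision: float
    f1: float

    def as_dict(self) -> Dict[str, float]:
        return asdict(self)


def evaluate(y_true: Sequence[int], y_pred: Sequence[int]) -> Metrics:
    """Accuracy/Spe/Sen/Pre/F1 from predicted labels, in percent.

    Undefined ratios (zero denominators) are reported as 0 with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    acc = ratio(tp + tn, len(y_true), "accuracy")
    sen = ratio(tp, tp + fn, "sensitivity")
    spe = ratio(tn, tn + fp, "specificity")
    pre = ratio(tp, tp + fp, "precision")
    f1 = 2 * pre * sen / (pre + sen) if (pre + sen) > 0 else 0.0
    return Metrics(
        accuracy=100 * acc,
        specificity=100 * spe,
        sensitivity=100 * sen,
        precision=100 * pre,
        f1=100 * f1,
    )


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------


class _Head(Module):
    """Classification head: Linear -> ReLU -> Dropout -> Linear (2 logits)."""

    def __init__(self, n_in: int, rng: np.random.Generator, hidden: int = 256,
                 dropout: float = 0.1):
        super().__init__()
        self.fc1 = Linear(n_in, hidden, rng)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Linear(hidden, 2, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class FusionNet(Module):
    """Complete multi-modal classifier with selectable fusion mode.

    Modes: ``cmff`` (cross-modal attention fusion), ``early`` (concatenated
    time-pooled latents), ``late`` (independent per-modality heads averaged
    1:1), ``expert_only``, ``signal_only``.
    """

    def __init__(
        self,
        backbone_cfg: BackboneConfig,
        n_heads: int = 8,
        fusion_mode: str = "cmff",
        dropout: float = 0.1,
        seed: int = 0,
    ):
        super().__init__()
        if fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        rng = np.random.default_rng(seed)
        self.fusion_mode = fusion_mode
        d = backbone_cfg.out_channels
        self.d_model = d
        self.uses_signal = fusion_mode != "expert_only"
        self.uses_expert = fusion_mode != "signal_only"
        self.backbone = SETCNBackbone(backbone_cfg, rng) if self.uses_signal else None
        self.embed = (
            ExpertEmbedding(N_FEATURES, d, rng) if self.uses_expert else None
        )
        self.cmff = (
            CrossModalFusion(d, n_heads, rng) if fusion_mode == "cmff" else None
        )
        if fusion_mode == "cmff":
            self.head = _Head(4 * d, rng, dropout=dropout)
        elif fusion_mode == "early":
            self.head = _Head(2 * d, rng, dropout=dropout)
        elif fusion_mode == "late":
            self.head_e = _Head(d, rng, dropout=dropout)
            self.head_s = _Head(d, rng, dropout=dropout)
        else:  # single modality
            self.head = _Head(d, rng, dropout=dropout)

    def forward(self, signal, feats):
        """Logits (B, 2); for late fusion, the pair of per-modality logits."""
        z_s = self.backbone(signal) if self.uses_signal else None
        z_e = self.embed(Tensor.as_tensor(feats)) if self.uses_expert else None
        mode = self.fusion_mode
        if mode == "cmff":
            return self.head(self.cmff(z_e, z_s))
        if mode == "early":
            return self.head(concat([z_e.mean(axis=1), z_s.mean(axis=1)], axis=-1))
        if mode == "late":
            return self.head_e(z_e.mean(axis=1)), self.head_s(z_s.mean(axis=1))
        if mode == "expert_only":
            return self.head(z_e.mean(axis=1))
        return self.head(z_s.mean(axis=1))

    def loss(self, signal, feats, targets) -> Tensor:
        out = self.forward(signal, feats)
        if self.fusion_mode == "late":
            le = cross_entropy_with_logits(out[0], targets)
            ls = cross_entropy_with_logits(out[1], targets)
            return (le + ls) * 0.5
        return cross_entropy_with_logits(out, targets)

    def predict_proba_batch(self, signal, feats) -> np.ndarray:
        from .nn.autograd import no_grad

        with no_grad():
            out = self.forward(signal, feats)

        def softmax(z: np.ndarray) -> np.ndarray:
            e = np.exp(z - z.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)

        if self.fusion_mode == "late":
            return 0.5 * (softmax(out[0].data) + softmax(out[1].data))
        return softmax(out.data)


def build_model(
    backbone_cfg: Optional[BackboneConfig] = None,
    fusion_mode: str = "cmff",
    n_heads: int = 8,
    dropout: float = 0.1,
    seed: int = 0,
) -> FusionNet:
    """Construct the classifier with seeded initialization."""
    cfg = backbone_cfg or BackboneConfig(seed=seed)
    if cfg.out_channels % n_heads:
        raise ValueError(
            f"backbone width {cfg.out_channels} not divisible by {n_heads} heads"
        )
    return FusionNet(cfg, n_heads=n_heads, fusion_mode=fusion_mode,
                     dropout=dropout, seed=seed)


# ---------------------------------------------------------------------------
# Data packing helpers
# ---------------------------------------------------------------------------


def stack_modalities(signals: np.ndarray, feats: np.ndarray) -> np.ndarray:
    """Pack signals (n, L) and features (n, 45) into one design matrix."""
    signals = np.asarray(signals, dtype=float)
    feats = np.asarray(feats, dtype=float)
    if signals.shape[0] != feats.shape[0]:
        raise ValueError("signals and features differ in sample count")
    return np.hstack([signals, feats])


def split_modalities(
    X: np.ndarray, input_length: int
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Undo :func:`stack_modalities`; returns (signals, features-or-None)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if X.shape[1] == input_length:
        return X, None
    if X.shape[1] == input_length + N_FEATURES:
        return X[:, :input_length], X[:, input_length:]
    raise ValueError(
        f"X must have {input_length} (signal) or {input_length + N_FEATURES} "
        f"(signal+features) columns, got {X.shape[1]}"
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class CTGFusionClassifier(ClassifierMixin, BaseEstimator):
    """Multi-modal fetal-acidosis classifier over raw 30-minute FHR windows.

    Parameters mirror the reference training recipe: Adam, batch 16,
    cosine-annealing learning rate starting at 2.5e-4 with restart decay
    0.8, dropout 0.1, kernel 15, 8 attention heads.  ``X`` passed to
    :meth:`fit` is either ``(n, input_length)`` cleaned windows (expert
    features are computed internally) or ``(n, input_length + 45)`` windows
    with precomputed features appended (see :func:`stack_modalities`).

    Class 1 (pathological) is the positive class; ties at probability 0.5
    go to pathological.
    """

    def __init__(
        self,
        fusion_mode: str = "cmff",
        kernel_size: int = 15,
        num_heads: int = 8,
        channels: Tuple[int, ...] = (64, 64, 128, 128, 256),
        dilations: Tuple[int, ...] = (2, 4, 8, 16, 32),
        strides: Tuple[int, ...] = (3, 1, 3, 1, 2),
        mdsc_kernel_sizes: Tuple[int, ...] = (1, 3, 5, 7),
        mdsc_channels: int = 16,
        se_reduction: int = 16,
        se_enabled: bool = True,
        dropout: float = 0.1,
        epochs: int = 120,
        batch_size: int = 16,
        learning_rate: float = 2.5e-4,
        lr_restart_period: int = 30,
        lr_restart_decay: float = 0.8,
        early_stopping_patience: int = 10,
        validation_fraction: float = 0.0,
        oversample: bool = False,
        input_length: int = 7200,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.fusion_mode = fusion_mode
        self.kernel_size = kernel_size
        self.num_heads = num_heads
        self.channels = channels
        self.dilations = dilations
        self.strides = strides
        self.mdsc_kernel_sizes = mdsc_kernel_sizes
        self.mdsc_channels = mdsc_channels
        self.se_reduction = se_reduction
        self.se_enabled = se_enabled
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lr_restart_period = lr_restart_period
        self.lr_restart_decay = lr_restart_decay
        self.early_stopping_patience = early_stopping_patience
        self.validation_fraction = validation_fraction
        self.oversample = oversample
        self.input_length = input_length
        self.random_state = random_state
        self.verbose = verbose

    # -- internals -----------------------------------------------------------

    def _backbone_config(self) -> BackboneConfig:
        return BackboneConfig(
            kernel_size=self.kernel_size,
            dilations=tuple(self.dilations),
            strides=tuple(self.strides),
            channels=tuple(self.channels),
            mdsc_kernel_sizes=tuple(self.mdsc_kernel_sizes),
            mdsc_channels=self.mdsc_channels,
            dropout=self.dropout,
            se_reduction=self.se_reduction,
            se_enabled=self.se_enabled,
            input_length=self.input_length,
            seed=self.random_state,
        )

    def _prepare(self, X, fit_scalers: bool) -> Tuple[np.ndarray, np.ndarray]:
        signals, feats = split_modalities(X, self.input_length)
        if feats is None:
            feats = ExpertFeatureExtractor().fit(signals).transform(signals)
        if fit_scalers:
            self.signal_mean_ = float(signals.mean())
            self.signal_std_ = float(signals.std()) or 1.0
            self.feature_mean_ = feats.mean(axis=0)
            std = feats.std(axis=0)
            self.feature_std_ = np.where(std > 0, std, 1.0)
        s = (signals - self.signal_mean_) / self.signal_std_
        f = (feats - self.feature_mean_) / self.feature_std_
        return (
            s[:, :, None].astype(np.float32),
            f.astype(np.float32),
        )

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam + cosine annealing; optional early stopping.

        A validation set for early stopping comes either from ``X_val`` /
        ``y_val`` or from an internal stratified split when
        ``validation_fraction`` > 0.
        """
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])
        rng = np.random.default_rng(self.random_state)

        if X_val is None and self.validation_fraction > 0:
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)),
                test_size=self.validation_fraction,
                stratify=y,
                random_state=self.random_state,
            )
            X, X_val = np.asarray(X)[idx_tr], np.asarray(X)[idx_va]
            y, y_val = y[idx_tr], y[idx_va]

        sig, feat = self._prepare(X, fit_scalers=True)
        if self.oversample:
            sig, feat, y = _oversample_minority(sig, feat, y, rng)
        if X_val is not None:
            sig_va, feat_va = self._prepare(X_val, fit_scalers=False)
            y_va = np.asarray(y_val, dtype=int)
        else:
            sig_va = None

        self.model_ = build_model(
            self._backbone_config(),
            fusion_mode=self.fusion_mode,
            n_heads=self.num_heads,
            dropout=self.dropout,
            seed=self.random_state,
        )
        opt = Adam(self.model_.parameters(), lr=self.learning_rate)
        n = len(y)
        best_val, best_state, patience_left = np.inf, None, self.early_stopping_patience
        self.history_: List[Dict[str, float]] = []
        for epoch in range(self.epochs):
            opt.lr = cosine_annealing_lr(
                epoch, self.learning_rate, self.lr_restart_period,
                self.lr_restart_decay,
            )
            order = rng.permutation(n)
            self.model_.train()
            total = 0.0
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                loss = self.model_.loss(sig[b], feat[b], y[b])
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * b.size
            entry = {"epoch": epoch, "train_loss": total / n, "lr": opt.lr}
            if sig_va is not None:
                self.model_.eval()
                proba = self._proba_batched(sig_va, feat_va)
                eps = 1e-12
                val_loss = float(
                    -np.mean(np.log(proba[np.arange(len(y_va)), y_va] + eps))
                )
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = [a.copy() for a in self.model_.state_arrays()]
                    patience_left = self.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        self.history_.append(entry)
                        break
            self.history_.append(entry)
            if self.verbose:
                print(f"epoch {epoch}: " + ", ".join(
                    f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch"))
        if best_state is not None:
            self.model_.load_state_arrays(best_state)
        self.model_.eval()
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _proba_batched(self, sig: np.ndarray, feat: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(sig), self.batch_size):
            out.append(
                self.model_.predict_proba_batch(
                    sig[start : start + self.batch_size],
                    feat[start : start + self.batch_size],
                )
            )
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        self.model_.eval()
        sig, feat = self._prepare(X, fit_scalers=False)
        return self._proba_batched(sig, feat)

    def predict(self, X) -> np.ndarray:
        # tie-break: probability exactly 0.5 goes to pathological
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _oversample_minority(sig, feat, y, rng: np.random.Generator):
    """Resample the minority class with replacement to a balanced train set."""
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    need = counts.max() - counts.min()
    if need == 0:
        return sig, feat, y
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=need, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return sig[idx], feat[idx], y[idx]


# ---------------------------------------------------------------------------
# Cross-validated ensemble
# ---------------------------------------------------------------------------


class FoldEnsemble:
    """Bag of per-fold models; test probability = mean of fold probabilities."""

    def __init__(self, models: List[CTGFusionClassifier],
                 fold_metrics: List[Metrics]):
        self.models = models
        self.fold_metrics = fold_metrics
        self.classes_ = np.array([0, 1])

    def predict_proba(self, X) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.models], axis=0)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_cv(
    X,
    y,
    estimator: Optional[CTGFusionClassifier] = None,
    n_folds: int = 5,
    random_state: int = 0,
) -> FoldEnsemble:
    """Stratified k-fold ensemble training with per-fold early stopping.

    Each fold trains on k-1 parts with the held-out part as its validation
    set (early stopping / best-weight restore); the returned ensemble
    averages the fold probabilities.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("dataset must contain both classes")
    X = np.asarray(X)
    base = estimator if estimator is not None else CTGFusionClassifier()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    models: List[CTGFusionClassifier] = []
    fold_metrics: List[Metrics] = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        m = copy.deepcopy(base)
        m.random_state = base.random_state + fold
        m.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
        fold_metrics.append(evaluate(y[va], m.predict(X[va])))
        models.append(m)
    return FoldEnsemble(models, fold_metrics)


def predict_record(model, record, feats: Optional[np.ndarray] = None):
    """Probability of acidosis and label for one cleaned, windowed record.

    ``model`` is any fitted estimator/ensemble with ``predict_proba``.
    """
    from .records import WINDOW_SAMPLES

    fhr = np.asarray(record.fhr, dtype=float)
    length = getattr(model, "input_length", WINDOW_SAMPLES)
    if fhr.size != length:
        raise ValueError(
            f"record has {fhr.size} samples; window it to {length} first"
        )
    X = fhr[None, :]
    if feats is not None:
        X = stack_modalities(X, np.atleast_2d(feats))
    p = float(model.predict_proba(X)[0, 1])
    return p, int(p >= 0.5)
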