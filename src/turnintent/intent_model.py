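"""Turn / no-turn classifiers: three MLP variants with cross-validation.

The network is the recipe used for all three variants: two hidden layers
of 25 rectified-linear units with 10% dropout, a sigmoid output, binary
cross-entropy loss, Adam for 500 epochs, evaluated with five-fold
cross-validation. Accuracy is (TP+TN)/(TP+TN+FP+FN) with "turn" as the
positive class, so a false negative is a missed turn — the safety-critical
cell. The implementation is a small, fully seeded numpy network so that
identical seeds give identical predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GroupKFold, KFold

from . import features as feat
from .features import EpochSet, FeatureMatrix

__all__ = [
    "NetConfig",
    "MLP",
    "TrainedClassifier",
    "EvalReport",
    "CVResult",
    "train_classifier",
    "evaluate",
    "run_cv",
    "cross_validate",
]


@dataclass(frozen=True)
class NetConfig:
    hidden_layers: int = 2
    hidden_units: int = 25
    dropout_rate: float = 0.10
    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None = full batch
    n_folds: int = 5
    threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


class MLP:
    """Seeded ReLU MLP with dropout, sigmoid output and Adam training.

    Dropout (inverted scaling) is active only during training; prediction
    is a deterministic forward pass.
    """

    def __init__(self, n_in: int, cfg: NetConfig, seed: int):
        rng = np.random.default_rng(seed)
        dims = [n_in] + [cfg.hidden_units] * cfg.hidden_layers + [1]
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            bound = np.sqrt(6.0 / fan_in)  # uniform fan-in (He-style) init
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self.cfg = cfg
        self._rng = rng

    def _forward(self, X, train=False):
        acts = [X]
        h = X
        masks = []
        p = self.cfg.dropout_rate
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if k < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if train and p > 0:
                    m = (self._rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                out = 1.0 / (1.0 + np.exp(-z))
        return out.ravel(), acts, masks

    def fit(self, X: np.ndarray, y: np.ndarray) -> float:
        cfg = self.cfg
        n = X.shape[0]
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        batch = cfg.batch_size or n
        loss = np.inf
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n) if batch < n else np.arange(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                Xb, yb = X[idx], y[idx]
                p, acts, masks = self._forward(Xb, train=True)
                pc = np.clip(p, 1e-12, 1 - 1e-12)
                loss = float(-np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                # backprop: sigmoid + BCE collapse to (p - y)
                delta = ((p - yb) / len(yb))[:, None]
                grads_W, grads_b = [], []
                for k in range(len(self.W) - 1, -1, -1):
                    a = acts[k]
                    grads_W.append(a.T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if k > 0:
                        delta = delta @ self.W[k].T
                        delta = delta * (acts[k] > 0)
                        if masks[k - 1] is not None:
                            delta = delta * masks[k - 1]
                grads_W.reverse()
                grads_b.reverse()
                t += 1
                for k in range(len(self.W)):
                    for g, m, v, param in (
                        (grads_W[k], mW, vW, self.W),
                        (grads_b[k], mb, vb, self.b),
                    ):
                        m[k] = b1 * m[k] + (1 - b1) * g
                        v[k] = b2 * v[k] + (1 - b2) * g * g
                        mhat = m[k] / (1 - b1 ** t)
                        vhat = v[k] / (1 - b2 ** t)
                        param[k] = param[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return loss

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float), train=False)[0]


@dataclass
class TrainedClassifier:
    model: MLP
    variant: str
    feature_names: list[str]
    final_train_loss: float
    train_accuracy: float
    seed: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


@dataclass
class EvalReport:
    """Confusion counts, accuracy and ROC for one test split."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    auc: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    scores: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_true: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def false_negative_rate(self) -> float:
        """Missed turns / actual turns (the safety-critical rate)."""
        denom = self.tp + self.fn
        return self.fn / denom if denom else np.nan

    def confusion_normalized(self) -> np.ndarray:
        """Rows = true (no-turn, turn), normalized per true class."""
        m = np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=float)
        sums = m.sum(axis=1, keepdims=True)
        return np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)


def train_classifier(fm: FeatureMatrix, cfg: NetConfig,
                     seed: int | None = None) -> TrainedClassifier:
    """Fit one network on a training feature matrix."""
    if len(np.unique(fm.y)) < 2:
        raise ValueError("training split contains a single class")
    seed = cfg.rng_seed if seed is None else seed
    mlp = MLP(fm.n_features, cfg, seed)
    loss = mlp.fit(fm.X.astype(float), fm.y.astype(float))
    acc = float(np.mean((mlp.predict_proba(fm.X) >= cfg.threshold) == fm.y))
    return TrainedClassifier(model=mlp, variant=fm.variant,
                             feature_names=fm.feature_names,
                             final_train_loss=loss, train_accuracy=acc,
                             seed=seed)


def evaluate(clf: TrainedClassifier, test: FeatureMatrix,
             threshold: float = 0.5) -> EvalReport:
    """Confusion matrix at the threshold, accuracy, ROC sweep and AUC."""
    if test.n_instances == 0:
        raise ValueError("empty test split")
    scores = clf.predict_proba(test.X)
    return report_from_scores(test.y, scores, threshold)


def report_from_scores(y_true: np.ndarray, scores: np.ndarray,
                       threshold: float = 0.5) -> EvalReport:
    y_true = np.asarray(y_true).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    accuracy = (tp + tn) / len(y_true)
    if len(np.unique(y_true)) == 2:
        fpr, tpr, _ = roc_curve(y_true, scores)
        auc_val = float(_trapezoid_auc(fpr, tpr))
        roc_points = np.column_stack([fpr, tpr])
    else:
        auc_val = np.nan
        roc_points = np.empty((0, 2))
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                      auc=auc_val, roc_points=roc_points,
                      scores=scores, y_true=y_true)


@dataclass
class CVResult:
    """Per-fold reports plus the aggregates reported for one subject."""

    variant: str
    folds: list[EvalReport]
    median_accuracy: float
    pooled_accuracy: float
    mean_auc: float
    sd_auc: float
    mean_confusion: np.ndarray  # per-true-class normalized, fold-averaged
    mean_fn_rate: float
    median_train_accuracy: float
    fold_models: list[TrainedClassifier] = field(default_factory=list)
    fold_test_matrices: list[FeatureMatrix] = field(default_factory=list)


def _fold_indices(groups: np.ndarray, n_folds: int, grouped: bool, seed: int):
    if grouped:
        splitter = GroupKFold(n_splits=n_folds)
        return list(splitter.split(np.zeros_like(groups), groups=groups))
    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2 ** 31))
    return list(splitter.split(np.zeros_like(groups)))


def cross_validate(epochs: EpochSet, variant: str, cfg: NetConfig,
                   grouped: bool = True, keep_models: bool = False) -> CVResult:
    """Five-fold cross-validation with fold-local PCA and standardization.

    For every fold the PCA eigenvectors and the feature standardization
    statistics are refitted on that fold's training epochs only, then
    frozen and applied to the test epochs — no test-set leakage. Folds are
    grouped by intersection by default so the 16 instances of one
    intersection never straddle the split; ``grouped=False`` gives plain
    instance-level splitting.
    """
    if len(epochs) < cfg.n_folds:
        raise ValueError("fewer epochs than folds")
    # folds are defined over epochs; both windows of an intersection share
    # a group id, so grouped splitting keeps them together
    idx_folds = _fold_indices(epochs.intersection_ids, cfg.n_folds, grouped,
                              cfg.rng_seed)
    reports: list[EvalReport] = []
    models, test_fms = [], []
    train_accs = []
    for k, (tr, te) in enumerate(idx_folds):
        ep_tr, ep_te = epochs.subset(tr), epochs.subset(te)
        if len(np.unique(ep_te.labels)) < 2:
            warnings.warn(f"fold {k}: single-class test split, skipped")
            continue
        pca = (feat.fit_pca(ep_tr) if variant in ("fnirs", "combined") else None)
        fm_tr = feat.build_features(ep_tr, pca, variant)
        fm_te = feat.build_features(ep_te, pca, variant)
        fm_tr, fm_te = feat.standardize_features(fm_tr, fm_te)
        clf = train_classifier(fm_tr, cfg, seed=cfg.rng_seed * 1000 + k)
        reports.append(evaluate(clf, fm_te, cfg.threshold))
        train_accs.append(clf.train_accuracy)
        if keep_models:
            models.append(clf)
            test_fms.append(fm_te)
    if not reports:
        raise ValueError("no usable folds")

    pooled_correct = sum(r.tp + r.tn for r in reports)
    pooled_n = sum(r.n for r in reports)
    aucs = np.array([r.auc for r in reports], dtype=float)
    return CVResult(
        variant=variant,
        folds=reports,
        median_accuracy=float(np.median([r.accuracy for r in reports])),
        pooled_accuracy=pooled_correct / pooled_n,
        mean_auc=float(np.nanmean(aucs)),
        sd_auc=float(np.nanstd(aucs)),
        mean_confusion=np.mean([r.confusion_normalized() for r in reports], axis=0),
        mean_fn_rate=float(np.nanmean([r.false_negative_rate for r in reports])),
        median_train_accuracy=float(np.median(train_accs)),
        fold_models=models,
        fold_test_matrices=test_fms,
    )


def run_cv(epochs: EpochSet, cfg: NetConfig, variants: tuple[str, ...] | None = None,
           grouped: bool = True, keep_models: bool = False) -> dict[str, CVResult]:
    """Cross-validate every model variant on one subject's epochs."""
    variants = variants or feat.VARIANTS
    return {v: cross_validate(epochs, v, cfg, grouped=grouped,
                              keep_models=keep_models) for v in variants}
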