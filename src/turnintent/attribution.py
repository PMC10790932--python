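"""Monte-Carlo Shapley feature attribution with an exact-enumeration oracle.

The estimator is the permutation-sampling form: for feature j and an
instance x, draw M (permutation, background-instance) pairs; x_{+j} takes
x's values on j and on the features preceding j in the permutation and
background values elsewhere, x_{-j} additionally replaces feature j with
the background value; the Shapley estimate is the mean of the M prediction
differences f(x_{+j}) - f(x_{-j}). Global importance of feature j is the
mean absolute Shapley value over instances, I_j = (1/n) sum_i |phi_j(i)|.
The background ("random feature values") is an empirical pool, by default
the training split.

``shap_exact`` enumerates all 2^p coalitions with the same background-
imputation value function; it satisfies the efficiency, symmetry, dummy
and linearity axioms exactly and serves as the test oracle for the
Monte-Carlo estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "ShapReport",
    "shap_mc",
    "shap_exact",
    "shap_dataset",
    "global_importance",
    "stratified_beeswarm",
]

DEFAULT_M = 2000


@dataclass
class ShapReport:
    """Per-instance Shapley values and the data for beeswarm/bar plots."""

    phi: np.ndarray  # instances x features
    feature_names: list[str]
    feature_values: np.ndarray  # instances x features, min-max normalized
    raw_feature_values: np.ndarray
    M: int
    background_id: str = "train"
    labels: np.ndarray | None = None

    @property
    def global_importance(self) -> np.ndarray:
        return np.abs(self.phi).mean(axis=0)

    def subset(self, mask: np.ndarray) -> "ShapReport":
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.sum() == 0:
            raise ValueError("mask selects no instances")
        if mask.dtype != bool and len(mask) == 0:
            raise ValueError("mask selects no instances")
        return ShapReport(
            phi=self.phi[mask],
            feature_names=self.feature_names,
            feature_values=self.feature_values[mask],
            raw_feature_values=self.raw_feature_values[mask],
            M=self.M,
            background_id=self.background_id,
            labels=None if self.labels is None else self.labels[mask],
        )


def _as_predict_fn(model):
    if callable(model):
        return model
    if hasattr(model, "predict_proba"):
        return model.predict_proba
    raise TypeError("model must be callable or expose predict_proba")


def shap_mc(model, instance: np.ndarray, background: np.ndarray, M: int = DEFAULT_M,
            seed: int | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Permutation-sampling Monte-Carlo Shapley values for one instance."""
    if M <= 0:
        raise ValueError("M must be >= 1")
    f = _as_predict_fn(model)
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != x.size:
        raise ValueError("background must be (n, p) with p matching the instance")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = x.size

    phi = np.zeros(p)
    # shared draws across features would bias nothing but correlate errors;
    # draw fresh permutations and background rows per feature
    for j in range(p):
        ranks = np.argsort(rng.random((M, p)), axis=1).argsort(axis=1)
        z = bg[rng.integers(0, bg.shape[0], size=M)]
        before = ranks < ranks[:, [j]]
        x_plus = np.where(before, x, z)
        x_plus[:, j] = x[j]
        x_minus = x_plus.copy()
        x_minus[:, j] = z[:, j]
        preds = f(np.vstack([x_plus, x_minus]))
        phi[j] = float(np.mean(preds[:M] - preds[M:]))
    return phi


def shap_mc_se(model, instance, background, M: int = DEFAULT_M,
               seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo Shapley values together with their standard errors."""
    if M <= 0:
        raise ValueError("M must be >= 1")
    f = _as_predict_fn(model)
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    rng = np.random.default_rng(seed)
    p = x.size
    phi = np.zeros(p)
    se = np.zeros(p)
    for j in range(p):
        ranks = np.argsort(rng.random((M, p)), axis=1).argsort(axis=1)
        z = bg[rng.integers(0, bg.shape[0], size=M)]
        before = ranks < ranks[:, [j]]
        x_plus = np.where(before, x, z)
        x_plus[:, j] = x[j]
        x_minus = x_plus.copy()
        x_minus[:, j] = z[:, j]
        preds = f(np.vstack([x_plus, x_minus]))
        diffs = preds[:M] - preds[M:]
        phi[j] = float(diffs.mean())
        se[j] = float(diffs.std(ddof=1) / np.sqrt(M)) if M > 1 else np.inf
    return phi, se


def shap_exact(model, instance: np.ndarray, background: np.ndarray,
               max_features: int = 12) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration.

    The value of coalition S is the background-imputation expectation
    v(S) = mean_z f(x_S, z_{\\bar S}) over the background pool. Exponential
    in the feature count; use :func:`shap_mc` beyond ``max_features``.
    """
    f = _as_predict_fn(model)
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[1] != x.size:
        raise ValueError("background must be (n, p) with p matching the instance")
    p = x.size
    if p > max_features:
        raise ValueError(f"{p} features exceed the enumeration limit "
                         f"{max_features}; use shap_mc")
    nb = bg.shape[0]
    n_coal = 1 << p
    masks = (np.arange(n_coal)[:, None] >> np.arange(p)) & 1  # coalitions x p

    # v(S) for every coalition: average prediction with S from x, rest from bg
    composite = np.where(masks[:, None, :].astype(bool), x, bg[None, :, :])
    preds = f(composite.reshape(-1, p)).reshape(n_coal, nb)
    v = preds.mean(axis=1)

    sizes = masks.sum(axis=1)
    weights = np.array([factorial(s) * factorial(p - s - 1) / factorial(p)
                        for s in range(p)])
    phi = np.zeros(p)
    for j in range(p):
        without = np.flatnonzero(masks[:, j] == 0)
        with_j = without | (1 << j)
        phi[j] = np.sum(weights[sizes[without]] * (v[with_j] - v[without]))
    return phi


def shap_dataset(model, X: np.ndarray, background: np.ndarray,
                 feature_names: list[str], M: int = DEFAULT_M,
                 seed: int = 0, labels: np.ndarray | None = None) -> ShapReport:
    """Monte-Carlo Shapley values for every row of ``X``.

    Feature values are min-max normalized per feature for beeswarm
    color-coding.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    phi = np.vstack([shap_mc(model, X[i], background, M=M, rng=rng)
                     for i in range(X.shape[0])])
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    norm = (X - lo) / span
    return ShapReport(phi=phi, feature_names=list(feature_names),
                      feature_values=norm, raw_feature_values=X, M=M,
                      labels=labels)


def global_importance(report: ShapReport) -> tuple[np.ndarray, list[str]]:
    """Mean |phi| per feature, sorted descending with matching names."""
    if report.phi.size == 0:
        raise ValueError("empty report")
    imp = report.global_importance
    order = np.argsort(imp)[::-1]
    return imp[order], [report.feature_names[k] for k in order]


def stratified_beeswarm(report: ShapReport, mask: np.ndarray) -> ShapReport:
    """Restrict a report to the instances selected by ``mask``.

    Used e.g. to compare attributions on context-model false negatives
    with below- vs above-average context feature values.
    """
    return report.subset(mask)
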