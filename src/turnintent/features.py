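"""Event-locked epoching, windowed standardization, PCA and feature assembly.

Each intersection yields two 4-s HbR epochs at 2 Hz (8 samples each): a
"turn" window from 2 s before the accelerator press to 2 s after (the
hemodynamic delay places the decision-related response there), and a
"no turn" waiting window ending 0.5 s before the turn window. Brain
activity is standardized within each 4-s window per channel, PCA is fitted
on the training epochs only (time samples as observations, channels as
variables), components with eigenvalues below 0.7 are discarded
(Kaiser/Jolliffe rule) and the first component is excluded as a movement-
artifact catcher; components 2-8 provide the seven fNIRS features. With
the per-intersection context pair (gap size, cars waited) this gives the
three model variants: context (2 features), fnirs (7) and combined (9).
One classifier instance is one window time sample, so 100 intersections
x 2 windows x 8 samples = 1,600 instances per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import ConcentrationSeries
from .simdata import EventLog

__all__ = [
    "EpochSet",
    "PCAModel",
    "FeatureMatrix",
    "extract_epochs",
    "standardize_windows",
    "fit_pca",
    "retained_after_rules",
    "build_features",
    "standardize_features",
    "VARIANTS",
]

VARIANTS = ("context", "fnirs", "combined")

TURN_PRE_S = 2.0
WINDOW_S = 4.0
PHASE_GAP_S = 0.5


@dataclass
class EpochSet:
    """Event-locked 4-s HbR windows with labels and per-epoch context.

    ``samples`` holds the raw (band-passed, un-standardized) HbR windows;
    window standardization is applied downstream where PC projection needs
    it, so that effect-size analysis can still see window-mean differences.
    """

    samples: np.ndarray  # epochs x channels x window samples
    labels: np.ndarray  # 1 = turn, 0 = no_turn
    intersection_ids: np.ndarray
    gap_size: np.ndarray  # per-epoch context (phase-specific)
    cars_waited: np.ndarray
    atypical: np.ndarray
    sampling_rate: float
    channel_indices: np.ndarray

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def samples_per_window(self) -> int:
        return self.samples.shape[2]

    def subset(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            samples=self.samples[idx],
            labels=self.labels[idx],
            intersection_ids=self.intersection_ids[idx],
            gap_size=self.gap_size[idx],
            cars_waited=self.cars_waited[idx],
            atypical=self.atypical[idx],
            sampling_rate=self.sampling_rate,
            channel_indices=self.channel_indices,
        )


def extract_epochs(conc: ConcentrationSeries, log: EventLog) -> EpochSet:
    """Cut turn / no-turn windows around each accelerator press.

    Turn window [press-2, press+2), no-turn window [press-6.5, press-2.5),
    half-open at sample resolution with the press snapped to the nearest
    sample. Intersections whose windows fall outside the recording are
    skipped with a warning.
    """
    fs = conc.sampling_rate
    w = int(round(WINDOW_S * fs))
    n = conc.n_samples
    ev = log.events

    samples, labels, iids, gaps, cars, atyps = [], [], [], [], [], []
    for _, row in ev.iterrows():
        press_idx = int(round(row.press_time_s * fs))
        turn_start = press_idx - int(round(TURN_PRE_S * fs))
        noturn_start = turn_start - int(round(PHASE_GAP_S * fs)) - w
        if noturn_start < 0 or turn_start + w > n:
            warnings.warn(
                f"intersection {int(row.intersection_id)}: window out of bounds, skipped"
            )
            continue
        for label, start, gap, waited in (
            (1, turn_start, row.gap_size_s, row.cars_waited),
            (0, noturn_start, row.noturn_gap_size_s, row.noturn_cars_waited),
        ):
            samples.append(conc.hbr[:, start:start + w])
            labels.append(label)
            iids.append(int(row.intersection_id))
            gaps.append(float(gap))
            cars.append(int(waited))
            atyps.append(bool(row.atypical))

    if not samples:
        raise ValueError("no epochs could be extracted")
    return EpochSet(
        samples=np.stack(samples),
        labels=np.asarray(labels),
        intersection_ids=np.asarray(iids),
        gap_size=np.asarray(gaps),
        cars_waited=np.asarray(cars),
        atypical=np.asarray(atyps),
        sampling_rate=fs,
        channel_indices=conc.retained_channels,
    )


def standardize_windows(samples: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-SD each channel within each 4-s window.

    Channels with zero within-window variance map to zeros.
    """
    mean = samples.mean(axis=-1, keepdims=True)
    sd = samples.std(axis=-1, keepdims=True)
    out = np.zeros_like(samples)
    np.divide(samples - mean, sd, out=out, where=sd > 0)
    return out


@dataclass
class PCAModel:
    """Channel-space PCA with eigenvalue retention and first-PC exclusion."""

    eigenvectors: np.ndarray  # channels x components (columns orthonormal)
    eigenvalues: np.ndarray  # descending
    mean: np.ndarray  # per-channel training mean
    retained_indices: np.ndarray  # 1-based components kept by the 0.7 rule
    dropped_first: bool
    model_feature_indices: np.ndarray  # 1-based components fed to classifiers

    def transform(self, epochs: EpochSet) -> np.ndarray:
        """PC scores for every window time sample (instances x components)."""
        x = standardize_windows(epochs.samples)  # epochs x channels x w
        x = np.moveaxis(x, 1, 2).reshape(-1, x.shape[1])  # (epochs*w) x channels
        return (x - self.mean) @ self.eigenvectors

    def model_scores(self, epochs: EpochSet) -> np.ndarray:
        return self.transform(epochs)[:, self.model_feature_indices - 1]


def retained_after_rules(eigenvalues: np.ndarray, cutoff: float = 0.7,
                         drop_first: bool = True) -> np.ndarray:
    """Apply the eigenvalue-cutoff retention rule, then drop the first PC.

    Returns 1-based component indices usable as model features.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    keep = np.flatnonzero(eigenvalues >= cutoff) + 1
    if drop_first:
        keep = keep[keep != 1]
    return keep


def fit_pca(train_epochs: EpochSet, eig_cutoff: float = 0.7,
            drop_first: bool = True,
            model_components: tuple[int, int] = (2, 8)) -> PCAModel:
    """Fit channel-space PCA on training-epoch time samples.

    Every time sample of every training window is one observation and
    channels are the variables, so eigenvectors live in channel space
    (their loadings map components back onto the optode montage). Because
    each window is standardized per channel first, per-channel variance is
    ~1 and the 0.7 eigenvalue cutoff acts like a correlation-matrix Kaiser
    rule.
    """
    if len(train_epochs) < 2:
        raise ValueError("need at least 2 training epochs")
    x = standardize_windows(train_epochs.samples)
    x = np.moveaxis(x, 1, 2).reshape(-1, x.shape[1])
    if x.shape[1] < 2:
        raise ValueError("need at least 2 channels")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant channel in training epochs")
    pca = PCA(svd_solver="full")
    pca.fit(x)
    retained = retained_after_rules(pca.explained_variance_, eig_cutoff, drop_first)
    lo, hi = model_components
    model_idx = np.arange(lo, hi + 1)
    return PCAModel(
        eigenvectors=pca.components_.T,
        eigenvalues=pca.explained_variance_,
        mean=pca.mean_,
        retained_indices=retained,
        dropped_first=drop_first,
        model_feature_indices=model_idx,
    )


@dataclass
class FeatureMatrix:
    """Per-instance features for one model variant.

    One instance per window time sample. Continuous features are
    standardized with training-split statistics; the discrete cars-waited
    count is passed through unscaled.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    variant: str
    groups: np.ndarray  # intersection id per instance
    atypical: np.ndarray
    standardization: dict = field(default_factory=dict)

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_features(epochs: EpochSet, pca: PCAModel | None, variant: str
                   ) -> FeatureMatrix:
    """Assemble the (unstandardized) instance matrix for a variant.

    fNIRS features are PC scores of components 2-8 at each window sample;
    context features (gap size, cars waited) repeat across a window's 8
    samples and are phase-specific (accepted gap for the turn window, the
    gap on offer during the waiting window for no-turn).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    w = epochs.samples_per_window
    y = np.repeat(epochs.labels, w)
    groups = np.repeat(epochs.intersection_ids, w)
    atypical = np.repeat(epochs.atypical, w)

    blocks, names = [], []
    if variant in ("context", "combined"):
        blocks.append(np.repeat(epochs.gap_size, w)[:, None])
        blocks.append(np.repeat(epochs.cars_waited, w)[:, None].astype(float))
        names += ["gap_size", "cars_waited"]
    if variant in ("fnirs", "combined"):
        if pca is None:
            raise ValueError(f"variant {variant!r} requires a fitted PCAModel")
        hi = pca.model_feature_indices.max()
        if pca.eigenvectors.shape[1] < hi:
            raise ValueError(
                f"only {pca.eigenvectors.shape[1]} components available, "
                f"{hi} needed; widen component retention"
            )
        scores = pca.model_scores(epochs)
        blocks.append(scores)
        names += [f"PC{k}" for k in pca.model_feature_indices]
    X = np.hstack(blocks)
    return FeatureMatrix(X=X, y=y, feature_names=names, variant=variant,
                         groups=groups, atypical=atypical)


def standardize_features(train: FeatureMatrix, *others: FeatureMatrix
                         ) -> tuple[FeatureMatrix, ...]:
    """Standardize continuous features with training-split statistics.

    All features except the discrete ``cars_waited`` are scaled to train
    mean 0 / SD 1; the same affine map is applied to every other split.
    """
    cont = np.array([nm != "cars_waited" for nm in train.feature_names])
    mu = train.X[:, cont].mean(axis=0)
    sd = train.X[:, cont].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    stats = {"continuous_mask": cont, "mean": mu, "sd": sd}

    out = []
    for fm in (train, *others):
        X = fm.X.copy()
        X[:, cont] = (X[:, cont] - mu) / sd
        out.append(FeatureMatrix(X=X, y=fm.y, feature_names=fm.feature_names,
                                 variant=fm.variant, groups=fm.groups,
                                 atypical=fm.atypical, standardization=stats))
    return tuple(out)
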