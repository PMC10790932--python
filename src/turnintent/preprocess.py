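"""Raw optical intensities -> band-limited HbO/HbR concentration changes.

The chain is: automated bad-channel rejection (robust spike score),
modified Beer-Lambert conversion of optical-density changes to chromophore
concentration changes, and a zero-phase 0.01-0.1 Hz Butterworth band-pass
that suppresses cardiac, respiratory and Mayer-wave physiology together
with slow drift. The band-pass and the Beer-Lambert relation are both
linear, so filtering the concentration series is numerically equivalent
(to first order in optical density) to filtering the raw data first, and
keeps the logarithmic conversion well defined.

Only HbR propagates to the downstream classifiers; HbO is computed and
carried for completeness but never used as a model input, as HbR is less
contaminated by systemic physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .simdata import (
    DEFAULT_DPF,
    DEFAULT_EXTINCTION,
    DEFAULT_SD_DISTANCE_CM,
    OpticalRecording,
)

__all__ = [
    "PreprocessConfig",
    "ConcentrationSeries",
    "bandpass_array",
    "bandpass",
    "reject_channels",
    "beer_lambert",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = (0.01, 0.1)  # Hz
    filter_order: int = 3
    spike_z_threshold: float = 8.0
    dpf: tuple[float, float] = DEFAULT_DPF
    extinction_coeffs: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy()
    )  # wavelengths x (HbO, HbR), 1/(mmol/l)/cm
    sd_distance_cm: float = DEFAULT_SD_DISTANCE_CM

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError("band must satisfy 0 < low < high")
        if any(d <= 0 for d in self.dpf):
            raise ValueError("dpf must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass
class ConcentrationSeries:
    """Per-channel HbO/HbR concentration change (mmol/l, relative)."""

    hbo: np.ndarray  # retained channels x samples
    hbr: np.ndarray
    sampling_rate: float
    retained_channels: np.ndarray  # original channel indices
    rejected_channels: dict[int, str] = field(default_factory=dict)
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have identical shapes")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("concentration series must be finite")

    @property
    def n_channels(self) -> int:
        return self.hbr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbr.shape[1]


def _sos(fs: float, cfg: PreprocessConfig):
    lo, hi = cfg.band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band high {hi} Hz must be below Nyquist {nyq} Hz")
    return signal.butter(cfg.filter_order, [lo, hi], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_array(x: np.ndarray, fs: float, cfg: PreprocessConfig) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The small residual mean that forward-backward filtering leaves on a
    finite record is subtracted, so the output is exactly zero-mean.
    """
    y = signal.sosfiltfilt(_sos(fs, cfg), x, axis=-1)
    return y - y.mean(axis=-1, keepdims=True)


def bandpass(raw: OpticalRecording, cfg: PreprocessConfig) -> OpticalRecording:
    """Band-pass each channel/wavelength of a raw recording (zero phase).

    The output intensities are zero-mean fluctuations (DC and drift
    removed); a constant input maps to zero. Intended for spectral
    inspection; the conversion pipeline filters concentrations instead.
    """
    filtered = bandpass_array(raw.intensities, raw.sampling_rate, cfg)
    # bypass __post_init__: filtered fluctuations are legitimately signed
    rec = OpticalRecording.__new__(OpticalRecording)
    rec.intensities = filtered
    rec.sampling_rate = raw.sampling_rate
    rec.channel_labels = raw.channel_labels
    rec.wavelengths = raw.wavelengths
    rec.ground_truth_active_channels = raw.ground_truth_active_channels
    rec.ground_truth_amplitude = raw.ground_truth_amplitude
    rec.hbr_truth = raw.hbr_truth
    rec.hbo_truth = raw.hbo_truth
    return rec


def _robust_max_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x, axis=-1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=-1, keepdims=True)
    mad = np.maximum(mad * 1.4826, 1e-12)
    return (np.abs(x - med) / mad).max(axis=(1, 2))


def spike_scores(raw: OpticalRecording) -> np.ndarray:
    """Robust per-channel spike score.

    Max over wavelengths and samples of the MAD-scaled robust z of the
    intensity deviations from the channel median, combined with the same
    statistic on successive differences. Isolated spikes dwarf both
    scales; physiological oscillations (including cardiac energy aliased
    close to Nyquist at 2 Hz sampling) stay bounded on either.
    """
    amp = _robust_max_z(raw.intensities)
    diff = _robust_max_z(np.diff(raw.intensities, axis=-1))
    return np.maximum(amp, diff)


def reject_channels(raw: OpticalRecording, cfg: PreprocessConfig
                    ) -> tuple[np.ndarray, dict[int, str]]:
    """Split channels into (retained indices, {rejected index: reason})."""
    if raw.n_channels < 2:
        raise ValueError("need at least 2 channels")
    scores = spike_scores(raw)
    rejected = {
        int(ch): f"spike score {scores[ch]:.1f} > {cfg.spike_z_threshold:g}"
        for ch in np.flatnonzero(scores > cfg.spike_z_threshold)
    }
    retained = np.array([ch for ch in range(raw.n_channels) if ch not in rejected])
    if retained.size == 0:
        raise ValueError("all channels rejected; recording unusable")
    return retained, rejected


def beer_lambert(raw: OpticalRecording, cfg: PreprocessConfig,
                 channels: np.ndarray | None = None) -> ConcentrationSeries:
    """Modified Beer-Lambert conversion to HbO/HbR concentration changes.

    Optical-density change per wavelength is dOD = -log10(I / I0) with I0
    the channel temporal mean; the 2x2 extinction system is solved per
    channel and sample, scaled by source-detector distance x DPF.
    """
    if channels is None:
        channels = np.arange(raw.n_channels)
    inten = raw.intensities[channels]
    if np.any(inten <= 0):
        ch, wl, s = np.unravel_index(int(np.argmax(inten <= 0)), inten.shape)
        raise ValueError(
            f"non-positive intensity at channel {channels[ch]}, wavelength index "
            f"{wl}, sample {s}"
        )
    ext = np.asarray(cfg.extinction_coeffs, dtype=float)
    if abs(np.linalg.det(ext)) < 1e-12:
        raise ValueError("extinction coefficient matrix is singular")
    i0 = inten.mean(axis=-1, keepdims=True)
    dod = -np.log10(inten / i0)  # channels x wavelengths x samples
    pathlength = cfg.sd_distance_cm * np.asarray(cfg.dpf)
    dod = dod / pathlength[None, :, None]
    conc = np.einsum("cw,kwn->kcn", np.linalg.inv(ext), dod)
    labels = ([raw.channel_labels[ch] for ch in channels]
              if raw.channel_labels else None)
    return ConcentrationSeries(
        hbo=conc[:, 0], hbr=conc[:, 1], sampling_rate=raw.sampling_rate,
        retained_channels=np.asarray(channels), channel_labels=labels,
    )


def preprocess(raw: OpticalRecording, cfg: PreprocessConfig | None = None
               ) -> ConcentrationSeries:
    """Full chain: reject channels -> Beer-Lambert -> band-pass."""
    if cfg is None:
        cfg = PreprocessConfig()
    retained, rejected = reject_channels(raw, cfg)
    conc = beer_lambert(raw, cfg, channels=retained)
    conc.hbo = bandpass_array(conc.hbo, conc.sampling_rate, cfg)
    conc.hbr = bandpass_array(conc.hbr, conc.sampling_rate, cfg)
    conc.rejected_channels = rejected
    return conc
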