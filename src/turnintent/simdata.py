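"""Synthetic driving + fNIRS data generation.

Emulates a gap-acceptance driving-simulator protocol: a driver waits at an
unsignalized intersection for a gap in oncoming traffic (~50 km/h), with gap
sizes between 1 and 6 s and 8-10 oncoming cars per intersection, over 100
intersections in 10 blocks. Alongside the behavioral event log, a forward
model produces a two-wavelength multichannel optical recording in which a
known subset of channels carries an HRF-shaped deoxyhemoglobin (HbR)
deactivation locked to each turning decision, embedded in cardiac,
respiratory, Mayer-wave, drift and white physiological noise. Because the
ground truth (active channels, amplitudes, atypical-turn flags) is known,
every downstream stage is testable without any recorded human data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit, gammaln

__all__ = [
    "ScenarioConfig",
    "DecisionModel",
    "EventLog",
    "OpticalRecording",
    "NoiseModel",
    "acceptance_probability",
    "simulate_behavior",
    "gap_distance",
    "double_gamma_hrf",
    "simulate_recording",
    "DEFAULT_EXTINCTION",
    "DEFAULT_DPF",
    "DEFAULT_SD_DISTANCE_CM",
]

# Molar extinction coefficients for (HbO, HbR) at 760 and 850 nm,
# 1/(mmol/l)/cm, from the standard compiled tables used by fNIRS toolboxes.
DEFAULT_EXTINCTION = np.array(
    [
        [1.4866, 3.8437],  # 760 nm: HbO, HbR
        [2.5264, 1.7986],  # 850 nm: HbO, HbR
    ]
)
DEFAULT_DPF = (6.0, 6.0)  # differential pathlength factor per wavelength
DEFAULT_SD_DISTANCE_CM = 3.0  # source-detector separation


@dataclass(frozen=True)
class ScenarioConfig:
    """Experimental-design parameters of one synthetic subject session."""

    n_intersections: int = 100
    n_blocks: int = 10
    oncoming_speed: float = 50.0  # km/h
    gap_range: tuple[float, float] = (1.0, 6.0)  # seconds
    cars_per_intersection: tuple[int, int] = (8, 10)
    sampling_rate: float = 2.0  # Hz
    n_channels: int = 107
    wavelengths: tuple[float, float] = (760.0, 850.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gap_range
        if not (0 < lo < hi):
            raise ValueError(f"gap_range must satisfy 0 < min < max, got {self.gap_range}")
        cl, ch = self.cars_per_intersection
        if not (1 <= cl <= ch <= 50):
            raise ValueError("cars_per_intersection must lie within [1, 50] with min <= max")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_intersections < 1 or self.n_blocks < 1:
            raise ValueError("n_intersections and n_blocks must be >= 1")


@dataclass(frozen=True)
class DecisionModel:
    """Logistic gap-acceptance rule with waiting-time urgency.

    A gap of size ``g`` presented after ``w`` cars have passed is accepted
    with probability ``sigmoid(steepness * (g - (critical_gap -
    urgency_rate * w)))``: the effective threshold drops as the driver
    waits, emulating the finding that drivers grow more aggressive with
    waiting time. With probability ``atypical_prob`` a rejected gap is
    taken anyway ("atypical" turn) and flagged; atypical decisions carry
    amplified neural activation in the forward model.
    """

    critical_gap: float = 3.5  # seconds
    steepness: float = 3.0  # 1/seconds
    urgency_rate: float = 0.15  # seconds of threshold per car waited
    atypical_prob: float = 0.08

    def __post_init__(self) -> None:
        if self.steepness <= 0 and not np.isinf(self.steepness):
            raise ValueError("steepness must be > 0")
        if not (0.0 <= self.atypical_prob <= 1.0):
            raise ValueError("atypical_prob must lie in [0, 1]")
        if self.urgency_rate < 0:
            raise ValueError("urgency_rate must be >= 0")


EVENT_COLUMNS = [
    "intersection_id",
    "block_id",
    "press_time_s",
    "gap_size_s",
    "cars_waited",
    "atypical",
    "noturn_gap_size_s",
    "noturn_cars_waited",
]


@dataclass
class EventLog:
    """Per-intersection behavioral record.

    ``gap_size_s``/``cars_waited`` describe the accepted gap; the
    ``noturn_*`` columns record the gap on offer and cars passed at the
    center of the waiting ("no turn") analysis window, 4.5 s before the
    accelerator press, so that context features exist for both phases.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"EventLog missing columns: {missing}")
        press = self.events["press_time_s"].to_numpy()
        if not np.all(np.diff(press) > 0):
            raise ValueError("press_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def press_times(self) -> np.ndarray:
        return self.events["press_time_s"].to_numpy()

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventLog":
        return cls(pd.read_csv(path))


@dataclass
class OpticalRecording:
    """Raw two-wavelength intensities (channels x wavelengths x samples)."""

    intensities: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    wavelengths: tuple[float, float] = (760.0, 850.0)
    ground_truth_active_channels: np.ndarray | None = None
    ground_truth_amplitude: float | None = None
    hbr_truth: np.ndarray | None = None  # channels x samples, mmol/l
    hbo_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.intensities.ndim != 3 or self.intensities.shape[1] != 2:
            raise ValueError("intensities must have shape (channels, 2, samples)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def acceptance_probability(gap: np.ndarray | float, cars_waited: np.ndarray | float,
                           dm: DecisionModel) -> np.ndarray | float:
    """P(accept) for a gap presented after ``cars_waited`` cars have passed."""
    threshold = dm.critical_gap - dm.urgency_rate * np.asarray(cars_waited, dtype=float)
    x = np.asarray(gap, dtype=float) - threshold
    if np.isinf(dm.steepness):
        return (x >= 0).astype(float)
    return expit(dm.steepness * x)


def gap_distance(gap: float, speed: float) -> float:
    """Metres travelled by oncoming traffic during a gap.

    Per-second distance is rounded to the nearest metre before scaling
    (50 km/h -> 14 m/s), which reproduces the conventional 14-84 m bracket
    for 1-6 s gaps at 50 km/h.
    """
    if gap <= 0 or speed <= 0:
        raise ValueError("gap and speed must be positive")
    return round(speed / 3.6) * gap


_APPROACH_S = 2.0  # first oncoming car crosses this long after arrival
_REACTION_S = 0.5  # press delay after the lead car of the accepted gap crosses
_INTER_TRIAL_S = 15.0  # turn execution + drive to the next intersection
_MAX_REDRAWS = 1000


def simulate_behavior(cfg: ScenarioConfig, dm: DecisionModel,
                      rng: np.random.Generator | None = None) -> EventLog:
    """Simulate one subject's session of gap-acceptance decisions.

    Gap sequences are drawn uniformly over ``cfg.gap_range`` and sorted
    ascending (small gaps are presented first, probing the minimal
    acceptable gap). If no gap in a sequence is accepted the sequence is
    re-drawn (the protocol forces acceptance within the presented cars);
    degenerate decision models that cannot accept raise after a bounded
    number of re-draws.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.gap_range
    per_block = int(np.ceil(cfg.n_intersections / cfg.n_blocks))

    rows = []
    t0 = 10.0  # arrival time at the first intersection
    for i in range(cfg.n_intersections):
        n_cars = int(rng.integers(cfg.cars_per_intersection[0],
                                  cfg.cars_per_intersection[1] + 1))
        n_gaps = n_cars - 1
        accepted = None
        for _ in range(_MAX_REDRAWS):
            gaps = np.sort(rng.uniform(lo, hi, size=n_gaps))
            atypical_draws = rng.random(n_gaps) < dm.atypical_prob
            u = rng.random(n_gaps)
            for j in range(n_gaps):
                p = acceptance_probability(gaps[j], j + 1, dm)
                if u[j] < p:
                    accepted = (j, gaps, False)
                    break
                if atypical_draws[j] and gaps[j] >= lo:
                    accepted = (j, gaps, True)
                    break
            if accepted is not None:
                break
        if accepted is None:
            raise RuntimeError(
                "no gap accepted after re-draw limit; decision model is degenerate "
                "(near-zero steepness with atypical_prob = 0?)"
            )
        j, gaps, atypical = accepted
        # car k crosses the intersection at t0 + approach + sum(gaps[:k]);
        # the accepted gap j opens when car j crosses.
        crossings = t0 + _APPROACH_S + np.concatenate([[0.0], np.cumsum(gaps)])
        press = crossings[j] + _REACTION_S
        # context during the waiting window (centered 4.5 s before press)
        t_query = press - 4.5
        cars_passed = int(np.searchsorted(crossings, t_query, side="right"))
        gap_on_offer = gaps[min(max(cars_passed - 1, 0), n_gaps - 1)]
        rows.append(
            dict(
                intersection_id=i,
                block_id=i // per_block,
                press_time_s=press,
                gap_size_s=gaps[j],
                cars_waited=j + 1,
                atypical=bool(atypical),
                noturn_gap_size_s=gap_on_offer,
                noturn_cars_waited=cars_passed,
            )
        )
        t0 = press + _INTER_TRIAL_S + rng.uniform(0.0, 5.0)

    return EventLog(pd.DataFrame(rows, columns=EVENT_COLUMNS))


def double_gamma_hrf(t: np.ndarray, peak: float = 5.5, under: float = 12.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, peak-normalized.

    ``peak``/``under`` set the modes (s) of the response and undershoot
    gamma densities (unit scale); ``ratio`` is the peak:undershoot
    amplitude ratio. Returned positive-going; the forward model flips the
    sign for HbR.
    """
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    for shape, sign, scale in (
        (peak + 1.0, 1.0, 1.0),
        (under + 1.0, -1.0 / ratio, 1.0),
    ):
        logpdf = (shape - 1) * np.log(t[pos]) - t[pos] - gammaln(shape)
        h[pos] += sign * np.exp(logpdf)
    m = h.max()
    if m > 0:
        h /= m
    return h


@dataclass(frozen=True)
class NoiseModel:
    """Amplitudes (mmol/l) of the physiological noise components.

    The oscillatory components (cardiac, respiratory, Mayer) are systemic:
    one waveform per subject, coupled into every channel with a random
    channel gain in [0.5, 1.5]. This global structure is what makes the
    first principal component a physiology/motion catcher in real
    recordings, and is why it is discarded downstream. Drift and white
    noise are independent per channel.
    """

    cardiac: float = 2.0e-4  # ~1 Hz, aliased at 2 Hz sampling
    respiratory: float = 1.5e-4  # ~0.3 Hz
    mayer: float = 1.5e-4  # ~0.1 Hz, inside the analysis band
    drift: float = 3.0e-4  # total linear excursion over the recording
    white: float = 1.0e-4  # per-sample SD
    spatial: float = 4.0e-5  # per-latent SD of spatially correlated noise
    n_latent: int = 15  # latent spatial noise components


def simulate_recording(
    cfg: ScenarioConfig,
    log: EventLog,
    active_channels: np.ndarray | None = None,
    amplitude: float = 1.0e-3,
    atypical_gain: float = 2.0,
    noise: NoiseModel = NoiseModel(),
    boxcar_s: float = 4.0,
    rng: np.random.Generator | None = None,
) -> OpticalRecording:
    """Forward-model a raw optical recording for a behavioral session.

    For each active channel a negative-going HbR response (amplitude in
    mmol/l, doubled for atypical decisions) is generated by convolving a
    ``boxcar_s``-long boxcar starting 2 s before each accelerator press
    with the canonical double-gamma HRF. HbO mirrors the activation with
    opposite sign and twice the magnitude, as typically observed.
    Physiological noise (cardiac, respiratory, Mayer, drift, white) is
    added per channel with random phases, and the modified Beer-Lambert
    relation is inverted to yield two-wavelength intensities, so that the
    preprocessing chain recovers the injected concentrations (round-trip
    property).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    if active_channels is None:
        n_active = min(10, cfg.n_channels)
        active_channels = rng.choice(cfg.n_channels, size=n_active, replace=False)
    active_channels = np.asarray(active_channels, dtype=int)
    if active_channels.size and (active_channels.min() < 0 or
                                 active_channels.max() >= cfg.n_channels):
        raise ValueError("active_channels out of range")

    fs = cfg.sampling_rate
    press = log.press_times
    if press.size and np.min(np.diff(press)) < boxcar_s + 2.0:
        warnings.warn("events closer together than window span; epochs may overlap")
    duration = (press.max() if press.size else 0.0) + 25.0
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs

    # event regressor: boxcar from press-2 s, convolved with the HRF,
    # normalized so its peak equals 1 per unit event weight
    stim = np.zeros(n)
    for p, atyp in zip(press, log.events["atypical"].to_numpy()):
        onset = int(round((p - 2.0) * fs))
        off = onset + int(round(boxcar_s * fs))
        w = atypical_gain if atyp else 1.0
        stim[max(onset, 0):min(off, n)] += w
    hrf_t = np.arange(0, 25.0, 1.0 / fs)
    hrf = double_gamma_hrf(hrf_t)
    single = np.convolve(np.ones(int(round(boxcar_s * fs))), hrf)
    peak_gain = single.max()  # response peak per unit boxcar weight
    regressor = np.convolve(stim, hrf)[:n] / peak_gain

    nc = cfg.n_channels
    hbr = np.zeros((nc, n))
    hbo = np.zeros((nc, n))
    gains = rng.uniform(0.6, 1.0, size=active_channels.size)
    for ch, g in zip(active_channels, gains):
        hbr[ch] -= amplitude * g * regressor
        hbo[ch] += 2.0 * amplitude * g * regressor

    # systemic oscillations: one waveform per subject per component,
    # coupled into every channel with a random gain
    sys_freqs = np.array([
        rng.uniform(1.0, 1.2),  # cardiac
        rng.uniform(0.25, 0.35),  # respiratory
        rng.uniform(0.08, 0.12),  # Mayer
    ])
    sys_phases = rng.uniform(0, 2 * np.pi, size=3)
    sys_amps = np.array([noise.cardiac, noise.respiratory, noise.mayer])
    systemic = np.sum(
        sys_amps[:, None] * np.sin(2 * np.pi * sys_freqs[:, None] * t[None, :]
                                   + sys_phases[:, None]),
        axis=0,
    )
    for series, scale in ((hbr, 1.0), (hbo, 2.0)):
        gains = rng.uniform(0.5, 1.5, size=(nc, 1))
        series += scale * gains * systemic[None, :]
        if noise.n_latent > 0 and noise.spatial > 0:
            # spatially correlated slow noise: latent smooth time courses
            # coupled through random channel patterns, giving the fat
            # eigenvalue spectrum of real multichannel recordings
            tc = gaussian_filter1d(
                rng.normal(size=(noise.n_latent, n)), sigma=2.0 * fs, axis=-1,
                mode="reflect",
            )
            tc /= np.maximum(tc.std(axis=-1, keepdims=True), 1e-12)
            patterns = rng.normal(size=(nc, noise.n_latent))
            series += noise.spatial * scale * (patterns @ tc)
        series += (rng.uniform(-1, 1, size=(nc, 1)) * noise.drift * scale
                   * (t[None, :] / max(duration, 1.0)))
        series += rng.normal(0.0, noise.white * scale, size=(nc, n))

    # invert the modified Beer-Lambert relation to intensities
    ext = DEFAULT_EXTINCTION
    pathlength = DEFAULT_SD_DISTANCE_CM * np.asarray(DEFAULT_DPF)
    conc = np.stack([hbo, hbr], axis=1)  # channels x 2 chromophores x samples
    dod = np.einsum("wc,kcn->kwn", ext, conc) * pathlength[None, :, None]
    baseline = rng.uniform(400.0, 600.0, size=(nc, 2, 1))  # uV-like
    intensities = baseline * 10.0 ** (-dod)

    labels = [f"S{ch // 8 + 1}-D{ch % 8 + 1}_{ch}" for ch in range(nc)]
    return OpticalRecording(
        intensities=intensities,
        sampling_rate=fs,
        channel_labels=labels,
        wavelengths=cfg.wavelengths,
        ground_truth_active_channels=active_channels,
        ground_truth_amplitude=amplitude,
        hbr_truth=hbr,
        hbo_truth=hbo,
    )
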