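"""Band-pass behavior, channel rejection and Beer-Lambert conversion."""

import numpy as np
import pytest

from turnintent.preprocess import (
    PreprocessConfig,
    bandpass,
    bandpass_array,
    beer_lambert,
    preprocess,
    reject_channels,
)
from turnintent.simdata import (
    NoiseModel,
    OpticalRecording,
    ScenarioConfig,
    simulate_behavior,
    simulate_recording,
    DecisionModel,
)

FS = 2.0


def _sine_recording(freq, n=4000, amp=5.0, base=500.0):
    t = np.arange(n) / FS
    x = base + amp * np.sin(2 * np.pi * freq * t)
    inten = np.tile(x, (2, 2, 1))
    return OpticalRecording(intensities=inten, sampling_rate=FS,
                            channel_labels=["a", "b"])


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,keep_min,keep_max",
        [
            (0.3, 0.0, 0.10),  # respiratory band: attenuated >= 90%
            (0.05, 0.90, 1.10),  # in-band: preserved within 10%
        ],
    )
    def test_frequency_response(self, freq, keep_min, keep_max, prep_cfg):
        rec = _sine_recording(freq)
        out = bandpass(rec, prep_cfg)
        mid = slice(500, -500)  # avoid filter edge transients
        gain = out.intensities[0, 0, mid].std() / (5.0 / np.sqrt(2))
        assert keep_min <= gain <= keep_max

    def test_constant_input_maps_to_zero(self, prep_cfg):
        rec = _sine_recording(0.05, amp=0.0)
        out = bandpass(rec, prep_cfg)
        assert np.allclose(out.intensities, 0.0, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        cfg = PreprocessConfig(band=(0.01, 1.5))
        rec = _sine_recording(0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, cfg)

    def test_zero_phase_no_shift(self, prep_cfg):
        """A band-centred sinusoid keeps its phase (forward-backward filter)."""
        rec = _sine_recording(0.04)
        out = bandpass(rec, prep_cfg)
        mid = slice(1000, 3000)
        x = rec.intensities[0, 0, mid] - 500.0
        y = out.intensities[0, 0, mid]
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.99


class TestRejectChannels:
    def test_clean_recording_keeps_all(self, small_recording, prep_cfg):
        retained, rejected = reject_channels(small_recording, prep_cfg)
        assert rejected == {}
        assert retained.size == small_recording.n_channels

    def test_spiked_channel_rejected_exactly(self, small_recording, prep_cfg):
        rec = OpticalRecording(
            intensities=small_recording.intensities.copy(),
            sampling_rate=small_recording.sampling_rate,
            channel_labels=small_recording.channel_labels,
        )
        ch = 5
        sd = rec.intensities[ch, 0].std()
        spikes = np.arange(50, rec.n_samples - 50, 97)
        rec.intensities[ch, 0, spikes] += 10 * sd * np.resize([1, -1], spikes.size)
        retained, rejected = reject_channels(rec, prep_cfg)
        assert set(rejected) == {ch}
        assert ch not in retained

    def test_infinite_threshold_disables_rejection(self, small_recording):
        cfg = PreprocessConfig(spike_z_threshold=np.inf)
        _, rejected = reject_channels(small_recording, cfg)
        assert rejected == {}

    def test_all_rejected_raises(self, small_recording):
        cfg = PreprocessConfig(spike_z_threshold=0.0)
        with pytest.raises(ValueError, match="all channels"):
            reject_channels(small_recording, cfg)


class TestBeerLambert:
    def test_constant_intensity_gives_zero_concentration(self, prep_cfg):
        rec = _sine_recording(0.05, amp=0.0)
        conc = beer_lambert(rec, prep_cfg)
        assert np.allclose(conc.hbo, 0.0, atol=1e-12)
        assert np.allclose(conc.hbr, 0.0, atol=1e-12)

    def test_wavelength_permutation_symmetry(self, small_recording, prep_cfg):
        """Swapping the wavelength rows together with the extinction rows
        (and DPFs) leaves the solved concentrations unchanged."""
        conc = beer_lambert(small_recording, prep_cfg)
        swapped = OpticalRecording(
            intensities=small_recording.intensities[:, ::-1],
            sampling_rate=small_recording.sampling_rate,
            channel_labels=small_recording.channel_labels,
        )
        cfg2 = PreprocessConfig(
            extinction_coeffs=prep_cfg.extinction_coeffs[::-1].copy(),
            dpf=prep_cfg.dpf[::-1],
        )
        conc2 = beer_lambert(swapped, cfg2)
        np.testing.assert_allclose(conc.hbr, conc2.hbr, atol=1e-12)
        np.testing.assert_allclose(conc.hbo, conc2.hbo, atol=1e-12)

    def test_linearity_in_optical_density(self, prep_cfg):
        """Scaling log-intensity fluctuations scales concentrations."""
        t = np.arange(2000) / FS
        dod = 0.01 * np.sin(2 * np.pi * 0.05 * t)
        base = 500.0
        i1 = np.tile(base * 10 ** (-dod), (1, 2, 1))
        i2 = np.tile(base * 10 ** (-3 * dod), (1, 2, 1))
        c1 = beer_lambert(OpticalRecording(i1, FS, ["a"]), prep_cfg)
        c2 = beer_lambert(OpticalRecording(i2, FS, ["a"]), prep_cfg)
        # the I0 normalization leaves a constant (Jensen) offset per
        # channel which the band-pass removes downstream; compare the
        # mean-removed fluctuations
        f1 = c1.hbr - c1.hbr.mean(axis=-1, keepdims=True)
        f2 = c2.hbr - c2.hbr.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(f2, 3 * f1, rtol=1e-4, atol=1e-12)

    def test_nonpositive_intensity_names_location(self, small_recording, prep_cfg):
        rec = OpticalRecording(
            intensities=small_recording.intensities.copy(),
            sampling_rate=FS, channel_labels=small_recording.channel_labels,
        )
        rec.intensities[3, 1, 10] = 0.0
        with pytest.raises(ValueError, match="channel 3"):
            beer_lambert(rec, prep_cfg)

    def test_singular_extinction_matrix_rejected(self, small_recording):
        cfg = PreprocessConfig(extinction_coeffs=np.ones((2, 2)))
        with pytest.raises(ValueError, match="singular"):
            beer_lambert(small_recording, cfg)


class TestRoundTrip:
    def test_injected_hbr_recovered_noise_free(self):
        """Generator forward model -> Beer-Lambert + band-pass recovers the
        injected HbR with high in-band fidelity (no noise)."""
        cfg = ScenarioConfig(n_intersections=8, n_blocks=2, n_channels=4,
                             rng_seed=21)
        log = simulate_behavior(cfg, DecisionModel())
        silent = NoiseModel(cardiac=0, respiratory=0, mayer=0, drift=0,
                            white=0, spatial=0)
        rec = simulate_recording(cfg, log, active_channels=np.array([0, 2]),
                                 noise=silent)
        # without noise the event deflections themselves dominate the robust
        # spike scale; rejection is irrelevant to the conversion round-trip
        pcfg = PreprocessConfig(spike_z_threshold=np.inf)
        conc = preprocess(rec, pcfg)
        truth = bandpass_array(rec.hbr_truth, cfg.sampling_rate, pcfg)
        for ch in (0, 2):
            r = np.corrcoef(conc.hbr[ch], truth[ch])[0, 1]
            assert r > 0.95
            rms = np.sqrt(np.mean((conc.hbr[ch] - truth[ch]) ** 2))
            assert rms < 0.01 * np.sqrt(np.mean(truth[ch] ** 2)) + 1e-12

    def test_channel_bookkeeping_lossless(self, small_recording, prep_cfg):
        conc = preprocess(small_recording, prep_cfg)
        all_ch = set(conc.retained_channels) | set(conc.rejected_channels)
        assert all_ch == set(range(small_recording.n_channels))
        assert not (set(conc.retained_channels)
                    & set(conc.rejected_channels))

    def test_filtered_concentrations_zero_mean(self, small_conc):
        sd = small_conc.hbr.std(axis=1)
        assert np.all(np.abs(small_conc.hbr.mean(axis=1)) < 1e-6 * sd)
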