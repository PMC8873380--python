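"""Time-frequency and feature-extraction tests, with independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import eegpref as eg
from eegpref.bands import DEFAULT_BANDS, get_band
from eegpref.epochs import EpochSet, Montage
from eegpref.tfr import TFR, band_time_average, morlet_tfr, psf
from conftest import make_epochs


def brute_force_band_average(tfr: TFR, band, window) -> np.ndarray:
    """Direct double-loop two-stage mean (inner over frequency bins, outer
    over window times); assumes a fully valid mask."""
    band = get_band(band) if isinstance(band, str) else band
    bins = [
        k for k, f in enumerate(tfr.freqs)
        if (band.fmin - 1e-9 <= f < band.fmax - 1e-9)
        or (band.fmax >= tfr.freqs.max() - 1e-9 and np.isclose(f, band.fmax))
    ]
    tsel = [k for k, t in enumerate(tfr.times) if window[0] - 1e-12 <= t < window[1] - 1e-12]
    out = np.zeros(tfr.power.shape[0])
    for ch in range(tfr.power.shape[0]):
        acc = 0.0
        for t in tsel:
            inner = 0.0
            for f in bins:
                inner += tfr.power[ch, f, t]
            acc += inner / len(bins)
        out[ch] = acc / len(tsel)
    return out


def random_tfr(seed=0, n_ch=3, n_freqs=49, n_times=20) -> TFR:
    rng = np.random.default_rng(seed)
    return TFR(
        power=rng.random((n_ch, n_freqs, n_times)),
        freqs=np.arange(1.0, n_freqs + 1.0),
        times=0.012 * np.arange(n_times),
        valid=np.ones((n_freqs, n_times), dtype=bool),
    )


class TestMorletTFR:
    def test_frequency_localization_of_pure_tone(self):
        sfreq, f0 = 512.0, 10.0
        t = np.arange(0, 4.0, 1 / sfreq)
        data = np.sin(2 * np.pi * f0 * t)[None, None, :]
        es = EpochSet(data=data, sfreq=sfreq, t0_offset=-1.0, channel_names=("c",))
        tfr = morlet_tfr(es)[0]
        central = (tfr.times > -0.5) & (tfr.times < 2.5)
        mean_power = np.where(tfr.valid[:, central], tfr.power[0][:, central], np.nan)
        profile = np.nanmean(mean_power, axis=1)
        assert tfr.freqs[np.nanargmax(profile)] == f0

    def test_zero_signal_zero_power(self):
        es = EpochSet(
            data=np.zeros((1, 2, 1126)), sfreq=512.0, t0_offset=-0.2,
            channel_names=("a", "b"),
        )
        tfr = morlet_tfr(es)[0]
        assert np.all(tfr.power == 0)

    def test_grid_geometry_and_mask(self, random_epochs):
        tfr = morlet_tfr(random_epochs)[0]
        assert np.allclose(np.diff(tfr.times), 0.012)
        assert np.any(np.isclose(tfr.times, 0.0))
        assert np.all(tfr.power >= 0)
        # low-frequency rows cannot be fully supported in a 2.2-s epoch
        assert not tfr.valid[0].any()
        # high-frequency rows are valid away from the edges
        assert tfr.valid[-1].sum() > 0.8 * tfr.times.size

    def test_white_noise_band_powers_match_stft_oracle(self):
        """Relative band powers from the wavelet path agree with an
        independent short-time-Fourier (Welch) estimate within 10%."""
        rng = np.random.default_rng(42)
        sfreq, n_ep = 512.0, 12
        data = rng.standard_normal((n_ep, 1, int(4 * sfreq)))
        es = EpochSet(data=data, sfreq=sfreq, t0_offset=-1.0, channel_names=("c",))
        tfrs = morlet_tfr(es)
        window = (0.0, 2.0)  # interior window: theta..gamma valid there
        bands = [b for b in DEFAULT_BANDS if b.name != "delta"]
        wav = np.array(
            [np.mean([band_time_average(t, b, window, strict=True)[0] for t in tfrs])
             for b in bands]
        )
        f, p = signal.welch(data[:, 0, :], fs=sfreq, nperseg=1024, axis=-1)
        stft = []
        for b in bands:
            sel = (f >= b.fmin) & (f < b.fmax) if b.name != "gamma" else (f >= b.fmin) & (f <= b.fmax)
            stft.append(p[:, sel].mean())
        stft = np.array(stft)
        np.testing.assert_allclose(wav / wav.sum(), stft / stft.sum(), rtol=0.10)


class TestBandAverage:
    def test_constant_plane_returns_constant(self):
        tfr = random_tfr()
        tfr.power[:] = 3.25
        for band in DEFAULT_BANDS:
            np.testing.assert_allclose(
                band_time_average(tfr, band, (0.0, 0.24)), 3.25
            )

    def test_two_by_two_plane_mean(self):
        """Two freqs x two times holding 1..4 average to 2.5."""
        tfr = TFR(
            power=np.array([[[1.0, 2.0], [3.0, 4.0]]]),
            freqs=np.array([8.0, 9.0]),
            times=np.array([0.0, 0.012]),
            valid=np.ones((2, 2), dtype=bool),
        )
        band = get_band("alpha")
        np.testing.assert_allclose(
            band_time_average(tfr, band, (0.0, 0.024)), [2.5]
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_summation(self, seed):
        tfr = random_tfr(seed=seed)
        for band in DEFAULT_BANDS:
            fast = band_time_average(tfr, band, (0.0, 0.2))
            slow = brute_force_band_average(tfr, band, (0.0, 0.2))
            np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_strict_mode_errors_without_valid_cells(self):
        tfr = random_tfr()
        tfr.valid[:] = False
        with pytest.raises(ValueError, match="no valid"):
            band_time_average(tfr, "alpha", (0.0, 0.2), strict=True)
        # lenient mode falls back to the zero-padded cells
        out = band_time_average(tfr, "alpha", (0.0, 0.2), strict=False)
        assert np.all(np.isfinite(out))

    def test_masked_cells_are_excluded(self):
        tfr = random_tfr(n_freqs=2, n_times=4)
        tfr.freqs = np.array([8.0, 9.0])
        tfr.power[:, :, 0] = 1e6  # poison the first column
        tfr.valid[:, 0] = False
        out = band_time_average(tfr, get_band("alpha"), (0.0, 0.048))
        expected = tfr.power[:, :, 1:4].mean(axis=(1, 2))
        np.testing.assert_allclose(out, expected)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="no grid time"):
            band_time_average(random_tfr(), "alpha", (5.0, 6.0))


class TestPSF:
    def test_no_change_is_zero(self):
        assert psf(2.0, 2.0) == 0.0

    def test_desynchronization_sign(self):
        assert psf(0.5, 1.0) == -0.5

    def test_nonpositive_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            psf(1.0, 0.0)

    def test_amplitude_doubling_gives_psf_three(self):
        """A sinusoid whose amplitude doubles at onset quadruples band
        power, so PSF = (4P - P) / P = 3."""
        sfreq, f0 = 512.0, 10.0
        t = np.arange(-2.0, 2.0, 1 / sfreq)
        amp = np.where(t >= 0, 2.0, 1.0)
        data = (amp * np.sin(2 * np.pi * f0 * t))[None, None, :]
        es = EpochSet(data=data, sfreq=sfreq, t0_offset=-2.0, channel_names=("c",))
        tfr = morlet_tfr(es)[0]
        v = band_time_average(tfr, "alpha", (0.5, 1.5), strict=True)
        b = band_time_average(tfr, "alpha", (-1.5, -0.5), strict=True)
        assert psf(v, b)[0] == pytest.approx(3.0, rel=0.05)

    def test_scale_invariance(self, tiny_montage):
        """Multiplying the raw signal by a constant leaves every PSF and
        asymmetry feature unchanged."""
        es = make_epochs(n_epochs=2, channel_names=tiny_montage.channel_names, seed=9)
        scaled = EpochSet(
            data=es.data * 7.3, sfreq=es.sfreq, t0_offset=es.t0_offset,
            channel_names=es.channel_names, subject_ids=es.subject_ids,
            labels=es.labels,
        )
        a = eg.extract_features(es, tiny_montage)
        b = eg.extract_features(scaled, tiny_montage)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9, atol=1e-12)


class TestAsymmetry:
    def test_identical_hemispheres_zero(self, tiny_montage):
        es = make_epochs(n_epochs=2, channel_names=tiny_montage.channel_names, seed=4)
        es.data[:, 1, :] = es.data[:, 0, :]  # R1 := L1
        es.data[:, 3, :] = es.data[:, 2, :]  # R2 := L2
        feats = eg.extract_features(es, tiny_montage)
        as_cols = [c for c in feats.columns if c.startswith("AS|")]
        np.testing.assert_allclose(feats[as_cols].to_numpy(), 0.0, atol=1e-10)

    def test_swapping_pair_members_negates_scores(self, tiny_montage):
        es = make_epochs(n_epochs=2, channel_names=tiny_montage.channel_names, seed=5)
        swapped = Montage(
            channel_names=tiny_montage.channel_names,
            pairs=tuple((r, l) for l, r in tiny_montage.pairs),
            midline=tiny_montage.midline,
        )
        a = eg.extract_features(es, tiny_montage)
        b = eg.extract_features(es, swapped)
        as_a = a[[c for c in a.columns if c.startswith("AS|")]].to_numpy()
        as_b = b[[c for c in b.columns if c.startswith("AS|")]].to_numpy()
        np.testing.assert_allclose(as_a, -as_b, rtol=1e-9, atol=1e-12)

    def test_subtraction_oracle(self, tiny_montage):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.standard_normal((5, 6)), columns=tiny_montage.channel_names
        )
        scores = eg.asymmetry_scores(table, tiny_montage)
        np.testing.assert_allclose(
            scores["L1/R1"], table["L1"] - table["R1"]
        )

    def test_missing_pair_member_errors(self, tiny_montage):
        table = pd.DataFrame({"L1": [0.1], "R1": [0.2]})
        with pytest.raises(ValueError, match="missing"):
            eg.asymmetry_scores(table, tiny_montage)


class TestExtractFeatures:
    def test_column_count_formula(self, tiny_montage):
        es = make_epochs(n_epochs=2, channel_names=tiny_montage.channel_names)
        feats = eg.extract_features(es, tiny_montage)
        assert feats.shape[1] == 6 * 5 + 2 * 5

    def test_column_names_parse_back(self, tiny_montage):
        es = make_epochs(n_epochs=1, channel_names=tiny_montage.channel_names)
        feats = eg.extract_features(es, tiny_montage)
        assert len(set(feats.columns)) == feats.shape[1]
        kind, band, where = eg.parse_feature_name(feats.columns[0])
        assert (kind, band, where) == ("PSF", "delta", "L1")
        kind, band, where = eg.parse_feature_name(feats.columns[-1])
        assert kind == "AS" and band == "gamma" and where == ("L2", "R2")

    def test_epoch_order_invariance(self, tiny_montage):
        es = make_epochs(n_epochs=5, channel_names=tiny_montage.channel_names, seed=21)
        perm = np.array([3, 0, 4, 1, 2])
        a = eg.extract_features(es, tiny_montage)
        b = eg.extract_features(es.select(perm), tiny_montage)
        np.testing.assert_allclose(a.to_numpy()[perm], b.to_numpy(), rtol=1e-9)

    def test_alpha_suppression_shows_in_psf(self, tiny_montage):
        """The generator's alpha desynchronization must surface as a lower
        engendered-class alpha PSF on the affected channel."""
        cfg = eg.SynthConfig(
            n_subjects=2, trials_per_subject=20, n_channels=6,
            effects=(eg.EffectSpec(band="alpha", multiplier=0.5, channels=("M1",)),),
            engendered_prevalence=0.5, rating_noise=0.0, rating1_fraction=0.0,
            snr=2.0, seed=23,
        )
        es, recs = eg.generate_dataset(cfg, tiny_montage)
        es.labels = eg.label_epochs(recs)
        feats = eg.extract_features(es, tiny_montage)
        eng = es.labels == "engendered"
        col = feats["PSF|alpha|M1"]
        assert col[eng].mean() < col[~eng].mean() - 0.5

    def test_channel_mismatch_errors(self, tiny_montage):
        es = make_epochs(n_epochs=1, n_channels=4)
        with pytest.raises(ValueError, match="montage"):
            eg.extract_features(es, tiny_montage)
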