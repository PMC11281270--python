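"""Wavelet band powers and the 26-feature bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from eegworkload.spectral import (
    BANDS,
    BAND_NAMES,
    BandPowerTable,
    FEATURE_IDS,
    WaveletConfig,
    band_powers,
    compute_features,
    cwt_power,
    epoch_band_powers,
    feature_catalog,
)

FS = 250.0


def band_centers():
    return {b: float(np.sqrt(lo * hi)) for b, (lo, hi) in BANDS.items()}


def sine(f0, seconds=4.0, amp=1.0):
    t = np.arange(int(seconds * FS)) / FS
    return amp * np.sin(2 * np.pi * f0 * t)


class TestCwt:
    def test_zero_signal_gives_zero_map(self):
        m = cwt_power(np.zeros(1000), FS)
        assert m.shape == (60, 1000)
        assert np.all(m == 0)

    def test_alpha_tone_peaks_in_alpha_rows(self):
        cfg = WaveletConfig()
        m = cwt_power(sine(10.0), FS, cfg)
        row = int(np.argmax(m.mean(axis=1)))
        assert 8.0 <= cfg.freqs[row] < 13.0

    def test_quadratic_homogeneity(self):
        x = np.random.default_rng(1).standard_normal(800)
        m1 = cwt_power(x, FS)
        m2 = cwt_power(2.0 * x, FS)
        assert np.allclose(m2, 4.0 * m1, rtol=1e-9)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            cwt_power(np.array([]), FS)

    def test_short_signal_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            cwt_power(np.ones(100), FS)

    def test_matches_mne_morlet_band_ranking(self):
        """Independent oracle: MNE's Morlet TFR ranks the five bands the
        same way on coloured noise."""
        mne = pytest.importorskip("mne")
        cfg = WaveletConfig()
        rng = np.random.default_rng(7)
        x = sps.sosfiltfilt(
            sps.butter(4, [6, 20], btype="bandpass", fs=FS, output="sos"),
            rng.standard_normal(int(16 * FS)),  # longer than the 1 Hz wavelet
        )
        mine = band_powers(cwt_power(x, FS, cfg), cfg)
        tfr = mne.time_frequency.tfr_array_morlet(
            x[None, None, :], FS, np.asarray(cfg.freqs),
            n_cycles=cfg.n_cycles, output="power", verbose="error",
        )[0, 0]
        rows = cfg.band_rows()
        theirs = np.array([tfr[rows[b]].mean() for b in BAND_NAMES])
        assert np.array_equal(np.argsort(mine), np.argsort(theirs))


class TestBandPowers:
    def test_alpha_tone_dominates_band_vector(self):
        cfg = WaveletConfig()
        bp = band_powers(cwt_power(sine(10.2), FS, cfg), cfg)
        assert bp[2] >= 0.8 * bp.sum()
        # cross-check with a periodogram oracle
        f, p = sps.periodogram(sine(10.2), fs=FS)
        assert p[(f >= 8) & (f < 13)].sum() >= 0.8 * p[(f >= 1)].sum()

    def test_zero_map_gives_zero_bands(self):
        assert np.all(band_powers(np.zeros((60, 100))) == 0)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            band_powers(np.zeros((10, 100)))

    def test_nonfinite_map_rejected(self):
        m = np.zeros((60, 10))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            band_powers(m)

    def test_fast_path_matches_map_path_where_support_fits(self):
        """The Parseval table agrees with mean-over-map band powers once
        the wavelet support is small against the epoch (30 s here). The
        cropped map undercounts edge energy, so the fast path can only
        sit above it — and does so negligibly for the short wavelets."""
        cfg = WaveletConfig()
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(30 * FS))
        fast = epoch_band_powers(x, FS, cfg)
        slow = band_powers(cwt_power(x, FS, cfg), cfg)
        assert np.allclose(fast[1:], slow[1:], rtol=0.12)
        assert np.all(fast >= slow * 0.999)  # edge deficit direction

    def test_fast_path_batch_shape(self):
        x = np.zeros((3, 4, 500))
        out = epoch_band_powers(x, FS)
        assert out.shape == (3, 4, 5)

    def test_wavelet_ranking_matches_analytic_oracle(self):
        """Oracle equivalence on stationary coloured noise.

        The oracle is the closed-form expectation of Morlet band power —
        the planted PSD integrated against the analytic power response
        |psi_hat(f)|^2 = 2 sqrt(pi) sigma_t exp(-4 pi^2 sigma_t^2
        (f - f0)^2) — so the two routes share no code. Fixtures whose
        expected band values nearly tie (< 30% separation, where a rank
        comparison is undefined at finite length) are redrawn; on the 100
        kept fixtures the implementation must reproduce the oracle's band
        ranking in >= 95% of cases."""
        rng = np.random.default_rng(11)
        cfg = WaveletConfig()
        n = int(40 * FS)
        gen_freqs = np.fft.rfftfreq(n, 1 / FS)
        fgrid = np.linspace(0.25, 125.0, 4000)
        rows = cfg.band_rows()
        responses = []
        for f0 in cfg.freqs:
            sigma_t = cfg.n_cycles / (2 * np.pi * f0)
            responses.append(2 * np.sqrt(np.pi) * sigma_t * np.exp(
                -4 * np.pi**2 * sigma_t**2 * (fgrid - f0) ** 2))
        levels = np.array([1.0, 2.5, 6.3, 16.0, 40.0])

        agree = 0
        n_fix = 0
        while n_fix < 100:
            gains = dict(zip(BAND_NAMES, rng.permutation(levels)))
            S_true = np.zeros_like(fgrid)
            for b, (lo, hi) in BANDS.items():
                m = (fgrid >= lo) & (fgrid < hi)
                S_true[m] = gains[b] / np.maximum(fgrid[m], 1.0)
            oracle_rows = np.array([np.trapezoid(S_true * r, fgrid)
                                    for r in responses])
            oracle = np.array([oracle_rows[rows[b]].mean() for b in BAND_NAMES])
            sv = np.sort(oracle)
            if (sv[1:] / sv[:-1]).min() < 1.3:
                continue  # near-tie in expectation: ranking undefined
            n_fix += 1
            amp = np.zeros_like(gen_freqs)
            for b, (lo, hi) in BANDS.items():
                m = (gen_freqs >= lo) & (gen_freqs < hi)
                amp[m] = np.sqrt(gains[b] / np.maximum(gen_freqs[m], 1.0))
            z = (rng.standard_normal(gen_freqs.size)
                 + 1j * rng.standard_normal(gen_freqs.size))
            x = np.fft.irfft(z * amp, n=n)
            wav = epoch_band_powers(x, FS, cfg)
            agree += np.array_equal(np.argsort(wav), np.argsort(oracle))
        assert agree >= 95


def bp_table(rows):
    """BandPowerTable from a list of 5-band tuples (single channel)."""
    arr = np.asarray(rows, dtype=float)[:, None, :]
    return BandPowerTable(
        powers=arr, labels=["resting"] * arr.shape[0],
        channel_labels=("CP2",), subjects=["s01"] * arr.shape[0],
    )


class TestFeatureBank:
    def test_catalog_is_the_26_feature_bank(self):
        cat = feature_catalog()
        assert len(cat) == 26
        assert [i for i, _ in cat] == list(range(1, 27))
        assert dict(cat)[1] == "δ"
        assert dict(cat)[16] == "β + θ + α + γ"

    @pytest.mark.parametrize("bands,checks", [
        # delta, theta, alpha, beta, gamma
        ((1, 1, 1, 1, 1), {16: 4.0, 26: 0.2, 11: 1.0, 5: 4.0, 6: 0.25}),
        ((2, 1, 1, 1, 3), {25: 0.6, 12: 2.0, 15: 8.0, 17: 1.5}),
    ])
    def test_table_values_forced_by_formulas(self, bands, checks):
        d, t, a, b, g = bands
        ft = compute_features(bp_table([(d, t, a, b, g)]))
        for fid, expected in checks.items():
            assert ft.feature(fid)[0, 0] == pytest.approx(expected)

    @given(st.lists(
        st.tuples(*[st.floats(0.01, 1e4) for _ in range(5)]),
        min_size=1, max_size=8,
    ))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_identities_hold_for_random_band_tuples(self, rows):
        ft = compute_features(bp_table(rows))
        delta = np.array([r[0] for r in rows])
        gamma = np.array([r[4] for r in rows])
        f15 = ft.feature(15)[:, 0]
        f16 = ft.feature(16)[:, 0]
        assert np.allclose(f15 - f16, delta, rtol=1e-9)
        assert np.allclose(ft.feature(26)[:, 0], gamma / f15, rtol=1e-9)
        shares = np.stack([ft.feature(i)[:, 0] for i in (6, 7, 8, 9)])
        assert np.allclose(shares.sum(axis=0), 1.0, rtol=1e-9)
        assert np.all((ft.feature(26)[:, 0] > 0) & (ft.feature(26)[:, 0] < 1))

    @given(st.tuples(*[st.floats(0.01, 1e3) for _ in range(5)]),
           st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_equivariance(self, bands, c):
        """Scaling the signal by c scales absolute-power features by c^2
        and leaves every ratio feature unchanged."""
        base = compute_features(bp_table([bands]))
        scaled = compute_features(bp_table([tuple(c**2 * v for v in bands)]))
        for fid in (1, 2, 3, 4, 5, 14, 15, 16):
            assert scaled.feature(fid)[0, 0] == pytest.approx(
                c**2 * base.feature(fid)[0, 0], rel=1e-9)
        for fid in tuple(range(6, 14)) + tuple(range(17, 27)):
            assert scaled.feature(fid)[0, 0] == pytest.approx(
                base.feature(fid)[0, 0], rel=1e-9)

    def test_zero_denominator_yields_nan_sentinel(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="eegworkload.spectral"):
            ft = compute_features(bp_table([(1.0, 1.0, 1.0, 0.0, 1.0)]))
        assert np.isnan(ft.feature(10)[0, 0])  # theta/beta with beta = 0
        assert "zero denominators" in caplog.text

    def test_negative_band_power_rejected(self):
        with pytest.raises(ValueError):
            BandPowerTable(
                powers=-np.ones((1, 1, 5)), labels=["resting"],
                channel_labels=("CP2",), subjects=["s01"],
            )

    def test_unknown_feature_id_rejected(self):
        with pytest.raises(KeyError):
            compute_features(bp_table([(1, 1, 1, 1, 1)]), (99,))
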