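"""Morlet wavelet band powers and the 26-feature spectral bank.

The time-frequency transform is the continuous wavelet transform with a
complex Morlet mother wavelet,

    W(a, b) = (1/sqrt(a)) * integral x(t) psi*((t - b)/a) dt,

realized as FFT cross-correlation with L2-normalized kernels on a
logarithmic frequency grid over 1-100 Hz. Band power is the MEAN of
|W|^2 over a band's frequency rows and the epoch's samples, which makes
the statistic independent of the grid density inside a band.

Canonical bands (half-open intervals, Hz):
    delta [1, 4), theta [4, 8), alpha [8, 13), beta [13, 30), gamma [30, 100).
The gamma band is closed at 100 Hz, the upper bandpass edge. Content in
[0.5, 1) Hz passes the filter but is ignored by the features.

The feature bank comprises 13 traditional band-power features (ids 1-13,
built from delta/theta/alpha/beta) and 13 gamma-augmented features
(ids 14-26), e.g. id 16 = beta + theta + alpha + gamma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .montage import CONDITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "BAND_NAMES",
    "WaveletConfig",
    "BandPowerTable",
    "FeatureTable",
    "morlet_kernel",
    "cwt_power",
    "band_powers",
    "epoch_band_powers",
    "band_power_table",
    "compute_features",
    "feature_catalog",
    "FEATURE_IDS",
    "GAMMA_FEATURE_IDS",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass(frozen=True)
class WaveletConfig:
    """Morlet analysis settings.

    n_cycles fixes the mother wavelet's time-frequency trade-off
    (sigma_t = n_cycles / (2 pi f)); the default 7 is the conventional
    compromise for band-power work. The default grid is 60 log-spaced
    frequencies over 1-100 Hz, guaranteeing >= 2 rows per band.
    """

    n_cycles: float = 7.0
    freqs: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.geomspace(1.0, 100.0, 60))
    )

    def __post_init__(self):
        f = np.asarray(self.freqs)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        for name, (lo, hi) in BANDS.items():
            if ((f >= lo) & (f < hi)).sum() < 2:
                raise ValueError(f"fewer than 2 grid points in band {name}")

    def band_rows(self) -> dict[str, np.ndarray]:
        f = np.asarray(self.freqs)
        return {name: np.flatnonzero((f >= lo) & (f < hi))
                for name, (lo, hi) in BANDS.items()}


def morlet_kernel(f0: float, fs: float, n_cycles: float) -> np.ndarray:
    """L2-normalized complex Morlet at centre frequency f0 (odd length)."""
    sigma_t = n_cycles / (2.0 * np.pi * f0)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / fs)  # unit L2 norm in continuous time
    return w


def cwt_power(signal: np.ndarray, fs: float, config: WaveletConfig | None = None) -> np.ndarray:
    """Magnitude-squared Morlet scalogram, shape (n_freqs, n_samples).

    Scaling the signal by c scales the map by c^2. A warning is issued when
    the signal is shorter than two cycles of the lowest analysis frequency.
    """
    config = config or WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a nonempty 1-D array")
    fmin = config.freqs[0]
    if x.size < 2 * fs / fmin:
        warnings.warn(
            f"signal ({x.size / fs:.2f} s) shorter than 2 cycles of "
            f"{fmin:g} Hz; low-frequency rows are edge-dominated",
            stacklevel=2,
        )
    n = x.size
    out = np.empty((len(config.freqs), n))
    for i, f0 in enumerate(config.freqs):
        w = morlet_kernel(f0, fs, config.n_cycles)
        nfft = sfft.next_fast_len(n + w.size - 1)
        spec = sfft.fft(x, nfft) * np.conj(sfft.fft(w, nfft))
        full = sfft.ifft(spec)
        start = (w.size - 1) // 2  # centre of the kernel -> "same" alignment
        out[i] = np.abs(full[start:start + n]) ** 2
    return out


def band_powers(power_map: np.ndarray, config: WaveletConfig | None = None) -> np.ndarray:
    """Mean |W|^2 over each band's rows and all samples -> 5 scalars.

    Order: delta, theta, alpha, beta, gamma.
    """
    config = config or WaveletConfig()
    pm = np.asarray(power_map)
    if not np.all(np.isfinite(pm)):
        raise ValueError("power map contains non-finite values")
    if pm.shape[0] != len(config.freqs):
        raise ValueError("power map rows do not match the analysis grid")
    rows = config.band_rows()
    return np.array([pm[rows[b]].mean() for b in BAND_NAMES])


from functools import lru_cache


@lru_cache(maxsize=8)
def _kernel_power_spectra_cached(
    n_samples: int, fs: float, n_cycles: float, freqs: tuple[float, ...]
) -> tuple[np.ndarray, int]:
    return _kernel_power_spectra(n_samples, fs, WaveletConfig(n_cycles, freqs))


def _kernel_power_spectra(n_samples: int, fs: float, config: WaveletConfig) -> tuple[np.ndarray, int]:
    """Kernel power spectra folded onto the rfft grid.

    Because the signal is real (|x_hat(-f)| = |x_hat(f)|) the negative-
    frequency kernel content is folded onto the positive bins, so the
    projection can use the signal's rfft periodogram without doubling.
    """
    max_half = int(np.ceil(5.0 * config.n_cycles / (2.0 * np.pi * config.freqs[0]) * fs))
    nfft = sfft.next_fast_len(n_samples + 2 * max_half)
    n_pos = nfft // 2 + 1
    spectra = np.empty((len(config.freqs), n_pos))
    for i, f0 in enumerate(config.freqs):
        w = morlet_kernel(f0, fs, config.n_cycles)
        s = np.abs(sfft.fft(w, nfft)) ** 2
        folded = s[:n_pos].copy()
        # interior bins: add the mirrored negative-frequency content
        folded[1:(nfft + 1) // 2] += s[nfft - 1:nfft - (nfft + 1) // 2:-1]
        spectra[i] = folded
    return spectra, nfft


def epoch_band_powers(
    epochs: np.ndarray, fs: float, config: WaveletConfig | None = None
) -> np.ndarray:
    """Band powers for a batch of epochs, shape (..., n_samples) -> (..., 5).

    Computed in the frequency domain via Parseval: the full-convolution
    time sum of |W(a, .)|^2 equals sum_f |x_hat(f)|^2 |psi_hat_a(f)|^2 / nfft,
    so the per-band mean over rows and epoch samples is a single weighted
    projection of the epoch periodogram. This is the fast path used for
    whole datasets; it matches cwt_power + band_powers up to edge
    truncation of the "same" window (noticeable only when the wavelet
    support rivals the epoch length, i.e. in the delta band for short
    epochs).
    """
    config = config or WaveletConfig()
    x = np.asarray(epochs, dtype=float)
    n = x.shape[-1]
    lead = x.shape[:-1]
    spectra, nfft = _kernel_power_spectra_cached(
        n, float(fs), float(config.n_cycles), tuple(config.freqs)
    )
    rows = config.band_rows()
    # (n_bins, 5): mean kernel power spectrum per band
    proj = np.stack([spectra[rows[b]].mean(axis=0) for b in BAND_NAMES], axis=1)
    flat = x.reshape(-1, n)
    out = np.empty((flat.shape[0], len(BAND_NAMES)))
    chunk = max(1, int(2**24 // nfft))
    for i0 in range(0, flat.shape[0], chunk):
        seg = flat[i0:i0 + chunk]
        p = np.abs(sfft.rfft(seg, nfft, axis=-1)) ** 2
        out[i0:i0 + chunk] = (p @ proj) / (nfft * n)
    return out.reshape(*lead, len(BAND_NAMES))


@dataclass
class BandPowerTable:
    """Per-epoch, per-channel power in the five canonical bands (µV²)."""

    powers: np.ndarray           # (n_epochs, n_channels, 5)
    labels: list[str]            # condition per epoch
    channel_labels: tuple[str, ...]
    subjects: list[str]          # subject id per epoch

    def __post_init__(self):
        p = self.powers
        if p.ndim != 3 or p.shape[-1] != len(BAND_NAMES):
            raise ValueError("powers must be (n_epochs, n_channels, 5)")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("band powers must be finite and non-negative")
        for lab in self.labels:
            if lab not in CONDITIONS:
                raise ValueError(f"unknown condition {lab!r}")


def band_power_table(epochsets, config: WaveletConfig | None = None) -> BandPowerTable:
    """Band-power table for one EpochSet or a list of them (same montage)."""
    if not isinstance(epochsets, (list, tuple)):
        epochsets = [epochsets]
    ref = epochsets[0].channel_labels
    blocks, labels, subjects = [], [], []
    for es in epochsets:
        if es.channel_labels != ref:
            raise ValueError("epoch sets have inconsistent channel labels")
        blocks.append(epoch_band_powers(es.epochs, es.sampling_rate, config))
        labels.extend(es.labels)
        subjects.extend([es.subject_id] * es.n_epochs)
    return BandPowerTable(
        powers=np.concatenate(blocks, axis=0),
        labels=labels,
        channel_labels=ref,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

# id -> (formula string, callable on (delta, theta, alpha, beta, gamma))
_CATALOG: dict[int, tuple[str, callable]] = {
    1: ("δ", lambda d, t, a, b, g: d),
    2: ("θ", lambda d, t, a, b, g: t),
    3: ("α", lambda d, t, a, b, g: a),
    4: ("β", lambda d, t, a, b, g: b),
    5: ("δ + β + θ + α", lambda d, t, a, b, g: d + b + t + a),
    6: ("δ/(δ + β + θ + α)", lambda d, t, a, b, g: d / (d + b + t + a)),
    7: ("θ/(δ + β + θ + α)", lambda d, t, a, b, g: t / (d + b + t + a)),
    8: ("α/(δ + β + θ + α)", lambda d, t, a, b, g: a / (d + b + t + a)),
    9: ("β/(δ + β + θ + α)", lambda d, t, a, b, g: b / (d + b + t + a)),
    10: ("θ/β", lambda d, t, a, b, g: t / b),
    11: ("α/β", lambda d, t, a, b, g: a / b),
    12: ("(α + θ)/β", lambda d, t, a, b, g: (a + t) / b),
    13: ("(α + θ)/(α + β)", lambda d, t, a, b, g: (a + t) / (a + b)),
    14: ("γ", lambda d, t, a, b, g: g),
    15: ("δ + β + θ + α + γ", lambda d, t, a, b, g: d + b + t + a + g),
    16: ("β + θ + α + γ", lambda d, t, a, b, g: b + t + a + g),
    17: ("γ/δ", lambda d, t, a, b, g: g / d),
    18: ("γ/θ", lambda d, t, a, b, g: g / t),
    19: ("γ/α", lambda d, t, a, b, g: g / a),
    20: ("γ/β", lambda d, t, a, b, g: g / b),
    21: ("γ/(α + β)", lambda d, t, a, b, g: g / (a + b)),
    22: ("γ/(θ + β)", lambda d, t, a, b, g: g / (t + b)),
    23: ("γ/(θ + α)", lambda d, t, a, b, g: g / (t + a)),
    24: ("γ/(θ + β + α)", lambda d, t, a, b, g: g / (t + b + a)),
    25: ("γ/(δ + β + θ + α)", lambda d, t, a, b, g: g / (d + b + t + a)),
    26: ("γ/(δ + β + θ + α + γ)", lambda d, t, a, b, g: g / (d + b + t + a + g)),
}

FEATURE_IDS = tuple(range(1, 27))
#: features whose formula involves the gamma band
GAMMA_FEATURE_IDS = tuple(range(14, 27))


def feature_catalog() -> list[tuple[int, str]]:
    """The 26 (id, formula) pairs of the spectral feature bank, in order."""
    return [(i, _CATALOG[i][0]) for i in FEATURE_IDS]


@dataclass
class FeatureTable:
    """Per-epoch, per-channel values of the selected features.

    Zero-denominator cells are NaN (a logged sentinel, never silently 0).
    """

    values: np.ndarray           # (n_epochs, n_channels, n_features)
    feature_ids: tuple[int, ...]
    labels: list[str]
    channel_labels: tuple[str, ...]
    subjects: list[str]

    def feature(self, feature_id: int) -> np.ndarray:
        """(n_epochs, n_channels) matrix of one feature's values."""
        return self.values[:, :, self.feature_ids.index(feature_id)]

    @property
    def conditions(self) -> np.ndarray:
        return np.asarray(self.labels)

    @property
    def subject_array(self) -> np.ndarray:
        return np.asarray(self.subjects)


def compute_features(
    bp: BandPowerTable, feature_ids: tuple[int, ...] = FEATURE_IDS
) -> FeatureTable:
    """Evaluate the catalog formulas on a band-power table.

    Denominators are evaluated exactly as written; a zero denominator
    yields NaN and is counted in a log message.
    """
    for fid in feature_ids:
        if fid not in _CATALOG:
            raise KeyError(f"unknown feature id {fid}")
    d, t, a, b, g = (bp.powers[:, :, i] for i in range(5))
    cols = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for fid in feature_ids:
            v = _CATALOG[fid][1](d, t, a, b, g)
            v = np.where(np.isfinite(v), v, np.nan)
            cols.append(v)
    values = np.stack(cols, axis=-1)
    n_bad = int(np.isnan(values).sum())
    if n_bad:
        logger.warning("compute_features: %d cells had zero denominators (set to NaN)", n_bad)
    return FeatureTable(
        values=values,
        feature_ids=tuple(feature_ids),
        labels=list(bp.labels),
        channel_labels=bp.channel_labels,
        subjects=list(bp.subjects),
    )
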