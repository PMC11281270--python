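"""Preprocessing chain: drop channels -> re-reference -> bandpass -> (ICA) -> epoch.

The filter is a 4th-order Butterworth applied forward-backward
(zero-phase), default 0.5-100 Hz. Re-referencing defaults to the common
average. ICA cleaning runs FastICA on PCA-reduced data with seeded
initialisation and flags artifact components by topography and spectrum;
flagged sources are zeroed and the signal back-projected, leaving channel
and sample counts unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._rng import child_seed
from .montage import FRONTAL, TEMPORAL
from .simulate import EEGRecording

__all__ = [
    "PreprocessConfig",
    "EpochSet",
    "ICAComponentFlag",
    "ICAReport",
    "ICAConvergenceError",
    "apply_filter",
    "rereference",
    "run_ica_clean",
    "epoch",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: tuple[float, float] = (0.5, 100.0)
    reference: str = "common_average"  # or a channel label
    drop_channels: tuple[str, ...] = ()
    ica: bool = False
    ica_components: int | None = 20
    epoch_length: float = 2.0      # seconds
    epoch_overlap: float = 0.0     # fraction in [0, 1)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if not 0 <= self.epoch_overlap < 1:
            raise ValueError("epoch_overlap must be in [0, 1)")


@dataclass
class EpochSet:
    """Epoched data: (n_epochs, n_channels, n_samples) in microvolts."""

    subject_id: str
    epochs: np.ndarray
    labels: list[str]              # condition per epoch
    channel_labels: tuple[str, ...]
    sampling_rate: float
    ica_applied: bool = False

    def __post_init__(self):
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def apply_filter(rec: EEGRecording, bandpass: tuple[float, float] = (0.5, 100.0)) -> EEGRecording:
    """Zero-phase 4th-order Butterworth bandpass; removes DC."""
    lo, hi = bandpass
    nyq = rec.sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"bandpass ({lo}, {hi}) Hz violates Nyquist limit {nyq} Hz"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = rec.copy()
    out.data = sps.sosfiltfilt(sos, out.data - out.data.mean(axis=1, keepdims=True), axis=1)
    return out


def rereference(rec: EEGRecording, reference: str = "common_average") -> EEGRecording:
    """Common-average or single-electrode re-reference."""
    out = rec.copy()
    if reference == "common_average":
        out.data = out.data - out.data.mean(axis=0, keepdims=True)
    else:
        if reference not in rec.channel_labels:
            raise ValueError(f"unknown reference channel {reference!r}")
        ref = rec.channel(reference)
        out.data = out.data - ref[None, :]
    out.reference = reference
    return out


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

class ICAConvergenceError(RuntimeError):
    def __init__(self, failed: list[int], max_iter: int, tol: float):
        super().__init__(
            f"FastICA: components {failed} did not converge within "
            f"max_iter={max_iter} at tol={tol}"
        )
        self.failed = failed


@dataclass
class ICAComponentFlag:
    component: int
    kind: str            # blink | emg | ecg | channel_noise
    evidence: dict


@dataclass
class ICAReport:
    n_components: int
    n_iter: list[int]            # iterations per component
    converged: list[bool]
    flags: list[ICAComponentFlag]


def _fastica_deflation(
    Z: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, list[int], list[bool]]:
    """Deflation FastICA (tanh contrast) on whitened data Z (d x n).

    Returns the orthonormal unmixing matrix W (rows = components) plus
    per-component iteration counts and convergence flags. On a Gaussian
    direction the fixed-point update degenerates to sample noise, so such
    components legitimately fail to settle; they are returned (orthogonal
    complement structure is still valid) but marked non-converged.
    """
    d, n = Z.shape
    W = np.zeros((d, d))
    n_iters: list[int] = []
    converged: list[bool] = []
    for k in range(d):
        w = rng.standard_normal(d)
        w -= W[:k].T @ (W[:k] @ w)
        w /= np.linalg.norm(w)
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            u = w @ Z
            g = np.tanh(u)
            gp = 1.0 - g**2
            w_new = (Z @ g) / n - gp.mean() * w
            w_new -= W[:k].T @ (W[:k] @ w_new)
            nrm = np.linalg.norm(w_new)
            if nrm < 1e-12:
                break
            w_new /= nrm
            delta = abs(abs(w_new @ w) - 1.0)
            w = w_new
            if delta < tol:
                ok = True
                break
        W[k] = w
        n_iters.append(it)
        converged.append(ok)
    return W, n_iters, converged


def _psd_fraction(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Fraction of Welch power inside [lo, hi) relative to [0.5, fs/2)."""
    f, p = sps.welch(x, fs=fs, nperseg=min(x.size, int(4 * fs)))
    total = p[(f >= 0.5)].sum()
    if total <= 0:
        return 0.0
    return float(p[(f >= lo) & (f < hi)].sum() / total)


def _looks_like_ecg(s: np.ndarray, fs: float) -> bool:
    """Quasi-periodic spikes at 0.5-1.5 Hz with a regular interval."""
    z = (s - s.mean()) / max(1e-12, s.std())
    kurt = float(np.mean(z**4))
    if kurt < 8.0:
        return False
    peaks, _ = sps.find_peaks(np.abs(z), height=3.0, distance=int(0.3 * fs))
    if peaks.size < 5:
        return False
    iv = np.diff(peaks) / fs
    mean_iv = float(iv.mean())
    return 0.4 <= mean_iv <= 2.0 and float(iv.std()) / mean_iv < 0.25


def _intermittency(s: np.ndarray, fs: float, annotations) -> float:
    """Within-block burstiness: std of log RMS over 1-s frames.

    Artifacts (blinks, EMG bursts) switch on and off within a condition
    block; genuine band-power workload structure is stationary inside a
    block and only shifts between blocks. Measuring variability within
    annotations therefore separates the two even when both are
    non-Gaussian over the whole session.
    """
    frame = int(fs)
    blocks = [(a, b) for a, b, _ in annotations] or [(0, s.size)]
    vals = []
    for a, b in blocks:
        seg = s[a:b]
        n_fr = seg.size // frame
        if n_fr < 3:
            continue
        r = seg[: n_fr * frame].reshape(n_fr, frame).std(axis=1)
        vals.append(np.log(np.maximum(r, 1e-12)).std())
    return float(np.mean(vals)) if vals else 0.0


def _between_block_variability(s: np.ndarray, annotations) -> float:
    """Std of log RMS across condition blocks.

    Contact (channel) noise keeps the same variance throughout the
    session; genuine workload signal shifts power between blocks.
    """
    if not annotations:
        return 0.0
    vals = [np.log(max(float(s[a:b].std()), 1e-12)) for a, b, _ in annotations]
    return float(np.std(vals))


def _flag_components(
    mixing: np.ndarray,
    sources: np.ndarray,
    channel_labels: tuple[str, ...],
    fs: float,
    annotations=(),
) -> list[ICAComponentFlag]:
    """Deterministic artifact rules on topography, spectrum and waveform.

    blink: frontal loading, <4 Hz spectral dominance, intermittent;
    emg: temporal loading, >30 Hz dominance, intermittent;
    channel_noise: one channel carries >0.9 of the loading norm with a
        broadband (high-frequency-heavy) stationary source;
    ecg: regular ~1 Hz spike train in the source waveform.

    The intermittency gate (within-block burstiness) keeps block-
    stationary workload signal out of the blink/EMG classes.
    """
    frontal = [i for i, c in enumerate(channel_labels) if c in FRONTAL]
    temporal = [i for i, c in enumerate(channel_labels) if c in TEMPORAL]
    flags: list[ICAComponentFlag] = []
    for k in range(mixing.shape[1]):
        col = mixing[:, k]
        norm2 = float(col @ col)
        if norm2 <= 0:
            continue
        u2 = col**2 / norm2
        front_load = float(u2[frontal].sum()) if frontal else 0.0
        temp_load = float(u2[temporal].sum()) if temporal else 0.0
        max_load = float(np.sqrt(u2.max()))
        s = sources[:, k]
        low = _psd_fraction(s, fs, 0.5, 4.0)
        high = _psd_fraction(s, fs, 30.0, fs / 2.0)
        burst = _intermittency(s, fs, annotations)
        if front_load > 0.6 and low > 0.5 and burst > 0.35:
            flags.append(ICAComponentFlag(
                k, "blink", {"frontal_loading": front_load,
                             "low_freq_fraction": low, "burstiness": burst}))
        elif temp_load > 0.5 and high > 0.4 and burst > 0.35:
            flags.append(ICAComponentFlag(
                k, "emg", {"temporal_loading": temp_load,
                           "high_freq_fraction": high, "burstiness": burst}))
        elif (max_load > 0.9 and high > 0.65 and burst <= 0.35
              and _between_block_variability(s, annotations) < 0.2):
            flags.append(ICAComponentFlag(
                k, "channel_noise", {"max_loading": max_load,
                                     "high_freq_fraction": high}))
        elif _looks_like_ecg(s, fs):
            flags.append(ICAComponentFlag(k, "ecg", {"kurtosis_spikes": True}))
    return flags


def run_ica_clean(
    rec: EEGRecording,
    n_components: int | None = 20,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    strict: bool = False,
    return_report: bool = False,
):
    """ICA artifact removal; channel/sample counts are preserved.

    The recording is PCA-reduced to ``n_components`` dimensions, whitened
    and unmixed with deflation FastICA (seeded init, so flags are
    reproducible). Sources whose topography/spectrum/waveform match one
    of the four artifact classes (blink, EMG, ECG, channel noise) are
    zeroed and the signal back-projected; the PCA residual is untouched.

    Components aligned with near-Gaussian background directions cannot
    converge (the FastICA update is degenerate there) and are kept as
    non-artifact residual sources; ``strict=True`` turns any such
    component into an ICAConvergenceError with iteration diagnostics.
    """
    if rec.n_channels < 2:
        raise ValueError("ICA requires at least 2 channels")
    if rec.n_samples < 30 * rec.sampling_rate:
        raise ValueError("ICA requires at least 30 s of data")
    n_comp = min(n_components or rec.n_channels, rec.n_channels)
    X = rec.data - rec.data.mean(axis=1, keepdims=True)  # (ch, n)
    n = X.shape[1]
    cov = (X @ X.T) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_comp]
    lam = np.maximum(evals[order], 1e-12)
    E = evecs[:, order]
    Z = (E / np.sqrt(lam)).T @ X                 # whitened (d, n)
    rng = np.random.default_rng(child_seed(seed, rec.subject_id, "ica"))
    W, n_iters, conv = _fastica_deflation(Z, rng, max_iter, tol)
    if strict and not all(conv):
        failed = [k for k, ok in enumerate(conv) if not ok]
        raise ICAConvergenceError(failed, max_iter, tol)
    S = W @ Z                                    # sources (d, n)
    mixing = (E * np.sqrt(lam)) @ W.T            # (ch, d)
    flags = _flag_components(mixing, S.T, rec.channel_labels, rec.sampling_rate,
                             rec.annotations)
    out = rec.copy()
    if flags:
        bad = [f.component for f in flags]
        out.data = rec.data - mixing[:, bad] @ S[bad, :]
    report = ICAReport(n_components=n_comp, n_iter=n_iters, converged=conv,
                       flags=flags)
    if return_report:
        return out, report
    return out


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch(rec: EEGRecording, epoch_length: float = 2.0, overlap: float = 0.0,
          ica_applied: bool = False) -> EpochSet:
    """Tile fixed-length windows inside each annotation; drop partial tails."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    n_win = int(round(epoch_length * rec.sampling_rate))
    step = max(1, int(round(n_win * (1.0 - overlap))))
    chunks, labels = [], []
    for start, end, cond in rec.annotations:
        if end - start < n_win:
            raise ValueError(
                f"epoch_length {epoch_length}s exceeds annotation "
                f"[{start}, {end}) ({cond})"
            )
        for i0 in range(start, end - n_win + 1, step):
            chunks.append(rec.data[:, i0:i0 + n_win])
            labels.append(cond)
    return EpochSet(
        subject_id=rec.subject_id,
        epochs=np.stack(chunks, axis=0),
        labels=labels,
        channel_labels=rec.channel_labels,
        sampling_rate=rec.sampling_rate,
        ica_applied=ica_applied,
    )


def preprocess_recording(rec: EEGRecording, config: PreprocessConfig) -> EpochSet:
    """Full chain in the fixed order drop -> re-reference -> filter -> (ICA) -> epoch."""
    out = rec
    if config.drop_channels:
        keep = [i for i, c in enumerate(out.channel_labels)
                if c not in config.drop_channels]
        out = out.copy()
        out.data = out.data[keep]
        out.channel_labels = tuple(out.channel_labels[i] for i in keep)
    out = rereference(out, config.reference)
    out = apply_filter(out, config.bandpass)
    if config.ica:
        out = run_ica_clean(out, n_components=config.ica_components, seed=config.seed)
    return epoch(out, config.epoch_length, config.epoch_overlap,
                 ica_applied=config.ica)
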