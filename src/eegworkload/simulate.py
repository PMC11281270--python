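"""Synthetic multi-channel EEG with a planted workload effect.

The generator is statistical, not biophysical: each channel is coloured
Gaussian noise whose power spectral density is a 1/f floor multiplied, on a
configurable set of "informative" channels, by per-band, per-condition gain
factors. Because disjoint frequency bins of a Gaussian process are
independent, shaping a single white-noise spectrum is exactly equivalent to
summing independent band-limited components — and gives direct control of
every band's expected power. Physiological artifacts (blink, EMG, ECG,
channel noise) are injected additively on their characteristic
topographies.

A session concatenates five condition blocks in the fixed order
resting -> scenario4 -> scenario3 -> scenario1 -> scenario2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .montage import (
    CHANNELS_59,
    CHANNEL_NUMBERS,
    CONDITION_ORDER,
    CONDITIONS,
    CONSENSUS_SET,
    WORKLOAD_RANK,
)

__all__ = [
    "ArtifactSpec",
    "SimulationConfig",
    "EEGRecording",
    "ConfigError",
    "default_band_gains",
    "simulate_subject",
    "inject_artifacts",
    "simulate_dataset",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

ARTIFACT_CLASSES = ("blink", "emg", "ecg", "channel_noise")


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact process: class, target channels, event rate, amplitude.

    rate is in events per second (ignored for channel_noise, which is
    continuous); amplitude is the peak deflection in microvolts.
    """

    kind: str
    channels: tuple[str, ...]
    rate: float = 0.25
    amplitude: float = 80.0
    width: float | None = None   # blink Gaussian sigma in s (default 0.08)

    def __post_init__(self):
        if self.kind not in ARTIFACT_CLASSES:
            raise ConfigError(
                f"unknown artifact class {self.kind!r}; valid classes are "
                f"{', '.join(ARTIFACT_CLASSES)}"
            )
        object.__setattr__(self, "channels", tuple(self.channels))


#: per-rank multiplicative band-gain steps of the default workload effect
_GAIN_STEPS = {"delta": 1.0, "theta": 1.3, "alpha": 0.9, "beta": 1.7, "gamma": 2.8}


def default_band_gains() -> dict[str, dict[str, float]]:
    """Per-condition band-power multipliers on informative channels.

    Workload rank r (resting=0 < scn1 < scn2 < scn4 < scn3=4) modulates
    the canonical bands geometrically (constant power ratio per rank
    step): theta, beta and above all gamma power rise with load while
    alpha is mildly suppressed; delta is load-neutral. The steep gamma
    step acts on the small broadband high-frequency floor, so the
    absolute power excursions stay physiological while the high-frequency
    content — the band with the most spectral degrees of freedom per
    epoch — carries most of the discriminative signal. This places the
    generator in the near-separable regime that high-accuracy workload
    detection presumes.
    """
    gains: dict[str, dict[str, float]] = {}
    for cond in CONDITIONS:
        r = WORKLOAD_RANK[cond]
        gains[cond] = {band: step**r for band, step in _GAIN_STEPS.items()}
    return gains


def _default_artifacts() -> tuple[ArtifactSpec, ...]:
    return (
        ArtifactSpec("blink", ("Fp1", "Fpz", "Fp2"), rate=0.25, amplitude=100.0),
        ArtifactSpec("emg", ("T7", "T8"), rate=0.10, amplitude=15.0),
        ArtifactSpec("ecg", CHANNELS_59, rate=1.1, amplitude=2.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level description of the synthetic dataset.

    Defaults emulate the controller experiment at desk scale: 59 channels,
    250 Hz, five 60 s condition blocks per subject, the workload effect
    planted on the six centro-parietal channels CP2/CP3/CP4/CP5/CP6/TP7,
    and background blink/EMG/ECG artifacts on their usual topographies.
    """

    n_subjects: int = 10
    n_channels: int = 59
    sampling_rate: float = 250.0
    condition_duration: float = 60.0
    band_gains: dict = field(default_factory=default_band_gains)
    informative_channels: tuple[str, ...] = CONSENSUS_SET
    subject_variability: float = 0.03
    artifact_spec: tuple[ArtifactSpec, ...] = field(default_factory=_default_artifacts)
    noise_floor: float = 20.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "informative_channels", tuple(self.informative_channels))
        object.__setattr__(self, "artifact_spec", tuple(
            a if isinstance(a, ArtifactSpec) else ArtifactSpec(**a)
            for a in self.artifact_spec
        ))
        self.validate()

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return CHANNELS_59[: self.n_channels]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 1 <= self.n_channels <= len(CHANNELS_59):
            raise ConfigError(f"n_channels must be in [1, {len(CHANNELS_59)}]")
        if self.sampling_rate <= 200.0:
            raise ConfigError(
                "sampling_rate must exceed 200 Hz so the gamma band "
                "(up to 100 Hz) is representable"
            )
        if self.condition_duration <= 0:
            raise ConfigError("condition_duration must be positive")
        if self.noise_floor <= 0:
            raise ConfigError("noise_floor must be positive")
        if self.subject_variability < 0:
            raise ConfigError("subject_variability must be >= 0")
        labels = self.channel_labels
        if not self.informative_channels:
            raise ConfigError("informative_channels must not be empty")
        for ch in self.informative_channels:
            if ch not in labels:
                raise ConfigError(f"informative channel {ch!r} not in montage")
        for cond, bands in self.band_gains.items():
            if cond not in CONDITIONS:
                raise ConfigError(f"band_gains references unknown condition {cond!r}")
            for band, g in bands.items():
                if band not in BAND_NAMES:
                    raise ConfigError(f"band_gains references unknown band {band!r}")
                if not g > 0:
                    raise ConfigError(f"band gain {band}/{cond} must be > 0, got {g}")
        for art in self.artifact_spec:
            for ch in art.channels:
                if ch not in labels:
                    raise ConfigError(f"artifact targets unknown channel {ch!r}")


@dataclass
class EEGRecording:
    """One subject's multi-channel session in microvolts.

    annotations are half-open sample intervals [start, end) tagged with the
    condition; they are sorted, non-overlapping and cover each of the five
    conditions exactly once.
    """

    subject_id: str
    sampling_rate: float
    channel_labels: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), float64 microvolts
    annotations: list[tuple[int, int, str]]
    reference: str = "linked-mastoid (simulated)"

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel label")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows != number of channel labels")
        last = 0
        for start, end, cond in self.annotations:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if not 0 <= start < end <= self.data.shape[1]:
                raise ValueError("annotation outside data")
            if start < last:
                raise ValueError("annotations overlap or are unsorted")
            last = end

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def channel_index_map(self) -> dict[str, int]:
        """label -> 1-based channel number (CP2=36 ... TP7=41)."""
        return {lab: CHANNEL_NUMBERS[lab] for lab in self.channel_labels}

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            subject_id=self.subject_id,
            sampling_rate=self.sampling_rate,
            channel_labels=self.channel_labels,
            data=self.data.copy(),
            annotations=list(self.annotations),
            reference=self.reference,
        )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

_F_LOW = 0.5    # lower edge of generated content, Hz
_F_KNEE = 1.0   # 1/f knee, Hz
_F_HIGH = 110.0  # upper edge of generated content, Hz
_HF_FLOOR = 0.04  # flat broadband floor relative to the 1 Hz power
                  # (real scalp EEG flattens above ~30 Hz; -14 dB here)


def _spectral_shape(freqs: np.ndarray) -> np.ndarray:
    """Amplitude shape of the noise floor over rfft frequencies: 1/f + flat."""
    shape = np.zeros_like(freqs)
    mask = (freqs >= _F_LOW) & (freqs <= _F_HIGH)
    shape[mask] = np.sqrt(1.0 / np.maximum(freqs[mask], _F_KNEE) + _HF_FLOOR)
    return shape


def _band_gain_profile(freqs: np.ndarray, gains: dict[str, float]) -> np.ndarray:
    """Per-frequency power multiplier implementing per-band gains."""
    prof = np.ones_like(freqs)
    for band, (lo, hi) in BAND_EDGES.items():
        g = gains.get(band, 1.0)
        prof[(freqs >= lo) & (freqs < hi)] = g
    return prof


def _subject_gain_table(config: SimulationConfig, subject_id: str) -> dict[str, dict[str, float]]:
    """Condition -> band -> gain after per-subject jitter.

    Jitter has two components per band: a level factor applied to every
    condition (shifts absolute power, preserves condition ratios) and an
    effect exponent applied to the condition gain (varies effect size
    across subjects). Both vanish when subject_variability is 0.
    """
    sv = config.subject_variability
    rng = substream(config.seed, subject_id, "gains")
    level = {b: float(np.exp(sv * rng.standard_normal())) for b in BAND_NAMES}
    expo = {b: float(max(0.2, 1.0 + sv * rng.standard_normal())) for b in BAND_NAMES}
    table: dict[str, dict[str, float]] = {}
    for cond in CONDITIONS:
        base = config.band_gains.get(cond, {})
        table[cond] = {
            b: level[b] * float(base.get(b, 1.0)) ** expo[b] for b in BAND_NAMES
        }
    return table


def _synth_block(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    gain_profiles: np.ndarray,  # (n_channels, n_freqs) power multipliers
    amplitude_scale: float,
) -> np.ndarray:
    """Coloured-noise block with per-channel spectral gain profiles."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    base = _spectral_shape(freqs)
    amp = base[None, :] * np.sqrt(gain_profiles)
    z = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
        (n_channels, freqs.size)
    )
    z[:, 0] = 0.0
    if n_samples % 2 == 0:
        z[:, -1] = z[:, -1].real
    x = np.fft.irfft(z * amp, n=n_samples, axis=1)
    return amplitude_scale * x


def _amplitude_scale(n_samples: int, fs: float, noise_floor: float) -> float:
    """Scale factor making a unit-gain block have RMS = noise_floor (µV)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    base = _spectral_shape(freqs)
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    var_unit = float(np.sum(w * base**2)) / n_samples**2
    return noise_floor / np.sqrt(var_unit)


def simulate_subject(config: SimulationConfig, subject_id: str) -> EEGRecording:
    """Generate one subject's five-condition session.

    Per-condition expected band power on informative channels equals the
    1/f floor's band power times the configured (jittered) band gain;
    non-informative channels have condition-independent spectra. Artifacts
    from config.artifact_spec are injected afterwards.
    """
    if not subject_id:
        raise ConfigError("subject_id must be nonempty")
    config.validate()
    fs = config.sampling_rate
    labels = config.channel_labels
    n_ch = config.n_channels
    n_block = int(round(config.condition_duration * fs))
    info_idx = np.array([labels.index(ch) for ch in config.informative_channels])

    gain_table = _subject_gain_table(config, subject_id)
    scale = _amplitude_scale(n_block, fs, config.noise_floor)
    freqs = np.fft.rfftfreq(n_block, 1.0 / fs)

    blocks = []
    annotations = []
    cursor = 0
    for cond in CONDITION_ORDER:
        rng = substream(config.seed, subject_id, "signal", cond)
        profiles = np.ones((n_ch, freqs.size))
        profiles[info_idx] = _band_gain_profile(freqs, gain_table[cond])[None, :]
        blocks.append(_synth_block(rng, n_ch, n_block, fs, profiles, scale))
        annotations.append((cursor, cursor + n_block, cond))
        cursor += n_block

    rec = EEGRecording(
        subject_id=subject_id,
        sampling_rate=fs,
        channel_labels=labels,
        data=np.concatenate(blocks, axis=1),
        annotations=annotations,
    )
    if config.artifact_spec:
        rec = inject_artifacts(rec, config.artifact_spec, seed=config.seed)
    return rec


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _blink_trace(rng, n, fs, rate, amplitude, sigma=None):
    """Sparse Gaussian-bump transients; width sets the spectral reach.

    The default sigma of 0.08 s (FWHM ~0.19 s) concentrates energy below
    4 Hz with a theta-band tail; narrower bumps push more energy into
    theta/alpha.
    """
    trace = np.zeros(n)
    sigma = 0.08 if sigma is None else sigma
    n_events = rng.poisson(rate * n / fs)
    centers = rng.uniform(0, n / fs, size=n_events)
    t = np.arange(n) / fs
    for c in centers:
        lo = max(0, int((c - 4 * sigma) * fs))
        hi = min(n, int((c + 4 * sigma) * fs))
        trace[lo:hi] += amplitude * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return trace


def _emg_trace(rng, n, fs, rate, amplitude):
    """Broadband 20-100 Hz bursts of ~0.5 s with a Tukey envelope."""
    from scipy import signal as sps

    trace = np.zeros(n)
    n_events = rng.poisson(rate * n / fs)
    starts = rng.uniform(0, max(1e-9, n / fs - 0.5), size=n_events)
    sos = sps.butter(4, [20.0, min(100.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    burst_len = int(0.5 * fs)
    env = sps.windows.tukey(burst_len, 0.5)
    for s in starts:
        i0 = int(s * fs)
        i1 = min(n, i0 + burst_len)
        noise = sps.sosfilt(sos, rng.standard_normal(burst_len))
        noise /= max(1e-12, np.std(noise))
        trace[i0:i1] += amplitude * (env * noise)[: i1 - i0]
    return trace


def _qrs_shape(fs):
    """A crude biphasic QRS complex, ~80 ms wide, unit peak."""
    t = np.arange(-0.06, 0.06, 1.0 / fs)
    shape = np.exp(-0.5 * (t / 0.012) ** 2) - 0.35 * np.exp(-0.5 * ((t - 0.03) / 0.02) ** 2)
    return shape / np.max(np.abs(shape))


def _ecg_source(rng, n, fs, rate):
    """Quasi-periodic QRS spike train at ~rate Hz with small RR jitter."""
    src = np.zeros(n)
    qrs = _qrs_shape(fs)
    t = rng.uniform(0.0, 1.0 / rate)
    while t * fs < n:
        i0 = int(t * fs)
        i1 = min(n, i0 + qrs.size)
        src[i0:i1] += qrs[: i1 - i0]
        t += (1.0 / rate) * (1.0 + 0.03 * rng.standard_normal())
    return src


def inject_artifacts(
    rec: EEGRecording,
    artifact_spec,
    seed: int = 0,
) -> EEGRecording:
    """Return a copy of ``rec`` with the requested artifacts added.

    blink: low-frequency transients on the targeted (frontal) channels.
    emg: 20-100 Hz bursts on the targeted (temporal) channels.
    ecg: one QRS spike train mixed at low amplitude into ALL targeted
         channels with random per-channel weights (volume conduction is
         global, so ecg is the one class that touches many channels).
    channel_noise: large-variance white noise on exactly one channel.

    Channels not targeted by any spec entry are returned bit-identical.
    """
    out = rec.copy()
    n = rec.n_samples
    fs = rec.sampling_rate
    for spec in artifact_spec:
        if not isinstance(spec, ArtifactSpec):
            spec = ArtifactSpec(**spec)
        for ch in spec.channels:
            if ch not in rec.channel_labels:
                raise ConfigError(f"artifact targets unknown channel {ch!r}")
        idx = [rec.channel_labels.index(ch) for ch in spec.channels]
        rng = substream(seed, rec.subject_id, "artifact", spec.kind,
                        ",".join(spec.channels))
        if spec.kind == "blink":
            for j, i in enumerate(idx):
                # shared ocular source, slightly different projection weights
                w = 1.0 - 0.1 * j / max(1, len(idx))
                out.data[i] += w * _blink_trace(
                    substream(seed, rec.subject_id, "blink-src"), n, fs,
                    spec.rate, spec.amplitude, spec.width)
        elif spec.kind == "emg":
            for i in idx:
                out.data[i] += _emg_trace(rng, n, fs, spec.rate, spec.amplitude)
        elif spec.kind == "ecg":
            src = _ecg_source(rng, n, fs, spec.rate)
            weights = spec.amplitude * rng.uniform(0.4, 1.0, size=len(idx))
            signs = rng.choice([-1.0, 1.0], size=len(idx))
            for w, s, i in zip(weights, signs, idx):
                out.data[i] += w * s * src
        elif spec.kind == "channel_noise":
            if len(idx) != 1:
                raise ConfigError("channel_noise targets exactly one channel")
            out.data[idx[0]] += spec.amplitude * rng.standard_normal(n)
    return out


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def subject_ids(n_subjects: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n_subjects)]


def simulate_dataset(config: SimulationConfig) -> tuple[list[EEGRecording], dict]:
    """One recording per subject plus a manifest dict.

    Subjects draw from hashed per-subject substreams, so enlarging
    n_subjects never changes earlier subjects' data.
    """
    recs = [simulate_subject(config, sid) for sid in subject_ids(config.n_subjects)]
    manifest = {
        "n_subjects": config.n_subjects,
        "sampling_rate": config.sampling_rate,
        "seed": config.seed,
        "condition_order": list(CONDITION_ORDER),
        "subjects": [
            {
                "subject_id": r.subject_id,
                "n_channels": r.n_channels,
                "n_samples": r.n_samples,
                "annotations": [
                    {"start": int(a), "end": int(b), "condition": c}
                    for a, b, c in r.annotations
                ],
            }
            for r in recs
        ],
        "config": {
            "n_channels": config.n_channels,
            "condition_duration": config.condition_duration,
            "informative_channels": list(config.informative_channels),
            "subject_variability": config.subject_variability,
            "noise_floor": config.noise_floor,
        },
    }
    return recs, manifest
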