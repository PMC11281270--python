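"""File formats: CSV/EDF recordings, npz epoch and feature containers.

Recordings travel either as an exact text layout (``data.csv`` with one
row per sample plus a JSON sidecar for rate/annotations) or as 16-bit EDF.
EDF writing is implemented here directly against the format's fixed-width
header layout because no EDF-writing library is available; reading uses
MNE when a ``.edf`` path is given. EDF quantizes to 16 bits, so its
round-trip is exact only to one quantization step; the CSV layout is
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .simulate import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_edf",
    "read_edf",
    "save_epochset",
    "load_epochset",
    "save_feature_table",
    "load_feature_table",
]


# ---------------------------------------------------------------------------
# CSV layout (lossless)
# ---------------------------------------------------------------------------

def write_recording_csv(rec: EEGRecording, path) -> Path:
    """Write ``<path>.csv`` (samples x channels, 17 sig digits) + ``<path>.json``."""
    path = Path(path)
    base = path.with_suffix("")
    header = ",".join(rec.channel_labels)
    np.savetxt(base.with_suffix(".csv"), rec.data.T, delimiter=",",
               header=header, comments="", fmt="%.17g")
    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "reference": rec.reference,
        "annotations": [
            {"start": int(a), "end": int(b), "condition": c}
            for a, b, c in rec.annotations
        ],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".csv")


def read_recording_csv(path) -> EEGRecording:
    path = Path(path)
    base = path.with_suffix("")
    csv_path = base.with_suffix(".csv")
    with open(csv_path) as fh:
        labels = tuple(fh.readline().strip().split(","))
    if len(set(labels)) != len(labels):
        raise ValueError(f"{csv_path}: duplicate channel label in header")
    data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2).T
    meta = json.loads(base.with_suffix(".json").read_text())
    return EEGRecording(
        subject_id=meta["subject_id"],
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=labels,
        data=data,
        annotations=[(a["start"], a["end"], a["condition"])
                     for a in meta["annotations"]],
        reference=meta.get("reference", "unknown"),
    )


# ---------------------------------------------------------------------------
# EDF (16-bit, one data record per second)
# ---------------------------------------------------------------------------

def _fix(value: str, width: int) -> bytes:
    b = str(value)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Minimal EDF writer: µV signals, 1 s data records, int16 samples.

    Requires an integer sampling rate; the signal is zero-padded to a
    whole number of records. Annotations go to a ``.json`` sidecar (this
    writer emits plain EDF, not EDF+).
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : rec.n_samples] = rec.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = (2 * phys_max) / (dig_max - dig_min)
    digital = np.clip(np.round((data + phys_max[:, None]) / scale[:, None]) + dig_min,
                      dig_min, dig_max).astype("<i2")

    header = b"".join([
        _fix("0", 8),
        _fix(rec.subject_id, 80),
        _fix("eegworkload synthetic", 80),
        _fix("01.01.00", 8),
        _fix("00.00.00", 8),
        _fix(str(256 * (1 + n_ch)), 8),
        _fix("", 44),
        _fix(str(n_rec), 8),
        _fix("1", 8),
        _fix(str(n_ch), 4),
    ])
    fields = [
        [lab for lab in rec.channel_labels],                      # label, 16
        ["" for _ in range(n_ch)],                                # transducer, 80
        ["uV" for _ in range(n_ch)],                              # dimension, 8
        [f"{-m:.6g}"[:8] for m in phys_max],                      # physical min, 8
        [f"{m:.6g}"[:8] for m in phys_max],                       # physical max, 8
        [str(dig_min) for _ in range(n_ch)],                      # digital min, 8
        [str(dig_max) for _ in range(n_ch)],                      # digital max, 8
        ["" for _ in range(n_ch)],                                # prefiltering, 80
        [str(fs) for _ in range(n_ch)],                           # samples/record, 8
        ["" for _ in range(n_ch)],                                # reserved, 32
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    for vals, width in zip(fields, widths):
        header += b"".join(_fix(v, width) for v in vals)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())

    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": rec.sampling_rate,
        "n_samples": rec.n_samples,
        "reference": rec.reference,
        "annotations": [
            {"start": int(a), "end": int(b), "condition": c}
            for a, b, c in rec.annotations
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_edf(path) -> EEGRecording:
    """Read an EDF file (via MNE) plus the JSON sidecar annotations."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    labels = tuple(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel label")
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        annotations = [(a["start"], a["end"], a["condition"])
                       for a in meta["annotations"]]
        subject = meta["subject_id"]
        n = meta.get("n_samples", data.shape[1])
        data = data[:, :n]
        reference = meta.get("reference", "unknown")
    else:
        annotations, subject, reference = [], path.stem, "unknown"
    return EEGRecording(
        subject_id=subject,
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        data=data,
        annotations=annotations,
        reference=reference,
    )


def write_recording(rec: EEGRecording, path) -> Path:
    path = Path(path)
    if path.suffix == ".edf":
        return write_edf(rec, path)
    return write_recording_csv(rec, path)


def read_recording(path) -> EEGRecording:
    path = Path(path)
    if path.suffix == ".edf":
        return read_edf(path)
    return read_recording_csv(path)


# ---------------------------------------------------------------------------
# npz containers for the intermediate pipeline stages
# ---------------------------------------------------------------------------

def save_epochset(es, path) -> Path:
    from .preprocess import EpochSet  # noqa: F401  (type documented)

    path = Path(path)
    np.savez_compressed(
        path,
        epochs=es.epochs,
        labels=np.asarray(es.labels),
        channel_labels=np.asarray(es.channel_labels),
        subject_id=np.asarray(es.subject_id),
        sampling_rate=np.asarray(es.sampling_rate),
        ica_applied=np.asarray(es.ica_applied),
    )
    return path


def load_epochset(path):
    from .preprocess import EpochSet

    z = np.load(Path(path), allow_pickle=False)
    return EpochSet(
        subject_id=str(z["subject_id"]),
        epochs=z["epochs"],
        labels=[str(x) for x in z["labels"]],
        channel_labels=tuple(str(x) for x in z["channel_labels"]),
        sampling_rate=float(z["sampling_rate"]),
        ica_applied=bool(z["ica_applied"]),
    )


def save_feature_table(ft, path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        values=ft.values,
        feature_ids=np.asarray(ft.feature_ids),
        labels=np.asarray(ft.labels),
        channel_labels=np.asarray(ft.channel_labels),
        subjects=np.asarray(ft.subjects),
    )
    return path


def load_feature_table(path):
    from .spectral import FeatureTable

    z = np.load(Path(path), allow_pickle=False)
    return FeatureTable(
        values=z["values"],
        feature_ids=tuple(int(i) for i in z["feature_ids"]),
        labels=[str(x) for x in z["labels"]],
        channel_labels=tuple(str(x) for x in z["channel_labels"]),
        subjects=[str(x) for x in z["subjects"]],
    )
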