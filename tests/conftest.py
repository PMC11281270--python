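import numpy as np
import pytest

from eegworkload.montage import CONDITIONS, WORKLOAD_RANK
from eegworkload.simulate import SimulationConfig, simulate_subject
from eegworkload.spectral import FEATURE_IDS, FeatureTable


def geometric_gains(theta=1.3, beta=1.7, gamma=2.8, alpha=0.9, delta=1.0):
    """Band-gain table with constant per-rank power ratios."""
    steps = {"delta": delta, "theta": theta, "alpha": alpha,
             "beta": beta, "gamma": gamma}
    return {c: {b: s ** WORKLOAD_RANK[c] for b, s in steps.items()}
            for c in CONDITIONS}


def gamma_only_gains(step=2.2):
    """Workload effect carried exclusively by the gamma band."""
    return geometric_gains(theta=1.0, beta=1.0, gamma=step, alpha=1.0)


@pytest.fixture(scope="session")
def small_clean_recording():
    """One artifact-free subject, 20 s per condition."""
    cfg = SimulationConfig(n_subjects=1, condition_duration=20.0, seed=77,
                           artifact_spec=(), subject_variability=0.0)
    return simulate_subject(cfg, "s01")


def synthetic_feature_table(
    n_subjects=4,
    epochs_per_condition=10,
    n_channels=6,
    informative=(0, 1, 2),
    class_gap=5.0,
    noise=0.3,
    seed=0,
    channel_labels=None,
):
    """Fabricated feature table: feature 16 separates conditions on the
    informative channels; everything else is noise. Fast substitute for
    the full simulation in classifier unit tests."""
    rng = np.random.default_rng(seed)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(n_channels))
    order = ("resting", "scenario4", "scenario3", "scenario1", "scenario2")
    values, labels, subjects = [], [], []
    for s in range(n_subjects):
        for cond in order:
            r = WORKLOAD_RANK[cond]
            for _ in range(epochs_per_condition):
                v = rng.normal(0.0, 1.0, size=(n_channels, len(FEATURE_IDS)))
                f16 = np.full(n_channels, rng.normal(0.0, 1.0))
                for ch in informative:
                    f16[ch] = class_gap * r + rng.normal(0.0, noise)
                v[:, list(FEATURE_IDS).index(16)] = f16
                values.append(v)
                labels.append(cond)
                subjects.append(f"s{s + 1:02d}")
    return FeatureTable(
        values=np.stack(values),
        feature_ids=FEATURE_IDS,
        labels=labels,
        channel_labels=tuple(channel_labels),
        subjects=subjects,
    )
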