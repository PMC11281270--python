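"""Synthetic EEG generator: determinism, spectral contract, artifacts."""

import numpy as np
import pytest
from scipy import signal as sps

from eegworkload.montage import CHANNELS_59, CONDITION_ORDER, CONSENSUS_SET
from eegworkload.simulate import (
    ArtifactSpec,
    ConfigError,
    SimulationConfig,
    inject_artifacts,
    simulate_dataset,
    simulate_subject,
)


def welch_band_power(x, fs, lo, hi):
    f, p = sps.welch(x, fs=fs, nperseg=min(x.size, 2048))
    return p[(f >= lo) & (f < hi)].mean()


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs,match", [
        (dict(n_subjects=0), "n_subjects"),
        (dict(sampling_rate=150.0), "sampling_rate"),
        (dict(noise_floor=-1.0), "noise_floor"),
        (dict(informative_channels=("XX",)), "XX"),
        (dict(informative_channels=()), "informative_channels"),
        (dict(band_gains={"resting": {"theta": 0.0}}), "theta"),
        (dict(band_gains={"nonsense": {"theta": 1.0}}), "nonsense"),
        (dict(n_channels=99), "n_channels"),
    ])
    def test_invalid_fields_are_named(self, kwargs, match):
        with pytest.raises(ConfigError, match=match):
            SimulationConfig(**kwargs)

    def test_unknown_artifact_class_lists_valid_ones(self):
        with pytest.raises(ConfigError, match="blink, emg, ecg, channel_noise"):
            ArtifactSpec("eyeroll", ("Fp1",))

    def test_channel_numbering_matches_report_convention(self):
        cfg = SimulationConfig(n_subjects=1, condition_duration=5.0)
        rec = simulate_subject(cfg, "s01")
        expected = {"CP2": 36, "CP3": 37, "CP4": 38, "CP5": 39,
                    "CP6": 40, "TP7": 41}
        for lab, num in expected.items():
            assert rec.channel_index_map[lab] == num


class TestSimulateSubject:
    def test_same_config_and_seed_is_bit_identical(self):
        cfg = SimulationConfig(n_subjects=1, condition_duration=5.0, seed=4)
        a = simulate_subject(cfg, "s01")
        b = simulate_subject(cfg, "s01")
        assert np.array_equal(a.data, b.data)

    def test_conditions_appear_in_session_order(self):
        cfg = SimulationConfig(n_subjects=1, condition_duration=5.0)
        rec = simulate_subject(cfg, "s01")
        assert tuple(c for _, _, c in rec.annotations) == CONDITION_ORDER
        starts = [a for a, _, _ in rec.annotations]
        assert starts == sorted(starts)

    def test_empty_subject_id_rejected(self):
        with pytest.raises(ConfigError):
            simulate_subject(SimulationConfig(), "")

    def test_planted_gamma_gain_on_cp2_only(self):
        """Gamma doubling planted on CP2 in scenario 3 moves CP2's gamma
        power by ~2x relative to resting and leaves Fz untouched
        (periodogram oracle)."""
        gains = {"scenario3": {"gamma": 2.0}}
        cfg = SimulationConfig(
            n_subjects=1, condition_duration=40.0, seed=8,
            band_gains=gains, informative_channels=("CP2",),
            artifact_spec=(), subject_variability=0.0,
        )
        rec = simulate_subject(cfg, "s01")
        ann = {c: (a, b) for a, b, c in rec.annotations}
        for ch, expected in [("CP2", 2.0), ("Fz", 1.0)]:
            x = rec.channel(ch)
            ratio = (
                welch_band_power(x[slice(*ann["scenario3"])], 250.0, 30, 100)
                / welch_band_power(x[slice(*ann["resting"])], 250.0, 30, 100)
            )
            assert ratio == pytest.approx(expected, rel=0.15)
        assert welch_band_power(
            rec.channel("CP2")[slice(*ann["scenario3"])], 250.0, 4, 8
        ) == pytest.approx(
            welch_band_power(rec.channel("CP2")[slice(*ann["resting"])], 250.0, 4, 8),
            rel=0.2,
        )

    def test_unit_gains_leave_spectra_condition_independent(self):
        flat = {c: {} for c in CONDITION_ORDER}
        cfg = SimulationConfig(
            n_subjects=1, condition_duration=40.0, seed=12, band_gains=flat,
            artifact_spec=(), subject_variability=0.0,
        )
        rec = simulate_subject(cfg, "s01")
        ann = {c: (a, b) for a, b, c in rec.annotations}
        x = rec.channel("CP4")
        ratios = [
            welch_band_power(x[slice(*ann[c])], 250.0, 4, 30)
            / welch_band_power(x[slice(*ann["resting"])], 250.0, 4, 30)
            for c in ("scenario1", "scenario3")
        ]
        assert np.allclose(ratios, 1.0, rtol=0.15)

    def test_spectral_contract_default_gains(self):
        """Empirical band-power ratio to resting matches the configured
        gain within 10% on 60 s blocks (Welch oracle)."""
        cfg = SimulationConfig(n_subjects=1, condition_duration=60.0, seed=2,
                               artifact_spec=(), subject_variability=0.0)
        rec = simulate_subject(cfg, "s01")
        ann = {c: (a, b) for a, b, c in rec.annotations}
        x = rec.channel("CP2")
        gains = cfg.band_gains["scenario3"]
        for band, (lo, hi) in [("beta", (13, 30)), ("gamma", (30, 100))]:
            ratio = (
                welch_band_power(x[slice(*ann["scenario3"])], 250.0, lo, hi)
                / welch_band_power(x[slice(*ann["resting"])], 250.0, lo, hi)
            )
            assert ratio == pytest.approx(gains[band], rel=0.10)


@pytest.fixture(scope="module")
def clean_rec():
    flat = {c: {} for c in CONDITION_ORDER}  # no planted effect
    cfg = SimulationConfig(n_subjects=1, condition_duration=20.0, seed=31,
                           band_gains=flat, artifact_spec=(),
                           subject_variability=0.0)
    return simulate_subject(cfg, "s01")


class TestArtifacts:

    def test_untargeted_channels_bit_identical(self, clean_rec):
        out = inject_artifacts(
            clean_rec, [ArtifactSpec("blink", ("Fp1", "Fp2"))], seed=1)
        assert np.array_equal(out.channel("CP2"), clean_rec.channel("CP2"))
        assert not np.array_equal(out.channel("Fp1"), clean_rec.channel("Fp1"))

    def test_blink_adds_low_frequency_power(self, clean_rec):
        out = inject_artifacts(
            clean_rec, [ArtifactSpec("blink", ("Fp1",), rate=0.4, amplitude=150)],
            seed=1)
        before = welch_band_power(clean_rec.channel("Fp1"), 250.0, 0.5, 4)
        after = welch_band_power(out.channel("Fp1"), 250.0, 0.5, 4)
        assert after > 2 * before

    def test_emg_burst_raises_high_band_power(self, clean_rec):
        out = inject_artifacts(
            clean_rec, [ArtifactSpec("emg", ("T7",), rate=0.3, amplitude=20)],
            seed=2)
        before = welch_band_power(clean_rec.channel("T7"), 250.0, 30, 100)
        after = welch_band_power(out.channel("T7"), 250.0, 30, 100)
        assert after > before

    def test_channel_noise_makes_target_the_max_variance_channel(self, clean_rec):
        out = inject_artifacts(
            clean_rec, [ArtifactSpec("channel_noise", ("Pz",), amplitude=60)],
            seed=3)
        variances = out.data.var(axis=1)
        assert out.channel_labels[int(np.argmax(variances))] == "Pz"

    def test_channel_noise_requires_single_target(self, clean_rec):
        with pytest.raises(ConfigError, match="exactly one"):
            inject_artifacts(
                clean_rec, [ArtifactSpec("channel_noise", ("Pz", "Cz"))], seed=0)

    def test_ecg_touches_all_targeted_channels(self, clean_rec):
        out = inject_artifacts(
            clean_rec, [ArtifactSpec("ecg", CHANNELS_59, rate=1.2, amplitude=5)],
            seed=4)
        changed = [not np.array_equal(out.data[i], clean_rec.data[i])
                   for i in range(out.n_channels)]
        assert all(changed)


class TestDataset:
    def test_adding_subjects_preserves_earlier_ones(self):
        base = dict(condition_duration=5.0, seed=9, artifact_spec=())
        recs3, _ = simulate_dataset(SimulationConfig(n_subjects=3, **base))
        recs5, _ = simulate_dataset(SimulationConfig(n_subjects=5, **base))
        for a, b in zip(recs3, recs5):
            assert a.subject_id == b.subject_id
            assert np.array_equal(a.data, b.data)

    def test_manifest_lists_full_cohort_and_conditions(self):
        # the emulated study design: 41 subjects, five conditions each
        cfg = SimulationConfig(n_subjects=41, condition_duration=2.0,
                               artifact_spec=(), seed=1)
        recs, manifest = simulate_dataset(cfg)
        assert len(manifest["subjects"]) == 41
        for entry in manifest["subjects"]:
            assert len(entry["annotations"]) == 5
            assert {a["condition"] for a in entry["annotations"]} == set(CONDITION_ORDER)

    def test_zero_variability_gives_identical_condition_profiles(self):
        cfg = SimulationConfig(n_subjects=2, condition_duration=40.0, seed=6,
                               artifact_spec=(), subject_variability=0.0)
        recs, _ = simulate_dataset(cfg)
        ratios = []
        for rec in recs:
            ann = {c: (a, b) for a, b, c in rec.annotations}
            x = rec.channel("CP2")
            ratios.append(
                welch_band_power(x[slice(*ann["scenario3"])], 250.0, 30, 100)
                / welch_band_power(x[slice(*ann["resting"])], 250.0, 30, 100)
            )
        assert ratios[0] == pytest.approx(ratios[1], rel=0.15)
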