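"""Per-subject mRMR channel ranking and cross-subject consensus.

The default generator plants the workload effect on six centro-parietal
channels (CP2, CP3, CP4, CP5, CP6, TP7 — channel numbers 36-41). Greedy
mRMR selection of the top 10 channels per subject, followed by the
>80%-of-subjects consensus rule, should recover exactly that set.
"""

from eegworkload import SimulationConfig, simulate_dataset, mrmr_select, consensus
from eegworkload.montage import CHANNEL_NUMBERS
from eegworkload.preprocess import PreprocessConfig, preprocess_recording
from eegworkload.ranking import apply_label_scheme
from eegworkload.spectral import band_power_table, compute_features

cfg = SimulationConfig(n_subjects=8, seed=11)
recs, _ = simulate_dataset(cfg)

rankings = []
for rec in recs:
    es = preprocess_recording(rec, PreprocessConfig())
    ft = compute_features(band_power_table(es), (16,))
    r = mrmr_select(ft.feature(16), apply_label_scheme(ft.conditions, "D"),
                    k=10, channel_labels=ft.channel_labels,
                    subject_id=rec.subject_id)
    rankings.append(r)
    print(f"{rec.subject_id} top-10: {r.labels}")

rep = consensus(rankings, 0.8)
print("\nchannels in >80% of subjects' top-10 lists:")
for ch in rep.selected:
    print(f"  {ch} (channel {CHANNEL_NUMBERS[ch]}): "
          f"{rep.frequencies[ch]:.0%} of subjects")
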