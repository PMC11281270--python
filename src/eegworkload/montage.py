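"""Fixed 59-channel 10-10 montage and condition vocabulary.

The channel ordering is chosen so that the centro-parietal electrodes the
consensus analysis singles out sit at 1-based positions 36-41:
CP2=36, CP3=37, CP4=38, CP5=39, CP6=40, TP7=41.
"""

from __future__ import annotations

CHANNELS_59: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP1", "CPz", "TP8",
    "CP2", "CP3", "CP4", "CP5", "CP6", "TP7",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

assert len(CHANNELS_59) == 59
assert CHANNELS_59[35:41] == ("CP2", "CP3", "CP4", "CP5", "CP6", "TP7")

#: label -> 1-based channel number (the numbering used in reports)
CHANNEL_NUMBERS: dict[str, int] = {lab: i + 1 for i, lab in enumerate(CHANNELS_59)}

#: frontal electrodes where ocular (blink) activity projects
FRONTAL = ("Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F5", "F3", "F1",
           "Fz", "F2", "F4", "F6", "F8")

#: temporal electrodes where scalp EMG projects
TEMPORAL = ("FT7", "FT8", "T7", "T8", "TP7", "TP8")

#: centro-parietal set that the default simulation plants the effect on
CONSENSUS_SET = ("CP2", "CP3", "CP4", "CP5", "CP6", "TP7")

RESTING = "resting"
SCENARIOS = ("scenario1", "scenario2", "scenario3", "scenario4")
CONDITIONS = (RESTING,) + SCENARIOS

#: presentation order of the recording blocks within a session
CONDITION_ORDER = ("resting", "scenario4", "scenario3", "scenario1", "scenario2")

#: rank of each condition on the induced-workload axis
#: (baseline traffic < high nominal < high off-nominal < overload)
WORKLOAD_RANK = {
    "resting": 0,
    "scenario1": 1,
    "scenario2": 2,
    "scenario4": 3,
    "scenario3": 4,
}
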