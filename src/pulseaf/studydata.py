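"""Published clinical validation counts used as replay inputs.

The clinical validation compared the algorithm's output with
cardiologist-interpreted 12-lead ECG on 171 participants (79 AFib, 92
non-AFib), measured with a main cuff ("FM31") and a sub cuff ("FL31"), and
reported subgroup analyses by age and upper-arm circumference. The raw
interval data are not public; the published 2x2 counts below are the inputs
from which every accuracy statistic and subgroup p-value can be recomputed.
"""

from __future__ import annotations

from .evaluation import ConfusionTable

__all__ = [
    "DEVICE_COUNTS",
    "SUBGROUP_TABLES",
    "AFIB_IRREGULARITY_INDEX",
    "MEAN_INTERVAL_80BPM_S",
    "PULSES_PER_MEASUREMENT",
]

#: algorithm output vs ECG truth per cuff: 79 AFib and 92 non-AFib datasets
DEVICE_COUNTS: dict[str, ConfusionTable] = {
    "FM31": ConfusionTable(tp=77, fn=2, tn=91, fp=1),
    "FL31": ConfusionTable(tp=74, fn=5, tn=92, fp=0),
}

#: subgroup 2x2 tables (rows: group A, group B; cols: correct, incorrect)
#: on the main-cuff dataset, by age (< 65 vs >= 65 years) and upper-arm
#: circumference (< 27 vs >= 27 cm)
SUBGROUP_TABLES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "age_sensitivity": ((15, 0), (62, 2)),
    "age_specificity": ((34, 0), (57, 1)),
    "arm_sensitivity": ((30, 1), (47, 1)),
    "arm_specificity": ((42, 0), (49, 1)),
}

#: literature coefficient of variation of pulse intervals in AFib
AFIB_IRREGULARITY_INDEX = 0.13

#: mean pulse interval at 80 beats per minute
MEAN_INTERVAL_80BPM_S = 0.75

#: mean pulses captured per single cuff measurement, by cuff
PULSES_PER_MEASUREMENT: dict[str, float] = {"FM31": 21.6, "FL31": 21.9}
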