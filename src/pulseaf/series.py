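"""Core domain types for pulse-interval screening.

A blood-pressure monitor with rhythm screening sees, per cuff inflation, a
short ordered sequence of pulse-to-pulse intervals (PPIs, in seconds).
:class:`PulseIntervalSeries` is that sequence plus an optional ground-truth
rhythm label used for training and evaluation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["RhythmLabel", "PulseIntervalSeries"]


class RhythmLabel(str, enum.Enum):
    """Ground-truth rhythm of one measurement.

    AFIB is the positive class for classification; SINUS and PC (premature
    contractions) are both non-AFib.
    """

    AFIB = "AFIB"
    SINUS = "SINUS"
    PC = "PC"

    @property
    def is_afib(self) -> bool:
        return self is RhythmLabel.AFIB


@dataclass
class PulseIntervalSeries:
    """Ordered pulse-to-pulse intervals (seconds) for one measurement.

    Parameters
    ----------
    intervals : array-like of float
        Strictly positive interval durations in seconds, in beat order.
    label : RhythmLabel or None
        Ground-truth rhythm, if known.
    measurement_id : str
        Identifier for the measurement.
    meta : dict
        Free-form provenance (generator name, seed, parameters, QC log).
    """

    intervals: np.ndarray
    label: RhythmLabel | None = None
    measurement_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size < 1:
            raise ValueError("intervals must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("intervals must be finite")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be strictly positive")
        if isinstance(self.label, str) and not isinstance(self.label, RhythmLabel):
            self.label = RhythmLabel(self.label)

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def duration(self) -> float:
        """Total measurement span covered by the intervals, in seconds."""
        return float(np.sum(self.intervals))

    @property
    def mean_interval(self) -> float:
        return float(np.mean(self.intervals))

    def replace(self, **changes: Any) -> "PulseIntervalSeries":
        """Return a copy with selected fields replaced."""
        out = {
            "intervals": self.intervals.copy(),
            "label": self.label,
            "measurement_id": self.measurement_id,
            "meta": dict(self.meta),
        }
        out.update(changes)
        return PulseIntervalSeries(**out)
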