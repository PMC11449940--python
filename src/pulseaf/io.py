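"""Reading and writing interval series, feature tables and waveforms.

The lingua franca between pipeline stages is a long-format CSV with columns
``measurement_id, beat_index, interval_s, label``; a JSON mirror (one object
per measurement with an ``intervals`` array) carries nested metadata.
Waveforms use a two-column CSV (``time_s, amplitude``) with the sampling
rate in a ``# sampling_rate_hz=...`` header comment.

An optional adapter ingests plain-text RR-interval lists (one value per
line, seconds or milliseconds) such as those exportable from public ECG
rhythm databases; it is never required by the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .oscillometry import PressurePulseWave
from .series import PulseIntervalSeries, RhythmLabel

__all__ = [
    "write_intervals_csv", "read_intervals_csv",
    "write_intervals_json", "read_intervals_json",
    "write_ppw_csv", "read_ppw_csv",
    "read_rr_list",
]


def _label_str(s: PulseIntervalSeries) -> str:
    return s.label.value if s.label is not None else ""


def _mid(s: PulseIntervalSeries, index: int) -> str:
    return s.measurement_id or f"m{index:05d}"


def write_intervals_csv(dataset: Sequence[PulseIntervalSeries], path: str | Path) -> None:
    rows = []
    for k, s in enumerate(dataset):
        for i, iv in enumerate(s.intervals):
            rows.append((_mid(s, k), i, float(iv), _label_str(s)))
    df = pd.DataFrame(rows, columns=["measurement_id", "beat_index", "interval_s", "label"])
    df.to_csv(path, index=False)


def read_intervals_csv(path: str | Path) -> list[PulseIntervalSeries]:
    df = pd.read_csv(path, dtype={"measurement_id": str, "label": str}, keep_default_na=False)
    required = {"measurement_id", "beat_index", "interval_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"interval CSV must have columns {sorted(required)}")
    out = []
    for mid, g in df.groupby("measurement_id", sort=False):
        g = g.sort_values("beat_index")
        label = g["label"].iloc[0]
        out.append(PulseIntervalSeries(
            g["interval_s"].to_numpy(),
            label=RhythmLabel(label) if label else None,
            measurement_id=str(mid),
        ))
    return out


def write_intervals_json(dataset: Sequence[PulseIntervalSeries], path: str | Path) -> None:
    objs = [
        {
            "measurement_id": _mid(s, k),
            "label": _label_str(s) or None,
            "intervals": [float(v) for v in s.intervals],
            "meta": _jsonable(s.meta),
        }
        for k, s in enumerate(dataset)
    ]
    Path(path).write_text(json.dumps(objs, indent=1))


def read_intervals_json(path: str | Path) -> list[PulseIntervalSeries]:
    objs = json.loads(Path(path).read_text())
    return [
        PulseIntervalSeries(
            np.asarray(o["intervals"], dtype=float),
            label=RhythmLabel(o["label"]) if o.get("label") else None,
            measurement_id=o.get("measurement_id", ""),
            meta=o.get("meta", {}),
        )
        for o in objs
    ]


def write_ppw_csv(ppw: PressurePulseWave, path: str | Path) -> None:
    with open(path, "w") as f:
        f.write(f"# sampling_rate_hz={ppw.sampling_rate}\n")
        f.write("time_s,amplitude\n")
        for t, a in zip(ppw.times, ppw.samples):
            f.write(f"{t:.6f},{a:.8g}\n")


def read_ppw_csv(path: str | Path) -> PressurePulseWave:
    with open(path) as f:
        header = f.readline()
        if not header.startswith("# sampling_rate_hz="):
            raise ValueError("waveform CSV must start with a '# sampling_rate_hz=' comment")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(f)
    return PressurePulseWave(df["amplitude"].to_numpy(), fs)


def read_rr_list(path: str | Path, unit: str = "auto") -> PulseIntervalSeries:
    """Read a plain-text RR-interval list (one value per line).

    ``unit`` is "s", "ms", or "auto" (values with a median above 10 are
    taken as milliseconds).
    """
    values = np.array(
        [float(line) for line in Path(path).read_text().split() if line.strip()]
    )
    if values.size == 0:
        raise ValueError(f"no intervals found in {path}")
    if unit == "auto":
        unit = "ms" if float(np.median(values)) > 10 else "s"
    if unit == "ms":
        values = values / 1000.0
    elif unit != "s":
        raise ValueError(f"unknown unit {unit!r}")
    return PulseIntervalSeries(values, measurement_id=Path(path).stem,
                               meta={"source": "rr_list", "unit": unit})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    return obj
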