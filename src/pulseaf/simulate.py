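"""Seeded generators for labeled pulse-interval series.

The classifier operates on a single blood-pressure measurement's worth of
pulse-to-pulse intervals (about 22 beats). These generators emulate the three
rhythm regimes the screen has to tell apart, plus the missed-pulse artifact an
oscillometric front end can introduce:

* **Sinus rhythm** — near-constant intervals with small Gaussian jitter.
* **Atrial fibrillation** — "irregularly irregular": i.i.d. intervals with a
  coefficient of variation around 0.13 (the irregularity index reported for
  AFib in the screening literature), drawn from a Gamma distribution by
  default (positive support, mild right skew, as real RR data show).
* **Premature contractions** — an early beat shortens its interval to a
  coupling fraction of the base interval and the following compensatory pause
  stretches the next to (2 - coupling) times the base, in bigeminy, trigeminy
  or random patterns.
* **Missed beats** — the detector skips a pulse, merging two adjacent
  intervals into their sum.

Every generator takes an explicit seed; there is no hidden global state.
"""

from __future__ import annotations

from typing import Any, Iterable, Sequence

import numpy as np

from .series import PulseIntervalSeries, RhythmLabel

__all__ = [
    "simulate_sinus",
    "simulate_afib",
    "simulate_pc",
    "inject_missed_beats",
    "generate_dataset",
    "ClassSpec",
]

_MAX_REDRAWS = 100


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws truncated to (0, inf) by redrawing."""
    x = rng.normal(mean, sd, size=n)
    for _ in range(_MAX_REDRAWS):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal sampling failed to converge; sd too large relative to mean")


def simulate_sinus(
    n: int,
    mean_interval: float = 0.75,
    jitter_sd: float = 0.02,
    seed: int | None = None,
) -> PulseIntervalSeries:
    """Simulate a normal-sinus-rhythm measurement.

    Intervals are ``mean_interval`` plus zero-mean Gaussian jitter, truncated
    positive. The default jitter of 20 ms reflects resting heart-rate
    variability; the resulting irregularity index (SD/mean ~ 0.027) sits far
    below the AFib regime (~0.13).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean_interval <= 0:
        raise ValueError(f"mean_interval must be positive, got {mean_interval}")
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be >= 0, got {jitter_sd}")
    rng = np.random.default_rng(seed)
    if jitter_sd == 0:
        intervals = np.full(n, mean_interval)
    else:
        intervals = _positive_normal(rng, mean_interval, jitter_sd, n)
    return PulseIntervalSeries(
        intervals,
        label=RhythmLabel.SINUS,
        meta={"generator": "sinus", "seed": seed,
              "mean_interval": mean_interval, "jitter_sd": jitter_sd},
    )


def simulate_afib(
    n: int,
    mean_interval: float = 0.75,
    cv: float = 0.13,
    seed: int | None = None,
    distribution: str = "gamma",
) -> PulseIntervalSeries:
    """Simulate an atrial-fibrillation measurement.

    Intervals are i.i.d. with mean ``mean_interval`` and standard deviation
    ``cv * mean_interval`` — at the defaults (0.75 s, cv 0.13) an SD of
    97.5 ms. Independence between consecutive intervals captures the
    "irregularly irregular" ventricular response (lag-1 autocorrelation ~ 0).

    Parameters
    ----------
    distribution : {"gamma", "truncnorm"}
        Sampling family. Gamma (default) has positive support and the mild
        right skew typical of AFib RR data; "truncnorm" is a positive-
        truncated Gaussian alternative.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean_interval <= 0:
        raise ValueError(f"mean_interval must be positive, got {mean_interval}")
    if not 0 < cv < 1:
        raise ValueError(f"cv must be in (0, 1), got {cv}")
    rng = np.random.default_rng(seed)
    if distribution == "gamma":
        shape = 1.0 / cv**2
        scale = mean_interval * cv**2
        intervals = rng.gamma(shape, scale, size=n)
    elif distribution == "truncnorm":
        intervals = _positive_normal(rng, mean_interval, cv * mean_interval, n)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return PulseIntervalSeries(
        intervals,
        label=RhythmLabel.AFIB,
        meta={"generator": "afib", "seed": seed, "mean_interval": mean_interval,
              "cv": cv, "distribution": distribution},
    )


_PC_PATTERNS = ("bigeminy", "trigeminy", "random")


def simulate_pc(
    n: int,
    mean_interval: float = 0.75,
    pattern: str = "bigeminy",
    coupling_fraction: float = 0.7,
    pc_probability: float = 0.2,
    seed: int | None = None,
    jitter_sd: float = 0.02,
) -> PulseIntervalSeries:
    """Simulate a measurement with premature contractions.

    A premature beat couples early at ``coupling_fraction * mean_interval``
    and is followed by a compensatory pause of
    ``(2 - coupling_fraction) * mean_interval``, so each premature/pause pair
    conserves two base intervals. ``bigeminy`` makes every second beat
    premature, ``trigeminy`` every third; ``random`` flags each beat
    independently with probability ``pc_probability`` (a flagged beat shortens
    its own interval; the next unflagged interval carries the pause).
    Gaussian jitter is added to every interval before the premature
    modification pattern is applied.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mean_interval <= 0:
        raise ValueError(f"mean_interval must be positive, got {mean_interval}")
    if not 0 < coupling_fraction < 1:
        raise ValueError(f"coupling_fraction must be in (0, 1), got {coupling_fraction}")
    if not 0 <= pc_probability <= 1:
        raise ValueError(f"pc_probability must be in [0, 1], got {pc_probability}")
    if pattern not in _PC_PATTERNS:
        raise ValueError(f"pattern must be one of {_PC_PATTERNS}, got {pattern!r}")
    rng = np.random.default_rng(seed)

    idx = np.arange(n)
    if pattern == "bigeminy":
        premature = idx % 2 == 0
    elif pattern == "trigeminy":
        premature = idx % 3 == 0
    else:
        premature = rng.random(n) < pc_probability

    factors = np.ones(n)
    factors[premature] = coupling_fraction
    after_pause = np.zeros(n, dtype=bool)
    after_pause[1:] = premature[:-1]
    # a premature beat immediately after another premature keeps its coupling
    pause = after_pause & ~premature
    factors[pause] = 2.0 - coupling_fraction

    if jitter_sd > 0:
        base = _positive_normal(rng, mean_interval, jitter_sd, n)
    else:
        base = np.full(n, mean_interval)
    intervals = base * factors
    return PulseIntervalSeries(
        intervals,
        label=RhythmLabel.PC,
        meta={"generator": "pc", "seed": seed, "pattern": pattern,
              "mean_interval": mean_interval, "coupling_fraction": coupling_fraction,
              "pc_probability": pc_probability, "jitter_sd": jitter_sd},
    )


def inject_missed_beats(
    series: PulseIntervalSeries, k: int, seed: int | None = None
) -> PulseIntervalSeries:
    """Merge ``k`` randomly chosen adjacent interval pairs into their sums.

    Emulates the front end skipping pulse detections: each merge replaces two
    neighboring intervals by one interval equal to their sum, so the total
    measurement duration is conserved exactly and the series shortens by one
    interval per merge. The rhythm label is preserved.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k >= len(series):
        raise ValueError(f"k={k} too large for a series of {len(series)} intervals")
    rng = np.random.default_rng(seed)
    intervals = list(series.intervals)
    for _ in range(k):
        j = int(rng.integers(0, len(intervals) - 1))
        intervals[j: j + 2] = [intervals[j] + intervals[j + 1]]
    meta = dict(series.meta)
    meta["missed_beats"] = meta.get("missed_beats", 0) + k
    return series.replace(intervals=np.asarray(intervals), meta=meta)


ClassSpec = tuple  # (RhythmLabel or generator name, parameter dict, count)

_GENERATORS = {
    RhythmLabel.SINUS: simulate_sinus,
    RhythmLabel.AFIB: simulate_afib,
    RhythmLabel.PC: simulate_pc,
}


def generate_dataset(
    class_specs: Sequence[tuple[RhythmLabel | str, dict[str, Any], int]],
    n_intervals_mean: float = 22.0,
    n_intervals_sd: float = 3.0,
    min_intervals: int = 10,
    seed: int | None = None,
) -> list[PulseIntervalSeries]:
    """Generate a labeled collection of measurements.

    Per-measurement interval counts are drawn Normal(``n_intervals_mean``,
    ``n_intervals_sd``), rounded, and truncated at ``min_intervals`` —
    defaults matching the roughly 22 +- 3 pulses captured by a single cuff
    inflation. ``class_specs`` is a list of ``(label, params, count)``
    triples; ``params`` are forwarded to the matching generator (sans ``n``
    and ``seed``). Deterministic for a fixed seed.
    """
    if not class_specs:
        raise ValueError("class_specs must not be empty")
    rng = np.random.default_rng(seed)
    out: list[PulseIntervalSeries] = []
    i = 0
    for label, params, count in class_specs:
        label = RhythmLabel(label)
        if count < 1:
            raise ValueError(f"count must be >= 1, got {count} for {label}")
        gen = _GENERATORS[label]
        for _ in range(count):
            n = max(min_intervals, int(round(rng.normal(n_intervals_mean, n_intervals_sd))))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            s = gen(n=n, seed=sub_seed, **params)
            s.measurement_id = f"m{i:05d}"
            out.append(s)
            i += 1
    return out
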