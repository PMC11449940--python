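"""End-to-end orchestration: simulate -> featurize -> train -> classify -> evaluate.

One master seed fixes the whole chain. The default study conditions are
balanced synthetic cohorts of single-measurement interval series (~22 beats
each): half atrial fibrillation (coefficient of variation 0.13), half
non-AFib split between sinus rhythm (20 ms jitter) and premature-contraction
patterns (bigeminy and random ectopy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boosting import AdaBoostM1Classifier, train_adaboost
from .config import PipelineConfig
from .features import FEATURE_NAMES, FeatureConfig, compute_features, feature_table
from .series import PulseIntervalSeries, RhythmLabel
from .simulate import generate_dataset, inject_missed_beats, simulate_afib

__all__ = [
    "default_class_specs",
    "make_dataset",
    "train_pipeline",
    "holdout_performance",
    "HoldoutResult",
    "missed_beat_flip_rate",
    "classify_series",
]


def default_class_specs(config: PipelineConfig | None = None):
    """Class composition triples for :func:`pulseaf.simulate.generate_dataset`."""
    g = (config or PipelineConfig()).generator
    specs = [
        (RhythmLabel.AFIB,
         {"mean_interval": g.mean_interval, "cv": g.afib_cv}, g.n_afib),
        (RhythmLabel.SINUS,
         {"mean_interval": g.mean_interval, "jitter_sd": g.sinus_jitter_sd}, g.n_sinus),
        (RhythmLabel.PC,
         {"mean_interval": g.mean_interval, "pattern": "bigeminy",
          "coupling_fraction": g.pc_coupling_fraction}, g.n_pc_bigeminy),
        (RhythmLabel.PC,
         {"mean_interval": g.mean_interval, "pattern": "random",
          "coupling_fraction": g.pc_coupling_fraction,
          "pc_probability": g.pc_probability}, g.n_pc_random),
    ]
    return [s for s in specs if s[2] > 0]


def make_dataset(config: PipelineConfig | None = None, seed: int | None = None):
    cfg = config or PipelineConfig()
    g = cfg.generator
    return generate_dataset(
        default_class_specs(cfg),
        n_intervals_mean=g.n_intervals_mean,
        n_intervals_sd=g.n_intervals_sd,
        min_intervals=g.min_intervals,
        seed=cfg.seed if seed is None else seed,
    )


def _feature_config(cfg: PipelineConfig) -> FeatureConfig:
    f = cfg.features
    return FeatureConfig(gap_threshold=f.gap_threshold,
                         relative_gap=f.relative_gap,
                         min_intervals=f.min_intervals)


def train_pipeline(
    config: PipelineConfig | None = None, seed: int | None = None
) -> AdaBoostM1Classifier:
    """Generate a training cohort and fit the boosted ensemble."""
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    dataset = make_dataset(cfg, seed=seed)
    table = feature_table(dataset, config=_feature_config(cfg))
    X = table[list(FEATURE_NAMES)]
    y = table["label"].to_numpy()
    return train_adaboost(X, y, rounds=cfg.classifier.rounds,
                          max_depth=cfg.classifier.max_depth, seed=seed)


@dataclass
class HoldoutResult:
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int


def holdout_performance(
    model: AdaBoostM1Classifier,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> HoldoutResult:
    """Evaluate a trained model on a freshly generated held-out cohort."""
    cfg = config or PipelineConfig()
    seed = (cfg.seed + 1) if seed is None else seed
    dataset = make_dataset(cfg, seed=seed)
    table = feature_table(dataset, config=_feature_config(cfg))
    pred = model.predict(table[list(FEATURE_NAMES)])
    truth = np.where(table["label"].to_numpy() == "AFIB", "AFIB", "NON_AFIB")
    pos = truth == "AFIB"
    sens = float(np.mean(pred[pos] == "AFIB"))
    spec = float(np.mean(pred[~pos] == "NON_AFIB"))
    return HoldoutResult(sens, spec, int(pos.sum()), int((~pos).sum()))


def classify_series(
    model: AdaBoostM1Classifier,
    series: PulseIntervalSeries,
    config: PipelineConfig | None = None,
) -> tuple[str, float]:
    """Classify one measurement; returns (label, margin)."""
    cfg = config or PipelineConfig()
    fv = compute_features(series, config=_feature_config(cfg))
    from .boosting import predict as _predict

    return _predict(model, fv)


def missed_beat_flip_rate(
    model: AdaBoostM1Classifier,
    n_draws: int = 1000,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> float:
    """Fraction of AFib measurements whose label flips after one missed beat.

    Each draw simulates an AFib measurement, classifies it, injects one
    missed-beat artifact (two adjacent intervals merged), reclassifies, and
    counts a flip when the two labels differ.
    """
    cfg = config or PipelineConfig()
    g = cfg.generator
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fcfg = _feature_config(cfg)
    flips = 0
    for _ in range(n_draws):
        n = max(g.min_intervals + 1,
                int(round(rng.normal(g.n_intervals_mean, g.n_intervals_sd))))
        s = simulate_afib(n, mean_interval=g.mean_interval, cv=g.afib_cv,
                          seed=int(rng.integers(0, 2**31 - 1)))
        s2 = inject_missed_beats(s, 1, seed=int(rng.integers(0, 2**31 - 1)))
        l1, _ = classify_series(model, s, cfg)
        l2, _ = classify_series(model, s2, cfg)
        flips += l1 != l2
    return flips / n_draws
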