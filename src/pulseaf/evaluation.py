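"""Diagnostic-accuracy statistics for screening validation.

Everything derives from 2x2 counts: sensitivity = TP/(TP+FN) over
AFib-by-ECG measurements, specificity = TN/(TN+FP) over non-AFib
measurements, each with a Wilson score 95% confidence interval (clipped to
[0, 1]; Wilson has good coverage at small n and near the boundary, which
matters for cells at 100%). Paired devices are compared with McNemar's test
on discordant counts (exact binomial by default, or the continuity-corrected
chi-square variant), and subgroups with the Pearson chi-square test without
continuity correction (the convention used in the validation analyses
reproduced here; a small-sample caveat applies when expected counts are
low).

The irregularity index (SD of pulse intervals divided by their mean, i.e. a
coefficient of variation) characterizes rhythms: about 0.13 in AFib — at a
mean interval of 0.75 s (80 bpm) an interval SD of 97.5 ms — versus well
under 0.05 in sinus rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .series import PulseIntervalSeries

__all__ = [
    "ConfusionTable",
    "ProportionEstimate",
    "SubgroupComparison",
    "sensitivity",
    "specificity",
    "wilson_ci",
    "mcnemar_test",
    "pearson_chi2_2x2",
    "irregularity_index",
    "measurement_period",
    "evaluate_study",
    "StudyReport",
    "format_percent",
]


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FN/TN/FP counts with AFib as the positive class."""

    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its two-sided confidence interval."""

    successes: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.point + 1e-12 or not self.point <= self.ci_high + 1e-12:
            raise ValueError("interval must bracket the point estimate")

    def render(self) -> str:
        """Percent string at 1 decimal, e.g. '97.5 (91.2-99.3)'."""
        return (f"{format_percent(self.point)} "
                f"({format_percent(self.ci_low)}–{format_percent(self.ci_high)})")


@dataclass(frozen=True)
class SubgroupComparison:
    """A 2x2 group-by-outcome comparison with its chi-square test."""

    table: tuple[tuple[int, int], tuple[int, int]]
    chi_square: float
    p_value: float


def format_percent(p: float) -> str:
    """Percent rounded half-up to 1 decimal; whole hundreds print as '100'."""
    q = Decimal(repr(p * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    if q == 100:
        return "100"
    return str(q)


def sensitivity(ct: ConfusionTable) -> float:
    """Fraction of truly AFib measurements flagged AFib."""
    if ct.n_positive < 1:
        raise ValueError("sensitivity undefined: no positive-class measurements")
    return ct.tp / ct.n_positive


def specificity(ct: ConfusionTable) -> float:
    """Fraction of truly non-AFib measurements flagged non-AFib."""
    if ct.n_negative < 1:
        raise ValueError("specificity undefined: no negative-class measurements")
    return ct.tn / ct.n_negative


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> ProportionEstimate:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    low, high = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    point = successes / n
    # clip to [0, 1] and absorb float noise so low <= point <= high exactly
    low = min(float(np.clip(low, 0, 1)), point)
    high = max(float(np.clip(high, 0, 1)), point)
    return ProportionEstimate(successes=successes, n=n, point=point,
                              ci_low=low, ci_high=high, confidence=confidence)


def mcnemar_test(
    discordant_b: int, discordant_c: int, method: str = "exact_binomial"
) -> float:
    """McNemar's test p-value from paired discordant counts.

    ``exact_binomial`` doubles the smaller binomial(n=b+c, p=1/2) tail,
    capped at 1; ``chi2_cc`` is the continuity-corrected chi-square
    (|b-c|-1)^2/(b+c) on 1 df. Zero discordance gives p = 1.
    """
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = discordant_b + discordant_c
    if n == 0:
        return 1.0
    if method == "exact_binomial":
        k = min(discordant_b, discordant_c)
        return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))
    if method == "chi2_cc":
        statistic = (abs(discordant_b - discordant_c) - 1) ** 2 / n
        return float(stats.chi2.sf(statistic, df=1))
    raise ValueError(f"unknown method {method!r}")


def pearson_chi2_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns (statistic, p-value on 1 df). Degenerate margins (an all-zero
    row or column) are an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) < 1) or np.any(t.sum(axis=1) < 1):
        raise ValueError("degenerate margin: every row and column needs a count")
    statistic, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(statistic), float(p)


def irregularity_index(series: PulseIntervalSeries) -> float:
    """SD of intervals divided by their mean (population convention)."""
    if len(series) < 2:
        raise ValueError("need >= 2 intervals for the irregularity index")
    x = series.intervals
    return float(np.std(x) / np.mean(x))


def measurement_period(n_pulses: float, mean_interval: float = 0.75) -> float:
    """Measurement span implied by a pulse count at a given mean interval."""
    if n_pulses <= 0 or mean_interval <= 0:
        raise ValueError("n_pulses and mean_interval must be positive")
    return n_pulses * mean_interval


@dataclass
class StudyReport:
    """Per-stratum accuracy with CIs, plus between-stratum comparisons."""

    confusion: dict[str, ConfusionTable]
    sensitivity: dict[str, ProportionEstimate]
    specificity: dict[str, ProportionEstimate]
    comparisons: dict[str, SubgroupComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {"strata": {}, "comparisons": {}}
        for s, ct in self.confusion.items():
            out["strata"][s] = {
                "tp": ct.tp, "fn": ct.fn, "tn": ct.tn, "fp": ct.fp,
                "sensitivity": self.sensitivity[s].render() if s in self.sensitivity else None,
                "specificity": self.specificity[s].render() if s in self.specificity else None,
            }
        for name, c in self.comparisons.items():
            out["comparisons"][name] = {
                "chi_square": c.chi_square, "p_value": c.p_value,
            }
        return out

    def render(self) -> str:
        lines = [f"{'stratum':<16}{'sens % (95% CI)':<24}{'spec % (95% CI)':<24}"]
        for s in self.confusion:
            sens = self.sensitivity[s].render() if s in self.sensitivity else "-"
            spec = self.specificity[s].render() if s in self.specificity else "-"
            lines.append(f"{s:<16}{sens:<24}{spec:<24}")
        for name, c in self.comparisons.items():
            lines.append(f"{name}: chi2 = {c.chi_square:.3f}, P = {c.p_value:.2f}")
        return "\n".join(lines)


def _confusion_from_vectors(pred: np.ndarray, truth: np.ndarray) -> ConfusionTable:
    pos = truth == "AFIB"
    flagged = pred == "AFIB"
    return ConfusionTable(
        tp=int(np.sum(pos & flagged)), fn=int(np.sum(pos & ~flagged)),
        tn=int(np.sum(~pos & ~flagged)), fp=int(np.sum(~pos & flagged)),
    )


def evaluate_study(
    predictions: Sequence[str],
    truth: Sequence[str],
    strata: Sequence[str] | None = None,
    confidence: float = 0.95,
) -> StudyReport:
    """Build the full accuracy report from aligned prediction/truth vectors.

    ``truth`` labels other than "AFIB" count as non-AFib. With ``strata``
    given (one group name per measurement), per-stratum tables are computed
    and, when exactly two strata are present, their sensitivities and
    specificities are compared by Pearson chi-square on correct/incorrect
    counts.
    """
    pred = np.asarray([str(p) for p in predictions])
    tru = np.asarray(["AFIB" if str(t) == "AFIB" else "NON_AFIB" for t in truth])
    if pred.shape != tru.shape:
        raise ValueError("predictions and truth must have equal length")
    if strata is not None and len(strata) != len(pred):
        raise ValueError("strata must align with predictions")
    groups: dict[str, np.ndarray] = {"all": np.ones(pred.size, dtype=bool)}
    if strata is not None:
        sv = np.asarray([str(s) for s in strata])
        for g in dict.fromkeys(sv):  # preserve first-appearance order
            groups[g] = sv == g

    confusion, sens, spec = {}, {}, {}
    for g, mask in groups.items():
        ct = _confusion_from_vectors(pred[mask], tru[mask])
        confusion[g] = ct
        if ct.n_positive >= 1:
            sens[g] = wilson_ci(ct.tp, ct.n_positive, confidence)
        if ct.n_negative >= 1:
            spec[g] = wilson_ci(ct.tn, ct.n_negative, confidence)

    comparisons: dict[str, SubgroupComparison] = {}
    strata_names = [g for g in groups if g != "all"]
    if len(strata_names) == 2:
        a, b = strata_names
        for kind in ("sensitivity", "specificity"):
            ca, cb = confusion[a], confusion[b]
            if kind == "sensitivity":
                t = ((ca.tp, ca.fn), (cb.tp, cb.fn))
            else:
                t = ((ca.tn, ca.fp), (cb.tn, cb.fp))
            if min(sum(t[0]), sum(t[1])) >= 1 and (t[0][0] + t[1][0]) >= 1:
                try:
                    statistic, p = pearson_chi2_2x2(t)
                except ValueError:
                    continue
                comparisons[f"{kind}:{a}_vs_{b}"] = SubgroupComparison(t, statistic, p)
    return StudyReport(confusion, sens, spec, comparisons)
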