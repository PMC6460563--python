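"""Skew classes, cohort distribution, and mother-daughter independence.

An individual's skew class is a deterministic function of her median
paternal ratio ``Mx``: maternal-skewed when ``Mx <= 0.35``, paternal-skewed
when ``Mx >= 0.65``, balanced in between; extreme when ``Mx >= 0.85`` or
``<= 0.15``; complete when ``Mx`` is exactly 0 or 1 (the same X inactive in
every sampled cell). All thresholds are configurable; the boundaries are
closed (<=, >=) as written.

Mothers, for whom parent of origin is unknown, are classified by the
mirrored criterion on the median measure of balance (balance <= 0.35 means
skewed). If X-inactivation is random, mother and daughter skews are
independent; this is checked with a Pearson correlation on paired median
measures of balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SkewThresholds",
    "SkewClass",
    "CorrelationResult",
    "classify_skew",
    "classify_cohort",
    "classify_balance",
    "population_distribution",
    "mother_daughter_correlation",
]

CLASS_LABELS = ("maternal_skewed", "balanced", "paternal_skewed")


@dataclass(frozen=True)
class SkewThresholds:
    maternal: float = 0.35
    paternal: float = 0.65
    extreme_low: float = 0.15
    extreme_high: float = 0.85
    complete_tolerance: float = 0.0

    def __post_init__(self):
        if not (self.extreme_low <= self.maternal < self.paternal <= self.extreme_high):
            raise ValueError("thresholds must be ordered: extreme_low <= maternal"
                             " < paternal <= extreme_high")


@dataclass(frozen=True)
class SkewClass:
    label: str                  # one of CLASS_LABELS, or "unclassified"
    extreme: bool = False
    complete: bool = False
    reason: str | None = None   # set when unclassified

    @property
    def skewed(self) -> bool:
        return self.label in ("maternal_skewed", "paternal_skewed")


def classify_skew(mx: float, thresholds: SkewThresholds | None = None) -> SkewClass:
    """Map a median paternal ratio to its skew class.

    NaN (uninformative sample) yields ``unclassified`` with a reason.
    Complete skew requires ``Mx`` within ``complete_tolerance`` of 0 or 1
    (exact by default); complete implies extreme implies skewed.
    """
    t = thresholds or SkewThresholds()
    if mx is None or (isinstance(mx, float) and np.isnan(mx)):
        return SkewClass("unclassified", reason="no informative SNVs")
    if not 0.0 <= mx <= 1.0:
        raise ValueError(f"Mx must lie in [0, 1], got {mx}")
    if mx <= t.maternal:
        label = "maternal_skewed"
    elif mx >= t.paternal:
        label = "paternal_skewed"
    else:
        label = "balanced"
    extreme = mx <= t.extreme_low or mx >= t.extreme_high
    complete = min(mx, 1.0 - mx) <= t.complete_tolerance
    return SkewClass(label, extreme=extreme, complete=complete)


def classify_cohort(summaries: pd.DataFrame,
                    thresholds: SkewThresholds | None = None) -> pd.DataFrame:
    """Append skew-class columns to an individual-summary table (uses Mx)."""
    classes = [classify_skew(mx, thresholds) for mx in summaries["Mx"]]
    out = summaries.copy()
    out["skew_class"] = [c.label for c in classes]
    out["skewed"] = [c.skewed for c in classes]
    out["extreme"] = [c.extreme for c in classes]
    out["complete"] = [c.complete for c in classes]
    return out


def classify_balance(balance: float, thresholds: SkewThresholds | None = None) -> str:
    """Classify an individual by median measure of balance (mothers).

    The balance statistic folds direction away, so the criterion mirrors the
    maternal/paternal threshold: balance <= the skew threshold means skewed.
    """
    t = thresholds or SkewThresholds()
    if balance is None or (isinstance(balance, float) and np.isnan(balance)):
        return "unclassified"
    return "skewed" if balance <= t.maternal else "balanced"


_HIST_BINS = np.round(np.arange(0.0, 1.0001, 0.05), 10)


def population_distribution(classified: pd.DataFrame) -> dict:
    """Cohort-level skew summary: class counts, fractions, and histograms.

    Every class is reported (zero counts included); fractions are over
    classified individuals and sum to 1. Histograms of ``Mx`` and the mean
    allelic ratio use fixed 0.05-wide bins for stable export.
    """
    labels = list(CLASS_LABELS) + ["unclassified"]
    counts = {lab: int((classified["skew_class"] == lab).sum()) for lab in labels}
    n_classified = sum(counts[lab] for lab in CLASS_LABELS)
    fractions = {lab: (counts[lab] / n_classified if n_classified else 0.0)
                 for lab in CLASS_LABELS}

    def hist(col: str) -> dict:
        vals = classified[col].dropna().to_numpy(dtype=float)
        h, edges = np.histogram(vals, bins=_HIST_BINS)
        return {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in h]}

    return {
        "n_individuals": int(len(classified)),
        "n_classified": n_classified,
        "counts": counts,
        "fractions": fractions,
        "n_extreme": int(classified["extreme"].sum()),
        "n_complete": int(classified["complete"].sum()),
        "fraction_skewed": ((counts["maternal_skewed"] + counts["paternal_skewed"])
                            / n_classified if n_classified else 0.0),
        "histogram_Mx": hist("Mx"),
        "histogram_mean_allelic_ratio": hist("mean_allelic_ratio"),
    }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int
    n_excluded: int
    status: str = "ok"          # "ok" or "undefined" (zero variance)


def mother_daughter_correlation(mother_values, daughter_values) -> CorrelationResult:
    """Pearson correlation between paired mother/daughter balance medians.

    Pairs with a NaN member are excluded and counted. Fewer than 3 complete
    pairs is an error; zero variance in either vector yields an undefined
    correlation (NaN, status "undefined") rather than an exception.
    """
    m = np.asarray(mother_values, dtype=float)
    d = np.asarray(daughter_values, dtype=float)
    if m.shape != d.shape:
        raise ValueError("mother and daughter vectors must have equal length")
    ok = ~np.isnan(m) & ~np.isnan(d)
    n_excluded = int((~ok).sum())
    m, d = m[ok], d[ok]
    if len(m) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(m)}")
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        return CorrelationResult(np.nan, np.nan, len(m), n_excluded, status="undefined")
    r, p = stats.pearsonr(m, d)
    return CorrelationResult(float(r), float(p), len(m), n_excluded)
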