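"""Precursor-cell model of population X-inactivation skew.

If the blood compartment descends from ``n`` embryonic precursor cells that
each inactivated the maternal or paternal X independently with probability
1/2, an individual's paternal ratio is ``Binomial(n, 0.5) / n``. Small
pools produce wide skew distributions — with 4 cells, 1 in 16 individuals
expresses only the paternal X and 1 in 8 is completely skewed in one
direction or the other; with 32 cells complete skew has probability
``2^-31`` (about 5e-10).

To infer the pool size behind an observed cohort, candidate counts are
simulated (10,000 draws each by default, mirroring population-scale
simulation) and compared with the empirical sample of per-individual median
paternal ratios by a two-sample Kolmogorov-Smirnov test; the candidate with
the highest KS p-value wins. The simulated samples are discrete (multiples
of ``1/n``) while empirical medians are nearly continuous, so the
asymptotic KS p-value is used; an exact one-sample comparison against the
analytic binomial CDF is available as an alternative mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import substream
from .synthetic_cohort import simulate_skews

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateFit",
    "PrecursorFit",
    "simulate_ratios",
    "complete_skew_probability",
    "ks_compare",
    "select_precursor_count",
]

DEFAULT_CANDIDATES = (4, 8, 16, 32)


def simulate_ratios(n_cells: int, n_individuals: int,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Simulate ``n_individuals`` paternal ratios under ``n_cells`` precursors.

    Each value is the mean of ``n_cells`` independent Bernoulli(0.5)
    inactivation choices, i.e. a multiple of ``1/n_cells`` with law
    ``Binomial(n_cells, 0.5) / n_cells``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return simulate_skews(n_cells, n_individuals, rng)


def complete_skew_probability(n_cells: int) -> dict[str, float]:
    """Exact probability that all precursor cells inactivate the same X.

    ``one_direction`` is the chance every cell keeps (say) the paternal X
    active, ``(1/2)**n_cells``; ``either_direction`` doubles it. A single
    cell is always completely skewed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    one = 0.5 ** n_cells
    return {"one_direction": one, "either_direction": min(1.0, 2.0 * one)}


def ks_compare(empirical: np.ndarray, simulated: np.ndarray) -> tuple[float, float]:
    """Two-sample KS comparison; returns ``(D, p)``.

    Uses the asymptotic p-value, appropriate for the heavily tied discrete
    simulated samples.
    """
    empirical = np.asarray(empirical, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if empirical.size == 0 or simulated.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(empirical, simulated, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _ks_discrete_exact(empirical: np.ndarray, n_cells: int) -> tuple[float, float]:
    """Sup-distance between the sample ECDF and the Binomial(n, 0.5)/n CDF.

    Both functions are right-continuous steps, so the supremum is attained
    at a jump point of either; evaluating left and right limits at the
    union of jump points gives the exact D. The p-value uses the usual
    Kolmogorov distribution, which is conservative for discrete models.
    """
    x = np.sort(empirical)
    m = len(x)
    support = np.arange(n_cells + 1) / n_cells
    points = np.union1d(x, support)
    ecdf_right = np.searchsorted(x, points, side="right") / m
    ecdf_left = np.searchsorted(x, points, side="left") / m
    k_right = np.floor(points * n_cells + 1e-9)
    cdf_right = stats.binom.cdf(k_right, n_cells, 0.5)
    on_support = np.isclose(points * n_cells, np.round(points * n_cells))
    cdf_left = np.where(on_support,
                        stats.binom.cdf(k_right - 1, n_cells, 0.5), cdf_right)
    d = float(max(np.max(np.abs(ecdf_right - cdf_right)),
                  np.max(np.abs(ecdf_left - cdf_left))))
    p = float(stats.kstwobign.sf(d * np.sqrt(m)))
    return d, p


@dataclass(frozen=True)
class CandidateFit:
    n_cells: int
    D: float
    p_value: float


@dataclass(frozen=True)
class PrecursorFit:
    candidates: tuple[CandidateFit, ...]
    selected_count: int
    seed: int
    reps: int
    mode: str = "two_sample"

    def as_dict(self) -> dict:
        return {
            "selected_count": self.selected_count,
            "seed": self.seed,
            "reps": self.reps,
            "mode": self.mode,
            "candidates": [c.__dict__ for c in self.candidates],
        }


def select_precursor_count(empirical: np.ndarray,
                           candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
                           reps: int = 10_000, seed: int = 0,
                           mode: str = "two_sample") -> PrecursorFit:
    """Pick the precursor count whose skew distribution best fits a cohort.

    ``empirical`` is the sample of per-individual median paternal ratios.
    Each candidate ``n`` is simulated with ``reps`` draws from a named
    substream of ``seed`` (so candidates do not share randomness) and scored
    by KS against the empirical sample; the candidate with the highest
    p-value is selected, ties broken by smaller D then smaller ``n``.

    ``mode="exact_cdf"`` skips simulation and runs a one-sample KS test
    against the analytic ``Binomial(n, 0.5)/n`` CDF instead.
    """
    empirical = np.asarray(empirical, dtype=float)
    if empirical.size == 0:
        raise ValueError("empirical sample must be non-empty")
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    if mode not in ("two_sample", "exact_cdf"):
        raise ValueError(f"unknown mode {mode!r}")

    fits = []
    for n in candidates:
        if mode == "two_sample":
            sim = simulate_ratios(n, reps, substream(seed, "precursor", str(n)))
            d, p = ks_compare(empirical, sim)
        else:
            d, p = _ks_discrete_exact(empirical, n)
        fits.append(CandidateFit(n, d, p))

    best = sorted(fits, key=lambda c: (-c.p_value, c.D, c.n_cells))[0]
    logger.info("precursor fit (%s): selected %d cells; %s", mode, best.n_cells,
                [(c.n_cells, round(c.D, 4), round(c.p_value, 4)) for c in fits])
    return PrecursorFit(tuple(fits), best.n_cells, seed, reps, mode)
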