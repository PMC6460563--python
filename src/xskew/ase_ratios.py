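"""SNV filters and per-individual allelic-ratio summaries.

The analysis keeps a heterozygous SNV only if it has at least
``min_coverage`` allele-supporting reads (ref + alt), overlaps an annotated
exon, and lies outside the pseudoautosomal regions. From the surviving SNVs
each individual gets:

* mean/median allelic ratio (alt / total, parent-agnostic);
* mean/median paternal ratio — the median is ``Mx``, the individual's
  skew estimate;
* the chromosome skew factor ``Sx = |Mx - 0.5|``;
* the median measure of balance, ``median(min(ref, alt) / total)`` — an
  orientation-free skew proxy usable when parental genotypes are missing
  (mothers).

Coordinate conventions: SNV positions are 1-based; BED intervals are 0-based
half-open; a position ``p`` overlaps ``[start, end)`` iff ``start < p <=
end``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "measure_of_balance",
    "annotate_intervals",
    "filter_snvs",
    "summarize_individual",
    "summarize_individuals",
]


def measure_of_balance(ref_count, alt_count):
    """min(ref, alt) / (ref + alt); NaN at zero coverage.

    Equals ``min(r, 1 - r)`` for allelic ratio ``r``: 0.5 means perfectly
    biallelic, 0 means monoallelic, regardless of which allele dominates.
    Accepts scalars or arrays.
    """
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, np.minimum(ref, alt) / total, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _build_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in bed.groupby("chrom"):
        t = IntervalTree()
        for row in sub.itertuples():
            t.addi(row.start, row.end, getattr(row, "gene_id", None))
        trees[str(chrom)] = t
    return trees


def annotate_intervals(records: pd.DataFrame, exons: pd.DataFrame,
                       par_intervals: pd.DataFrame) -> pd.DataFrame:
    """Add ``exonic``, ``in_par`` and ``gene_ids`` columns to SNV records.

    ``gene_ids`` is a tuple of the genes whose exons overlap the position
    (empty when non-exonic). A 1-based position ``p`` hits a BED interval
    ``[start, end)`` when ``start <= p - 1 < end``.
    """
    etrees = _build_trees(exons)
    ptrees = _build_trees(par_intervals)
    exonic, in_par, gene_ids = [], [], []
    for row in records.itertuples():
        p0 = row.pos - 1
        hits = etrees.get(str(row.chrom), IntervalTree())[p0]
        genes = tuple(sorted({iv.data for iv in hits if iv.data is not None}))
        exonic.append(bool(hits))
        gene_ids.append(genes)
        in_par.append(bool(ptrees.get(str(row.chrom), IntervalTree())[p0]))
    out = records.copy()
    out["exonic"] = exonic
    out["in_par"] = in_par
    out["gene_ids"] = gene_ids
    return out


def filter_snvs(records: pd.DataFrame, exons: pd.DataFrame,
                par_intervals: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Apply the coverage / exonic / non-PAR filters to SNV records.

    ``records`` needs ``chrom, pos, ref_count, alt_count`` (phased columns
    pass through untouched, so the same filter serves daughters' phased
    records and mothers' unphased ones). Returns the surviving records with
    annotation columns attached; exclusions are logged per category, with
    PAR taking precedence over non-exonic, then low coverage.
    """
    ann = annotate_intervals(records, exons, par_intervals)
    coverage = ann["ref_count"] + ann["alt_count"]
    keep = (coverage >= min_coverage) & ann["exonic"] & ~ann["in_par"]

    tally = {
        "par": int(ann["in_par"].sum()),
        "non_exonic": int((~ann["in_par"] & ~ann["exonic"]).sum()),
        "low_coverage": int((~ann["in_par"] & ann["exonic"]
                             & (coverage < min_coverage)).sum()),
        "kept": int(keep.sum()),
    }
    logger.info("SNV filter (min_coverage=%d): %s", min_coverage, tally)
    if tally["kept"] == 0:
        logger.warning("no SNVs survived filtering; summaries will be uninformative")
    return ann[keep].reset_index(drop=True)


def summarize_individual(records: pd.DataFrame, sample_id: str) -> dict:
    """Summary statistics for one sample's filtered SNVs.

    Paternal-ratio statistics (``Mx``, ``Sx``) are NaN when the records are
    unphased (mothers). An empty record set yields an all-NaN summary
    flagged ``informative=False``.
    """
    n = len(records)
    if n == 0:
        return {"sample_id": sample_id, "n_informative_snvs": 0,
                "mean_allelic_ratio": np.nan, "median_allelic_ratio": np.nan,
                "mean_paternal_ratio": np.nan, "Mx": np.nan, "Sx": np.nan,
                "median_measure_of_balance": np.nan, "informative": False}
    ar = records["allelic_ratio"].to_numpy(dtype=float)
    mob = measure_of_balance(records["ref_count"], records["alt_count"])
    if "paternal_ratio" in records:
        pr = records["paternal_ratio"].to_numpy(dtype=float)
        mean_pr, mx = float(np.mean(pr)), float(np.median(pr))
        sx = abs(mx - 0.5)
    else:
        mean_pr = mx = sx = np.nan
    return {
        "sample_id": sample_id,
        "n_informative_snvs": n,
        "mean_allelic_ratio": float(np.mean(ar)),
        "median_allelic_ratio": float(np.median(ar)),
        "mean_paternal_ratio": mean_pr,
        "Mx": mx,
        "Sx": sx,
        "median_measure_of_balance": float(np.median(mob)),
        "informative": True,
    }


def summarize_individuals(filtered: pd.DataFrame,
                          sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-individual summary table over filtered records.

    ``sample_ids`` may list samples that must appear even with zero
    surviving SNVs (they come out flagged uninformative). For records
    lacking an ``allelic_ratio`` column (raw counts), the ratio is computed
    on the fly.
    """
    recs = filtered.copy()
    if "allelic_ratio" not in recs:
        total = recs["ref_count"] + recs["alt_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            recs["allelic_ratio"] = np.where(total > 0, recs["alt_count"] / total, np.nan)
    rows = []
    seen = []
    for sid, sub in recs.groupby("sample_id", sort=True):
        rows.append(summarize_individual(sub, str(sid)))
        seen.append(str(sid))
    if sample_ids is not None:
        for sid in sample_ids:
            if sid not in seen:
                rows.append(summarize_individual(recs.iloc[0:0], sid))
    out = pd.DataFrame(rows).sort_values("sample_id", kind="stable").reset_index(drop=True)
    return out
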