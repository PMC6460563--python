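"""Gene-level test for escape from X-inactivation.

Rationale: in an individual with skewed X-inactivation, an inactivated gene
is expressed almost entirely from the active haplotype, so its median
paternal ratio ``Mg`` tracks the chromosome-wide median ``Mx``. An escapee
gene is transcribed from both X chromosomes and its ratio is pulled back
toward 0.5. Writing ``Sx = |Mx - 0.5|`` and ``Sg = |Mg - 0.5|``, the screen
asks — across skewed individuals (``Mx <= 0.35`` or ``>= 0.65``) — whether
the gene is systematically *less* skewed than its chromosome.

Per sample the gene contributes a signed skew ``g = Sg`` when ``Mg`` and
``Mx`` deviate from 0.5 on the same side, and ``g = -Sg`` when they
disagree (deviating past 0.5 in the opposite direction is even stronger
evidence of biallelic expression). The paired one-sided t-test is then on
the differences ``d_k = Sx_k - g_k`` with alternative ``mean(d) > 0``; a
gene needs at least ``min_samples`` (default 5) informative skewed samples
to be tested, and is called an escapee at ``p < alpha`` (default 0.05, no
multiple-testing correction, Benjamini-Hochberg available by flag).

*XIST* is the built-in control: it is expressed from the inactive X, so its
``Mg`` should sit on the *opposite* side of 0.5 from ``Mx`` in nearly every
skewed individual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GeneEscapeResult",
    "gene_sample_medians",
    "escape_test",
    "run_escape_screen",
    "xist_check",
]


@dataclass(frozen=True)
class GeneEscapeResult:
    gene_id: str
    n_samples: int
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    escapee_call: bool
    testable: bool = True
    reference_bias_suspect: bool = False
    note: str | None = None


def gene_sample_medians(filtered: pd.DataFrame, summaries: pd.DataFrame,
                        skewed_sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-(gene, sample) medians over filtered, phased SNV records.

    ``filtered`` must carry ``gene_ids`` (from the exon-overlap annotation)
    and ``paternal_ratio``; records overlapping several genes contribute to
    each. ``summaries`` supplies each sample's chromosome-wide ``Mx``.
    When ``skewed_sample_ids`` is given, only those samples are kept.

    Returns columns: gene_id, sample_id, n_snvs, Mg, Sg, Mx, Sx,
    agrees_with_chromosome, ref_reads, total_reads.
    """
    recs = filtered.copy()
    if skewed_sample_ids is not None:
        recs = recs[recs["sample_id"].isin(set(skewed_sample_ids))]
    recs = recs.explode("gene_ids").rename(columns={"gene_ids": "gene_id"})
    recs = recs.dropna(subset=["gene_id"])

    mx = summaries.set_index("sample_id")["Mx"]
    rows = []
    for (gene, sid), sub in recs.groupby(["gene_id", "sample_id"], sort=True):
        mg = float(np.median(sub["paternal_ratio"]))
        sample_mx = float(mx.get(sid, np.nan))
        sg = abs(mg - 0.5)
        sx = abs(sample_mx - 0.5)
        # tie Mg == 0.5 counts as agreement; Sg = 0 contributes identically
        # under either branch
        agrees = (mg - 0.5) * (sample_mx - 0.5) >= 0
        rows.append((gene, sid, len(sub), mg, sg, sample_mx, sx, agrees,
                     int(sub["ref_count"].sum()),
                     int((sub["ref_count"] + sub["alt_count"]).sum())))
    return pd.DataFrame(rows, columns=[
        "gene_id", "sample_id", "n_snvs", "Mg", "Sg", "Mx", "Sx",
        "agrees_with_chromosome", "ref_reads", "total_reads"])


def escape_test(gene_records: pd.DataFrame, alpha: float = 0.05,
                min_samples: int = 5,
                direction: str = "gene_less_skewed") -> GeneEscapeResult:
    """Paired one-sided t-test of gene vs chromosome skew for one gene.

    ``gene_records`` is the :func:`gene_sample_medians` slice for a single
    gene across skewed samples. The signed gene skew is ``+Sg`` on
    agreement and ``-Sg`` on disagreement; the default alternative is
    ``mean(Sx - signed Sg) > 0`` (the gene sits closer to 0.5 than the
    chromosome). ``direction="gene_more_skewed"`` flips the alternative,
    mirroring an R ``t.test(Sx, Sg, alternative="less")`` call with that
    literal argument order.

    Genes with fewer than ``min_samples`` samples raise ValueError (callers
    exclude them beforehand); zero variance of the differences makes the
    gene untestable (no call, NaN p).
    """
    gene_id = str(gene_records["gene_id"].iloc[0])
    n = len(gene_records)
    if n < min_samples:
        raise ValueError(f"{gene_id}: {n} samples < required {min_samples}")
    if direction not in ("gene_less_skewed", "gene_more_skewed"):
        raise ValueError(f"unknown direction {direction!r}")

    signed_sg = np.where(gene_records["agrees_with_chromosome"],
                         gene_records["Sg"], -gene_records["Sg"])
    d = gene_records["Sx"].to_numpy(dtype=float) - signed_sg
    suspect = _reference_bias_suspect(gene_records)
    if np.ptp(d) == 0:
        return GeneEscapeResult(gene_id, n, np.nan, n - 1, np.nan,
                                escapee_call=False, testable=False,
                                reference_bias_suspect=suspect,
                                note="zero variance of paired differences")
    alternative = "greater" if direction == "gene_less_skewed" else "less"
    res = stats.ttest_1samp(d, 0.0, alternative=alternative)
    p = float(res.pvalue)
    return GeneEscapeResult(gene_id, n, float(res.statistic), n - 1, p,
                            escapee_call=bool(p < alpha),
                            reference_bias_suspect=suspect)


def _reference_bias_suspect(gene_records: pd.DataFrame,
                            threshold: float = 0.9) -> bool:
    """Flag genes whose pooled reads are overwhelmingly reference.

    Near-exclusive reference-allele expression across samples is the
    signature of reads from a homologous locus mis-mapping onto the gene
    (classically a pseudogene) rather than of escape; flagged, not removed.
    """
    total = gene_records["total_reads"].sum()
    return bool(total > 0 and gene_records["ref_reads"].sum() / total > threshold)


def run_escape_screen(filtered: pd.DataFrame, classified: pd.DataFrame,
                      alpha: float = 0.05, min_samples: int = 5,
                      direction: str = "gene_less_skewed",
                      bh_correction: bool = False) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Screen every sufficiently covered gene across skewed individuals.

    ``classified`` is the per-individual summary with skew classes; only
    skewed samples enter. Returns ``(results, audit, counts)``: one result
    row per informative gene (>= ``min_samples`` skewed samples), the full
    per-(gene, sample) audit table, and bookkeeping counts. With
    ``bh_correction`` the calls use Benjamini-Hochberg-adjusted p-values.
    """
    skewed_ids = classified.loc[classified["skewed"], "sample_id"].tolist()
    status = {"n_skewed_individuals": len(skewed_ids)}
    if not skewed_ids:
        logger.warning("no skewed individuals: escape screen is empty")
        empty = pd.DataFrame(columns=["gene_id", "n_samples", "t_statistic",
                                      "degrees_of_freedom", "p_value", "p_adjusted",
                                      "escapee_call", "testable",
                                      "reference_bias_suspect", "note"])
        return empty, pd.DataFrame(), {**status, "n_genes_total": 0,
                                       "n_genes_informative": 0,
                                       "n_genes_tested": 0, "n_escapee_calls": 0}

    audit = gene_sample_medians(filtered, classified, skewed_ids)
    results = []
    for gene, sub in audit.groupby("gene_id", sort=True):
        if len(sub) < min_samples:
            continue
        results.append(escape_test(sub, alpha=alpha, min_samples=min_samples,
                                   direction=direction))
    res = pd.DataFrame([r.__dict__ for r in results])
    if len(res):
        res["p_adjusted"] = np.nan
        testable = res["testable"].to_numpy(dtype=bool)
        if bh_correction and testable.any():
            adj = stats.false_discovery_control(res.loc[testable, "p_value"])
            res.loc[testable, "p_adjusted"] = adj
            res["escapee_call"] = res["p_adjusted"] < alpha
        res = res.sort_values("gene_id", kind="stable").reset_index(drop=True)

    counts = {
        **status,
        "n_genes_total": int(audit["gene_id"].nunique()),
        "n_genes_informative": int(len(res)),
        "n_genes_tested": int(res["testable"].sum()) if len(res) else 0,
        "n_escapee_calls": int(res["escapee_call"].sum()) if len(res) else 0,
    }
    logger.info("escape screen: %s", counts)
    return res, audit, counts


def xist_check(audit: pd.DataFrame, classified: pd.DataFrame,
               xist_gene_id: str = "XIST") -> dict:
    """Verify that XIST's allelic direction opposes the chromosome's.

    For each skewed sample with informative XIST SNVs, flags whether
    ``Mg_XIST`` and ``Mx`` fall on opposite sides of 0.5. Returns the
    per-sample flags and the opposed fraction; status "uninformative" when
    no skewed sample covers XIST.
    """
    skewed_ids = set(classified.loc[classified["skewed"], "sample_id"])
    sub = audit[(audit["gene_id"] == xist_gene_id)
                & audit["sample_id"].isin(skewed_ids)]
    if len(sub) == 0:
        return {"status": "uninformative", "n_samples": 0,
                "fraction_opposed": np.nan, "per_sample": []}
    opposed = ((sub["Mg"] - 0.5) * (sub["Mx"] - 0.5) < 0).to_numpy()
    per_sample = [{"sample_id": str(s), "Mg": float(mg), "Mx": float(mx),
                   "opposed": bool(o)}
                  for s, mg, mx, o in zip(sub["sample_id"], sub["Mg"],
                                          sub["Mx"], opposed)]
    return {"status": "ok", "n_samples": int(len(sub)),
            "fraction_opposed": float(opposed.mean()), "per_sample": per_sample}
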