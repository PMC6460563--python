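"""End-to-end orchestration: files in, skew/escapee/precursor results out.

Stages: parent-of-origin phasing of the daughters' counts, SNV filtering
(coverage >= 10, exonic, non-PAR), per-individual ratio summaries, skew
classification, the gene-level escape screen with the XIST opposition
check, mother-daughter balance correlation, and precursor-count model
selection on the daughters' median paternal ratios.

Every excluded count record is attributed to exactly one category
(unknown site, uninformative genotype, Mendelian-inconsistent, PAR,
non-exonic, low coverage), so category counts plus survivors add up to the
input; the tally lands in the cohort report. A run is deterministic for a
fixed seed and writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as xio
from .ase_ratios import annotate_intervals, summarize_individuals
from .escapee_screen import run_escape_screen, xist_check
from .precursor_model import DEFAULT_CANDIDATES, PrecursorFit, select_precursor_count
from .skew_classification import (SkewThresholds, classify_balance, classify_cohort,
                                  mother_daughter_correlation, population_distribution)
from .trio_phasing import phase_counts, phase_genotypes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "read_inputs", "run_pipeline",
           "run_pipeline_from_data"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and thresholds for a pipeline run; JSON round-trip stable."""

    genotypes_vcf: str = ""
    counts_tsv: str = ""
    exons_bed: str = ""
    par_bed: str = ""
    trios_tsv: str = ""
    output_dir: str = "xskew_out"
    min_coverage: int = 10
    skew_maternal: float = 0.35
    skew_paternal: float = 0.65
    extreme_low: float = 0.15
    extreme_high: float = 0.85
    alpha: float = 0.05
    min_gene_samples: int = 5
    xist_gene_id: str = "XIST"
    precursor_candidates: tuple[int, ...] = DEFAULT_CANDIDATES
    precursor_reps: int = 10_000
    seed: int = 0
    log_level: str = "INFO"

    def thresholds(self) -> SkewThresholds:
        return SkewThresholds(maternal=self.skew_maternal, paternal=self.skew_paternal,
                              extreme_low=self.extreme_low, extreme_high=self.extreme_high)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["precursor_candidates"] = tuple(raw["precursor_candidates"])
        return cls(**raw)


@dataclass
class PipelineResult:
    phased: pd.DataFrame
    filtered: pd.DataFrame
    summaries: pd.DataFrame          # daughters + mothers, with skew classes
    cohort_report: dict
    escape_results: pd.DataFrame
    escape_audit: pd.DataFrame
    precursor_fit: PrecursorFit


def read_inputs(config: PipelineConfig) -> dict:
    """Load and cross-validate the five input files.

    Beyond per-file schema checks, verifies that every count-table sample id
    is a daughter or mother named in the trio table.
    """
    trios = pd.read_csv(config.trios_tsv, sep="\t")
    for col in ("trio_id", "daughter_id", "mother_id", "father_id"):
        if col not in trios.columns:
            raise xio.InputValidationError(config.trios_tsv, None, col,
                                           "missing required column")
    genotypes = xio.read_vcf(config.genotypes_vcf, trios)
    counts = xio.read_counts(config.counts_tsv)
    exons = xio.read_bed(config.exons_bed, named=True)
    par = xio.read_bed(config.par_bed)
    known = set(trios["daughter_id"]) | set(trios["mother_id"]) | set(trios["father_id"])
    unknown = sorted(set(counts["sample_id"]) - known)
    if unknown:
        raise xio.InputValidationError(config.counts_tsv, None, "sample_id",
                                       f"unknown sample ids: {unknown}")
    return {"trios": trios, "genotypes": genotypes, "counts": counts,
            "exons": exons, "par": par}


def _exclusion_tally(counts: pd.DataFrame, trios: pd.DataFrame,
                     assignments: pd.DataFrame, annotated: pd.DataFrame,
                     min_coverage: int) -> dict:
    """Attribute each daughter count record to one exclusion category."""
    daughters = trios.rename(columns={"daughter_id": "sample_id"})[["trio_id", "sample_id"]]
    cts = counts.merge(daughters, on="sample_id", how="inner")
    merged = cts.merge(assignments[["trio_id", "chrom", "pos", "status"]],
                       on=["trio_id", "chrom", "pos"], how="left")
    ann = annotated.set_index(["sample_id", "pos"])
    cov = merged["ref_count"] + merged["alt_count"]
    cat = np.full(len(merged), "kept", dtype=object)
    idx = pd.MultiIndex.from_frame(merged[["sample_id", "pos"]])
    in_par = ann["in_par"].reindex(idx).to_numpy(dtype=object)
    exonic = ann["exonic"].reindex(idx).to_numpy(dtype=object)
    cat[np.asarray(exonic == False) & np.asarray(in_par == False)] = "non_exonic"  # noqa: E712
    cat[np.asarray(in_par == True)] = "par"                                        # noqa: E712
    low = (cov < min_coverage).to_numpy() & (cat == "kept")
    cat[low] = "low_coverage"
    cat[merged["status"] == "not_informative"] = "genotype_not_informative"
    cat[merged["status"] == "inconsistent"] = "mendelian_inconsistent"
    cat[merged["status"].isna()] = "unknown_site"
    tally = pd.Series(cat).value_counts().to_dict()
    tally["input_records"] = int(len(merged))
    return {k: int(v) for k, v in tally.items()}


def run_pipeline_from_data(genotypes: pd.DataFrame, counts: pd.DataFrame,
                           exons: pd.DataFrame, par: pd.DataFrame,
                           trios: pd.DataFrame,
                           config: PipelineConfig | None = None) -> PipelineResult:
    """Run every analysis stage on in-memory tables."""
    cfg = config or PipelineConfig()
    thresholds = cfg.thresholds()

    assignments = phase_genotypes(genotypes)
    phased = phase_counts(counts, assignments, trios)

    # one shared interval annotation serves both filtering and the tally
    ann = annotate_intervals(phased, exons, par)
    cov = ann["ref_count"] + ann["alt_count"]
    filtered = ann[(cov >= cfg.min_coverage) & ann["exonic"]
                   & ~ann["in_par"]].reset_index(drop=True)
    tally = _exclusion_tally(counts, trios, assignments, ann, cfg.min_coverage)

    daughters = trios["daughter_id"].tolist()
    mothers = trios["mother_id"].tolist()
    d_sum = summarize_individuals(filtered, daughters)
    d_sum["role"] = "daughter"

    mother_counts = counts[counts["sample_id"].isin(mothers)]
    m_ann = annotate_intervals(mother_counts, exons, par)
    m_cov = m_ann["ref_count"] + m_ann["alt_count"]
    m_filtered = m_ann[(m_cov >= cfg.min_coverage) & m_ann["exonic"]
                       & ~m_ann["in_par"]].reset_index(drop=True)
    m_sum = summarize_individuals(m_filtered, mothers)
    m_sum["role"] = "mother"

    d_class = classify_cohort(d_sum, thresholds)
    m_class = m_sum.copy()
    m_class["skew_class"] = [classify_balance(b, thresholds)
                             for b in m_class["median_measure_of_balance"]]
    m_class["skewed"] = m_class["skew_class"] == "skewed"
    m_class["extreme"] = False
    m_class["complete"] = False
    summaries = pd.concat([d_class, m_class], ignore_index=True)

    distribution = population_distribution(d_class)

    pair_m = m_sum.set_index("sample_id")["median_measure_of_balance"]
    pair_d = d_sum.set_index("sample_id")["median_measure_of_balance"]
    mo = pair_m.reindex(trios["mother_id"]).to_numpy()
    da = pair_d.reindex(trios["daughter_id"]).to_numpy()
    try:
        corr = mother_daughter_correlation(mo, da)
        corr_report = dataclasses.asdict(corr)
    except ValueError as exc:
        corr_report = {"status": "insufficient_data", "detail": str(exc)}

    escape_results, escape_audit, escape_counts = run_escape_screen(
        filtered, d_class, alpha=cfg.alpha, min_samples=cfg.min_gene_samples)
    xist = xist_check(escape_audit, d_class, xist_gene_id=cfg.xist_gene_id)

    empirical = d_sum.loc[d_sum["informative"], "Mx"].to_numpy(dtype=float)
    fit = select_precursor_count(empirical, candidates=cfg.precursor_candidates,
                                 reps=cfg.precursor_reps, seed=cfg.seed)

    report = {
        "exclusion_tally": tally,
        "population": distribution,
        "mother_daughter_correlation": corr_report,
        "escape_screen": escape_counts,
        "xist_check": xist,
        "precursor_fit": fit.as_dict(),
    }
    return PipelineResult(phased=phased, filtered=filtered, summaries=summaries,
                          cohort_report=report, escape_results=escape_results,
                          escape_audit=escape_audit, precursor_fit=fit)


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    if "gene_ids" in out:
        out["gene_ids"] = out["gene_ids"].map(
            lambda g: ",".join(g) if isinstance(g, (tuple, list)) else g)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based run: read inputs, analyse, write the output bundle.

    Outputs land in ``config.output_dir``: phased_snvs.tsv,
    snvs_filtered.tsv, individual_summaries.tsv, cohort_report.json,
    escape_screen.tsv, escape_audit.tsv, precursor_fit.json, and the
    resolved configuration. Identical config + seed gives byte-identical
    outputs.
    """
    logging.getLogger("xskew").setLevel(config.log_level)
    data = read_inputs(config)
    result = run_pipeline_from_data(data["genotypes"], data["counts"],
                                    data["exons"], data["par"], data["trios"],
                                    config)
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    _write_tsv(result.phased, os.path.join(outdir, "phased_snvs.tsv"))
    _write_tsv(result.filtered, os.path.join(outdir, "snvs_filtered.tsv"))
    _write_tsv(result.summaries, os.path.join(outdir, "individual_summaries.tsv"))
    _write_tsv(result.escape_results, os.path.join(outdir, "escape_screen.tsv"))
    _write_tsv(result.escape_audit, os.path.join(outdir, "escape_audit.tsv"))
    with open(os.path.join(outdir, "cohort_report.json"), "w") as fh:
        json.dump(result.cohort_report, fh, indent=2, sort_keys=True)
    with open(os.path.join(outdir, "precursor_fit.json"), "w") as fh:
        json.dump(result.precursor_fit.as_dict(), fh, indent=2, sort_keys=True)
    config.to_json(os.path.join(outdir, "resolved_config.json"))
    logger.info("pipeline outputs written to %s", outdir)
    return result
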