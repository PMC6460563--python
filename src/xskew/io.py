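"""Readers and writers for the pipeline's on-disk formats.

Formats: VCF 4.2 for trio genotypes (GT only; the father's hemizygous X
call may be spelled haploid ``0`` or homozygous-diploid ``0/0`` — both
dialects are read), TSV for allele-specific counts and summaries, BED
(0-based half-open) for exons and pseudoautosomal intervals, JSON for truth
summaries and reports. VCF parsing goes through pysam; everything tabular
through pandas. Validation errors name the file, line and field.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import pysam

from .synthetic_cohort import Cohort, CohortConfig, CohortTruth

__all__ = [
    "InputValidationError",
    "write_vcf", "read_vcf",
    "write_counts", "read_counts",
    "write_bed", "read_bed",
    "write_cohort", "read_cohort",
]


class InputValidationError(ValueError):
    """An input file failed schema validation."""

    def __init__(self, path: str, line: int | None, field: str, message: str):
        self.path, self.line, self.field = path, line, field
        where = f"{path}" + (f", line {line}" if line is not None else "")
        super().__init__(f"{where}, field '{field}': {message}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(genotypes: pd.DataFrame, trios: pd.DataFrame, path: str,
              chrom_length: int = 155_270_560) -> None:
    """Write trio genotypes as a merged plain-text VCF.

    Samples are ordered daughter, mother, father per trio. Variants are
    private to one trio; other samples get ``./.``. To cover both
    hemizygous dialects seen in real call sets, the father's X genotype is
    written haploid (``0``) for even-indexed trios and homozygous diploid
    (``0/0``) for odd-indexed ones.
    """
    sample_order: list[str] = []
    for row in trios.itertuples():
        sample_order += [row.daughter_id, row.mother_id, row.father_id]
    trio_idx = {row.trio_id: i for i, row in enumerate(trios.itertuples())}
    cols = {row.trio_id: (row.daughter_id, row.mother_id, row.father_id)
            for row in trios.itertuples()}

    chrom = str(genotypes["chrom"].iloc[0]) if len(genotypes) else "X"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={chrom_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_order),
    ]

    def gt_index(allele: str, ref: str, alt: str) -> str:
        return "0" if allele == ref else "1"

    ordered = genotypes.sort_values(["chrom", "pos"], kind="stable")
    for row in ordered.itertuples():
        calls = {s: "./." for s in sample_order}
        d_id, m_id, f_id = cols[row.trio_id]
        da, db = row.daughter_gt.split("/")
        ma, mb = row.mother_gt.split("/")
        calls[d_id] = f"{gt_index(da, row.ref, row.alt)}/{gt_index(db, row.ref, row.alt)}"
        calls[m_id] = f"{gt_index(ma, row.ref, row.alt)}/{gt_index(mb, row.ref, row.alt)}"
        fa = gt_index(row.father_allele, row.ref, row.alt)
        calls[f_id] = fa if trio_idx[row.trio_id] % 2 == 0 else f"{fa}/{fa}"
        lines.append("\t".join([
            chrom, str(row.pos), ".", row.ref, row.alt, ".", "PASS", ".", "GT",
        ] + [calls[s] for s in sample_order]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gt_to_alleles(gt: tuple, ref: str, alts: tuple) -> list[str] | None:
    alleles = []
    for idx in gt:
        if idx is None:
            return None
        alleles.append(ref if idx == 0 else alts[idx - 1])
    return alleles


def read_vcf(path: str, trios: pd.DataFrame) -> pd.DataFrame:
    """Read a merged trio VCF back into the genotype-table schema.

    Multi-allelic records are skipped with a count (the analysis is
    restricted to biallelic SNVs). For each record, the owning trio is the
    one whose daughter has a called genotype; records with no called
    daughter are ignored. Father calls are normalised to a single allele
    when haploid or homozygous; a genuinely heterozygous diploid father
    call is preserved as ``"A/G"`` so phasing can flag it.
    """
    rows = []
    n_multiallelic = 0
    vcf = pysam.VariantFile(path)
    trio_list = list(trios.itertuples())
    with vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 \
                    or len(rec.alts[0]) != 1:
                n_multiallelic += 1
                continue
            for trow in trio_list:
                d = _gt_to_alleles(rec.samples[trow.daughter_id]["GT"],
                                   rec.ref, rec.alts)
                if d is None:
                    continue
                m = _gt_to_alleles(rec.samples[trow.mother_id]["GT"],
                                   rec.ref, rec.alts)
                f = _gt_to_alleles(rec.samples[trow.father_id]["GT"],
                                   rec.ref, rec.alts)
                father = None
                if f is not None:
                    father = f[0] if len(set(f)) == 1 else "/".join(sorted(f))
                rows.append((trow.trio_id, rec.chrom, rec.pos, rec.ref, rec.alts[0],
                             "/".join(sorted(d)),
                             "/".join(sorted(m)) if m is not None else None,
                             father))
                break
    if n_multiallelic:
        import logging
        logging.getLogger(__name__).warning(
            "skipped %d non-biallelic/non-SNV records in %s", n_multiallelic, path)
    return pd.DataFrame(rows, columns=[
        "trio_id", "chrom", "pos", "ref", "alt",
        "daughter_gt", "mother_gt", "father_allele"])


# ---------------------------------------------------------------------------
# counts TSV / BED
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts[_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            raise InputValidationError(path, None, col, "missing required column")
    for col, line_offset in (("ref_count", 2), ("alt_count", 2)):
        vals = df[col]
        bad = vals.isna() | (vals < 0) | (vals != vals.astype(int))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise InputValidationError(path, i + line_offset, col,
                                       f"invalid count {vals.iloc[i]!r}")
    bad_pos = df["pos"] < 1
    if bad_pos.any():
        i = int(np.flatnonzero(bad_pos)[0])
        raise InputValidationError(path, i + 2, "pos", "positions are 1-based (>= 1)")
    return df.astype({"ref_count": int, "alt_count": int, "pos": int})


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    cols = ["chrom", "start", "end"] + (["gene_id"] if "gene_id" in intervals else [])
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str, named: bool = False) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["gene_id"] if named else [])
    df = pd.read_csv(path, sep="\t", header=None, names=names,
                     usecols=range(len(names)))
    bad = (df["start"] < 0) | (df["start"] >= df["end"])
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise InputValidationError(
            path, i + 1, "start/end",
            f"invalid interval [{df['start'].iloc[i]}, {df['end'].iloc[i]})")
    return df


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, outdir: str) -> dict[str, str]:
    """Serialize a synthetic cohort (inputs + truth) to a directory."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "genotypes": "genotypes.vcf", "counts": "counts.tsv",
        "exons": "exons.bed", "par": "par.bed", "trios": "trios.tsv",
        "truth_individuals": "truth_individuals.tsv",
        "truth_genes": "truth_genes.tsv",
        "truth_variable_escape": "truth_variable_escape.tsv",
        "truth_sites": "truth_sites.tsv",
        "truth_summary": "truth.json", "config": "cohort_config.json",
    }.items()}
    write_vcf(cohort.genotypes, cohort.trios, paths["genotypes"],
              chrom_length=cohort.config.chrom_length)
    write_counts(cohort.counts, paths["counts"])
    write_bed(cohort.exons, paths["exons"])
    write_bed(cohort.par, paths["par"])
    cohort.trios.to_csv(paths["trios"], sep="\t", index=False)
    t = cohort.truth
    t.individuals.to_csv(paths["truth_individuals"], sep="\t", index=False)
    t.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    t.variable_escape.to_csv(paths["truth_variable_escape"], sep="\t", index=False)
    t.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    summary = {
        "n_trios": int(len(cohort.trios)),
        "n_genotype_records": int(len(cohort.genotypes)),
        "n_count_records": int(len(cohort.counts)),
        "xist_gene_id": t.xist_gene_id,
        "gene_status_counts": t.genes["status"].value_counts().to_dict(),
    }
    with open(paths["truth_summary"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cohort.config), fh, indent=2, sort_keys=True)
    return paths


def read_cohort(outdir: str) -> Cohort:
    """Load a cohort bundle written by :func:`write_cohort`."""
    with open(os.path.join(outdir, "cohort_config.json")) as fh:
        raw = json.load(fh)
    raw["snvs_per_individual_range"] = tuple(raw["snvs_per_individual_range"])
    raw["par_intervals"] = tuple(tuple(iv) for iv in raw["par_intervals"])
    config = CohortConfig(**raw)
    trios = pd.read_csv(os.path.join(outdir, "trios.tsv"), sep="\t")
    genotypes = read_vcf(os.path.join(outdir, "genotypes.vcf"), trios)
    counts = read_counts(os.path.join(outdir, "counts.tsv"))
    exons = read_bed(os.path.join(outdir, "exons.bed"), named=True)
    par = read_bed(os.path.join(outdir, "par.bed"))
    truth = CohortTruth(
        individuals=pd.read_csv(os.path.join(outdir, "truth_individuals.tsv"), sep="\t"),
        genes=pd.read_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t"),
        variable_escape=pd.read_csv(os.path.join(outdir, "truth_variable_escape.tsv"), sep="\t"),
        sites=pd.read_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t"),
    )
    return Cohort(config=config, trios=trios, genotypes=genotypes, counts=counts,
                  exons=exons, par=par, truth=truth)
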