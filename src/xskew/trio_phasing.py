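"""Parent-of-origin assignment on chrX from trio genotypes.

Fathers are hemizygous on the non-pseudoautosomal X, so at any SNV where the
daughter is heterozygous the paternal allele is forced: it is whichever of
her two alleles the father carries, and the other allele is maternal. The
mother's genotype is used purely as a consistency check — the assignment
never depends on it, but a site whose implied maternal allele the mother
does not carry is a Mendelian error and is dropped.

Assignment is a pure function of genotypes; read counts never influence it.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PhasingStatus",
    "TrioGenotypeRecord",
    "Assignment",
    "MissingGenotypeError",
    "assign_parent_of_origin",
    "phase_genotypes",
    "phase_counts",
]


class PhasingStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    NOT_INFORMATIVE = "not_informative"   # daughter homozygous
    INCONSISTENT = "inconsistent"         # Mendelian error


class MissingGenotypeError(ValueError):
    """The daughter's genotype is absent; the record cannot be used."""


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """One X-chromosomal biallelic SNV with trio genotypes.

    ``daughter_gt``/``mother_gt`` are unordered allele pairs like ``"A/G"``;
    ``father_allele`` is the hemizygous single allele, but a homozygous
    diploid spelling ("A/A") is also accepted. ``mother_gt`` may be None
    (consistency then unchecked). A heterozygous father call on non-PAR X is
    itself treated as inconsistent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    daughter_gt: str | None
    mother_gt: str | None
    father_allele: str | None


@dataclass(frozen=True)
class Assignment:
    status: PhasingStatus
    paternal_allele: str | None = None
    maternal_allele: str | None = None
    mother_checked: bool = True


def _split_gt(gt: str) -> tuple[str, ...]:
    return tuple(gt.split("/")) if "/" in gt else (gt,)


def assign_parent_of_origin(record: TrioGenotypeRecord) -> Assignment:
    """Resolve the daughter's alleles to paternal/maternal.

    Rules (daughter heterozygous required for informativeness):

    * daughter homozygous -> NOT_INFORMATIVE;
    * father's allele not among the daughter's alleles -> INCONSISTENT;
    * father effectively heterozygous -> INCONSISTENT (impossible on
      hemizygous non-PAR X);
    * the remaining (maternal) allele absent from the mother's genotype ->
      INCONSISTENT; a missing mother genotype skips this check and the
      assignment is flagged ``mother_checked=False``.
    """
    if record.daughter_gt is None:
        raise MissingGenotypeError(
            f"missing daughter genotype at {record.chrom}:{record.pos}")
    if record.father_allele is None:
        raise MissingGenotypeError(
            f"missing father genotype at {record.chrom}:{record.pos}")

    d = _split_gt(record.daughter_gt)
    if len(set(d)) == 1:
        return Assignment(PhasingStatus.NOT_INFORMATIVE)

    f = set(_split_gt(record.father_allele))
    if len(f) > 1:  # "A/G" father call: not a valid hemizygous X genotype
        return Assignment(PhasingStatus.INCONSISTENT)
    father = next(iter(f))
    if father not in d:
        return Assignment(PhasingStatus.INCONSISTENT)

    paternal = father
    maternal = d[0] if d[1] == paternal else d[1]

    if record.mother_gt is None:
        return Assignment(PhasingStatus.ASSIGNED, paternal, maternal,
                          mother_checked=False)
    if maternal not in _split_gt(record.mother_gt):
        return Assignment(PhasingStatus.INCONSISTENT)
    return Assignment(PhasingStatus.ASSIGNED, paternal, maternal)


def phase_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`assign_parent_of_origin` to a genotype table.

    Expects columns ``trio_id, chrom, pos, ref, alt, daughter_gt, mother_gt,
    father_allele``; returns the table with ``status``, ``paternal_allele``
    and ``maternal_allele`` columns appended. Counts of each status are
    logged.
    """
    statuses, pats, mats = [], [], []
    for row in genotypes.itertuples():
        rec = TrioGenotypeRecord(row.chrom, row.pos, row.ref, row.alt,
                                 row.daughter_gt, row.mother_gt, row.father_allele)
        a = assign_parent_of_origin(rec)
        statuses.append(a.status.value)
        pats.append(a.paternal_allele)
        mats.append(a.maternal_allele)
    out = genotypes.copy()
    out["status"] = statuses
    out["paternal_allele"] = pats
    out["maternal_allele"] = mats
    tally = out["status"].value_counts().to_dict()
    logger.info("parent-of-origin assignment: %s", tally)
    return out


def phase_counts(counts: pd.DataFrame, assignments: pd.DataFrame,
                 trios: pd.DataFrame) -> pd.DataFrame:
    """Resolve per-sample ref/alt read counts to paternal/maternal.

    ``counts`` has ``sample_id, chrom, pos, ref, alt, ref_count, alt_count``;
    ``assignments`` is :func:`phase_genotypes` output; ``trios`` maps
    ``trio_id`` to ``daughter_id``. Only daughters' counts can be phased.
    Sites without an ASSIGNED status are dropped (the reason is logged and
    tallied). Zero-coverage records are kept with NaN ratios — the coverage
    filter removes them later.
    """
    daughters = trios.rename(columns={"daughter_id": "sample_id"})[["trio_id", "sample_id"]]
    cts = counts.merge(daughters, on="sample_id", how="inner")
    merged = cts.merge(
        assignments[["trio_id", "chrom", "pos", "status",
                     "paternal_allele", "maternal_allele"]],
        on=["trio_id", "chrom", "pos"], how="left")

    unassigned = merged["status"].isna()
    if unassigned.any():
        logger.warning("%d count records had no genotype record and were dropped",
                       int(unassigned.sum()))
    dropped = merged.loc[~unassigned & (merged["status"] != PhasingStatus.ASSIGNED.value)]
    if len(dropped):
        logger.info("dropped by phasing status: %s",
                    dropped["status"].value_counts().to_dict())
    keep = merged[merged["status"] == PhasingStatus.ASSIGNED.value].copy()

    pat_is_ref = keep["paternal_allele"] == keep["ref"]
    keep["paternal_count"] = np.where(pat_is_ref, keep["ref_count"], keep["alt_count"])
    keep["maternal_count"] = np.where(pat_is_ref, keep["alt_count"], keep["ref_count"])
    total = keep["ref_count"] + keep["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        keep["allelic_ratio"] = np.where(total > 0, keep["alt_count"] / total, np.nan)
        keep["paternal_ratio"] = np.where(total > 0, keep["paternal_count"] / total, np.nan)
    cols = ["sample_id", "trio_id", "chrom", "pos", "ref", "alt",
            "paternal_allele", "maternal_allele",
            "ref_count", "alt_count", "paternal_count", "maternal_count",
            "allelic_ratio", "paternal_ratio"]
    return keep[cols].reset_index(drop=True)
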