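"""Parent-of-origin assignment against a brute-force rule oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xskew.trio_phasing import (Assignment, MissingGenotypeError, PhasingStatus,
                                TrioGenotypeRecord, assign_parent_of_origin,
                                phase_counts, phase_genotypes)


def oracle(daughter: tuple[str, str], father: str, mother: tuple[str, str] | None):
    """Independent enumeration oracle for parent-of-origin assignment.

    Tries every (paternal, maternal) ordering of the daughter's alleles and
    keeps the ones compatible with the parents; exactly one survives for a
    valid heterozygous site.
    """
    if daughter[0] == daughter[1]:
        return ("not_informative", None, None)
    valid = []
    for pat, mat in (daughter, daughter[::-1]):
        if pat != father:
            continue
        if mother is not None and mat not in mother:
            continue
        valid.append((pat, mat))
    if not valid:
        return ("inconsistent", None, None)
    assert len(valid) == 1
    return ("assigned", *valid[0])


ALLELES = ("A", "G", "C")  # ref, alt, and an off-target third allele


def all_genotype_combinations():
    daughters = list(itertools.combinations_with_replacement(("A", "G"), 2))
    mothers = list(itertools.combinations_with_replacement(("A", "G"), 2)) + [None]
    for d, f, m in itertools.product(daughters, ALLELES, mothers):
        yield d, f, m


@pytest.mark.parametrize("daughter,father,mother", list(all_genotype_combinations()))
def test_assignment_matches_enumeration_oracle(daughter, father, mother):
    rec = TrioGenotypeRecord("X", 100, "A", "G", "/".join(daughter),
                             "/".join(mother) if mother else None, father)
    got = assign_parent_of_origin(rec)
    status, pat, mat = oracle(daughter, father, mother)
    assert got.status.value == status
    assert got.paternal_allele == pat
    assert got.maternal_allele == mat
    if status == "assigned":
        assert got.mother_checked is (mother is not None)


@pytest.mark.parametrize("daughter,father,mother,expected", [
    ("A/G", "A", "G/G", ("assigned", "A", "G")),   # forced by hemizygosity
    ("A/A", "A", "A/G", ("not_informative", None, None)),
    ("A/G", "C", "A/G", ("inconsistent", None, None)),
    ("A/G", "A", "A/A", ("inconsistent", None, None)),  # maternal allele absent
])
def test_canonical_cases(daughter, father, mother, expected):
    rec = TrioGenotypeRecord("X", 1, "A", "G", daughter, mother, father)
    got = assign_parent_of_origin(rec)
    assert (got.status.value, got.paternal_allele, got.maternal_allele) == expected


def test_father_dialects():
    # homozygous-diploid spelling of a hemizygous call is accepted
    rec = TrioGenotypeRecord("X", 1, "A", "G", "A/G", "G/G", "A/A")
    assert assign_parent_of_origin(rec).paternal_allele == "A"
    # a genuinely heterozygous father on non-PAR X is impossible
    rec = TrioGenotypeRecord("X", 1, "A", "G", "A/G", "G/G", "A/G")
    assert assign_parent_of_origin(rec).status is PhasingStatus.INCONSISTENT


def test_missing_genotypes():
    with pytest.raises(MissingGenotypeError):
        assign_parent_of_origin(TrioGenotypeRecord("X", 1, "A", "G", None, "A/G", "A"))
    with pytest.raises(MissingGenotypeError):
        assign_parent_of_origin(TrioGenotypeRecord("X", 1, "A", "G", "A/G", "A/G", None))
    got = assign_parent_of_origin(TrioGenotypeRecord("X", 1, "A", "G", "A/G", None, "A"))
    assert got.status is PhasingStatus.ASSIGNED and not got.mother_checked


def _phase_one(ref_count, alt_count, paternal_is_alt):
    genotypes = pd.DataFrame([{
        "trio_id": "T1", "chrom": "X", "pos": 10, "ref": "A", "alt": "G",
        "daughter_gt": "A/G", "mother_gt": "A/G",
        "father_allele": "G" if paternal_is_alt else "A"}])
    counts = pd.DataFrame([{
        "sample_id": "T1-D", "chrom": "X", "pos": 10, "ref": "A", "alt": "G",
        "ref_count": ref_count, "alt_count": alt_count}])
    trios = pd.DataFrame([{"trio_id": "T1", "daughter_id": "T1-D",
                           "mother_id": "T1-M", "father_id": "T1-F"}])
    return phase_counts(counts, phase_genotypes(genotypes), trios).iloc[0]


def test_phase_counts_arithmetic():
    row = _phase_one(3, 7, paternal_is_alt=True)
    assert row["paternal_ratio"] == pytest.approx(0.7)
    assert row["allelic_ratio"] == pytest.approx(0.7)
    row = _phase_one(7, 3, paternal_is_alt=True)
    assert row["paternal_ratio"] == pytest.approx(0.3)
    assert row["allelic_ratio"] == pytest.approx(0.3)


def test_zero_coverage_record_retained_with_nan_ratio():
    row = _phase_one(0, 0, paternal_is_alt=False)
    assert np.isnan(row["paternal_ratio"]) and np.isnan(row["allelic_ratio"])


def test_truth_agreement_on_error_free_cohort(small_cohort):
    """Without injected errors, every het site's assignment matches truth."""
    assignments = phase_genotypes(small_cohort.genotypes)
    merged = assignments.merge(small_cohort.truth.sites,
                               on=["trio_id", "chrom", "pos"], suffixes=("", "_truth"))
    het = merged["status"] == "assigned"
    truth_het = ~merged["site_class"].isin(["homozygous"])
    assert het.equals(truth_het)
    agree = merged.loc[het, "paternal_allele"] == merged.loc[het, "paternal_allele_truth"]
    assert agree.all()
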