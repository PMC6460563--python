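"""SNV filters and ratio summaries on hand-enumerated fixtures."""

import numpy as np
import pandas as pd
import pytest

from xskew.ase_ratios import (filter_snvs, measure_of_balance,
                              summarize_individual, summarize_individuals)

EXONS = pd.DataFrame({"chrom": ["X"] * 2, "start": [100, 5000],
                      "end": [200, 5100], "gene_id": ["GA", "GB"]})
PAR = pd.DataFrame({"chrom": ["X"], "start": [4000], "end": [6000]})


def _records(rows):
    df = pd.DataFrame(rows, columns=["pos", "ref_count", "alt_count"])
    df["chrom"] = "X"
    df["sample_id"] = "S1"
    total = df["ref_count"] + df["alt_count"]
    df["allelic_ratio"] = np.where(total > 0, df["alt_count"] / total, np.nan)
    return df


def test_toy_fixture_filters():
    """Per-record filter outcomes, enumerated by hand.

    Six records: cov 12 exonic non-PAR (keep); cov 8 exonic (low coverage);
    cov 30 intronic (non-exonic); cov 40 exonic but in PAR; cov 10 exonic
    non-PAR (boundary, keep); cov 0 exonic. Two survive.
    """
    recs = _records([
        (150, 6, 6),      # keep
        (151, 4, 4),      # cov 8 < 10
        (900, 15, 15),    # intronic
        (5050, 20, 20),   # exonic but PAR
        (152, 5, 5),      # keep: "at least 10" is inclusive
        (153, 0, 0),      # zero coverage
    ])
    out = filter_snvs(recs, EXONS, PAR, min_coverage=10)
    assert sorted(out["pos"]) == [150, 152]
    assert all(g == ("GA",) for g in out["gene_ids"])


def test_coverage_boundary():
    recs = _records([(150, 4, 5), (151, 4, 6)])  # cov 9 vs cov 10
    out = filter_snvs(recs, EXONS, PAR, min_coverage=10)
    assert out["pos"].tolist() == [151]


def test_bed_half_open_position_convention():
    # BED [100, 200) covers 1-based positions 101..200
    recs = _records([(100, 6, 6), (101, 6, 6), (200, 6, 6), (201, 6, 6)])
    out = filter_snvs(recs, EXONS, PAR, min_coverage=10)
    assert out["pos"].tolist() == [101, 200]


def test_filter_monotone_in_coverage_threshold(small_result):
    phased = small_result.phased
    survivors = []
    for min_cov in (0, 5, 10, 20, 40):
        cov = phased["ref_count"] + phased["alt_count"]
        survivors.append(int((cov >= min_cov).sum()))
    assert survivors == sorted(survivors, reverse=True)


@pytest.mark.parametrize("ref,alt,expected", [
    (7, 3, 0.3), (5, 5, 0.5), (10, 0, 0.0), (0, 10, 0.0), (3, 7, 0.3)])
def test_measure_of_balance(ref, alt, expected):
    assert measure_of_balance(ref, alt) == pytest.approx(expected)


def test_measure_of_balance_zero_coverage_is_nan():
    assert np.isnan(measure_of_balance(0, 0))


def _summary_from_ratios(paternal_ratios, cov=20):
    n = len(paternal_ratios)
    df = pd.DataFrame({
        "sample_id": "S1", "chrom": "X", "pos": np.arange(n) + 1,
        "paternal_ratio": paternal_ratios,
        "allelic_ratio": paternal_ratios,
        "alt_count": (np.asarray(paternal_ratios) * cov).round().astype(int),
    })
    df["ref_count"] = cov - df["alt_count"]
    return summarize_individual(df, "S1")


def test_summary_complete_skew():
    s = _summary_from_ratios([1.0, 1.0, 1.0])
    assert s["Mx"] == 1.0 and s["Sx"] == 0.5


def test_summary_symmetric_set():
    s = _summary_from_ratios([0.4, 0.5, 0.6])
    assert s["Mx"] == pytest.approx(0.5) and s["Sx"] == pytest.approx(0.0)


def test_summary_even_count_median_averages_central_pair():
    s = _summary_from_ratios([0.2, 0.4, 0.6, 1.0])
    assert s["Mx"] == pytest.approx(0.5)


def test_median_balance_equals_folded_ratio_median(small_result):
    """median measure of balance == median of min(r, 1-r) over allelic ratios."""
    for sid, sub in small_result.filtered.groupby("sample_id"):
        mob = np.median(np.minimum(sub["ref_count"], sub["alt_count"])
                        / (sub["ref_count"] + sub["alt_count"]))
        r = sub["allelic_ratio"].to_numpy()
        assert mob == pytest.approx(np.median(np.minimum(r, 1 - r)))


def test_summary_recovers_generating_skew(rng):
    """101 SNVs at theta=0.8, coverage 50: Mx lands inside the binomial CI."""
    theta, cov, n = 0.8, 50, 101
    ratios = rng.binomial(cov, theta, size=n) / cov
    s = _summary_from_ratios(list(ratios), cov=cov)
    from scipy import stats
    lo = stats.binom.ppf(0.001, cov, theta) / cov
    hi = stats.binom.ppf(0.999, cov, theta) / cov
    assert lo <= s["Mx"] <= hi


def test_relabelling_parents_mirrors_mx(small_result):
    flipped = small_result.filtered.copy()
    flipped["paternal_ratio"] = 1 - flipped["paternal_ratio"]
    orig = summarize_individuals(small_result.filtered)
    mirr = summarize_individuals(flipped)
    assert np.allclose(mirr["Mx"], 1 - orig["Mx"])
    assert np.allclose(mirr["Sx"], orig["Sx"])
    assert np.allclose(mirr["median_measure_of_balance"],
                       orig["median_measure_of_balance"])


def test_empty_sample_flagged_uninformative():
    out = summarize_individuals(_records([]), sample_ids=["S9"])
    assert not out.loc[out["sample_id"] == "S9", "informative"].iloc[0]
    assert np.isnan(out.loc[out["sample_id"] == "S9", "Mx"].iloc[0])
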