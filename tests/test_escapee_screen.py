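"""Gene-level escape test: frozen oracle values, edge cases, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from xskew import CohortConfig, generate_cohort, run_pipeline_from_data
from xskew.escapee_screen import (escape_test, gene_sample_medians,
                                  run_escape_screen, xist_check)


def _gene_frame(sx, sg, agree=None, gene_id="G1"):
    n = len(sx)
    agree = [True] * n if agree is None else agree
    return pd.DataFrame({
        "gene_id": gene_id, "sample_id": [f"S{i}" for i in range(n)],
        "n_snvs": 1, "Mg": 0.5 + np.where(agree, sg, -np.asarray(sg)),
        "Sg": sg, "Mx": 0.5 + np.asarray(sx), "Sx": sx,
        "agrees_with_chromosome": agree,
        "ref_reads": 10, "total_reads": 20})


def test_paired_t_matches_precomputed_oracle():
    """Values frozen from an independent textbook paired-t computation."""
    res = escape_test(_gene_frame(sx=[0.30, 0.25, 0.35, 0.40, 0.28],
                                  sg=[0.05, 0.02, 0.10, 0.00, 0.04]))
    assert res.t_statistic == pytest.approx(8.6388, abs=1e-3)
    assert res.degrees_of_freedom == 4
    assert res.p_value == pytest.approx(4.937e-4, rel=1e-3)
    assert res.escapee_call


def test_disagreeing_gene_strengthens_evidence():
    """Disagreement contributes Sx + Sg: same spread, larger mean difference."""
    sx = [0.30, 0.25, 0.35, 0.40, 0.28]
    agree = escape_test(_gene_frame(sx, [0.1] * 5))
    disagree = escape_test(_gene_frame(sx, [0.1] * 5, agree=[False] * 5))
    assert disagree.t_statistic > agree.t_statistic
    assert disagree.p_value < agree.p_value


def test_zero_variance_untestable():
    res = escape_test(_gene_frame([0.3] * 5, [0.3] * 5))
    assert not res.testable and not res.escapee_call and np.isnan(res.p_value)


def test_minimum_sample_requirement():
    with pytest.raises(ValueError):
        escape_test(_gene_frame([0.3] * 4, [0.1] * 4))


def test_direction_variants_are_complementary():
    frame = _gene_frame(sx=[0.30, 0.25, 0.35, 0.40, 0.28],
                        sg=[0.05, 0.02, 0.10, 0.00, 0.04])
    less = escape_test(frame, direction="gene_less_skewed")
    more = escape_test(frame, direction="gene_more_skewed")
    assert less.p_value + more.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        escape_test(frame, direction="sideways")


def test_gene_sample_medians_basic(small_result):
    classified = small_result.summaries[small_result.summaries["role"] == "daughter"]
    audit = gene_sample_medians(small_result.filtered, classified)
    one = audit[audit["n_snvs"] == 1]
    assert len(one) > 0
    merged = one.merge(small_result.filtered.explode("gene_ids")
                       .rename(columns={"gene_ids": "gene_id"}),
                       on=["gene_id", "sample_id"])
    assert np.allclose(merged["Mg"], merged["paternal_ratio"])


def test_median_of_three_and_tie_agreement():
    recs = pd.DataFrame({
        "sample_id": "S1", "gene_ids": [("G1",)] * 3, "pos": [1, 2, 3],
        "paternal_ratio": [0.1, 0.2, 0.9], "ref_count": 10, "alt_count": 10})
    summaries = pd.DataFrame({"sample_id": ["S1"], "Mx": [0.9]})
    audit = gene_sample_medians(recs, summaries)
    assert audit["Mg"].iloc[0] == pytest.approx(0.2)
    # tie case: Mg exactly 0.5 counts as agreement with Sg = 0
    recs2 = recs.assign(paternal_ratio=[0.4, 0.5, 0.6])
    audit2 = gene_sample_medians(recs2, summaries)
    assert audit2["Sg"].iloc[0] == 0.0 and bool(audit2["agrees_with_chromosome"].iloc[0])


@pytest.fixture(scope="module")
def escapee_cohort():
    """Strongly powered cohort: full escapees only, deep coverage."""
    c = generate_cohort(CohortConfig(n_trios=80, n_genes=40, escapee_fraction=0.25,
                                     variable_escapee_fraction=0.0,
                                     min_coverage=30, coverage_mean=60, seed=9))
    res = run_pipeline_from_data(c.genotypes, c.counts, c.exons, c.par, c.trios)
    return c, res


def test_escapee_genes_less_skewed_than_chromosome(escapee_cohort):
    c, res = escapee_cohort
    status = c.truth.genes.set_index("gene_id")["status"]
    audit = res.escape_audit.copy()
    audit["true_status"] = status.reindex(audit["gene_id"]).to_numpy()
    esc = audit[audit["true_status"] == "escapee"]
    assert esc["Sg"].mean() < esc["Sx"].mean()


def test_screen_recovers_true_escapees(escapee_cohort):
    c, res = escapee_cohort
    status = c.truth.genes.set_index("gene_id")["status"]
    r = res.escape_results[res.escape_results["testable"]].copy()
    r["true_status"] = status.reindex(r["gene_id"]).to_numpy()
    esc = r[r["true_status"] == "escapee"]
    ina = r[(r["true_status"] == "inactivated")]
    assert len(esc) >= 3
    assert esc["escapee_call"].mean() >= 0.8
    assert ina["escapee_call"].mean() <= 0.15
    assert (r["n_samples"] >= 5).all()


def test_screen_determinism(escapee_cohort):
    c, res = escapee_cohort
    again = run_pipeline_from_data(c.genotypes, c.counts, c.exons, c.par, c.trios)
    pd.testing.assert_frame_equal(res.escape_results, again.escape_results)


def test_no_skewed_individuals_yields_empty_screen(small_result):
    balanced = small_result.summaries[small_result.summaries["role"] == "daughter"].copy()
    balanced["skewed"] = False
    results, audit, counts = run_escape_screen(small_result.filtered, balanced)
    assert len(results) == 0 and counts["n_skewed_individuals"] == 0


def test_xist_opposition(escapee_cohort):
    c, res = escapee_cohort
    x = res.cohort_report["xist_check"]
    assert x["status"] == "ok"
    assert x["fraction_opposed"] >= 0.9


def test_xist_check_flags():
    audit = pd.DataFrame({
        "gene_id": ["XIST", "XIST"], "sample_id": ["S1", "S2"],
        "Mg": [0.1, 0.9], "Mx": [0.9, 0.9], "Sg": [0.4, 0.4],
        "Sx": [0.4, 0.4], "n_snvs": 1,
        "agrees_with_chromosome": [False, True],
        "ref_reads": 1, "total_reads": 2})
    classified = pd.DataFrame({"sample_id": ["S1", "S2"], "skewed": [True, True]})
    out = xist_check(audit, classified)
    flags = {p["sample_id"]: p["opposed"] for p in out["per_sample"]}
    assert flags == {"S1": True, "S2": False}
    assert out["fraction_opposed"] == pytest.approx(0.5)


def test_xist_uninformative_when_absent():
    audit = pd.DataFrame(columns=["gene_id", "sample_id", "Mg", "Mx", "Sg",
                                  "Sx", "n_snvs", "agrees_with_chromosome",
                                  "ref_reads", "total_reads"])
    classified = pd.DataFrame({"sample_id": ["S1"], "skewed": [True]})
    assert xist_check(audit, classified)["status"] == "uninformative"
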