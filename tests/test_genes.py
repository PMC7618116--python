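import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_two_sided, percentile_by_sorting
from synquant.genes import (
    GeneRecord,
    classify_deg,
    filter_expressed,
    genes_from_table,
    overlap_enrichment,
    score_candidates,
)
from synquant.simulate import simulate_gene_table


def gene(gid="g", fc=2.0, p=0.01, direction="up", rpkm=10.0, **criteria):
    return GeneRecord(gid, fc, p, direction, rpkm, criteria=dict(criteria))


# ------------------------------------------------------------ expression


def test_expressed_filter_against_sorting_percentile_oracle(rng):
    bg = rng.lognormal(0, 1, 1000)
    cutoff = percentile_by_sorting(bg, 99)
    genes = [
        gene("hi", rpkm=percentile_by_sorting(bg, 99.5)),
        gene("lo", rpkm=percentile_by_sorting(bg, 95)),
    ]
    kept, meta = filter_expressed(genes, bg)
    assert [g.gene_id for g in kept] == ["hi"]
    assert meta["cutoff"] == pytest.approx(cutoff, rel=1e-9)
    assert meta["mode"] == "percentile"


def test_all_zero_background_keeps_any_expressed_gene():
    genes = [gene("a", rpkm=0.001), gene("b", rpkm=0.0)]
    kept, _ = filter_expressed(genes, np.zeros(50))
    assert [g.gene_id for g in kept] == ["a"]


def test_scalar_mode_uses_literal_99_percent_rule():
    genes = [gene("a", rpkm=1.0), gene("b", rpkm=0.98)]
    kept, meta = filter_expressed(genes, np.array([1.0]), mode="scalar")
    assert meta["cutoff"] == pytest.approx(0.99)
    assert [g.gene_id for g in kept] == ["a"]
    with pytest.raises(ValueError):
        filter_expressed(genes, np.array([]))


def test_filter_monotone_in_rpkm(rng):
    bg = rng.lognormal(0, 1, 500)
    lo = [gene(f"g{i}", rpkm=v) for i, v in enumerate(rng.lognormal(0, 1, 100))]
    hi = [gene(g.gene_id, rpkm=g.rpkm * 2) for g in lo]
    kept_lo = {g.gene_id for g in filter_expressed(lo, bg)[0]}
    kept_hi = {g.gene_id for g in filter_expressed(hi, bg)[0]}
    assert kept_lo <= kept_hi


# ------------------------------------------------------------------ DEGs


def test_deg_thresholds_inclusive_at_boundary():
    records = [
        gene("boundary", fc=1.5, p=0.05, direction="down"),
        gene("strong_small_fc", fc=1.4, p=0.001),
        gene("weak_big_fc", fc=3.0, p=0.06),
        gene("clear", fc=1.6, p=0.04, direction="down"),
    ]
    res = classify_deg(records)
    assert {g.gene_id for g in res["down"]} == {"boundary", "clear"}
    assert res["up"] == []


def test_proportion_down_arithmetic():
    records = [gene(f"d{i}", direction="down") for i in range(7)] + [
        gene(f"u{i}") for i in range(3)
    ]
    assert classify_deg(records)["proportion_down"] == pytest.approx(0.7)
    assert np.isnan(classify_deg([gene("x", fc=1.0)])["proportion_down"])


def test_simulated_table_recovers_planted_down_fraction():
    genes, truth = simulate_gene_table(n_genes=5000, frac_de=0.04, seed=21)
    n_de = len(truth.de_ids)
    res = classify_deg(genes)
    prop = res["proportion_down"]
    half_width = 1.96 * np.sqrt(0.7 * 0.3 / n_de)
    assert abs(prop - 0.7) < half_width + 0.02
    # essentially no false positives among null genes
    called = {g.gene_id for g in res["up"] + res["down"]}
    assert len(called - truth.de_ids) <= max(3, 0.001 * len(genes))


# ------------------------------------------------------------ candidates


CRITERIA = ["expr_p10", "expr_p30", "pv_enriched", "literature"]


def crit(*met):
    return {c: (c in met) for c in CRITERIA}


def test_candidate_scoring_ranks_and_floors():
    genes = [
        GeneRecord("all4", 2, 0.01, "down", rpkm=20, criteria=crit(*CRITERIA)),
        GeneRecord("three", 2, 0.01, "down", rpkm=20, criteria=crit(*CRITERIA[:3])),
        GeneRecord("low_expr", 2, 0.01, "down", rpkm=4.9, criteria=crit(*CRITERIA)),
        GeneRecord("none", 2, 0.01, "down", rpkm=20, criteria=crit()),
    ]
    df = score_candidates(genes, CRITERIA)
    assert list(df.gene_id) == ["all4", "three", "none"]  # low_expr removed
    assert list(df.score) == [4, 3, 0]
    top = score_candidates(genes, CRITERIA, min_score=3)
    assert set(top.gene_id) == {"all4", "three"}


def test_min_score_filter_matches_brute_force_count(rng):
    genes = []
    for i in range(50):
        met = [c for c in CRITERIA if rng.uniform() < 0.5]
        genes.append(
            GeneRecord(f"g{i:02d}", 2, 0.01, "down", rpkm=10, criteria=crit(*met))
        )
    expected = sum(1 for g in genes if sum(g.criteria.values()) >= 3)
    assert len(score_candidates(genes, CRITERIA, min_score=3)) == expected
    # ties broken alphabetically within equal scores
    df = score_candidates(genes, CRITERIA)
    for s in df.score.unique():
        ids = list(df[df.score == s].gene_id)
        assert ids == sorted(ids)


def test_missing_criterion_column_raises():
    g = GeneRecord("x", 2, 0.01, "down", rpkm=10, criteria={"expr_p10": True})
    with pytest.raises(KeyError):
        score_candidates([g], CRITERIA)


# ------------------------------------------------------------ enrichment


def test_fold_enrichment_worked_example():
    query = [f"q{i}" for i in range(90)] + [f"shared{i}" for i in range(10)]
    ref = [f"shared{i}" for i in range(10)] + [f"r{i}" for i in range(190)]
    res = overlap_enrichment(query, ref, 20_000)
    assert res.fold_enrichment == pytest.approx((10 / 100) / (200 / 20_000))
    assert res.fold_enrichment == 10.0
    assert res.overlap_count == 10


def test_zero_overlap_gives_zero_fold_and_oracle_p():
    query = [f"q{i}" for i in range(20)]
    ref = [f"r{i}" for i in range(30)]
    res = overlap_enrichment(query, ref, 500)
    assert res.fold_enrichment == 0.0
    assert res.p_value == pytest.approx(fisher_two_sided(0, 20, 30, 500), abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    q=st.integers(1, 15),
    r=st.integers(1, 15),
    extra=st.integers(0, 15),
    k_frac=st.floats(0, 1),
)
def test_fisher_p_matches_enumeration_oracle(q, r, extra, k_frac):
    universe = q + r + extra
    k = int(round(k_frac * min(q, r)))
    query = [f"s{i}" for i in range(k)] + [f"q{i}" for i in range(q - k)]
    ref = [f"s{i}" for i in range(k)] + [f"r{i}" for i in range(r - k)]
    res = overlap_enrichment(query, ref, universe)
    assert res.p_value == pytest.approx(fisher_two_sided(k, q, r, universe), abs=1e-10)


def test_fisher_symmetric_in_query_and_reference():
    a = [f"x{i}" for i in range(40)] + [f"s{i}" for i in range(5)]
    b = [f"y{i}" for i in range(25)] + [f"s{i}" for i in range(5)]
    p1 = overlap_enrichment(a, b, 1000).p_value
    p2 = overlap_enrichment(b, a, 1000).p_value
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_enrichment_input_validation():
    with pytest.raises(ValueError, match="empty query"):
        overlap_enrichment([], ["a"], 10)
    with pytest.raises(ValueError, match="universe"):
        overlap_enrichment(["a"], ["b", "c"], 2)


def test_fold_enrichment_unity_at_expectation():
    # overlap k = q·r/U exactly → fold enrichment 1
    q, r, universe, k = 20, 50, 1000, 1
    query = ["s0"] + [f"q{i}" for i in range(q - 1)]
    ref = ["s0"] + [f"r{i}" for i in range(r - 1)]
    res = overlap_enrichment(query, ref, universe)
    assert res.fold_enrichment == pytest.approx(1.0)


# ------------------------------------------------------------ table round-trip


def test_genes_from_table_roundtrip():
    import pandas as pd

    df = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "fold_change": [2.0, 1.2],
            "p_value": [0.01, 0.5],
            "direction": ["down", "up"],
            "rpkm": [10.0, 3.0],
            "expr_p10": [True, False],
        }
    )
    genes = genes_from_table(df, criteria_names=["expr_p10"])
    assert genes[0].criteria == {"expr_p10": True}
    assert genes[1].direction == "up"
    with pytest.raises(ValueError):
        GeneRecord("bad", fold_change=2.0, p_value=1.5)
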