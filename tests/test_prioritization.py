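"""Co-expression scoring, score algebra, and ranked target tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bgcoex import (
    BgcRegion,
    ConfigError,
    FoldChangeTable,
    FunctionalMap,
    GeneCatalog,
    coexpression_score,
    rank_and_filter,
    score_all,
)
from bgcoex.prioritization import ScoreRecord


def test_score_hand_example_and_sign_flip():
    rec = coexpression_score({"e1": 2.0, "e2": -1.0}, {"e1": 2.0, "e2": -1.0}, ["e1", "e2"])
    assert rec.contributions == {"e1": 4.0, "e2": 1.0}
    assert rec.score == 5.0 and rec.concordance == "concordant"
    flipped = coexpression_score({"e1": -2.0, "e2": 1.0}, {"e1": 2.0, "e2": -1.0}, ["e1", "e2"])
    assert flipped.score == -5.0 and flipped.concordance == "discordant"


def test_zero_gene_scores_zero_and_has_no_concordance():
    rec = coexpression_score({"e1": 0.0, "e2": 0.0}, {"e1": 2.0, "e2": -1.0}, ["e1", "e2"])
    assert rec.score == 0.0 and rec.concordance is None


def test_filtered_experiments_contribute_nothing_and_leave_combination():
    rec = coexpression_score({"e1": 3.0, "e2": float("nan")}, {"e1": 2.0, "e2": 5.0}, ["e1", "e2"])
    assert rec.combination == {"e1"} and rec.score == 6.0
    assert coexpression_score({"e1": float("nan")}, {"e1": 2.0}, ["e1"]) is None


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    bfc=st.lists(st.floats(-4, 4), min_size=4, max_size=4),
    gfc=st.lists(st.floats(-4, 4), min_size=4, max_size=4),
)
def test_score_additivity_over_disjoint_experiment_sets(bfc, gfc):
    exps = ["e1", "e2", "e3", "e4"]
    b = dict(zip(exps, bfc))
    g = dict(zip(exps, gfc))
    full = coexpression_score(g, b, exps).score
    left = coexpression_score(g, b, exps[:2]).score
    right = coexpression_score(g, b, exps[2:]).score
    assert full == pytest.approx(left + right, rel=1e-12, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(b=st.floats(-4, 4), g=st.floats(-4, 4))
def test_sign_symmetry_of_contributions(b, g):
    """Negating both fold changes leaves the contribution unchanged;
    negating only the gene's negates it."""
    base = coexpression_score({"e1": g}, {"e1": b}, ["e1"]).score
    joint = coexpression_score({"e1": -g}, {"e1": -b}, ["e1"]).score
    gene_only = coexpression_score({"e1": -g}, {"e1": b}, ["e1"]).score
    assert joint == base and gene_only == -base


# --- score_all against the brute-force oracle --------------------------------

def toy_catalog(genes, bgc_block):
    starts = np.arange(len(genes)) * 1000 + 1
    table = pd.DataFrame(
        {"contig": "chr1", "start": starts, "end": starts + 500, "strand": "+",
         "length": 501},
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneCatalog(table=table)


def naive_score_all(fc_df, bgc_fc, gene_ids, selected):
    """Triple-nested-loop reference for the scoring rule."""
    out = {}
    for g in gene_ids:
        contributions = {}
        for e in selected:
            gv = fc_df.loc[g, e]
            bv = bgc_fc[e]
            if np.isfinite(gv) and np.isfinite(bv):
                contributions[e] = bv * gv
        if contributions:
            total = 0.0
            for e in selected:
                if e in contributions:
                    total = total + contributions[e]
            out[g] = (total, contributions)
    return out


@pytest.mark.parametrize("seed", range(3))
def test_score_all_equals_nested_loop_reference_exactly(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(50)]
    exps = [f"e{j}" for j in range(1, 7)]
    vals = rng.normal(0, 2, (50, 6))
    mask = rng.random((50, 6)) < 0.85
    fc_df = pd.DataFrame(np.where(mask, vals, np.nan),
                         index=pd.Index(genes, name="gene_id"), columns=exps)
    fct = FoldChangeTable(log2fc=fc_df, expressed=pd.DataFrame(mask, index=fc_df.index, columns=exps))
    bgc = BgcRegion("r1", "chr1", 1, 2000, frozenset(genes[:2]), frozenset(genes[:1]))
    bgc_fc = {e: float(rng.normal(0, 2)) for e in exps}
    records = score_all(fct, bgc_fc, toy_catalog(genes, 2), FunctionalMap(), bgc,
                        selected=exps, exclude_members=False)
    expected = naive_score_all(fc_df, bgc_fc, genes, exps)
    assert {r.gene_id for r in records} == set(expected)
    for r in records:
        total, contributions = expected[r.gene_id]
        assert r.score == total  # exact: same accumulation order
        assert r.contributions == contributions


def test_self_score_is_sum_of_squared_bgc_fold_changes():
    exps = ["e1", "e2", "e3"]
    bgc_fc = {"e1": 2.0, "e2": -1.5, "e3": 0.5}
    rec = coexpression_score(bgc_fc, bgc_fc, exps)
    assert rec.score == pytest.approx(sum(v * v for v in bgc_fc.values()))


def test_member_exclusion_and_kegg_sharing():
    genes = ["g000", "g001", "g002", "g003"]
    exps = ["e1"]
    fc_df = pd.DataFrame([[1.0], [2.0], [3.0], [-1.0]],
                         index=pd.Index(genes, name="gene_id"), columns=exps)
    fct = FoldChangeTable(log2fc=fc_df, expressed=fc_df.notna())
    bgc = BgcRegion("r1", "chr1", 1, 2000, frozenset({"g000", "g001"}), frozenset({"g000"}))
    functional = FunctionalMap(
        category={"g002": "transport"},
        kegg_pathways={"g000": frozenset({"map01059"}), "g002": frozenset({"map01059"})},
    )
    records = score_all(fct, {"e1": 1.0}, toy_catalog(genes, 2), functional, bgc)
    ids = {r.gene_id for r in records}
    assert ids == {"g002", "g003"}  # members excluded by default
    by_id = {r.gene_id: r for r in records}
    assert by_id["g002"].same_kegg_as_bgc is True
    assert by_id["g003"].same_kegg_as_bgc is False
    with_members = score_all(fct, {"e1": 1.0}, toy_catalog(genes, 2), functional, bgc,
                             exclude_members=False)
    assert {r.gene_id for r in with_members} == set(genes)


# --- ranking and filtering --------------------------------------------------

def rec(gene_id, score, category="other", kegg=False):
    return ScoreRecord(
        gene_id=gene_id, score=score, contributions={"e1": score},
        combination=frozenset({"e1"}),
        concordance="concordant" if score > 0 else "discordant" if score < 0 else None,
        category=category, same_kegg_as_bgc=kegg,
    )


def test_rank_split_sort_and_zero_exclusion():
    records = [rec("a", 5.0), rec("b", -3.0), rec("c", 2.0), rec("d", 0.0)]
    conc, disc = rank_and_filter(records, ["e1"])
    assert conc.table["gene_id"].tolist() == ["a", "c"]
    assert disc.table["gene_id"].tolist() == ["b"]
    assert "d" not in set(conc.table["gene_id"]) | set(disc.table["gene_id"])


def test_ties_break_lexicographically():
    records = [rec("z", 2.0), rec("a", 2.0), rec("m", 2.0)]
    conc, _ = rank_and_filter(records, ["e1"])
    assert conc.table["gene_id"].tolist() == ["a", "m", "z"]


def test_category_filter_keeps_order_and_class():
    records = [rec("a", 5.0, "regulation"), rec("b", 4.0, "transport"),
               rec("c", 3.0, "regulation"), rec("d", -2.0, "regulation")]
    conc, disc = rank_and_filter(records, ["e1"], category_filter="regulation")
    assert conc.table["gene_id"].tolist() == ["a", "c"]
    assert disc.table["gene_id"].tolist() == ["d"]
    conc_kegg, _ = rank_and_filter([rec("a", 1.0, kegg=True), rec("b", 2.0)],
                                   ["e1"], category_filter="same_kegg_as_bgc")
    assert conc_kegg.table["gene_id"].tolist() == ["a"]


def test_unknown_category_lists_valid_names():
    with pytest.raises(ConfigError, match="regulation.*same_kegg_as_bgc"):
        rank_and_filter([rec("a", 1.0)], ["e1"], category_filter="mystery")


def test_contributions_sum_to_score_in_tables():
    records = [rec("a", 5.0), rec("b", -3.0)]
    conc, disc = rank_and_filter(records, ["e1"])
    for table in (conc.table, disc.table):
        np.testing.assert_allclose(table["contrib_e1"], table["score"])
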