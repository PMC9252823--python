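"""Cluster-level aggregation and expressed/silent labelling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bgcoex import (
    BgcRegion,
    ConfigError,
    ExperimentDesign,
    FoldChangeTable,
    UndefinedReferenceError,
    bgc_expression,
    bgc_fold_change,
    classify_expression,
    reference_levels,
)


@pytest.fixture
def design():
    return ExperimentDesign(
        condition_of={"s1": "A", "s2": "A", "s3": "B"},
        experiments=(("e1", "A", "B"),),
    )


def tpm_frame(values, genes, samples):
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)


def region(core, members=None, start=1, end=10_000):
    members = members or core
    return BgcRegion("r1", "chr1", start, end, frozenset(members), frozenset(core))


def fc_table(log2fc, expressed, genes, experiments):
    fc = pd.DataFrame(log2fc, index=pd.Index(genes, name="gene_id"), columns=experiments)
    ex = pd.DataFrame(expressed, index=fc.index, columns=experiments, dtype=bool)
    return FoldChangeTable(log2fc=fc.where(ex), expressed=ex)


# --- reference levels -------------------------------------------------------

def test_reference_level_hand_example():
    tpm = tpm_frame([[100], [300], [10], [30]], ["g1", "g2", "g3", "g4"], ["s1"])
    ref = reference_levels(tpm, {"g1", "g2"})
    row = ref.per_sample.loc["s1"]
    assert (row["hk_mean"], row["non_hk_mean"], row["all_mean"]) == (200.0, 20.0, 110.0)


def test_all_genes_housekeeping_makes_hk_equal_all():
    tpm = tpm_frame([[100], [300]], ["g1", "g2"], ["s1"])
    ref = reference_levels(tpm, {"g1", "g2"})
    assert ref.per_sample.loc["s1", "hk_mean"] == ref.per_sample.loc["s1", "all_mean"]


def test_disjoint_housekeeping_set_rejected():
    tpm = tpm_frame([[100]], ["g1"], ["s1"])
    with pytest.raises(ConfigError, match="disjoint"):
        reference_levels(tpm, {"gX"})


def test_all_mean_between_hk_and_non_hk(design):
    rng = np.random.default_rng(5)
    tpm = tpm_frame(rng.uniform(0, 500, (20, 3)), [f"g{i}" for i in range(20)],
                    ["s1", "s2", "s3"])
    ref = reference_levels(tpm, {f"g{i}" for i in range(6)}, design=design)
    for _, row in ref.per_condition.iterrows():
        lo, hi = sorted([row["hk_mean"], row["non_hk_mean"]])
        assert lo <= row["all_mean"] <= hi


# --- cluster expression -----------------------------------------------------

def test_bgc_expression_condition_means(design):
    tpm = tpm_frame([[40, 60, 10], [140, 160, 30]], ["g1", "g2"], ["s1", "s2", "s3"])
    out = bgc_expression(region(["g1", "g2"]), tpm, design)
    assert out["A"] == pytest.approx(100.0)  # mean(mean(40,60), mean(140,160))
    assert out["B"] == pytest.approx(20.0)


def test_single_core_gene_is_identity(design):
    tpm = tpm_frame([[80, 80, 80]], ["g1"], ["s1", "s2", "s3"])
    out = bgc_expression(region(["g1"]), tpm, design)
    assert out["A"] == 80.0


def test_silent_core_gene_drags_the_mean(design):
    tpm = tpm_frame([[0, 0, 0], [80, 80, 80]], ["g1", "g2"], ["s1", "s2", "s3"])
    out = bgc_expression(region(["g1", "g2"]), tpm, design)
    assert out["A"] == pytest.approx(40.0)


def test_core_gene_order_never_matters(design):
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(8)]
    tpm = tpm_frame(rng.uniform(0, 100, (8, 3)), genes, ["s1", "s2", "s3"])
    a = bgc_expression(region(genes), tpm, design)
    b = bgc_expression(region(genes[::-1]), tpm, design)
    pd.testing.assert_series_equal(a, b)


# --- classification ---------------------------------------------------------

def test_classification_examples():
    assert classify_expression(150.0, 100.0, 1.0) == (1.5, True)
    assert classify_expression(100.0, 100.0, 1.0)[1] is True  # inclusive boundary
    assert classify_expression(150.0, 100.0, 2.0)[1] is False


def test_zero_reference_is_an_explicit_error():
    with pytest.raises(UndefinedReferenceError):
        classify_expression(10.0, 0.0, 1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    tpm=st.floats(0, 1e5), ref=st.floats(1e-3, 1e5),
    m1=st.floats(0.1, 10), m2=st.floats(0.1, 10),
)
def test_classification_monotone_in_tpm_antitone_in_multiplier(tpm, ref, m1, m2):
    ratio, expressed = classify_expression(tpm, ref, m1)
    ratio_hi, expressed_hi = classify_expression(tpm * 2 + 1, ref, m1)
    assert ratio_hi > ratio and (expressed_hi or not expressed)
    lo, hi = sorted([m1, m2])
    assert classify_expression(tpm, ref, hi)[1] <= classify_expression(tpm, ref, lo)[1]


# --- cluster fold change ----------------------------------------------------

def test_bgc_fold_change_means_and_symmetry():
    fct = fc_table([[2.0], [4.0]], [[True], [True]], ["g1", "g2"], ["e1"])
    assert bgc_fold_change(region(["g1", "g2"]), fct, "e1") == pytest.approx(3.0)
    fct2 = fc_table([[2.0], [-2.0]], [[True], [True]], ["g1", "g2"], ["e1"])
    assert bgc_fold_change(region(["g1", "g2"]), fct2, "e1") == pytest.approx(0.0)


def test_filtered_core_gene_excluded_from_fold_change_mean():
    fct = fc_table([[2.0], [9.0]], [[True], [False]], ["g1", "g2"], ["e1"])
    assert bgc_fold_change(region(["g1", "g2"]), fct, "e1") == pytest.approx(2.0)


def test_no_evaluable_core_gene_yields_missing_marker():
    fct = fc_table([[2.0]], [[False]], ["g1"], ["e1"])
    assert np.isnan(bgc_fold_change(region(["g1"]), fct, "e1"))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_bgc_fold_change_bounded_by_core_extremes(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]
    vals = rng.normal(0, 3, (6, 1))
    fct = fc_table(vals, np.ones((6, 1), dtype=bool), genes, ["e1"])
    out = bgc_fold_change(region(genes), fct, "e1")
    assert vals.min() <= out <= vals.max()
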