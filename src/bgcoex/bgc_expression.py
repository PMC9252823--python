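"""Cluster-level aggregation and the expressed/not-expressed label.

A cluster is represented by the arithmetic mean of its core biosynthetic
genes: mean TPM for expression level, mean log2 fold change (i.e. geometric
mean of the linear fold changes) for regulation.  Zero-TPM core genes drag
the expression mean down by design — a silent gene is evidence of a silent
cluster — while fold-change means skip genes that failed the expression
filter, and a cluster with no evaluable core gene in an experiment is
marked missing rather than zero.

Because no exact threshold separates an expressed from a silent cluster,
the label is relative: cluster TPM is compared against a reference level
derived from housekeeping genes (constitutively expressed essentials),
their complement, or all genes, scaled by a user multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_model import (
    BgcRegion,
    ConfigError,
    ExperimentDesign,
    FoldChangeTable,
    GeneCatalog,
    REFERENCE_MODES,
)


class UndefinedReferenceError(ValueError):
    """The requested reference expression level is zero or unavailable."""


@dataclass(frozen=True)
class ReferenceLevels:
    """Mean TPM of housekeeping / non-housekeeping / all genes.

    ``per_sample`` has one row per sample with columns ``hk_mean``,
    ``non_hk_mean``, ``all_mean``; ``per_condition`` averages those rows
    over each condition's samples when a design is supplied.
    """

    per_sample: pd.DataFrame
    per_condition: Optional[pd.DataFrame] = None

    def value(self, mode: str, condition: Optional[str] = None, sample: Optional[str] = None) -> float:
        if mode not in REFERENCE_MODES:
            raise ConfigError(
                f"unknown reference mode {mode!r}; valid: {', '.join(REFERENCE_MODES)}"
            )
        col = f"{mode}_mean"
        if condition is not None:
            if self.per_condition is None:
                raise ConfigError("no design supplied: condition-level reference unavailable")
            return float(self.per_condition.loc[condition, col])
        if sample is not None:
            return float(self.per_sample.loc[sample, col])
        raise ConfigError("reference lookup needs a condition or a sample")


def reference_levels(
    tpm: pd.DataFrame,
    hk: frozenset[str] | set[str],
    design: Optional[ExperimentDesign] = None,
    catalog: Optional[GeneCatalog] = None,
) -> ReferenceLevels:
    """Per-sample (and, with a design, per-condition) reference TPM means.

    The housekeeping set may be empty, in which case only ``non_hk_mean``
    (= ``all_mean``) is meaningful and hk-mode classification will fail
    downstream with an explicit error.
    """
    hk = frozenset(hk)
    if catalog is not None:
        missing = hk - set(catalog.gene_ids)
        if missing:
            raise ConfigError(
                f"housekeeping gene(s) not in catalog: {', '.join(sorted(missing)[:5])}"
            )
    unknown = hk - set(tpm.index)
    if hk and unknown == hk:
        raise ConfigError("housekeeping set is disjoint from the expression matrix")
    is_hk = tpm.index.isin(hk)
    per_sample = pd.DataFrame(
        {
            "hk_mean": tpm.loc[is_hk].mean(axis=0) if is_hk.any() else np.nan,
            "non_hk_mean": tpm.loc[~is_hk].mean(axis=0) if (~is_hk).any() else np.nan,
            "all_mean": tpm.mean(axis=0),
        }
    )
    per_condition = None
    if design is not None:
        rows = {
            cond: per_sample.loc[design.samples_of(cond)].mean(axis=0)
            for cond in design.conditions
        }
        per_condition = pd.DataFrame(rows).T
        per_condition.index.name = "condition"
    return ReferenceLevels(per_sample=per_sample, per_condition=per_condition)


def bgc_expression(
    bgc: BgcRegion, tpm: pd.DataFrame, design: ExperimentDesign
) -> pd.Series:
    """Per-condition cluster expression: mean over core genes of each
    condition's mean TPM.  Zero-TPM core genes count toward the mean."""
    core = sorted(bgc.core_genes)
    missing = [g for g in core if g not in tpm.index]
    if missing:
        raise ConfigError(
            f"region {bgc.region_id!r}: core gene {missing[0]!r} absent from TPM matrix"
        )
    core_tpm = tpm.loc[core]
    values = {
        cond: float(core_tpm[design.samples_of(cond)].mean(axis=1).mean())
        for cond in design.conditions
    }
    return pd.Series(values, name=bgc.region_id)


def classify_expression(
    bgc_tpm: float, ref_value: float, multiplier: float = 1.0
) -> tuple[float, bool]:
    """Label a cluster expressed when its TPM reaches ``multiplier`` times
    the reference level (inclusive boundary).  Returns (ratio, expressed)."""
    if multiplier <= 0:
        raise ConfigError("multiplier must be positive")
    if not np.isfinite(ref_value) or ref_value <= 0:
        raise UndefinedReferenceError(
            f"reference expression level is {ref_value!r}; cannot classify"
        )
    ratio = bgc_tpm / ref_value
    return ratio, bool(ratio >= multiplier)


def bgc_fold_change(bgc: BgcRegion, fc: FoldChangeTable, experiment: str) -> float:
    """Mean log2 fold change over the cluster's core genes that passed the
    expression filter in this experiment; NaN when none did."""
    if experiment not in fc.log2fc.columns:
        raise ConfigError(f"experiment {experiment!r} not in fold-change table")
    core = sorted(bgc.core_genes & set(fc.log2fc.index))
    vals = fc.log2fc.loc[core, experiment].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def summarize_bgc(
    bgc: BgcRegion,
    tpm: pd.DataFrame,
    fc: FoldChangeTable,
    design: ExperimentDesign,
    ref: Optional[ReferenceLevels] = None,
    mode: str = "all",
    multiplier: float = 1.0,
) -> pd.DataFrame:
    """One-row summary table for a cluster: per-experiment mean core-gene
    log2 fold change, per-condition core-gene TPM, and — when reference
    levels are supplied — the per-condition ratio and expressed label under
    the chosen reference mode."""
    row: dict[str, object] = {"region_id": bgc.region_id, "product": bgc.product or ""}
    for e in fc.experiment_names:
        row[f"log2fc_{e}"] = bgc_fold_change(bgc, fc, e)
    cond_tpm = bgc_expression(bgc, tpm, design)
    for cond, v in cond_tpm.items():
        row[f"tpm_{cond}"] = v
    if ref is not None:
        for cond in design.conditions:
            ratio, expressed = classify_expression(
                float(cond_tpm[cond]), ref.value(mode, condition=cond), multiplier
            )
            row[f"ratio_{mode}_{cond}"] = ratio
            row[f"expressed_{mode}_{cond}"] = expressed
    return pd.DataFrame([row])
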