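"""Per-gene log2 fold changes between conditions.

The built-in estimator is deliberately simple: counts are divided by their
sample's size factor, averaged per condition, and the fold change is the
pseudocount-stabilized log ratio

    log2fc = log2(mean_B + pc) - log2(mean_A + pc)

computed as a difference of logs so that reversing a contrast negates every
value bit-exactly.  No p-values are attached: the downstream score is a
ranking device, and calibrated inference (e.g. DESeq2 results) can be
brought in through :func:`import_de_table` instead.

Genes whose summed condition means fall below ``min_count`` are flagged
not-expressed and excluded from scoring and ranking.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ConfigError,
    ContrastResult,
    CountMatrix,
    ExperimentDesign,
    FormatError,
)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_COUNT = 10.0


def fold_changes(
    cm: CountMatrix,
    sf: pd.Series,
    design: ExperimentDesign,
    experiment: str,
    pc: float = DEFAULT_PSEUDOCOUNT,
    min_count: float = DEFAULT_MIN_COUNT,
) -> ContrastResult:
    """Estimate log2 fold changes (condition B relative to A) for one
    experiment of the design.

    Parameters
    ----------
    sf:
        Size factors indexed by sample id; required for every sample of the
        two conditions.
    pc:
        Pseudocount in normalized-count units added to both condition means.
    min_count:
        Expression filter: a gene with ``mean_A + mean_B < min_count`` is
        flagged not-expressed.
    """
    if pc <= 0:
        raise ConfigError("pseudocount must be positive")
    name, cond_a, cond_b = design.experiment(experiment)
    samples_a = design.samples_of(cond_a)
    samples_b = design.samples_of(cond_b)
    if not samples_a or not samples_b:
        empty = cond_a if not samples_a else cond_b
        raise ConfigError(f"experiment {name!r}: condition {empty!r} has no samples")
    for s in samples_a + samples_b:
        if s not in cm.counts.columns:
            raise ConfigError(f"design sample {s!r} not present in count matrix")
        if s not in sf.index:
            raise ConfigError(f"no size factor for sample {s!r}")
    norm = cm.counts / sf
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    log2fc = np.log2(mean_b + pc) - np.log2(mean_a + pc)
    expressed = (mean_a + mean_b) >= min_count
    table = pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc, "expressed": expressed}
    )
    return ContrastResult(experiment=name, table=table)


def import_de_table(
    path: str | Path,
    experiment: str,
    gene_ids: Sequence[str],
) -> ContrastResult:
    """Adopt an externally computed differential-expression table verbatim.

    Expects a TSV with a gene-id column (``gene_id`` or the first column),
    ``log2FoldChange`` and optionally ``padj`` — header names matched
    case-insensitively, as in DESeq2 result exports.  Genes of the catalog
    absent from the table are flagged not-expressed.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower(): c for c in df.columns}
    if "log2foldchange" not in lower:
        raise FormatError(f"{path}: missing log2FoldChange column")
    id_col = lower.get("gene_id", df.columns[0])
    fc_col = lower["log2foldchange"]
    fc_vals = pd.to_numeric(df[fc_col], errors="coerce")
    if fc_vals.isna().to_numpy().any() and df[fc_col].notna().to_numpy().any():
        bad = df.loc[fc_vals.isna() & df[fc_col].notna(), fc_col].iloc[0]
        raise FormatError(f"{path}: non-numeric log2FoldChange value {bad!r}")
    imported = pd.DataFrame(
        {"log2fc": fc_vals.to_numpy(dtype=float)},
        index=pd.Index(df[id_col].astype(str), name="gene_id"),
    )
    if "padj" in lower:
        imported["padj"] = pd.to_numeric(df[lower["padj"]], errors="coerce").to_numpy()
    idx = pd.Index(gene_ids, name="gene_id")
    table = imported.reindex(idx)
    table["mean_a"] = np.nan
    table["mean_b"] = np.nan
    table["expressed"] = np.isfinite(table["log2fc"].to_numpy())
    cols = ["mean_a", "mean_b", "log2fc", "expressed"]
    if "padj" in table.columns:
        cols.append("padj")
    return ContrastResult(experiment=experiment, table=table[cols])
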