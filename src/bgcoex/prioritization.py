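"""Genome-wide target-gene scoring and ranked concordant/discordant tables.

For each candidate gene the co-expression score against a cluster of
interest is the sum, over the selected experiments, of the product of the
cluster's and the gene's log2 fold changes:

    score(g) = sum_e  bgc_log2fc_e * gene_log2fc_e

Working on the log2 scale makes co-directional regulation contribute
positively and opposite regulation negatively, so the sign of the score
separates concordantly from discordantly co-regulated genes.  Experiments
where the gene failed the expression filter contribute nothing and are
dropped from the gene's "combination" (the experiments that actually back
its score).  The score ranks candidates; it carries no significance — a
high score flags strong parallel expression changes, not a proven
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    BgcRegion,
    CATEGORIES,
    ConfigError,
    FoldChangeTable,
    FunctionalMap,
    GeneCatalog,
    TargetTable,
)

#: categories accepted by rank_and_filter (functional classes plus the
#: shared-KEGG-pathway filter)
FILTER_CATEGORIES = ("regulation", "transport", "resistance", "sm_pathway", "same_kegg_as_bgc")


@dataclass(frozen=True)
class ScoreRecord:
    gene_id: str
    score: float
    contributions: Mapping[str, float]
    combination: frozenset[str]
    concordance: Optional[str]  # None when score == 0
    category: str = "other"
    same_kegg_as_bgc: bool = False


def coexpression_score(
    gene_fc: Mapping[str, float],
    bgc_fc: Mapping[str, float],
    selected: Sequence[str],
) -> Optional[ScoreRecord]:
    """Score one gene against the cluster over the selected experiments.

    Experiments where either fold change is missing (NaN) are skipped; a
    gene with no evaluable experiment yields ``None`` and is omitted from
    the tables.
    """
    contributions: dict[str, float] = {}
    combination = set()
    for e in selected:
        b = bgc_fc.get(e, float("nan"))
        g = gene_fc.get(e, float("nan"))
        if np.isfinite(b) and np.isfinite(g):
            contributions[e] = b * g
            combination.add(e)
    if not combination:
        return None
    score = float(sum(contributions[e] for e in selected if e in contributions))
    concordance = "concordant" if score > 0 else "discordant" if score < 0 else None
    return ScoreRecord(
        gene_id="",
        score=score,
        contributions=contributions,
        combination=frozenset(combination),
        concordance=concordance,
    )


def score_all(
    fc: FoldChangeTable,
    bgc_fc: Mapping[str, float],
    catalog: GeneCatalog,
    functional: FunctionalMap,
    bgc: BgcRegion,
    selected: Optional[Sequence[str]] = None,
    exclude_members: bool = True,
) -> list[ScoreRecord]:
    """Score every evaluable gene of the catalog against the cluster.

    Cluster member genes are excluded by default — engineering targets lie
    outside the cluster — and ``same_kegg_as_bgc`` is set when a gene shares
    at least one KEGG pathway with any cluster member.
    """
    if selected is None:
        selected = [e for e in fc.experiment_names if np.isfinite(bgc_fc.get(e, np.nan))]
    selected = list(selected)
    for e in selected:
        if e not in fc.log2fc.columns:
            raise ConfigError(f"selected experiment {e!r} not in fold-change table")
        if not np.isfinite(bgc_fc.get(e, float("nan"))):
            raise ConfigError(
                f"experiment {e!r}: cluster fold change is not evaluable"
            )
    bgc_pathways: frozenset[str] = frozenset().union(
        *(functional.pathways_of(g) for g in bgc.member_genes)
    ) if bgc.member_genes else frozenset()

    gene_ids = [g for g in catalog.gene_ids if g in fc.log2fc.index]
    if exclude_members:
        gene_ids = [g for g in gene_ids if g not in bgc.member_genes]

    b = np.array([bgc_fc[e] for e in selected], dtype=float)
    fc_mat = fc.log2fc.loc[gene_ids, selected].to_numpy(dtype=float)
    evaluable = np.isfinite(fc_mat)
    contrib = np.where(evaluable, fc_mat * b[None, :], 0.0)
    scores = contrib.sum(axis=1)

    records: list[ScoreRecord] = []
    for i, g in enumerate(gene_ids):
        if not evaluable[i].any():
            continue
        combo = frozenset(e for j, e in enumerate(selected) if evaluable[i, j])
        s = float(scores[i])
        records.append(
            ScoreRecord(
                gene_id=g,
                score=s,
                contributions={e: float(contrib[i, j]) for j, e in enumerate(selected) if evaluable[i, j]},
                combination=combo,
                concordance="concordant" if s > 0 else "discordant" if s < 0 else None,
                category=functional.category_of(g),
                same_kegg_as_bgc=bool(functional.pathways_of(g) & bgc_pathways),
            )
        )
    return records


def _to_frame(records: Iterable[ScoreRecord], experiments: Sequence[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {"gene_id": r.gene_id, "score": r.score}
        for e in experiments:
            row[f"contrib_{e}"] = r.contributions.get(e, np.nan)
        row["combination"] = ";".join(e for e in experiments if e in r.combination)
        row["category"] = r.category
        row["same_kegg_as_bgc"] = r.same_kegg_as_bgc
        rows.append(row)
    cols = (
        ["gene_id", "score"]
        + [f"contrib_{e}" for e in experiments]
        + ["combination", "category", "same_kegg_as_bgc"]
    )
    return pd.DataFrame(rows, columns=cols)


def rank_and_filter(
    records: Sequence[ScoreRecord],
    experiments: Sequence[str],
    category_filter: Optional[str] = None,
    top_n: Optional[int] = None,
) -> tuple[TargetTable, TargetTable]:
    """Split scored genes into ranked concordant and discordant tables.

    Concordant genes (score > 0) are sorted by score descending, discordant
    (score < 0) ascending, i.e. both by decreasing |score|; ties break on
    gene id.  Zero-score genes appear in neither table.  ``category_filter``
    keeps only one functional class, or only genes sharing a KEGG pathway
    with the cluster (``same_kegg_as_bgc``).
    """
    if category_filter is not None:
        if category_filter not in FILTER_CATEGORIES:
            raise ConfigError(
                f"unknown category {category_filter!r}; valid: "
                f"{', '.join(FILTER_CATEGORIES)}"
            )
        if category_filter == "same_kegg_as_bgc":
            records = [r for r in records if r.same_kegg_as_bgc]
        else:
            records = [r for r in records if r.category == category_filter]
    conc = sorted(
        (r for r in records if r.concordance == "concordant"),
        key=lambda r: (-r.score, r.gene_id),
    )
    disc = sorted(
        (r for r in records if r.concordance == "discordant"),
        key=lambda r: (r.score, r.gene_id),
    )
    if top_n is not None:
        conc = conc[:top_n]
        disc = disc[:top_n]
    return (
        TargetTable(concordance="concordant", table=_to_frame(conc, experiments)),
        TargetTable(concordance="discordant", table=_to_frame(disc, experiments)),
    )


def heatmap_matrix(fc: FoldChangeTable, bgc: BgcRegion, catalog: GeneCatalog) -> pd.DataFrame:
    """Cluster member genes x experiments log2 fold-change matrix, ordered
    by genomic position (the overview heatmap surface)."""
    members = [g for g in bgc.member_genes if g in fc.log2fc.index]
    order = catalog.table.loc[members, "start"].sort_values().index
    return fc.log2fc.loc[order]
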