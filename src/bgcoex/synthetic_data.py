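"""Self-contained synthetic RNA-seq datasets with planted co-regulation.

The generator emulates the comparative designs the pipeline is built for: a
bacterial genome whose gene counts follow a negative binomial (mean mu,
size k, variance mu + mu^2/k), one control condition and one treatment
condition per experiment, a cluster of co-regulated genes with a known
log2 effect per experiment, satellite genes planted elsewhere in the genome
that share (concordant) or oppose (discordant) the cluster's regulation,
and stably high housekeeping genes.  Per-sample library-size factors are
drawn log-normal so that size-factor estimation is exercised.

Everything — counts, gene catalog, cluster definition, functional map,
housekeeping list, design, and a truth table of planted roles and effects —
is derived from a single seed and can be written in the exact input
dialects the readers accept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_model import (
    BgcRegion,
    ConfigError,
    CountMatrix,
    ExperimentDesign,
    FunctionalMap,
    GeneCatalog,
)

#: KEGG pathway id attached to cluster genes (secondary-metabolite biosynthesis)
BGC_PATHWAY = "map01059"

ROLES = ("bgc_core", "bgc_member", "concordant", "discordant", "housekeeping", "background")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a 1000-gene genome assayed in four two-condition
    experiments (control vs treatment, 3 replicates each), a 10-gene cluster
    (5 core) up-regulated by 2 log2 units in every treatment, 10 concordant
    and 10 discordant satellites at the same effect magnitude, and 50
    housekeeping genes.  Baseline means are log-normal around 100 counts;
    NB dispersion k = 10 (variance mu + mu^2/10).
    """

    n_genes: int = 1000
    n_experiments: int = 4
    replicates: int = 3
    dispersion: float = 10.0
    baseline_meanlog: float = math.log(100.0)
    baseline_sdlog: float = 1.0
    bgc_core_size: int = 5
    bgc_extra_members: int = 5
    bgc_effects: Optional[tuple[float, ...]] = None  # per-experiment log2; default +2 each
    n_concordant: int = 10
    concordant_multiplier: float = 1.0
    n_discordant: int = 10
    discordant_multiplier: float = 1.0
    n_housekeeping: int = 50
    hk_stability: float = 5.0  # multiplies NB size k for housekeeping genes
    library_size_sdlog: float = 0.1
    kegg_share_fraction: float = 0.5
    seed: int = 1

    def resolved_effects(self) -> np.ndarray:
        if self.bgc_effects is None:
            return np.full(self.n_experiments, 2.0)
        eff = np.asarray(self.bgc_effects, dtype=float)
        if eff.shape != (self.n_experiments,):
            raise ConfigError(
                f"bgc_effects needs {self.n_experiments} values, got {eff.size}"
            )
        if not np.isfinite(eff).all():
            raise ConfigError("bgc_effects must be finite")
        return eff

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_experiments < 1 or self.replicates < 1:
            raise ConfigError("n_genes, n_experiments, replicates must be positive")
        if self.dispersion <= 0 or self.hk_stability <= 0:
            raise ConfigError("dispersion and hk_stability must be positive")
        if self.bgc_core_size < 1:
            raise ConfigError("bgc_core_size must be >= 1")
        planted = (
            self.bgc_core_size
            + self.bgc_extra_members
            + self.n_concordant
            + self.n_discordant
            + self.n_housekeeping
        )
        if planted > self.n_genes:
            raise ConfigError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        self.resolved_effects()


@dataclass
class SimBundle:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    counts: CountMatrix
    catalog: GeneCatalog
    bgc: BgcRegion
    functional: FunctionalMap
    housekeeping: frozenset[str]
    design: ExperimentDesign
    truth: pd.DataFrame  # index gene_id; role + effect_<experiment> columns
    library_factors: pd.Series


def _truncated_lognormal(
    rng: np.random.Generator, n: int, meanlog: float, sdlog: float, lower_q: float
) -> np.ndarray:
    """Log-normal draws restricted to the upper (1 - lower_q) quantile tail."""
    u = rng.uniform(lower_q, 1.0, size=n)
    return np.exp(meanlog + sdlog * stats.norm.ppf(u))


def generate(config: SimConfig) -> SimBundle:
    """Draw a full dataset from the configured study conditions.

    The same config (including seed) always yields an identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    effects = config.resolved_effects()
    width = max(4, len(str(n)))
    gene_ids = np.array([f"g{i + 1:0{width}d}" for i in range(n)])

    # --- genome layout: genes tiled on one contig, cluster in the middle ---
    lengths = rng.integers(300, 5001, size=n)
    gaps = np.full(n, 100)
    starts = np.empty(n, dtype=int)
    pos = 1
    for i in range(n):
        starts[i] = pos
        pos += lengths[i] + gaps[i]
    ends = starts + lengths - 1
    strands = rng.choice(["+", "-"], size=n)

    # --- role assignment ---
    n_cluster = config.bgc_core_size + config.bgc_extra_members
    block_start = n // 2
    cluster_idx = np.arange(block_start, block_start + n_cluster)
    core_idx = cluster_idx[: config.bgc_core_size]
    member_idx = cluster_idx[config.bgc_core_size:]
    remaining = np.setdiff1d(np.arange(n), cluster_idx)
    picked = rng.choice(
        remaining,
        size=config.n_concordant + config.n_discordant + config.n_housekeeping,
        replace=False,
    )
    conc_idx = picked[: config.n_concordant]
    disc_idx = picked[config.n_concordant : config.n_concordant + config.n_discordant]
    hk_idx = picked[config.n_concordant + config.n_discordant :]

    roles = np.full(n, "background", dtype=object)
    roles[core_idx] = "bgc_core"
    roles[member_idx] = "bgc_member"
    roles[conc_idx] = "concordant"
    roles[disc_idx] = "discordant"
    roles[hk_idx] = "housekeeping"

    # --- baselines: planted genes from the upper half of the distribution,
    # housekeeping from the top quartile (constitutively well expressed) ---
    baseline = np.exp(
        config.baseline_meanlog + config.baseline_sdlog * rng.standard_normal(n)
    )
    planted = np.concatenate([cluster_idx, conc_idx, disc_idx])
    baseline[planted] = _truncated_lognormal(
        rng, planted.size, config.baseline_meanlog, config.baseline_sdlog, 0.5
    )
    baseline[hk_idx] = _truncated_lognormal(
        rng, hk_idx.size, config.baseline_meanlog, config.baseline_sdlog, 0.75
    )

    # --- true per-experiment log2 effects ---
    effect_mat = np.zeros((n, config.n_experiments))
    effect_mat[cluster_idx] = effects
    effect_mat[conc_idx] = config.concordant_multiplier * effects
    effect_mat[disc_idx] = -config.discordant_multiplier * effects

    # --- samples: ctrl + one treatment condition per experiment ---
    conditions = ["ctrl"] + [f"t{j + 1}" for j in range(config.n_experiments)]
    sample_ids, sample_cond = [], []
    for cond in conditions:
        for r in range(config.replicates):
            sample_ids.append(f"{cond}_r{r + 1}")
            sample_cond.append(cond)
    n_samples = len(sample_ids)
    lib = np.exp(config.library_size_sdlog * rng.standard_normal(n_samples))

    # --- NB counts: mean = baseline * lib * 2^effect, size k (hk genes
    # tighter by hk_stability) ---
    cond_effect = np.zeros((n, n_samples))
    for s, cond in enumerate(sample_cond):
        if cond != "ctrl":
            j = conditions.index(cond) - 1
            cond_effect[:, s] = effect_mat[:, j]
    mu = baseline[:, None] * lib[None, :] * np.exp2(cond_effect)
    k = np.full(n, config.dispersion)
    k[hk_idx] *= config.hk_stability
    p = k[:, None] / (k[:, None] + mu)
    counts = rng.negative_binomial(k[:, None], p).astype(float)

    # --- assemble domain objects ---
    catalog = GeneCatalog(
        table=pd.DataFrame(
            {
                "contig": "chr1",
                "start": starts,
                "end": ends,
                "strand": strands,
                "length": lengths,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    cm = CountMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        ),
        lengths=pd.Series(lengths.astype(float), index=pd.Index(gene_ids, name="gene_id"), name="length"),
    )
    bgc = BgcRegion(
        region_id="region001",
        contig="chr1",
        start=int(starts[cluster_idx].min()),
        end=int(ends[cluster_idx].max()),
        member_genes=frozenset(gene_ids[cluster_idx]),
        core_genes=frozenset(gene_ids[core_idx]),
        product="synthetic-compound",
    )

    sat_idx = np.concatenate([conc_idx, disc_idx])
    category = {g: "sm_pathway" for g in gene_ids[cluster_idx]}
    sat_cats = rng.choice(
        ["regulation", "transport", "resistance", "sm_pathway"], size=sat_idx.size
    )
    kegg: dict[str, frozenset[str]] = {g: frozenset([BGC_PATHWAY]) for g in gene_ids[cluster_idx]}
    share = rng.random(sat_idx.size) < config.kegg_share_fraction
    for i, gi in enumerate(sat_idx):
        g = gene_ids[gi]
        category[g] = str(sat_cats[i])
        if share[i]:
            kegg[g] = frozenset([BGC_PATHWAY])
    functional = FunctionalMap(category=category, kegg_pathways=kegg)

    design = ExperimentDesign(
        condition_of=dict(zip(sample_ids, sample_cond)),
        experiments=tuple(
            (f"e{j + 1}", "ctrl", f"t{j + 1}") for j in range(config.n_experiments)
        ),
    )

    truth = pd.DataFrame(
        {"role": roles, "baseline": baseline},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for j in range(config.n_experiments):
        truth[f"effect_e{j + 1}"] = effect_mat[:, j]

    return SimBundle(
        config=config,
        counts=cm,
        catalog=catalog,
        bgc=bgc,
        functional=functional,
        housekeeping=frozenset(gene_ids[hk_idx]),
        design=design,
        truth=truth,
        library_factors=pd.Series(lib, index=sample_ids, name="library_factor"),
    )


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the input dialects the readers accept, plus the
    truth table.  Byte-identical across reruns of the same config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "catalog": out / "genes.gff3",
        "bgc": out / "bgc_regions.tsv",
        "functional": out / "functional.tsv",
        "housekeeping": out / "housekeeping.txt",
        "design": out / "design.yaml",
        "truth": out / "truth.tsv",
    }

    cat = bundle.catalog.table
    counts_df = pd.DataFrame(
        {
            "Geneid": cat.index,
            "Chr": cat["contig"].to_numpy(),
            "Start": cat["start"].to_numpy(),
            "End": cat["end"].to_numpy(),
            "Strand": cat["strand"].to_numpy(),
            "Length": cat["length"].to_numpy(),
        }
    )
    for s in bundle.counts.sample_ids:
        counts_df[s] = bundle.counts.counts[s].to_numpy(dtype=int)
    with open(paths["counts"], "w") as fh:
        fh.write("# Program:bgcoex-simulate\n")
        counts_df.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    with open(paths["catalog"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g, row in cat.iterrows():
            fh.write(
                f"{row['contig']}\tbgcoex_sim\tgene\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\tID={g}\n"
            )

    bgc = bundle.bgc
    rows = [
        {
            "region_id": bgc.region_id,
            "contig": bgc.contig,
            "start": bgc.start,
            "end": bgc.end,
            "gene_id": g,
            "is_core": str(g in bgc.core_genes).lower(),
            "product": bgc.product or "",
        }
        for g in sorted(bgc.member_genes)
    ]
    pd.DataFrame(rows).to_csv(paths["bgc"], sep="\t", index=False, lineterminator="\n")

    fun_rows = [
        {
            "gene_id": g,
            "category": bundle.functional.category_of(g),
            "kegg_pathways": ";".join(sorted(bundle.functional.pathways_of(g))),
        }
        for g in sorted(set(bundle.functional.category) | set(bundle.functional.kegg_pathways))
    ]
    pd.DataFrame(fun_rows).to_csv(paths["functional"], sep="\t", index=False, lineterminator="\n")

    with open(paths["housekeeping"], "w") as fh:
        for g in sorted(bundle.housekeeping):
            fh.write(g + "\n")

    design_doc = {
        "samples": dict(bundle.design.condition_of),
        "experiments": [
            {"name": n, "condition_a": a, "condition_b": b}
            for n, a, b in bundle.design.experiments
        ],
    }
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(design_doc, fh, sort_keys=True)

    bundle.truth.to_csv(paths["truth"], sep="\t", float_format="%.6g", lineterminator="\n")
    return paths


def config_from_yaml(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from YAML; absent keys keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: simulation config must be a mapping")
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown simulation key(s) {sorted(unknown)}")
    if "bgc_effects" in raw and raw["bgc_effects"] is not None:
        raw["bgc_effects"] = tuple(float(x) for x in raw["bgc_effects"])
    return SimConfig(**raw)
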