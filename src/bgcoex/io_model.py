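"""Input parsing, validation, output writing and the shared domain types.

All tabular inputs are plain TSV; gene annotation is accepted as GFF3 or a
flat five-column table; experiment designs are YAML.  Coordinates are 1-based
inclusive throughout (GFF3 convention).  Sample identifiers taken from count
matrix headers are normalized by stripping any directory prefix and a
trailing ``.bam`` so that design files can be written against clean names.

Output tables are deterministic: fixed column order, ``\\t`` separator,
floats printed with 6 significant digits, missing values as ``NA``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

FLOAT_FORMAT = "%.6g"
NA_REP = "NA"

#: closed set of functional categories used for target-table filtering
CATEGORIES = ("regulation", "transport", "resistance", "sm_pathway", "other")

#: reference modes for labelling a cluster as expressed
REFERENCE_MODES = ("hk", "non_hk", "all")


class FormatError(ValueError):
    """An input file violates its dialect (bad value, missing column...)."""


class ValidationError(ValueError):
    """Parsed objects violate a domain invariant."""


class ConfigError(ValueError):
    """Run or design configuration is inconsistent with the data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts per gene and sample, with per-gene lengths (bp).

    ``counts`` is genes x samples; values are stored as floats so that an
    optional +1 pseudocount mode downstream stays representable, but inputs
    must be non-negative integers.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count matrix")
        vals = c.to_numpy()
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise FormatError("counts must be finite and non-negative")
        if not (vals == np.floor(vals)).all():
            raise FormatError("counts must be integers")
        if not self.lengths.index.equals(c.index):
            raise ValidationError("lengths index must match count matrix genes")
        if (self.lengths.to_numpy() < 1).any():
            raise FormatError("gene lengths must be >= 1 bp")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class GeneCatalog:
    """Gene coordinates per id: contig, start, end (1-based inclusive),
    strand and length.  Length equals the gene span unless the input stated
    an explicit length (e.g. featureCounts exon-union lengths)."""

    table: pd.DataFrame  # index gene_id; columns contig, start, end, strand, length

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in gene catalog")
        if (t["end"] < t["start"]).any():
            bad = t.index[t["end"] < t["start"]][0]
            raise FormatError(f"gene {bad!r} has end < start")
        if (t["length"] < 1).any():
            bad = t.index[t["length"] < 1][0]
            raise FormatError(f"gene {bad!r} has non-positive length")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class BgcRegion:
    """A biosynthetic gene cluster: its genomic interval, member genes and
    the core biosynthetic subset whose average expression represents it."""

    region_id: str
    contig: str
    start: int
    end: int
    member_genes: frozenset[str]
    core_genes: frozenset[str]
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.core_genes:
            raise ValidationError(f"region {self.region_id!r}: core gene set is empty")
        if not self.core_genes <= self.member_genes:
            extra = sorted(self.core_genes - self.member_genes)[0]
            raise ValidationError(
                f"region {self.region_id!r}: core gene {extra!r} not in member list"
            )
        if self.end < self.start:
            raise ValidationError(f"region {self.region_id!r}: end < start")

    def validate_against(self, catalog: GeneCatalog) -> None:
        for g in sorted(self.member_genes):
            if g not in catalog:
                raise ValidationError(
                    f"region {self.region_id!r}: member gene {g!r} not in gene catalog"
                )
            row = catalog.table.loc[g]
            if (
                row["contig"] != self.contig
                or row["start"] < self.start
                or row["end"] > self.end
            ):
                raise ValidationError(
                    f"region {self.region_id!r}: member gene {g!r} lies outside "
                    f"{self.contig}:{self.start}-{self.end}"
                )


@dataclass(frozen=True)
class FunctionalMap:
    """Functional category and KEGG pathway ids per gene.

    Genes absent from the map default to category ``other`` with no
    pathways.
    """

    category: Mapping[str, str] = field(default_factory=dict)
    kegg_pathways: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, cat in self.category.items():
            if cat not in CATEGORIES:
                raise FormatError(
                    f"gene {g!r}: unknown category {cat!r}; valid: {', '.join(CATEGORIES)}"
                )

    def category_of(self, gene_id: str) -> str:
        return self.category.get(gene_id, "other")

    def pathways_of(self, gene_id: str) -> frozenset[str]:
        return self.kegg_pathways.get(gene_id, frozenset())


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample-to-condition map plus ordered condition contrasts.

    Each experiment is an ordered pair (A, B); fold changes are reported as
    B relative to A.
    """

    condition_of: Mapping[str, str]
    experiments: tuple[tuple[str, str, str], ...]  # (name, condition_A, condition_B)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.experiments]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ConfigError(f"duplicate experiment name {dup!r}")
        conditions = set(self.condition_of.values())
        for name, a, b in self.experiments:
            for cond in (a, b):
                if cond not in conditions:
                    raise ConfigError(
                        f"experiment {name!r} references condition {cond!r} "
                        f"with no samples"
                    )

    @property
    def experiment_names(self) -> list[str]:
        return [e[0] for e in self.experiments]

    def experiment(self, name: str) -> tuple[str, str, str]:
        for e in self.experiments:
            if e[0] == name:
                return e
        raise ConfigError(f"unknown experiment {name!r}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.condition_of.values():
            if c not in seen:
                seen.append(c)
        return seen

    def validate_against(self, cm: CountMatrix) -> None:
        for s in cm.sample_ids:
            if s not in self.condition_of:
                raise ConfigError(f"sample {s!r} in counts has no condition in design")


HousekeepingSet = frozenset


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene outcome of one contrast: normalized-count means of both
    conditions, the log2 fold change (B vs A) and the low-count filter flag."""

    experiment: str
    table: pd.DataFrame  # index gene_id; columns mean_a, mean_b, log2fc, expressed[, padj]

    def __post_init__(self) -> None:
        t = self.table
        expressed = t["expressed"].to_numpy(dtype=bool)
        if not np.isfinite(t.loc[expressed, "log2fc"].to_numpy()).all():
            raise ValidationError(
                f"experiment {self.experiment!r}: non-finite log2fc on expressed gene"
            )


@dataclass(frozen=True)
class FoldChangeTable:
    """Gene x experiment log2 fold changes; genes failing the expression
    filter carry NaN (explicit missing marker), never silent zeros."""

    log2fc: pd.DataFrame     # NaN where not expressed
    expressed: pd.DataFrame  # boolean mask, same shape
    padj: Optional[pd.DataFrame] = None

    @classmethod
    def from_contrasts(cls, contrasts: Sequence[ContrastResult]) -> "FoldChangeTable":
        names = [c.experiment for c in contrasts]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate experiment names among contrasts")
        fc = pd.DataFrame(
            {c.experiment: c.table["log2fc"].where(c.table["expressed"]) for c in contrasts}
        )
        ex = pd.DataFrame({c.experiment: c.table["expressed"] for c in contrasts})
        padj = None
        if any("padj" in c.table.columns for c in contrasts):
            padj = pd.DataFrame(
                {
                    c.experiment: c.table["padj"]
                    if "padj" in c.table.columns
                    else pd.Series(np.nan, index=c.table.index)
                    for c in contrasts
                }
            )
        return cls(log2fc=fc, expressed=ex.astype(bool), padj=padj)

    @property
    def experiment_names(self) -> list[str]:
        return list(self.log2fc.columns)


@dataclass(frozen=True)
class TargetTable:
    """Ranked target-gene records for one concordance class."""

    concordance: str  # "concordant" or "discordant"
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.concordance not in ("concordant", "discordant"):
            raise ValidationError(f"bad concordance label {self.concordance!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

#: featureCounts annotation columns that are not samples
_FEATURECOUNTS_META = ("Geneid", "Chr", "Start", "End", "Strand", "Length")


def normalize_sample_id(raw: str) -> str:
    """Strip directory components and a trailing ``.bam`` from a header name."""
    base = os.path.basename(raw.strip())
    if base.endswith(".bam"):
        base = base[: -len(".bam")]
    return base


def read_counts(path: str | Path) -> CountMatrix:
    """Read a featureCounts-style TSV into a :class:`CountMatrix`.

    The header must contain ``Geneid`` and ``Length``; every non-annotation
    column is a sample.  ``#`` comment lines are permitted.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    for col in ("Geneid", "Length"):
        if col not in df.columns:
            raise FormatError(f"count table {path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in _FEATURECOUNTS_META]
    if not sample_cols:
        raise FormatError(f"count table {path}: no sample columns found")
    counts = df[sample_cols].copy()
    for c in sample_cols:
        col = pd.to_numeric(counts[c], errors="coerce")
        if col.isna().any():
            raise FormatError(f"count table {path}: non-numeric count in column {c!r}")
        counts[c] = col
    counts.index = pd.Index(df["Geneid"].astype(str), name="gene_id")
    counts.columns = [normalize_sample_id(c) for c in sample_cols]
    lengths = pd.to_numeric(df["Length"], errors="coerce")
    if lengths.isna().any():
        raise FormatError(f"count table {path}: non-numeric Length value")
    lengths = pd.Series(lengths.to_numpy(dtype=float), index=counts.index, name="length")
    return CountMatrix(counts=counts.astype(float), lengths=lengths)


_CATALOG_COLUMNS = ("gene_id", "contig", "start", "end", "strand", "length")


def read_gene_catalog(path: str | Path, feature_type: str = "gene") -> GeneCatalog:
    """Read gene coordinates from GFF3 (``.gff``/``.gff3``) or a flat TSV.

    For GFF3 the length is computed as ``end - start + 1``; a TSV may carry
    an explicit ``length`` column which takes precedence over the span.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_catalog_gff3(path, feature_type)
    return _read_catalog_tsv(path)


def _read_catalog_gff3(path: Path, feature_type: str) -> GeneCatalog:
    import gffutils

    records = []
    try:
        for feat in gffutils.iterators.DataIterator(str(path)):
            if feat.featuretype != feature_type:
                continue
            ids = feat.attributes.get("ID") or feat.attributes.get("gene_id")
            if not ids:
                raise FormatError(
                    f"{path}: {feature_type} feature at {feat.seqid}:{feat.start} "
                    "lacks an ID attribute"
                )
            if feat.end < feat.start:
                raise FormatError(f"{path}: gene {ids[0]!r} has end < start")
            records.append(
                (ids[0], feat.seqid, int(feat.start), int(feat.end),
                 feat.strand if feat.strand in "+-" else "+",
                 int(feat.end) - int(feat.start) + 1)
            )
    except FormatError:
        raise
    except Exception as exc:  # gffutils reports the offending line itself
        raise FormatError(f"{path}: unparseable GFF3 ({exc})") from exc
    if not records:
        raise FormatError(f"{path}: no {feature_type!r} features found")
    table = pd.DataFrame.from_records(
        records, columns=_CATALOG_COLUMNS
    ).set_index("gene_id")
    return GeneCatalog(table=table)


def _read_catalog_tsv(path: Path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    missing = [c for c in ("gene_id", "contig", "start", "end", "strand") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing catalog column(s) {missing}")
    df = df.set_index("gene_id")
    span = df["end"] - df["start"] + 1
    if "length" in df.columns:
        # explicit lengths win (featureCounts exon-union lengths); fall back
        # to the span where the column is empty
        length = pd.to_numeric(df["length"], errors="coerce").fillna(span)
    else:
        length = span
    table = df.assign(length=length.astype(int))[["contig", "start", "end", "strand", "length"]]
    return GeneCatalog(table=table)


def read_bgc_regions(path: str | Path, catalog: GeneCatalog) -> list[BgcRegion]:
    """Read cluster definitions from long-form TSV or JSON and validate each
    region against the gene catalog."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        regions = [
            BgcRegion(
                region_id=str(r["region_id"]),
                contig=str(r["contig"]),
                start=int(r["start"]),
                end=int(r["end"]),
                member_genes=frozenset(r["member_genes"]),
                core_genes=frozenset(r["core_genes"]),
                product=r.get("product"),
            )
            for r in raw
        ]
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        needed = ("region_id", "contig", "start", "end", "gene_id", "is_core")
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing BGC column(s) {missing}")
        regions = []
        for rid, grp in df.groupby("region_id", sort=True):
            members = frozenset(grp["gene_id"])
            core = frozenset(grp.loc[grp["is_core"].str.lower().isin(("1", "true", "yes")), "gene_id"])
            product = None
            if "product" in grp.columns:
                vals = grp["product"].dropna().unique()
                product = vals[0] if len(vals) else None
            regions.append(
                BgcRegion(
                    region_id=str(rid),
                    contig=str(grp["contig"].iloc[0]),
                    start=int(grp["start"].iloc[0]),
                    end=int(grp["end"].iloc[0]),
                    member_genes=members,
                    core_genes=core,
                    product=product,
                )
            )
    for region in regions:
        region.validate_against(catalog)
    return regions


def read_functional_map(path: str | Path, catalog: Optional[GeneCatalog] = None) -> FunctionalMap:
    """Read the gene -> category / KEGG pathway table.

    Genes unknown to the catalog raise a warning only; they are harmless for
    scoring (unlike unknown BGC members, which break core-gene averaging).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "gene_id" not in df.columns or "category" not in df.columns:
        raise FormatError(f"{path}: functional map needs gene_id and category columns")
    if catalog is not None:
        unknown = [g for g in df["gene_id"] if g not in catalog]
        if unknown:
            warnings.warn(
                f"{path}: {len(unknown)} gene(s) not in catalog (e.g. {unknown[0]!r})",
                stacklevel=2,
            )
    category = dict(zip(df["gene_id"], df["category"]))
    kegg: dict[str, frozenset[str]] = {}
    if "kegg_pathways" in df.columns:
        for g, raw in zip(df["gene_id"], df["kegg_pathways"]):
            if isinstance(raw, str) and raw.strip():
                kegg[g] = frozenset(p for p in raw.split(";") if p)
    return FunctionalMap(category=category, kegg_pathways=kegg)


def read_housekeeping(path: str | Path, catalog: Optional[GeneCatalog] = None) -> frozenset[str]:
    """Read the housekeeping gene list (one id per line, ``#`` comments)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    hk = frozenset(ids)
    if catalog is not None:
        missing = hk - set(catalog.gene_ids)
        if missing:
            raise ConfigError(
                f"{path}: housekeeping gene(s) not in catalog: "
                f"{', '.join(sorted(missing)[:5])}"
            )
    return hk


def read_design(path: str | Path) -> ExperimentDesign:
    """Read the experiment design (YAML: ``samples`` map + ``experiments`` list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "samples" not in raw or "experiments" not in raw:
        raise ConfigError(f"{path}: design needs 'samples' and 'experiments' sections")
    condition_of = {str(s): str(c) for s, c in raw["samples"].items()}
    experiments = []
    for e in raw["experiments"]:
        try:
            experiments.append((str(e["name"]), str(e["condition_a"]), str(e["condition_b"])))
        except (KeyError, TypeError) as exc:
            raise ConfigError(
                f"{path}: each experiment needs name, condition_a, condition_b"
            ) from exc
    return ExperimentDesign(condition_of=condition_of, experiments=tuple(experiments))


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None) -> None:
    df.to_csv(
        path,
        sep="\t",
        float_format=FLOAT_FORMAT,
        na_rep=NA_REP,
        index=index_label is not None,
        index_label=index_label,
        lineterminator="\n",
    )


@dataclass
class RunResults:
    """Everything one pipeline run produces, ready for :func:`write_tables`."""

    tpm: pd.DataFrame
    size_factors: pd.Series
    fold_changes: FoldChangeTable
    bgc_summary: pd.DataFrame
    heatmap: pd.DataFrame
    concordant: TargetTable
    discordant: TargetTable
    summary: dict


def write_tables(results: RunResults, out_dir: str | Path) -> dict[str, Path]:
    """Write all result tables as deterministic TSVs plus a JSON run summary.

    Returns a name -> path map of everything written.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "tpm": out / "tpm.tsv",
        "size_factors": out / "size_factors.tsv",
        "fold_changes": out / "fold_changes.tsv",
        "bgc_summary": out / "bgc_summary.tsv",
        "heatmap": out / "heatmap.tsv",
        "concordant": out / "targets_concordant.tsv",
        "discordant": out / "targets_discordant.tsv",
        "summary": out / "run_summary.json",
    }
    _write_tsv(results.tpm, paths["tpm"], "gene_id")
    _write_tsv(results.size_factors.rename("factor").to_frame(), paths["size_factors"], "sample")
    _write_tsv(results.fold_changes.log2fc, paths["fold_changes"], "gene_id")
    _write_tsv(results.bgc_summary, paths["bgc_summary"], None)
    _write_tsv(results.heatmap, paths["heatmap"], "gene_id")
    _write_tsv(results.concordant.table, paths["concordant"], None)
    _write_tsv(results.discordant.table, paths["discordant"], None)
    with open(paths["summary"], "w") as fh:
        json.dump(results.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
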