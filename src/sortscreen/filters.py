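"""In-silico candidate filtering.

The raw primary gene set from the screen is narrowed in two annotation-driven
stages: (1) keep genes positively annotated to nuclear or cytosolic cellular
components — the screen looks for factors acting on chromatin silencing or on
the expression machinery of its components; (2) keep genes actually expressed
in the screened cell types, mean log2-cpm strictly greater than 3 across the
supplied expression datasets.  A separate routine reproduces the reporter-gene
selection: strongly inducible (DEG log2-fc > 4, log2-cpm > 2) genes carrying
high PRC2 promoter occupancy (median score > 0.4), ranked by expression.

All thresholds are strict inequalities.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, FormatError


def default_component_terms() -> list[str]:
    """The shipped nuclear/cytosolic cellular-component term list."""
    text = resources.files("sortscreen").joinpath("data/component_terms.yaml").read_text()
    return list(yaml.safe_load(text)["allowed_terms"])


@dataclass
class GeneAnnotation:
    """Per-gene annotation used by the filter cascade.

    component_terms: gene -> set of cellular-component terms (may be empty).
    expression: DataFrame, rows = genes, one log2-cpm column per dataset.
    modules: optional Series gene -> module name (PRC / Myc / Core / none).
    bivalent: optional set of bivalent-chromatin genes.
    """

    component_terms: Mapping[str, frozenset[str]]
    expression: pd.DataFrame
    modules: pd.Series | None = None
    bivalent: frozenset[str] = frozenset()

    @staticmethod
    def terms_from_tsv(path: str | Path) -> dict[str, frozenset[str]]:
        """Long-format TSV (gene, term) -> gene -> term set."""
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "term"} <= set(df.columns):
            raise FormatError(f"{path}: needs columns gene, term")
        return {
            g: frozenset(sub["term"]) for g, sub in df.groupby("gene", sort=False)
        }

    @staticmethod
    def expression_from_tsv(path: str | Path) -> pd.DataFrame:
        """Wide-format TSV: gene column + one log2-cpm column per dataset."""
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns:
            raise FormatError(f"{path}: needs a 'gene' column")
        return df.set_index("gene")

    @staticmethod
    def modules_from_tsv(path: str | Path) -> pd.Series:
        df = pd.read_csv(path, sep="\t")
        if not {"gene", "module"} <= set(df.columns):
            raise FormatError(f"{path}: needs columns gene, module")
        return df.set_index("gene")["module"]


@dataclass
class FilterStage:
    name: str
    rule: str
    genes: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.genes)


@dataclass
class CandidateSet:
    """Ordered filter stages; each stage's gene set nests inside the previous."""

    stages: list[FilterStage] = field(default_factory=list)
    dropped_unannotated: frozenset[str] = frozenset()

    def append(self, stage: FilterStage) -> None:
        if self.stages and not stage.genes <= self.stages[-1].genes:
            raise ValueError(
                f"stage {stage.name!r} is not a subset of {self.stages[-1].name!r}"
            )
        self.stages.append(stage)

    @property
    def final(self) -> frozenset[str]:
        return self.stages[-1].genes

    def counts(self) -> dict[str, int]:
        return {s.name: s.count for s in self.stages}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stages": [
                        {"name": s.name, "rule": s.rule, "count": s.count,
                         "genes": sorted(s.genes)}
                        for s in self.stages
                    ],
                    "dropped_unannotated": sorted(self.dropped_unannotated),
                },
                fh,
                indent=2,
            )


def component_filter(
    genes: Iterable[str],
    annotation: GeneAnnotation,
    allowed_terms: Iterable[str] | None = None,
) -> tuple[frozenset[str], frozenset[str]]:
    """Keep genes whose component-term set intersects the allowed list.

    Genes with no component annotation at all are dropped (the filter keeps
    only positively annotated genes) and returned separately for logging.
    """
    allowed = frozenset(allowed_terms if allowed_terms is not None else default_component_terms())
    if not allowed:
        raise ConfigError("allowed_terms must be non-empty")
    kept, unannotated = set(), set()
    for g in genes:
        terms = annotation.component_terms.get(g)
        if not terms:
            unannotated.add(g)
        elif terms & allowed:
            kept.add(g)
    return frozenset(kept), frozenset(unannotated)


def expression_filter(
    genes: Iterable[str],
    annotation: GeneAnnotation,
    datasets: Iterable[str] | None = None,
    log2cpm_min: float = 3.0,
) -> tuple[frozenset[str], pd.Series]:
    """Keep genes with mean log2-cpm strictly above the threshold.

    The mean is taken across the named expression datasets (default: all
    columns present).  Genes missing from a dataset fail the filter and are
    reported with a NaN mean.
    """
    datasets = list(datasets) if datasets is not None else list(annotation.expression.columns)
    missing_ds = set(datasets) - set(annotation.expression.columns)
    if missing_ds:
        raise ConfigError(f"unknown expression dataset(s): {sorted(missing_ds)}")
    genes = list(genes)
    means = annotation.expression.reindex(genes)[datasets].mean(axis=1, skipna=False)
    kept = frozenset(means.index[means > log2cpm_min])
    return kept, means


def run_filter_cascade(
    primary_genes: Iterable[str],
    annotation: GeneAnnotation,
    allowed_terms: Iterable[str] | None = None,
    datasets: Iterable[str] | None = None,
    log2cpm_min: float = 3.0,
) -> CandidateSet:
    """primary -> component filter -> expression filter, with full provenance."""
    primary = frozenset(primary_genes)
    cs = CandidateSet()
    cs.append(FilterStage("primary", "mean log2-fc and t-test cut-offs", primary))
    comp, unannotated = component_filter(primary, annotation, allowed_terms)
    cs.dropped_unannotated = unannotated
    cs.append(FilterStage("component", "nuclear or cytosolic component term", comp))
    expr, _means = expression_filter(comp, annotation, datasets, log2cpm_min)
    cs.append(
        FilterStage("expression", f"mean log2-cpm > {log2cpm_min}", expr)
    )
    return cs


def select_reporter_genes(
    deg_table: pd.DataFrame,
    occupancy_table: pd.DataFrame,
    lfc_min: float = 4.0,
    cpm_min: float = 2.0,
    occupancy_min: float = 0.4,
) -> pd.DataFrame:
    """Reporter-gene candidates: inducible, expressed, PRC2-occupied.

    deg_table: columns gene, log2fc, log2cpm (per-gene differential
    expression upon induction).  occupancy_table: columns gene, median_score
    (PRC2 promoter-occupancy median).  Genes absent from the occupancy table
    are excluded.  Returns the retained genes ranked by log2cpm descending,
    with the scatter-plot columns (log2fc, log2cpm) retained.
    """
    deg = deg_table.set_index("gene") if "gene" in deg_table.columns else deg_table
    occ = (
        occupancy_table.set_index("gene")
        if "gene" in occupancy_table.columns
        else occupancy_table
    )
    joined = deg.join(occ["median_score"], how="inner")
    keep = (
        (joined["log2fc"] > lfc_min)
        & (joined["log2cpm"] > cpm_min)
        & (joined["median_score"] > occupancy_min)
    )
    out = joined[keep].sort_values("log2cpm", ascending=False)
    out.index.name = "gene"
    return out.reset_index()


def venn_partition(named_sets: Mapping[str, set]) -> dict[str, int]:
    """Counts of every non-empty exclusive intersection region.

    Region keys are '&'-joined sorted set names (e.g. ``"A&B"`` is the region
    in A and B but in no other set).  The regions partition the union, so the
    counts sum to ``len(union)``.
    """
    if len(named_sets) < 2:
        raise ConfigError("venn_partition needs at least 2 sets")
    names = sorted(named_sets)
    union = set().union(*named_sets.values())
    regions: dict[str, int] = {}
    for el in union:
        key = "&".join(n for n in names if el in named_sets[n])
        regions[key] = regions.get(key, 0) + 1
    return regions
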