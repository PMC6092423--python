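"""End-to-end orchestration: counts (or simulation) -> statistics -> candidates.

Every run writes plain TSV/JSON artifacts plus a manifest recording the exact
configuration, input checksums and per-stage gene/construct counts, so a rerun
with the same seed and config reproduces the stage counts byte-identically.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .countmatrix import CountMatrix
from .counting import count_samples, read_library_table, read_sample_sheet
from .enrichment import (
    PrimarySelection,
    SelectionThresholds,
    compute_construct_stats,
    primary_select,
)
from .errors import ConfigError, StageError
from .filters import GeneAnnotation, run_filter_cascade
from .simulate import EffectMap, SimConfig, assign_effects, make_library, simulate_screen


@dataclass
class RunConfig:
    """Flat run configuration with the screen's published cut-offs as defaults."""

    seed: int
    outdir: str = "sortscreen_out"
    # input: either a simulation, a precomputed count table, or FASTQs + sheet
    simulate: SimConfig | None = None
    counts: str | None = None
    library: str | None = None
    samples: str | None = None
    barcode_offset: int = 0
    max_mismatch: int = 0
    # enrichment / selection
    lfc_min: float = 0.3
    p_max: float = 0.01
    pseudocount: float = 0.5
    # filter cascade (optional; needs annotation tables)
    terms: str | None = None
    expression: str | None = None
    log2cpm_min: float = 3.0
    datasets: list[str] | None = None

    def thresholds(self) -> SelectionThresholds:
        return SelectionThresholds(
            lfc_min=self.lfc_min, p_max=self.p_max, pseudocount=self.pseudocount
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError(f"{path}: 'seed' is mandatory")
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim.setdefault("seed", raw["seed"])
            for key in ("constructs_per_gene", "efficacy_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        try:
            return cls(simulate=sim, **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    started: str
    finished: str = ""
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        """Atomic write (tmp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        os.replace(tmp, path)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_screen(config: RunConfig) -> RunManifest:
    """Execute the pipeline described by ``config``; returns the manifest.

    Stages: obtain counts (simulate, load TSV, or count FASTQs) ->
    quantile normalization + per-construct statistics -> primary selection ->
    optional annotation filter cascade.  A stage failure aborts with the stage
    name; partial outputs stay on disk next to a FAILED marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        input_checksums={},
        stage_counts={},
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    effects: EffectMap | None = None
    try:
        stage = "counts"
        manifest.input_checksums = {
            p: _sha256(p)
            for p in (config.counts, config.library, config.samples,
                      config.terms, config.expression)
            if p
        }
        if config.simulate is not None:
            library, abundance = make_library(config.simulate)
            effects = assign_effects(library, config.simulate)
            matrix = simulate_screen(library, abundance, effects, config.simulate)
            library.to_tsv(outdir / "library.tsv")
            truth = pd.DataFrame(
                {"delta": effects.gene_delta}
            )
            truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
        elif config.counts is not None:
            matrix = CountMatrix.from_tsv(config.counts)
        elif config.library is not None and config.samples is not None:
            library = read_library_table(config.library)
            sheet = read_sample_sheet(config.samples)
            matrix, report = count_samples(
                sheet, library, config.barcode_offset, config.max_mismatch
            )
            report.to_json(outdir / "counting_report.json")
        else:
            raise ConfigError(
                "config must provide 'simulate', 'counts', or 'library'+'samples'"
            )
        matrix.to_tsv(outdir / "counts.tsv")
        manifest.stage_counts["constructs"] = matrix.counts.shape[0]
        manifest.stage_counts["samples"] = matrix.counts.shape[1]

        stage = "stats"
        stats = compute_construct_stats(matrix, pseudocount=config.pseudocount)
        stats.to_csv(outdir / "stats.tsv", sep="\t")

        stage = "primary_selection"
        selection = primary_select(stats, config.thresholds())
        selection.table.to_csv(outdir / "primary.tsv", sep="\t")
        manifest.stage_counts["primary_constructs"] = len(selection.constructs)
        manifest.stage_counts["primary_genes"] = len(selection.genes)

        if config.terms is not None and config.expression is not None:
            stage = "filter_cascade"
            annotation = GeneAnnotation(
                component_terms=GeneAnnotation.terms_from_tsv(config.terms),
                expression=GeneAnnotation.expression_from_tsv(config.expression),
            )
            cascade = run_filter_cascade(
                selection.genes,
                annotation,
                datasets=config.datasets,
                log2cpm_min=config.log2cpm_min,
            )
            cascade.to_json(outdir / "cascade.json")
            for s in cascade.stages:
                manifest.stage_counts[f"cascade_{s.name}"] = s.count
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(outdir / "manifest.json")
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def evaluate_against_truth(
    selected_genes,
    effects: EffectMap,
    stats: pd.DataFrame | None = None,
) -> dict:
    """Recovery metrics of a selection against simulation ground truth.

    recall = fraction of true modifier genes selected; precision = fraction of
    selected genes that are true modifiers.  With a null truth (no modifiers)
    recall is None and the gene-level false-positive rate is reported instead.
    If the per-construct stats table is given, a per-gene best-construct rank
    table (by mean log2-fc, descending) is included under ``"ranks"``.
    """
    if effects is None:
        raise ConfigError("no ground truth available")
    truth = effects.modifier_genes
    universe = set(effects.gene_delta.index)
    selected = set(selected_genes)
    tp = len(selected & truth)
    out: dict = {
        "n_true_modifiers": len(truth),
        "n_selected": len(selected),
        "recall": tp / len(truth) if truth else None,
        "precision": tp / len(selected) if selected else None,
        "false_positive_rate": len(selected - truth) / max(len(universe - truth), 1),
    }
    if stats is not None:
        ranked = stats.sort_values("mean_log2fc", ascending=False)
        best_rank = (
            pd.Series(range(1, len(ranked) + 1), index=ranked.index)
            .groupby(ranked["gene"])
            .min()
            .sort_values()
        )
        out["ranks"] = pd.DataFrame(
            {"best_construct_rank": best_rank, "is_modifier": best_rank.index.isin(truth)}
        )
    return out
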