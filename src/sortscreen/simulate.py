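"""Generative model of a FACS-sorted pooled shRNA screen.

The simulator reproduces, with known ground truth, the structure of a
reporter-based knockdown screen: a barcoded lentiviral library with 5-7
constructs per target gene, construct representation varying by less than
100-fold, puromycin-selected cells carrying exactly one construct each, a
reporter whose log-intensity is shifted when a silencing-modifier gene is
knocked down, a FACS gate collecting the brightest ~10% of cells next to a
simple-random-sampled input fraction, and multinomial sequencing of barcode
amplicons from each pooled fraction.

Intensity model
---------------
A cell carrying construct ``j`` against gene ``g`` has log-reporter-intensity

    x ~ Normal(mu0 + delta_g * e_j, tau)

where ``delta_g`` is the gene's full-knockdown de-repression shift (0 for
non-modifiers), ``e_j`` in [0, 1] the construct's knockdown efficacy and
``tau`` the intra-population spread.  The gate keeps cells above the
empirical (1 - gate_fraction) quantile of the pooled intensities, so a
construct with effective shift ``d = delta_g * e_j`` is enriched in the high
fraction by the normal tail factor  Phibar((z_q*tau - d)/tau) / gate_fraction
with ``z_q`` the standard-normal gate cutoff.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .countmatrix import CountMatrix, sample_name
from .errors import ConfigError, SimulationError

BASES = np.array(list("ACGT"))

# fixed flanks for FASTQ emission: vector sequence surrounding the barcode
_FIVE_PRIME = "ACCGGTTAACTCGAGAAGGTATATTGCTGTTGACAGTGAG"
_THREE_PRIME = "TTTTTGAATTCGCTAGCTAGGTCTTGAAAGGAGTGGGAAT"


@dataclass
class SimConfig:
    """Parameters of one simulated screen module.

    Defaults follow the screened library and sorting design: ~4,600 target
    genes at 5-7 constructs each (~27,500 constructs per module), <100-fold
    representation spread, a 10% high-intensity gate with a 10% input
    fraction, three biological replicates and 2e7 reads per pooled fraction.
    """

    seed: int
    n_genes: int = 4600
    constructs_per_gene: tuple[int, int] = (5, 7)
    abundance_sigma: float = 0.8
    fraction_modifiers: float = 0.01
    effect_size: float = 1.5          # delta for modifier genes, in units of tau
    efficacy_range: tuple[float, float] = (0.3, 0.9)
    mu0: float = 0.0
    tau: float = 1.0
    n_cells: int = 20_000_000
    gate_fraction: float = 0.10
    input_fraction: float = 0.10
    n_reads: int = 20_000_000
    n_replicates: int = 3
    barcode_length: int = 18
    module_id: str = "M1"

    def __post_init__(self) -> None:
        lo, hi = self.constructs_per_gene
        if lo < 1 or lo > hi:
            raise ConfigError(f"invalid constructs_per_gene range ({lo}, {hi})")
        if not (0.0 < self.gate_fraction <= 1.0):
            raise ConfigError("gate_fraction must be in (0, 1]")
        if not (0.0 < self.input_fraction <= 1.0):
            raise ConfigError("input_fraction must be in (0, 1]")
        if not (0.0 <= self.fraction_modifiers <= 1.0):
            raise ConfigError("fraction_modifiers must be in [0, 1]")
        if self.n_genes < 1 or self.n_cells < 1 or self.n_reads < 1 or self.n_replicates < 1:
            raise ConfigError("counts must be positive integers")
        if self.tau <= 0:
            raise ConfigError("tau must be positive")
        if self.abundance_sigma < 0:
            raise ConfigError("abundance_sigma must be non-negative")
        if self.module_id not in ("M1", "M2"):
            raise ConfigError("module_id must be 'M1' or 'M2'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigError(f"{path}: 'seed' is mandatory in the simulation config")
        for key in ("constructs_per_gene", "efficacy_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class LibrarySpec:
    """Barcoded construct library: construct_id, barcode, gene, module_id."""

    table: pd.DataFrame  # columns: construct_id, barcode, gene, module_id

    def __post_init__(self) -> None:
        required = {"construct_id", "barcode", "gene", "module_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigError(f"library table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ConfigError("library has no constructs")
        dup = self.table["barcode"].duplicated()
        if dup.any():
            raise ConfigError(
                f"duplicate barcode(s): {self.table.loc[dup, 'barcode'].iloc[0]}"
            )

    @property
    def construct_ids(self) -> pd.Index:
        return pd.Index(self.table["construct_id"])

    @property
    def genes(self) -> pd.Series:
        return pd.Series(
            self.table["gene"].to_numpy(), index=self.construct_ids, name="gene"
        )

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EffectMap:
    """Ground truth: per-gene de-repression shifts and per-construct efficacies."""

    gene_delta: pd.Series        # gene -> delta_g (0 for non-modifiers)
    construct_efficacy: pd.Series  # construct_id -> e_j in [0, 1]
    mu0: float
    tau: float

    @property
    def modifier_genes(self) -> set[str]:
        return set(self.gene_delta.index[self.gene_delta > 0])

    def construct_shift(self, library: LibrarySpec) -> pd.Series:
        """Effective intensity shift delta_g * e_j per construct."""
        delta = self.gene_delta.reindex(library.genes.to_numpy()).to_numpy()
        eff = self.construct_efficacy.reindex(library.construct_ids).to_numpy()
        return pd.Series(delta * eff, index=library.construct_ids, name="shift")


def _random_barcodes(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """Unique random DNA barcodes (re-draws collisions)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out), length))
        for row in block:
            bc = "".join(BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return np.array(out)


def make_library(config: SimConfig) -> tuple[LibrarySpec, pd.Series]:
    """Build a barcoded library and its relative-abundance profile.

    Abundances are log-normal with dispersion ``abundance_sigma``; draws
    falling outside a 100-fold window around the geometric mean are resampled
    (not clipped) so the max/min ratio invariant holds without a point mass at
    the bounds.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.constructs_per_gene
    per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    genes = np.repeat(
        [f"Gene{idx + 1:05d}" for idx in range(config.n_genes)], per_gene
    )
    within = np.concatenate([np.arange(1, k + 1) for k in per_gene])
    construct_ids = np.array(
        [f"{g}_sh{i}" for g, i in zip(genes, within)]
    )
    n = len(construct_ids)
    barcodes = _random_barcodes(n, config.barcode_length, rng)

    if config.abundance_sigma == 0:
        raw = np.ones(n)
    else:
        # log-normal in natural log space, centred at 0 => geometric mean 1
        half_span = math.log(100.0) / 2.0
        raw = rng.normal(0.0, config.abundance_sigma, size=n)
        bad = np.abs(raw) > half_span
        while bad.any():
            raw[bad] = rng.normal(0.0, config.abundance_sigma, size=int(bad.sum()))
            bad = np.abs(raw) > half_span
        raw = np.exp(raw)
    abundance = pd.Series(raw / raw.sum(), index=construct_ids, name="abundance")

    table = pd.DataFrame(
        {
            "construct_id": construct_ids,
            "barcode": barcodes,
            "gene": genes,
            "module_id": config.module_id,
        }
    )
    return LibrarySpec(table), abundance


def assign_effects(library: LibrarySpec, config: SimConfig) -> EffectMap:
    """Plant modifier genes and draw construct efficacies.

    Exactly ``round(fraction_modifiers * n_genes)`` genes receive the shift
    ``effect_size * tau``; all other genes get 0.  Every construct draws an
    efficacy from Uniform(efficacy_range), so within one modifier gene some
    constructs are weak — single-construct dropouts are an expected feature.
    """
    if len(library) == 0:
        raise ConfigError("library is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = pd.unique(library.table["gene"])
    n_mod = int(round(config.fraction_modifiers * len(genes)))
    modifiers = rng.choice(genes, size=n_mod, replace=False)
    delta = pd.Series(0.0, index=pd.Index(genes, name="gene"), name="delta")
    delta.loc[modifiers] = config.effect_size * config.tau
    lo, hi = config.efficacy_range
    eff = pd.Series(
        rng.uniform(lo, hi, size=len(library)),
        index=library.construct_ids,
        name="efficacy",
    )
    return EffectMap(
        gene_delta=delta, construct_efficacy=eff, mu0=config.mu0, tau=config.tau
    )


def _simulate_replicate(
    cell_counts: np.ndarray,
    shifts: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell counts per construct in the (input, high) fractions of one replicate."""
    n_constructs = len(cell_counts)
    total = int(cell_counts.sum())
    n_gate = int(round(config.gate_fraction * total))
    if n_gate < 1:
        raise SimulationError(
            "gate produces an empty high fraction; increase n_cells or gate_fraction"
        )
    idx = np.repeat(np.arange(n_constructs), cell_counts)
    if config.gate_fraction >= 1.0:
        high = cell_counts.copy()
    else:
        x = (config.mu0 + shifts[idx]) + config.tau * rng.standard_normal(total)
        thr = np.quantile(x, 1.0 - config.gate_fraction)
        high = np.bincount(idx[x > thr], minlength=n_constructs)
    n_input = int(round(config.input_fraction * total))
    if n_input < 1:
        raise SimulationError("input fraction is empty; increase n_cells")
    inp = rng.multivariate_hypergeometric(cell_counts, n_input)
    return inp, high


def simulate_screen(
    library: LibrarySpec,
    abundance: pd.Series,
    effects: EffectMap,
    config: SimConfig,
    keep_cells: bool = False,
) -> CountMatrix | tuple[CountMatrix, CountMatrix]:
    """Run the full screen: infection, sorting, and fraction sequencing.

    Per replicate: cells are assigned to constructs by a multinomial over the
    abundance profile; each cell draws a log-intensity from the normal model;
    the high fraction keeps cells above the pooled (1 - gate_fraction)
    intensity quantile while the input fraction is a simple random sample of
    ``input_fraction`` of all cells; finally ``n_reads`` barcode reads per
    fraction are drawn multinomially over that fraction's cell counts, so
    every sample column sums to exactly ``n_reads``.

    With ``keep_cells=True`` also returns the pre-sequencing cell-count
    matrix of the two fractions (useful for gate-model diagnostics).
    """
    ids = library.construct_ids
    if not (abundance.index.equals(ids) and effects.construct_efficacy.index.equals(ids)):
        raise ConfigError("library, abundance and effects must share one construct set")
    shifts = effects.construct_shift(library).to_numpy()
    ab = abundance.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    reads: dict[str, np.ndarray] = {}
    cells: dict[str, np.ndarray] = {}
    for rep in range(1, config.n_replicates + 1):
        cell_counts = rng.multinomial(config.n_cells, ab)
        inp, high = _simulate_replicate(cell_counts, shifts, config, rng)
        for frac, counts in (("input", inp), ("high", high)):
            col = sample_name(rep, frac)
            cells[col] = counts
            tot = counts.sum()
            if tot == 0:
                raise SimulationError(f"{col}: fraction is empty")
            reads[col] = rng.multinomial(config.n_reads, counts / tot)

    genes = library.genes
    read_cm = CountMatrix(pd.DataFrame(reads, index=ids), genes)
    if not keep_cells:
        return read_cm
    cell_cm = CountMatrix(pd.DataFrame(cells, index=ids), genes)
    return read_cm, cell_cm


def emit_fastq(
    counts: CountMatrix,
    library: LibrarySpec,
    outdir: str | Path,
    barcode_offset: int = 0,
    read_length: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write one FASTQ per sample with reads carrying each construct's barcode.

    Reads are vector flank + barcode + vector flank, barcode starting at
    ``barcode_offset``; constant Phred-33 quality 'I'.  Read order within a
    file is shuffled so downstream counting cannot rely on grouping.  Returns
    a sample sheet DataFrame (file, replicate, fraction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bc_len = len(library.table["barcode"].iloc[0])
    if read_length is None:
        read_length = barcode_offset + bc_len
    if read_length < barcode_offset + bc_len:
        raise ConfigError("read_length shorter than barcode_offset + barcode length")
    prefix = (_FIVE_PRIME * (barcode_offset // len(_FIVE_PRIME) + 1))[:barcode_offset]
    tail_len = read_length - barcode_offset - bc_len
    suffix = (_THREE_PRIME * (tail_len // len(_THREE_PRIME) + 1))[:tail_len]
    qual = "I" * read_length
    barcodes = library.table["barcode"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))

    rows = []
    for col in counts.counts.columns:
        vec = counts.counts[col].to_numpy()
        order = np.repeat(np.arange(len(vec)), vec)
        rng.shuffle(order)
        path = outdir / f"{col}.fastq"
        with open(path, "w") as fh:
            for i, j in enumerate(order):
                fh.write(f"@{col}:{i}\n{prefix}{barcodes[j]}{suffix}\n+\n{qual}\n")
        from .countmatrix import parse_sample_name

        rep, frac = parse_sample_name(col)
        rows.append({"file": str(path), "replicate": rep, "fraction": frac})
    return pd.DataFrame(rows)


def simulate_gene_annotation(
    genes: list[str] | np.ndarray,
    seed: int,
    p_component: float = 0.7,
    component_term: str = "nucleus",
    other_term: str = "plasma membrane",
    expression_mean: float = 5.0,
    expression_sd: float = 2.0,
    datasets: tuple[str, ...] = ("F9", "ESC"),
):
    """Synthetic gene annotation with known pass rates for the filter cascade.

    Each gene is flagged nuclear with probability ``p_component`` (else it
    gets a non-allowed term) and draws an independent log2-cpm per dataset
    from Normal(expression_mean, expression_sd).  Returns a
    :class:`sortscreen.filters.GeneAnnotation`.
    """
    from .filters import GeneAnnotation

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    genes = list(genes)
    nuclear = rng.random(len(genes)) < p_component
    terms = {
        g: frozenset([component_term if keep else other_term])
        for g, keep in zip(genes, nuclear)
    }
    expr = pd.DataFrame(
        rng.normal(expression_mean, expression_sd, size=(len(genes), len(datasets))),
        index=pd.Index(genes, name="gene"),
        columns=list(datasets),
    )
    return GeneAnnotation(component_terms=terms, expression=expr)
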