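"""Downstream validation statistics.

Covers four independent checks of a candidate modifier gene set:

* DEG thresholding of knockout RNA-seq tables (|log2-fc| > 1, P < 0.01).
* A 2x2 chi-square test for bias of the differentially expressed genes toward
  the Polycomb (PRC) co-regulation module versus the Myc or Core module.
* Fold-enrichment ranking of annotation terms in the candidate set against a
  background universe, with hypergeometric tail P-values.
* Metagene profiles of ChIP log2-fold-enrichment over input (e.g. H3K27me3)
  across a gene set, from plain bedGraph coverage tracks and BED regions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateTableError, FormatError


def deg_filter(
    table: pd.DataFrame, lfc_abs_min: float = 1.0, p_max: float = 0.01
) -> tuple[frozenset[str], frozenset[str]]:
    """Split a DEG table into up- and down-regulated gene sets (strict cuts).

    table: columns gene, log2fc, p_value.  up = log2fc > +lfc_abs_min and
    P < p_max; down symmetric.  The two sets are disjoint by construction.
    """
    for col in ("gene", "log2fc", "p_value"):
        if col not in table.columns:
            raise FormatError(f"DEG table missing column {col!r}")
    sig = table["p_value"] < p_max
    up = frozenset(table.loc[sig & (table["log2fc"] > lfc_abs_min), "gene"])
    down = frozenset(table.loc[sig & (table["log2fc"] < -lfc_abs_min), "gene"])
    return up, down


@dataclass
class ModuleBiasResult:
    chi2: float
    p_value: float
    log10_p: float         # always reported; safe below the float underflow limit
    table: pd.DataFrame    # rows = modules, columns = DEG / non-DEG


def module_bias_test(
    deg_genes: set[str] | frozenset[str],
    modules: pd.Series,
    module_a: str = "PRC",
    module_b: str = "Myc",
    correction: bool = False,
) -> ModuleBiasResult:
    """Pearson chi-square (df=1) for DEG bias between two gene modules.

    Builds the 2x2 table (module_a vs module_b membership) x (DEG vs non-DEG)
    over the genes assigned to either module.  No Yates continuity correction
    by default; pass ``correction=True`` to apply it.  P-values below the
    float64 underflow limit are available via ``log10_p`` (computed from the
    chi-square log survival function).
    """
    a_genes = set(modules.index[modules == module_a])
    b_genes = set(modules.index[modules == module_b])
    if not a_genes or not b_genes:
        raise ConfigError(f"module {module_a!r} or {module_b!r} is empty")
    deg = set(deg_genes)
    obs = np.array(
        [
            [len(a_genes & deg), len(a_genes - deg)],
            [len(b_genes & deg), len(b_genes - deg)],
        ],
        dtype=float,
    )
    expected = sps.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise DegenerateTableError("degenerate table: an expected cell is zero")
    chi2, p, _, _ = sps.chi2_contingency(obs, correction=correction)
    log10_p = sps.chi2.logsf(chi2, df=1) / math.log(10.0)
    table = pd.DataFrame(
        obs.astype(int),
        index=pd.Index([module_a, module_b], name="module"),
        columns=["DEG", "non-DEG"],
    )
    return ModuleBiasResult(chi2=float(chi2), p_value=float(p), log10_p=float(log10_p), table=table)


def term_fold_enrichment(
    candidates: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
    term_annotation: dict[str, frozenset[str]] | pd.Series,
) -> pd.DataFrame:
    """Rank annotation terms by fold enrichment in the candidate set.

    fold = (k/n) / (K/N) with k = candidates carrying the term, n = number of
    candidates, K = background genes carrying the term, N = background size;
    the hypergeometric upper-tail P(X >= k) accompanies each term.  Terms with
    k = 0 are omitted; ranking is by fold descending (ties broken by P).
    """
    candidates = set(candidates)
    background = set(background)
    if not background:
        raise ConfigError("empty background")
    if not candidates <= background:
        raise ConfigError("candidates must be a subset of the background")
    if isinstance(term_annotation, pd.Series):
        term_annotation = term_annotation.to_dict()
    n, N = len(candidates), len(background)
    term_k: dict[str, int] = {}
    term_K: dict[str, int] = {}
    for g in background:
        for t in term_annotation.get(g, ()):  # genes without terms contribute nothing
            term_K[t] = term_K.get(t, 0) + 1
            if g in candidates:
                term_k[t] = term_k.get(t, 0) + 1
    rows = []
    for t, k in term_k.items():
        K = term_K[t]
        fold = (k / n) / (K / N)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": t, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p_value": p})
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "fold", "p_value"])
    return out.sort_values(["fold", "p_value"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metagene profiles


class CoverageTrack:
    """Piecewise-constant genome coverage loaded from a 4-column bedGraph.

    Stores, per chromosome, the breakpoint positions and the cumulative
    coverage mass, so the mean coverage of any interval is an O(log n)
    interpolation.  Regions of the genome not covered by any bedGraph line
    count as zero coverage; positions outside [first start, last end] of a
    chromosome are out of bounds.
    """

    def __init__(self, per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._per_chrom = per_chrom
        self.total_mass = float(
            sum(cum[-1] for _, cum in per_chrom.values())
        )

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].str.startswith("track")]
        if len(df) == 0:
            raise FormatError(f"{path}: empty bedGraph")
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=float)
            ends = sub["end"].to_numpy(dtype=float)
            vals = sub["value"].to_numpy(dtype=float)
            if (ends <= starts).any():
                raise FormatError(f"{path}: interval with end <= start on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise FormatError(f"{path}: overlapping intervals on {chrom}")
            # breakpoints: each segment contributes (start, end); gaps are flat
            pos = np.empty(2 * len(sub))
            pos[0::2], pos[1::2] = starts, ends
            mass = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            cum = np.empty(2 * len(sub))
            cum[0::2], cum[1::2] = mass[:-1], mass[1:]
            # adjacent segments sharing a breakpoint: keep strictly increasing pos
            keep = np.concatenate([[True], pos[1:] > pos[:-1]])
            per_chrom[chrom] = (pos[keep], cum[keep])
        return cls(per_chrom)

    def bounds(self, chrom: str) -> tuple[float, float] | None:
        if chrom not in self._per_chrom:
            return None
        pos, _ = self._per_chrom[chrom]
        return float(pos[0]), float(pos[-1])

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean coverage in each [edges[i], edges[i+1]) bin."""
        pos, cum = self._per_chrom[chrom]
        cum_at = np.interp(edges, pos, cum)
        return np.diff(cum_at) / np.diff(edges)


@dataclass
class MetageneLayout:
    """Bin layout: fixed-width flank bins, gene body rescaled to body_bins."""

    flank: int = 2000
    flank_bins: int = 50
    body_bins: int = 100

    def __post_init__(self) -> None:
        if self.flank_bins < 1 or self.body_bins < 1 or self.flank < 1:
            raise ConfigError("layout bins and flank must be positive")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


@dataclass
class MetageneProfile:
    log2_fe: np.ndarray
    layout: MetageneLayout
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        fb, bb = self.layout.flank_bins, self.layout.body_bins
        zone = ["upstream"] * fb + ["body"] * bb + ["downstream"] * fb
        return pd.DataFrame(
            {"bin": np.arange(self.layout.n_bins), "zone": zone, "log2_fe": self.log2_fe}
        )


def read_bed(path) -> pd.DataFrame:
    """6-column BED (chrom, start, end, name, score, strand), 0-based half-open."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: BED region with start >= end")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


def _region_edges(start: float, end: float, layout: MetageneLayout) -> np.ndarray:
    up = np.linspace(start - layout.flank, start, layout.flank_bins + 1)
    body = np.linspace(start, end, layout.body_bins + 1)
    down = np.linspace(end, end + layout.flank, layout.flank_bins + 1)
    return np.concatenate([up[:-1], body[:-1], down])


def metagene_profile(
    chip: CoverageTrack,
    input_: CoverageTrack,
    regions: pd.DataFrame,
    layout: MetageneLayout | None = None,
    pseudocount: float = 0.1,
) -> MetageneProfile:
    """Mean per-bin log2 ChIP/input fold enrichment over a region set.

    Each region maps onto flank_bins fixed-width upstream bins, body_bins
    length-rescaled body bins and flank_bins downstream bins; minus-strand
    regions are reversed so bin 0 is always the 5' flank.  Per-bin coverage of
    each track is depth-normalized to reads-per-million of the track's total
    mass before log2((chip + pc) / (input + pc)); the default pseudocount 0.1
    corresponds to 1 read per 10 million.  Regions extending beyond either
    track's covered span are skipped with a warning.
    """
    layout = layout or MetageneLayout()
    chip_scale = 1e6 / chip.total_mass
    input_scale = 1e6 / input_.total_mass
    profiles = []
    for _, reg in regions.iterrows():
        lo = reg["start"] - layout.flank
        hi = reg["end"] + layout.flank
        ok = True
        for track in (chip, input_):
            b = track.bounds(reg["chrom"])
            if b is None or lo < b[0] or hi > b[1]:
                ok = False
        if not ok:
            warnings.warn(
                f"region {reg['name']} ({reg['chrom']}:{reg['start']}-{reg['end']}) "
                "outside track bounds; skipped",
                stacklevel=2,
            )
            continue
        edges = _region_edges(float(reg["start"]), float(reg["end"]), layout)
        c = chip.binned_means(reg["chrom"], edges) * chip_scale
        i = input_.binned_means(reg["chrom"], edges) * input_scale
        lfe = np.log2(c + pseudocount) - np.log2(i + pseudocount)
        if reg["strand"] == "-":
            lfe = lfe[::-1]
        profiles.append(lfe)
    if not profiles:
        raise ConfigError("all regions skipped: nothing to average")
    return MetageneProfile(
        log2_fe=np.mean(profiles, axis=0), layout=layout, n_regions=len(profiles)
    )
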