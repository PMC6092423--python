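"""Core enrichment statistic of the sorted screen.

Pipeline: quantile-normalize all sample columns jointly, take the per-replicate
log2 fold change of the high-intensity fraction over the input (with a
half-count pseudocount), then a two-sided one-sample Student's t-test of the
replicate log2-fc values against zero (df = R - 1; the replicates are paired
by construction, each infection yielding both fractions).  Primary candidates
are constructs with mean log2-fc > 0.3 and P < 0.01 (strict), and the primary
gene set is every gene with at least one passing construct.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .countmatrix import CountMatrix, parse_sample_name
from .errors import ConfigError, PairingError


@dataclass
class SelectionThresholds:
    """Primary-selection cut-offs; defaults are the screen's published values."""

    lfc_min: float = 0.3
    p_max: float = 0.01
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.p_max <= 1.0):
            raise ConfigError("p_max must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization to the rank-mean reference distribution.

    After normalization every column's sorted values equal the across-column
    mean of sorted values.  Ties within a column receive the mean of the
    reference values spanned by their tied ranks, which makes the result
    deterministic and independent of input row order.  Idempotent on tie-free
    data; with ties, collapsing a tied span to its mean perturbs the reference
    of a second pass, so repeated application is only approximately stable.
    """
    if df.shape[1] < 2:
        raise ConfigError("quantile normalization needs at least 2 columns")
    vals = df.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        sorter = order[:, j]
        sv = vals[sorter, j]
        starts = np.flatnonzero(np.concatenate([[True], sv[1:] != sv[:-1]]))
        ends = np.concatenate([starts[1:], [n]])
        span_means = (cum[ends] - cum[starts]) / (ends - starts)
        out[sorter, j] = np.repeat(span_means, ends - starts)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def replicate_log2fc(
    normalized: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-construct, per-replicate log2(high + pc) - log2(input + pc).

    Columns must be named ``rep{i}_{input|high}``; output has one ``rep{i}``
    column per replicate.
    """
    pairs: dict[int, dict[str, str]] = {}
    for col in normalized.columns:
        rep, frac = parse_sample_name(col)
        pairs.setdefault(rep, {})[frac] = col
    lfc = {}
    for rep in sorted(pairs):
        cols = pairs[rep]
        if set(cols) != {"input", "high"}:
            raise PairingError(f"replicate {rep} lacks a paired fraction")
        lfc[f"rep{rep}"] = np.log2(
            normalized[cols["high"]] + pseudocount
        ) - np.log2(normalized[cols["input"]] + pseudocount)
    return pd.DataFrame(lfc, index=normalized.index)


def construct_test(lfc: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-test of replicate log2-fc against 0, per construct.

    Zero-variance convention: if all replicate values coincide, P := 0 when the
    common value is non-zero (infinitely strong evidence under the model) and
    P := 1 when it is zero.  A zero t statistic likewise gives P = 1.
    """
    r = lfc.shape[1]
    if r < 2:
        raise ConfigError("insufficient replicates: need R >= 2")
    vals = lfc.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(r))
        p = 2.0 * sps.t.sf(np.abs(t), df=r - 1)
    # identical replicate values (up to float noise) count as zero variance
    zero_var = sd <= 1e-12 * np.abs(mean)
    p[zero_var & (mean != 0)] = 0.0
    p[zero_var & (mean == 0)] = 1.0
    t[zero_var] = np.where(
        mean[zero_var] > 0, np.inf, np.where(mean[zero_var] < 0, -np.inf, 0.0)
    )
    out = lfc.copy()
    out["mean_log2fc"] = mean
    out["t"] = t
    out["p_value"] = p
    return out


def construct_test_unpaired(normalized: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Unpaired variant: two-sample t between log2 high and log2 input columns.

    Provided for comparison; the paired one-sample form is the default because
    each infection replicate yields both fractions.
    """
    highs, inputs = [], []
    for col in normalized.columns:
        _, frac = parse_sample_name(col)
        (highs if frac == "high" else inputs).append(col)
    if len(highs) < 2 or len(inputs) < 2:
        raise ConfigError("insufficient replicates: need R >= 2")
    lh = np.log2(normalized[highs].to_numpy() + pseudocount)
    li = np.log2(normalized[inputs].to_numpy() + pseudocount)
    t, p = sps.ttest_ind(lh, li, axis=1, equal_var=True)
    out = pd.DataFrame(index=normalized.index)
    out["mean_log2fc"] = lh.mean(axis=1) - li.mean(axis=1)
    out["t"] = t
    out["p_value"] = p
    return out


def compute_construct_stats(
    matrix: CountMatrix,
    pseudocount: float = 0.5,
    paired: bool = True,
) -> pd.DataFrame:
    """Quantile normalization -> replicate log2-fc -> t-test, in one call.

    Returns a DataFrame indexed by construct_id with columns gene,
    rep1..repR (paired mode), mean_log2fc, t, p_value and a BH-adjusted
    q_value (informational only; selection uses raw P).
    """
    norm = quantile_normalize(matrix.counts)
    if paired:
        lfc = replicate_log2fc(norm, pseudocount=pseudocount)
        stats = construct_test(lfc)
    else:
        stats = construct_test_unpaired(norm, pseudocount=pseudocount)
    stats.insert(0, "gene", matrix.genes)
    stats["q_value"] = sps.false_discovery_control(stats["p_value"].to_numpy())
    return stats


@dataclass
class PrimarySelection:
    """Primary hits with per-gene provenance of which constructs passed."""

    constructs: frozenset[str]
    genes: frozenset[str]
    provenance: dict[str, list[str]]  # gene -> passing construct ids
    table: pd.DataFrame               # stats table with a 'selected' flag

    def __len__(self) -> int:
        return len(self.constructs)


def primary_select(
    stats: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> PrimarySelection:
    """Apply the primary cut-offs (strict: mean_log2fc > lfc_min AND p < p_max).

    A gene is selected when at least one of its constructs passes — the upper
    significantly-enriched group of the screen scatter.  Empty selections are
    valid.
    """
    thresholds = thresholds or SelectionThresholds()
    sel = (stats["mean_log2fc"] > thresholds.lfc_min) & (
        stats["p_value"] < thresholds.p_max
    )
    table = stats.copy()
    table["selected"] = sel
    passing = table.index[sel]
    provenance: dict[str, list[str]] = {}
    for cid, gene in table.loc[passing, "gene"].items():
        provenance.setdefault(gene, []).append(cid)
    return PrimarySelection(
        constructs=frozenset(passing),
        genes=frozenset(provenance),
        provenance=provenance,
        table=table,
    )
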