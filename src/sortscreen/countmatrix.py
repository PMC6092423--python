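"""Construct x sample count matrix for a sorted pooled screen.

Samples are named ``rep{i}_{fraction}`` with fraction one of ``input`` (the
unselected reference pool) or ``high`` (the sorted high-reporter-intensity
pool).  Every replicate must carry exactly one column of each fraction.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError

FRACTIONS = ("input", "high")

_SAMPLE_RE = re.compile(r"^rep(\d+)_(input|high)$")


def sample_name(replicate: int, fraction: str) -> str:
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}")
    return f"rep{replicate}_{fraction}"


def parse_sample_name(name: str) -> tuple[int, str]:
    """Split ``rep{i}_{fraction}`` into (replicate, fraction)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(f"sample column {name!r} is not of the form rep<i>_<input|high>")
    return int(m.group(1)), m.group(2)


@dataclass
class CountMatrix:
    """Integer barcode-read counts, one row per shRNA construct.

    Parameters
    ----------
    counts
        DataFrame indexed by construct_id with one integer column per sample.
    genes
        Series mapping construct_id -> target gene symbol, aligned to
        ``counts.index``.
    """

    counts: pd.DataFrame
    genes: pd.Series

    def __post_init__(self) -> None:
        if self.counts.shape[1] == 0 or self.counts.shape[0] == 0:
            raise FormatError("count matrix is empty")
        by_rep: dict[int, set[str]] = {}
        for col in self.counts.columns:
            rep, frac = parse_sample_name(col)
            fracs = by_rep.setdefault(rep, set())
            if frac in fracs:
                raise FormatError(f"duplicate sample column {col!r}")
            fracs.add(frac)
        for rep, fracs in by_rep.items():
            missing = set(FRACTIONS) - fracs
            if missing:
                raise PairingError(
                    f"replicate {rep} lacks fraction(s): {', '.join(sorted(missing))}"
                )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("count matrix values must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("count matrix values must be non-negative")
        self.genes = self.genes.reindex(self.counts.index)
        if self.genes.isna().any():
            raise FormatError("every construct needs a gene annotation")
        # canonical column order: replicate ascending, input before high
        ordered = [
            sample_name(r, f)
            for r in sorted(by_rep)
            for f in FRACTIONS
        ]
        self.counts = self.counts[ordered]

    @property
    def replicates(self) -> list[int]:
        return sorted({parse_sample_name(c)[0] for c in self.counts.columns})

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def pair(self, replicate: int) -> tuple[str, str]:
        """Return the (input, high) column names of one replicate."""
        return sample_name(replicate, "input"), sample_name(replicate, "high")

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "gene", self.genes)
        out.index.name = "construct_id"
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="construct_id")
        if "gene" not in df.columns:
            raise FormatError(f"{path}: missing 'gene' column")
        genes = df["gene"]
        return cls(counts=df.drop(columns="gene"), genes=genes)
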