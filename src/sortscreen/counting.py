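"""Barcode deconvolution: FASTQ reads -> construct x sample count matrix.

Each sequencing read carries the construct barcode at a fixed, configurable
offset (the amplicon is produced by two-round PCR, so the barcode position is
constant).  A read is assigned to the unique construct whose barcode matches
the read substring within ``max_mismatch`` Hamming distance; reads with no
match are *unmatched*, reads tied between two or more constructs at the best
distance are *ambiguous* and never counted.
"""
from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .countmatrix import CountMatrix, sample_name
from .errors import FormatError, PairingError
from .simulate import LibrarySpec

_AMBIG = object()  # sentinel for barcode-neighborhood collisions


@dataclass
class CountingReport:
    """Read-assignment accounting; matched + unmatched + ambiguous == total."""

    total: int = 0
    matched: int = 0
    unmatched: int = 0
    ambiguous: int = 0
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)

    def add_sample(self, name: str, total: int, matched: int, unmatched: int, ambiguous: int) -> None:
        assert matched + unmatched + ambiguous == total
        self.per_sample[name] = {
            "total": total,
            "matched": matched,
            "unmatched": unmatched,
            "ambiguous": ambiguous,
            "match_rate": matched / total if total else float("nan"),
        }
        self.total += total
        self.matched += matched
        self.unmatched += unmatched
        self.ambiguous += ambiguous

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total": self.total,
                    "matched": self.matched,
                    "unmatched": self.unmatched,
                    "ambiguous": self.ambiguous,
                    "per_sample": self.per_sample,
                },
                fh,
                indent=2,
            )


def read_library_table(path: str | Path) -> LibrarySpec:
    """Load and validate a library annotation TSV.

    Requires columns construct_id, barcode, gene; module_id is optional and
    defaults to M1.  Duplicate barcodes are rejected by name.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no constructs") from None
    missing = {"construct_id", "barcode", "gene"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no constructs")
    dup = df["barcode"].duplicated(keep=False)
    if dup.any():
        raise FormatError(
            f"{path}: duplicate barcode {df.loc[dup, 'barcode'].iloc[0]!r}"
        )
    if "module_id" not in df.columns:
        df["module_id"] = "M1"
    lengths = df["barcode"].str.len().unique()
    if len(lengths) != 1:
        raise FormatError(f"{path}: barcodes have mixed lengths {sorted(lengths)}")
    return LibrarySpec(df[["construct_id", "barcode", "gene", "module_id"]])


def _hamming1_neighbors(barcode: str) -> list[str]:
    out = []
    for i, b in enumerate(barcode):
        for c in "ACGT":
            if c != b:
                out.append(barcode[:i] + c + barcode[i + 1:])
    return out


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_barcodes(
    fastq_path: str | Path,
    library: LibrarySpec,
    barcode_offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict[str, int]]:
    """Count reads per construct in one FASTQ (plain or gzip).

    Returns (counts aligned to the full library, zeros included;
    assignment tallies dict with keys total/matched/unmatched/ambiguous).
    """
    barcodes = library.table["barcode"].to_numpy()
    ids = library.construct_ids
    bc_len = len(barcodes[0])
    exact = {bc: i for i, bc in enumerate(barcodes)}

    near: dict[str, object] | None = None
    if max_mismatch == 1:
        near = {}
        for i, bc in enumerate(barcodes):
            for var in _hamming1_neighbors(bc):
                if var in exact:
                    continue  # resolved at distance 0
                near[var] = _AMBIG if var in near else i
    bc_mat = None
    if max_mismatch >= 2:
        # slow generic path: vectorized Hamming scan of the whole library
        bc_mat = np.frombuffer(
            "".join(barcodes).encode(), dtype=np.uint8
        ).reshape(len(barcodes), bc_len)

    counts = np.zeros(len(ids), dtype=np.int64)
    total = matched = unmatched = ambiguous = 0
    end = barcode_offset + bc_len
    with _open_maybe_gzip(fastq_path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                total += 1
                if len(seq) < end:
                    unmatched += 1
                    continue
                sub = seq[barcode_offset:end].upper()
                hit = exact.get(sub)
                if hit is None and near is not None:
                    hit = near.get(sub)
                elif hit is None and bc_mat is not None:
                    q = np.frombuffer(sub.encode(), dtype=np.uint8)
                    dist = (bc_mat != q).sum(axis=1)
                    best = dist.min()
                    if best <= max_mismatch:
                        winners = np.flatnonzero(dist == best)
                        hit = int(winners[0]) if len(winners) == 1 else _AMBIG
                if hit is None:
                    unmatched += 1
                elif hit is _AMBIG:
                    ambiguous += 1
                else:
                    counts[hit] += 1
                    matched += 1
        except ValueError as exc:
            raise FormatError(
                f"{fastq_path}: malformed FASTQ near record {total + 1}: {exc}"
            ) from exc
    return (
        pd.Series(counts, index=ids, name="count"),
        {"total": total, "matched": matched, "unmatched": unmatched, "ambiguous": ambiguous},
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"file", "replicate", "fraction"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s) {sorted(missing)}")
    return df


def assemble_count_matrix(
    per_sample_counts: dict[str, pd.Series],
    sample_sheet: pd.DataFrame,
    genes: pd.Series,
) -> CountMatrix:
    """Stack per-sample count vectors into a validated CountMatrix.

    ``per_sample_counts`` is keyed by file path / file label as given in the
    sample sheet's ``file`` column.  Column order in the input is irrelevant;
    the matrix is canonically ordered.  A replicate missing either fraction
    raises :class:`PairingError` (enforced by CountMatrix itself).
    """
    cols = {}
    for _, row in sample_sheet.iterrows():
        name = sample_name(int(row["replicate"]), str(row["fraction"]))
        if name in cols:
            raise FormatError(f"duplicate sample (replicate {row['replicate']}, {row['fraction']})")
        cols[name] = per_sample_counts[row["file"]]
    df = pd.DataFrame(cols)
    return CountMatrix(counts=df, genes=genes)


def count_samples(
    sample_sheet: pd.DataFrame,
    library: LibrarySpec,
    barcode_offset: int = 0,
    max_mismatch: int = 0,
) -> tuple[CountMatrix, CountingReport]:
    """Count every FASTQ in a sample sheet and assemble the matrix."""
    report = CountingReport()
    per_sample: dict[str, pd.Series] = {}
    for _, row in sample_sheet.iterrows():
        counts, tallies = count_barcodes(
            row["file"], library, barcode_offset=barcode_offset, max_mismatch=max_mismatch
        )
        per_sample[row["file"]] = counts
        report.add_sample(
            sample_name(int(row["replicate"]), str(row["fraction"])), **tallies
        )
    matrix = assemble_count_matrix(per_sample, sample_sheet, library.genes)
    return matrix, report
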