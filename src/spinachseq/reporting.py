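"""Accounting and summary arithmetic: read-count bookkeeping, percentage roll-ups,
and assembly statistics (N50, mean length, GC%, length histogram).

A reference nine-accession sequencing summary (read counts per library from a
published spinach germplasm panel) ships with the package as example input for the
accounting functions; totals and percentages are always recomputed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AccessionRecord",
    "AssemblyStats",
    "accounting_table",
    "percent",
    "assembly_stats",
    "load_sequencing_summary",
]

ACCOUNTING_COLUMNS = [
    "sample_id",
    "accession_number",
    "species",
    "raw_reads",
    "high_quality_reads",
    "rrna_reads",
    "final_cleaned_reads",
    "final_cleaned_nucleotides",
]
_NUMERIC = ACCOUNTING_COLUMNS[3:]


@dataclass(frozen=True)
class AccessionRecord:
    """Per-library read accounting; cleaned reads = high-quality reads - rRNA reads."""

    sample_id: str
    accession_number: str
    species: str
    raw_reads: int
    high_quality_reads: int
    rrna_reads: int
    final_cleaned_reads: int
    final_cleaned_nucleotides: int


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_bp: int
    mean_length_bp: float
    n50_bp: int
    gc_percent: float
    length_histogram: tuple[tuple[float, ...], tuple[int, ...]]  # (bin edges, counts)


def load_sequencing_summary() -> pd.DataFrame:
    """The bundled nine-library sequencing summary (one row per accession)."""
    with resources.files("spinachseq.data").joinpath("sequencing_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def accounting_table(
    records: Union[pd.DataFrame, Iterable[AccessionRecord]],
    strict: bool = False,
) -> pd.DataFrame:
    """Per-accession accounting rows plus a column-wise ``Total`` row.

    Each row is checked for the invariant ``final_cleaned_reads =
    high_quality_reads - rrna_reads``; violations set ``consistent`` to False and,
    in strict mode, raise.
    """
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([r.__dict__ for r in records])
    missing = set(ACCOUNTING_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"accounting table is missing columns: {sorted(missing)}")
    if frame.empty:
        raise ValueError("need at least one accession record")
    for col in _NUMERIC:
        frame[col] = frame[col].astype("int64")
        if (frame[col] < 0).any():
            raise ValueError(f"{col} contains negative values")

    frame["consistent"] = (
        frame["final_cleaned_reads"]
        == frame["high_quality_reads"] - frame["rrna_reads"]
    )
    if strict and not frame["consistent"].all():
        bad = frame.loc[~frame["consistent"], "sample_id"].tolist()
        raise ValueError(f"inconsistent accounting rows: {bad}")

    total = {col: frame[col].sum() for col in _NUMERIC}
    total.update(
        sample_id="Total",
        accession_number="",
        species="",
        consistent=bool(frame["consistent"].all()),
    )
    out = pd.concat([frame, pd.DataFrame([total])], ignore_index=True)
    return out[ACCOUNTING_COLUMNS + ["consistent"]]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-away-from-zero to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def _n50(lengths: np.ndarray) -> int:
    ordered = np.sort(lengths)[::-1]
    cumulative = np.cumsum(ordered)
    half = cumulative[-1] / 2
    return int(ordered[np.searchsorted(cumulative, half)])


def assembly_stats(
    fasta: Union[str, Path, Sequence[tuple[str, str]]],
    histogram_bins: int = 20,
) -> AssemblyStats:
    """Summary statistics of an assembly from a FASTA path or (id, sequence) pairs.

    N50 is the length L such that sequences of length >= L jointly cover at least
    half of the total bases (descending cumulative sum). GC% counts G+C over
    unambiguous A/C/G/T bases only.
    """
    if isinstance(fasta, (str, Path)):
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta), "fasta")]
    else:
        seqs = list(fasta)
    if not seqs:
        raise ValueError("assembly contains no sequences")
    lengths = np.array([len(s) for _, s in seqs], dtype=np.int64)
    joined = "".join(s.upper() for _, s in seqs)
    gc = joined.count("G") + joined.count("C")
    at = joined.count("A") + joined.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases in assembly")
    counts, edges = np.histogram(lengths, bins=histogram_bins)
    return AssemblyStats(
        n_sequences=int(len(seqs)),
        total_bp=int(lengths.sum()),
        mean_length_bp=float(lengths.mean()),
        n50_bp=_n50(lengths),
        gc_percent=100.0 * gc / (gc + at),
        length_histogram=(tuple(edges.tolist()), tuple(counts.tolist())),
    )
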