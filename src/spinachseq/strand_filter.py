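"""Antisense-artifact contig filtering for strand-specific RNA-Seq assemblies.

Strand-specific libraries can retain spurious antisense contigs when second-strand
digestion is incomplete. After aligning reads back to the assembly, a contig whose
sense-direction read count is less than one tenth of its antisense count is treated
as such an artifact and discarded. The comparison is done in integer arithmetic
(``10 * sense < antisense``) so the boundary case ``10 * sense == antisense`` is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "StrandedContigCounts",
    "filter_antisense",
    "read_strand_tsv",
    "write_strand_tsv",
]


@dataclass(frozen=True)
class StrandedContigCounts:
    """Sense/antisense read tallies for one assembled contig."""

    contig_id: str
    sense_reads: int
    antisense_reads: int

    def __post_init__(self) -> None:
        for name in ("sense_reads", "antisense_reads"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValueError(f"{name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


CountsLike = Union[Iterable[StrandedContigCounts], pd.DataFrame]


def _as_frame(counts: CountsLike) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        frame = counts.copy()
    else:
        frame = pd.DataFrame(
            [(c.contig_id, c.sense_reads, c.antisense_reads) for c in counts],
            columns=["contig_id", "sense_reads", "antisense_reads"],
        )
    required = {"contig_id", "sense_reads", "antisense_reads"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"strand count table is missing columns: {sorted(missing)}")
    if frame["contig_id"].duplicated().any():
        dupes = frame.loc[frame["contig_id"].duplicated(), "contig_id"].tolist()
        raise ValueError(f"duplicate contig ids in strand counts: {dupes[:5]}")
    for col in ("sense_reads", "antisense_reads"):
        values = frame[col]
        if not pd.api.types.is_integer_dtype(values):
            as_int = values.astype("int64", errors="raise")
            if not (as_int == values).all():
                raise ValueError(f"{col} must contain integers")
            frame[col] = as_int
        if (frame[col] < 0).any():
            raise ValueError(f"{col} contains negative counts")
    return frame


def filter_antisense(counts: CountsLike) -> tuple[set[str], set[str]]:
    """Partition contigs into (kept, discarded) by the 1/10 sense:antisense rule.

    A contig is discarded iff ``10 * sense_reads < antisense_reads``. Contigs with
    no reads at all carry no evidence of antisense dominance and are kept.

    Returns
    -------
    (kept, discarded)
        Two disjoint sets of contig ids whose union is the input set.
    """
    frame = _as_frame(counts)
    discard_mask = 10 * frame["sense_reads"] < frame["antisense_reads"]
    discarded = set(frame.loc[discard_mask, "contig_id"])
    kept = set(frame.loc[~discard_mask, "contig_id"])
    return kept, discarded


def write_strand_tsv(counts: CountsLike, path: Union[str, Path]) -> pd.DataFrame:
    """Write the strand-count table with a ``kept`` 0/1 verdict column."""
    frame = _as_frame(counts)
    kept, _ = filter_antisense(frame)
    out = frame.loc[:, ["contig_id", "sense_reads", "antisense_reads"]].copy()
    out["kept"] = out["contig_id"].isin(kept).astype(int)
    out.to_csv(path, sep="\t", index=False)
    return out


def read_strand_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a strand-count TSV (``kept`` column, if present, is ignored on input)."""
    frame = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    return _as_frame(frame[["contig_id", "sense_reads", "antisense_reads"]])
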