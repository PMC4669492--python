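"""RNA-Seq based SNP genotyping from read alignments.

The genotyping path mirrors a pileup-based transcriptome SNP workflow for a small
germplasm panel:

1. exact-duplicate reads (same accession, contig, start, strand and sequence) are
   collapsed to one record to damp PCR-amplification artifacts;
2. the remaining reads are piled up into per-accession, per-position base counts;
3. a homozygous genotype is called where the majority base is supported by at least
   ``min_reads`` deduplicated reads and its frequency exceeds ``min_freq`` (default
   3 reads, 75%); sites with enough depth but no dominant base are ``ambiguous``,
   shallow sites are ``missing``;
4. a position is a SNP when at least two distinct alleles are called across
   accessions; an optional completeness filter keeps only sites genotyped in every
   required accession (the substrate for diversity counts and the phylogeny).

All coordinates are 1-based. Ambiguous calls are treated as missing downstream; the
allele universe is {A, C, G, T} and other read bases are ignored before pileup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentRecord",
    "SiteObservation",
    "GenotypeCall",
    "records_to_frame",
    "deduplicate_reads",
    "pileup",
    "call_genotype",
    "call_genotypes",
    "identify_snp_sites",
    "filter_complete",
    "count_group_snps",
    "write_vcf",
    "read_pileup_tsv",
    "write_pileup_tsv",
    "write_genotype_tsv",
]

BASES = ("A", "C", "G", "T")
COUNT_COLUMNS = ["count_A", "count_C", "count_G", "count_T"]
RECORD_KEY = ["accession", "contig", "start", "strand", "sequence"]
PILEUP_COLUMNS = ["contig", "pos", "accession"] + COUNT_COLUMNS

# read-base byte -> allele code, -1 for anything outside {A,C,G,T}
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (post-alignment contract; the aligner itself is upstream)."""

    contig_id: str
    start: int  # 1-based leftmost aligned position
    strand: str  # "+" or "-"
    read_sequence: str
    accession_id: str
    is_duplicate: bool = False  # simulator ground truth, ignored by dedup

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if not self.read_sequence:
            raise ValueError("read_sequence must be non-empty")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class SiteObservation:
    """Deduplicated base counts for one accession at one contig position."""

    contig_id: str
    pos: int
    accession_id: str
    base_counts: Mapping[str, int]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.get(b, 0) for b in BASES)


@dataclass(frozen=True)
class GenotypeCall:
    contig_id: str
    pos: int
    accession_id: str
    state: str  # "called" | "ambiguous" | "missing"
    allele: Optional[str]
    supporting_reads: int
    allele_frequency: float


RecordsLike = Union[pd.DataFrame, Iterable[AlignmentRecord]]


def records_to_frame(records: RecordsLike) -> pd.DataFrame:
    """Normalize a record collection to the columnar alignment-table form."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(
            [
                (r.accession_id, r.contig_id, r.start, r.strand, r.read_sequence,
                 r.is_duplicate)
                for r in records
            ],
            columns=RECORD_KEY + ["is_duplicate"],
        )
    missing = set(RECORD_KEY) - set(frame.columns)
    if missing:
        raise ValueError(f"alignment table is missing columns: {sorted(missing)}")
    return frame


def deduplicate_reads(records: RecordsLike) -> pd.DataFrame:
    """Collapse exact read duplicates, keeping the first occurrence in input order.

    Two records are duplicates when accession, contig, start, strand and sequence
    all coincide — the PCR-duplicate signature available without alignment flags.
    Idempotent: applying it twice equals applying it once.
    """
    frame = records_to_frame(records)
    return frame.drop_duplicates(subset=RECORD_KEY, keep="first").reset_index(drop=True)


def pileup(
    records: RecordsLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Pile deduplicated reads into per-(contig, pos, accession) base counts.

    Returns a table with columns ``contig pos accession count_A count_C count_G
    count_T``, sorted by (contig, pos, accession). Positions a read covers with a
    non-ACGT base contribute nothing at that position. If ``contig_lengths`` is
    given, reads extending past a contig end raise.
    """
    frame = records_to_frame(records)
    if frame.empty:
        return pd.DataFrame(columns=PILEUP_COLUMNS)

    seqs = frame["sequence"].to_numpy()
    seq_lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    starts = frame["start"].to_numpy(dtype=np.int64)
    if (starts < 1).any():
        raise ValueError("alignment start positions must be >= 1")

    contig_codes, contig_index = pd.factorize(frame["contig"], sort=True)
    acc_codes, acc_index = pd.factorize(frame["accession"], sort=True)

    if contig_lengths is not None:
        for cid, end in zip(
            contig_index,
            pd.Series(starts + seq_lens - 1).groupby(contig_codes).max(),
        ):
            limit = contig_lengths.get(str(cid))
            if limit is None:
                raise ValueError(f"contig {cid!r} absent from contig_lengths")
            if end > limit:
                raise ValueError(
                    f"read extends to position {end} beyond contig {cid!r} "
                    f"length {limit}"
                )

    total = int(seq_lens.sum())
    read_idx = np.repeat(np.arange(len(seqs)), seq_lens)
    offsets = np.arange(total) - np.repeat(np.cumsum(seq_lens) - seq_lens, seq_lens)
    pos = starts[read_idx] + offsets
    base = _BASE_CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]

    keep = base >= 0
    pos, base, read_idx = pos[keep], base[keep].astype(np.int64), read_idx[keep]
    site = (
        acc_codes[read_idx].astype(np.int64) * len(contig_index) + contig_codes[read_idx]
    ) * (int(pos.max()) + 1) + pos
    key = site * 4 + base
    uniq, counts = np.unique(key, return_counts=True)
    u_base = uniq % 4
    u_site = uniq // 4
    site_keys, inverse = np.unique(u_site, return_inverse=True)
    mat = np.zeros((len(site_keys), 4), dtype=np.int64)
    mat[inverse, u_base] = counts

    span = int(pos.max()) + 1
    s_pos = site_keys % span
    s_rest = site_keys // span
    s_contig = s_rest % len(contig_index)
    s_acc = s_rest // len(contig_index)

    out = pd.DataFrame(
        {
            "contig": contig_index.take(s_contig),
            "pos": s_pos,
            "accession": acc_index.take(s_acc),
        }
    )
    for j, col in enumerate(COUNT_COLUMNS):
        out[col] = mat[:, j]
    return out.sort_values(["contig", "pos", "accession"]).reset_index(drop=True)


def _validate_thresholds(min_reads: int, min_freq: float) -> None:
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if not (0.0 <= min_freq < 1.0):
        raise ValueError(f"min_freq must lie in [0, 1), got {min_freq}")


def call_genotypes(
    observations: pd.DataFrame,
    min_reads: int = 3,
    min_freq: float = 0.75,
) -> pd.DataFrame:
    """Vectorized genotype calling over a pileup table.

    Rules, with M the majority-base count and T the total deduplicated depth:
    ``called`` iff M >= min_reads and M/T > min_freq (strict); ``missing`` iff
    T < min_reads; otherwise ``ambiguous``. Called genotypes are homozygous by
    construction. Returns columns ``contig pos accession state allele
    supporting_reads allele_frequency``.
    """
    _validate_thresholds(min_reads, min_freq)
    counts = observations[COUNT_COLUMNS].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative base counts in pileup")
    total = counts.sum(axis=1)
    best = counts.max(axis=1)
    allele = np.array(BASES)[counts.argmax(axis=1)]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, best / np.maximum(total, 1), 0.0)

    called = (best >= min_reads) & (freq > min_freq)
    missing = total < min_reads
    state = np.where(called, "called", np.where(missing, "missing", "ambiguous"))

    out = observations[["contig", "pos", "accession"]].copy()
    out["state"] = state
    out["allele"] = np.where(called, allele, None)
    out["supporting_reads"] = best
    out["allele_frequency"] = freq
    return out


def call_genotype(
    obs: SiteObservation, min_reads: int = 3, min_freq: float = 0.75
) -> GenotypeCall:
    """Call a single site observation (scalar convenience over ``call_genotypes``)."""
    frame = pd.DataFrame(
        [
            {
                "contig": obs.contig_id,
                "pos": obs.pos,
                "accession": obs.accession_id,
                **{f"count_{b}": int(obs.base_counts.get(b, 0)) for b in BASES},
            }
        ]
    )
    row = call_genotypes(frame, min_reads=min_reads, min_freq=min_freq).iloc[0]
    return GenotypeCall(
        contig_id=obs.contig_id,
        pos=obs.pos,
        accession_id=obs.accession_id,
        state=row["state"],
        allele=row["allele"],
        supporting_reads=int(row["supporting_reads"]),
        allele_frequency=float(row["allele_frequency"]),
    )


def identify_snp_sites(calls: pd.DataFrame) -> pd.DataFrame:
    """Identify SNP sites from genotype calls across accessions.

    A (contig, pos) is a SNP when at least two distinct alleles occur among
    ``called`` states; ambiguous and missing calls contribute nothing to the allele
    set. Returns the site-by-accession allele table (rows: MultiIndex (contig, pos)
    sorted; columns: every accession present in ``calls``; NaN where not called),
    restricted to SNP rows.
    """
    accessions = sorted(calls["accession"].unique())
    called = calls[calls["state"] == "called"]
    if called.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["contig", "pos"])
        return pd.DataFrame(index=idx, columns=accessions, dtype=object)
    table = called.pivot_table(
        index=["contig", "pos"],
        columns="accession",
        values="allele",
        aggfunc="first",
    ).reindex(columns=accessions)
    n_alleles = table.apply(lambda row: row.dropna().nunique(), axis=1)
    return table.loc[n_alleles >= 2].sort_index()


def filter_complete(
    snp_table: pd.DataFrame, required_accessions: Sequence[str]
) -> pd.DataFrame:
    """Keep SNP sites called in every required accession (no missing entries).

    The returned matrix is restricted to ``required_accessions`` (in the given
    order); sites that are monomorphic within the required subset are retained, as
    their polymorphism was established over the full panel.
    """
    required = list(required_accessions)
    if not required:
        raise ValueError("required_accessions must be non-empty")
    unknown = [a for a in required if a not in snp_table.columns]
    if unknown:
        raise ValueError(f"accessions absent from SNP table: {unknown}")
    sub = snp_table[required]
    return sub.loc[sub.notna().all(axis=1)]


def count_group_snps(
    matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    unions: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.Series:
    """Count polymorphic sites within named accession groups (and group unions).

    For group G the count is the number of matrix sites with >= 2 distinct
    non-missing alleles among the accessions of G. ``unions`` maps a name to a list
    of group names whose accession sets are pooled; union counts are always >= the
    count of any member group.
    """
    resolved: dict[str, list[str]] = {}
    for name, accs in groups.items():
        accs = list(accs)
        unknown = [a for a in accs if a not in matrix.columns]
        if unknown:
            raise ValueError(f"group {name!r} references unknown accessions {unknown}")
        resolved[name] = accs
    if unions:
        for name, members in unions.items():
            pooled: list[str] = []
            for g in members:
                if g not in resolved:
                    raise ValueError(f"union {name!r} references unknown group {g!r}")
                pooled.extend(resolved[g])
            resolved[name] = sorted(set(pooled))

    counts = {}
    for name, accs in resolved.items():
        sub = matrix[accs]
        counts[name] = int((sub.apply(lambda r: r.dropna().nunique(), axis=1) >= 2).sum())
    return pd.Series(counts, name="n_snps")


def write_vcf(
    snp_table: pd.DataFrame,
    path: Union[str, Path],
    source: str = "spinachseq",
) -> None:
    """Write the site-by-accession allele table as VCF 4.2.

    REF is the most frequent called allele at the site (ties broken alphabetically),
    remaining alleles become ALT in descending-count then alphabetical order.
    Genotypes are homozygous (``0/0``, ``1/1``, ...) or ``./.`` where not called.
    """
    accessions = list(snp_table.columns)
    contigs = sorted({str(c) for c, _ in snp_table.index})
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(accessions)
    )
    for (contig, pos), row in snp_table.sort_index().iterrows():
        alleles = row.dropna()
        order = sorted(
            alleles.value_counts().items(), key=lambda kv: (-kv[1], kv[0])
        )
        ordered = [a for a, _ in order]
        ref, alts = ordered[0], ordered[1:]
        index = {a: i for i, a in enumerate(ordered)}
        gts = [
            "./." if pd.isna(row[a]) else f"{index[row[a]]}/{index[row[a]]}"
            for a in accessions
        ]
        lines.append(
            "\t".join(
                [str(contig), str(int(pos)), ".", ref, ",".join(alts) or ".", ".",
                 "PASS", ".", "GT"] + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_pileup_tsv(observations: pd.DataFrame, path: Union[str, Path]) -> None:
    observations[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read the simple columnar pileup dialect (header line, tab-separated)."""
    frame = pd.read_csv(path, sep="\t", dtype={"contig": str, "accession": str})
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"pileup file is missing columns: {sorted(missing)}")
    return frame[PILEUP_COLUMNS]


def write_genotype_tsv(snp_table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = snp_table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep=".")
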