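"""RPKM expression profiles, correlation, and average-linkage clustering.

Expression for each unigene is normalized to RPKM (reads per kilobase of transcript
per million mapped reads): ``RPKM = count * 1e9 / (length_bp * library_size)``,
with the library size taken as total reads mapped to the unigene set per accession.

Accession similarity is the Pearson correlation of log2(RPKM + 1) profiles (the log
damps the heavy right tail of RPKM; the untransformed option is exposed). Profiles
are clustered on the dissimilarity 1 - r with unweighted average linkage (UPGMA
update), and cluster robustness is assessed by resampling genes with replacement:
the support of a cluster is the percentage of replicate dendrograms containing that
exact accession subset as a cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ClusterTree",
    "rpkm",
    "pearson_matrix",
    "hier_cluster",
    "bootstrap_clusters",
]


@dataclass
class ClusterTree:
    """Agglomerative dendrogram over accessions.

    ``merges`` lists (left members, right members, height) in merge order with
    non-decreasing heights; ``supports`` maps each merged accession subset to its
    bootstrap percentage.
    """

    labels: tuple[str, ...]
    merges: list[tuple[frozenset, frozenset, float]]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def clusters(self) -> set[frozenset]:
        """Every non-singleton cluster created by a merge (including the root)."""
        return {frozenset(a | b) for a, b, _ in self.merges}

    def has_cluster(self, members) -> bool:
        members = frozenset(members)
        return len(members) == 1 or members in self.clusters()

    def newick(self) -> str:
        """Ultrametric newick; supports, where present, as internal node labels."""
        nodes: dict[frozenset, tuple[str, float]] = {
            frozenset({lab}): (lab, 0.0) for lab in self.labels
        }
        text = ""
        for left, right, height in self.merges:
            parts = sorted(
                (min(side), nodes[frozenset(side)]) for side in (left, right)
            )
            inner = ",".join(
                f"{txt}:{height - h:.10g}" for _, (txt, h) in parts
            )
            merged = frozenset(left | right)
            label = ""
            if merged in self.supports:
                label = f"{self.supports[merged]:.10g}"
            text = f"({inner}){label}"
            nodes[merged] = (text, height)
        return text + ";"


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Normalize a genes x accessions raw count matrix to RPKM.

    ``library_sizes`` defaults to the per-accession column sums (total mapped
    reads). Zero or negative lengths/library sizes raise.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"gene lengths missing for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0 for every accession")
    return counts.div(lengths, axis=0).div(library_sizes, axis=1) * 1e9


def pearson_matrix(
    expr: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Accession-by-accession Pearson correlation of expression profiles.

    Profiles are log2(x + 1)-transformed by default. A zero-variance profile has
    no defined correlation: the affected entries are NaN and a warning is issued
    rather than silently reporting 0.
    """
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes to correlate profiles")
    x = expr.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    centered = x - x.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    zero_var = norms == 0
    if zero_var.any():
        bad = [str(c) for c, z in zip(expr.columns, zero_var) if z]
        warnings.warn(
            f"zero-variance expression profile(s), correlation undefined: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero_var, 1.0, norms)
    corr = (centered / safe).T @ (centered / safe)
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    np.fill_diagonal(corr, np.where(zero_var, np.nan, 1.0))
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=expr.columns, columns=expr.columns)


def hier_cluster(corr: pd.DataFrame) -> ClusterTree:
    """Average-linkage (UPGMA) agglomeration on the dissimilarity 1 - r.

    Between-cluster dissimilarity is the unweighted average over member pairs;
    equal-dissimilarity ties are broken by the smallest pair of cluster labels
    (a cluster is labeled by its smallest member), so the merge sequence is
    independent of input order.
    """
    labels = [str(c) for c in corr.columns]
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains undefined entries")
    diss = 1.0 - corr.to_numpy(dtype=float)

    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    clusters: dict[str, frozenset] = {lab: frozenset({lab}) for lab in labels}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d[_key(a, labels[j])] = float(diss[i, j])

    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        ordered = sorted(clusters)
        height, a, b = min(
            (d[_key(x, y)], x, y)
            for i, x in enumerate(ordered)
            for y in ordered[i + 1 :]
        )
        merges.append((clusters[a], clusters[b], height))
        merged = clusters[a] | clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        new_label = min(a, b)
        fresh = {
            c: (na * d[_key(a, c)] + nb * d[_key(b, c)]) / (na + nb)
            for c in clusters
            if c not in (a, b)
        }
        for k in [k for k in d if a in k or b in k]:
            del d[k]
        for c, value in fresh.items():
            d[_key(new_label, c)] = value
        del clusters[a], clusters[b]
        clusters[new_label] = merged
    return ClusterTree(tuple(labels), merges)


def bootstrap_clusters(
    expr: pd.DataFrame,
    replicates: int = 1000,
    seed: Optional[int] = None,
    log_transform: bool = True,
) -> ClusterTree:
    """Gene-bootstrap support for every cluster of the full-data dendrogram.

    Genes (rows) are resampled with replacement; the support of a cluster is the
    percentage of replicates whose dendrogram contains the same exact accession
    subset. The returned dendrogram is the one from the full data.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    main = hier_cluster(pearson_matrix(expr, log_transform=log_transform))
    targets = main.clusters()
    hits = {c: 0 for c in targets}
    rng = np.random.default_rng(seed)
    n_genes = expr.shape[0]
    values = expr.to_numpy(dtype=float)
    for _ in range(replicates):
        idx = rng.integers(0, n_genes, size=n_genes)
        sample = pd.DataFrame(values[idx], columns=expr.columns)
        rep = hier_cluster(pearson_matrix(sample, log_transform=log_transform))
        for cluster in rep.clusters() & targets:
            hits[cluster] += 1
    main.supports = {c: 100.0 * k / replicates for c, k in hits.items()}
    return main
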