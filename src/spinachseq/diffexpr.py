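"""Two-group differential expression and the "highly differentially expressed" rule.

Significance is assessed with a two-group negative-binomial exact test: counts are
scaled to a common effective library size, summed within each group, and the
p-value is the total probability — conditional on the combined sum — of all group
splits as likely or less likely than the one observed, under NB sampling with a
single common dispersion. At dispersion 0 the NB degenerates to Poisson and the
conditional law is exactly binomial, which the tests exploit as an independent
oracle. The common dispersion is a method-of-moments estimate pooled over genes.

Raw p-values are corrected per comparison with the Benjamini–Hochberg step-up, and
a gene is declared *highly* differentially expressed between two species when all
three of the following hold:

1. the minimum RPKM in one species is at least ``fold`` (default 5) times the
   maximum RPKM in the other species;
2. the minimum RPKM in the higher-expressed species is at least ``min_rpkm``
   (default 5);
3. the BH-adjusted q-value is below ``alpha`` (default 0.05).

Boundaries follow the rule's wording: ">= " for the fold and floor ("at least"),
strict "<" for alpha ("less than").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ComparisonSpec",
    "nb_exact_test",
    "estimate_common_dispersion",
    "bh_adjust",
    "classify_highly_de",
    "de_table",
    "venn_counts",
    "enrichment_test",
]

_TIE_TOL = 1e-10  # log-probability tolerance for "as likely as observed"


@dataclass(frozen=True)
class ComparisonSpec:
    """A named two-group comparison between disjoint accession sets."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("comparison groups must be disjoint")


def _scaled_sums(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors: Optional[np.ndarray],
) -> tuple[int, int]:
    if size_factors is None:
        return int(round(counts_a.sum())), int(round(counts_b.sum()))
    sf = np.asarray(size_factors, dtype=float)
    if len(sf) != len(counts_a) + len(counts_b):
        raise ValueError("size_factors must cover all samples of both groups")
    if (sf <= 0).any():
        raise ValueError("size factors must be > 0")
    ref = np.exp(np.mean(np.log(sf)))
    merged = np.concatenate([counts_a, counts_b]) * (ref / sf)
    na = len(counts_a)
    return int(round(merged[:na].sum())), int(round(merged[na:].sum()))


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    dispersion: float,
    size_factors: Optional[Sequence[float]] = None,
) -> float:
    """Exact conditional test of equal means between two groups of NB counts.

    Counts are rescaled to a common effective library size (geometric-mean
    reference) and summed within groups. Conditional on the total, the group-A sum
    follows the convolution law of the two groups' NB sums under the null; the
    two-sided p-value accumulates every outcome whose conditional probability does
    not exceed the observed one. ``dispersion`` 0 reduces to the exact binomial
    split test. An all-zero gene returns p = 1 by convention.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("each group needs at least one sample")
    sa, sb = _scaled_sums(ca, cb, None if size_factors is None else np.asarray(size_factors))
    total = sa + sb
    if total == 0:
        return 1.0
    na, nb = len(ca), len(cb)
    support = np.arange(total + 1)
    if dispersion == 0.0:
        logp = stats.binom.logpmf(support, total, na / (na + nb))
    else:
        mu = total / (na + nb)  # common per-sample mean under the null
        ra, rb = na / dispersion, nb / dispersion
        logp = stats.nbinom.logpmf(support, ra, ra / (ra + na * mu)) + stats.nbinom.logpmf(
            total - support, rb, rb / (rb + nb * mu)
        )
        logp -= logsumexp(logp)
    observed = logp[sa]
    mask = logp <= observed + _TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> float:
    """Method-of-moments common NB dispersion across genes.

    Counts are adjusted by library-size factors (column sums over their mean, so
    equal libraries give factors of exactly 1). For each gene and each group with
    >= 2 replicates the moment estimate
    (s^2 - m) / m^2 is formed; group estimates are averaged within gene, clipped at
    zero, and averaged over genes with positive mean. With no replicated group the
    estimate is 0 and a warning is raised.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every accession needs a positive library size")
    factors = lib / lib.mean()
    adjusted = counts / factors

    replicated = [list(a) for a in groups.values() if len(a) >= 2]
    if not replicated:
        import warnings

        warnings.warn(
            "no group has >= 2 replicates; dispersion cannot be estimated, using 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0

    per_gene = []
    for accs in replicated:
        sub = adjusted[accs].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, np.nan)
        per_gene.append(phi)
    phi_gene = np.nanmean(np.column_stack(per_gene), axis=1)
    phi_gene = np.clip(phi_gene[~np.isnan(phi_gene)], 0.0, None)
    if phi_gene.size == 0:
        return 0.0
    return float(phi_gene.mean())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1 and order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_table(
    counts: pd.DataFrame,
    comparison: ComparisonSpec,
    dispersion: Optional[float] = None,
    size_factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene exact-test p and BH q values for one comparison.

    ``dispersion`` defaults to the pooled method-of-moments estimate over the two
    groups; ``size_factors`` defaults to library-size (column-sum) factors.
    """
    for acc in comparison.group_a + comparison.group_b:
        if acc not in counts.columns:
            raise ValueError(f"accession {acc!r} absent from count matrix")
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            counts, {"A": comparison.group_a, "B": comparison.group_b}
        )
    if size_factors is None:
        size_factors = counts[list(comparison.group_a + comparison.group_b)].sum(axis=0)
    sf = size_factors.reindex(list(comparison.group_a + comparison.group_b)).to_numpy(
        dtype=float
    )
    a = counts[list(comparison.group_a)].to_numpy(dtype=float)
    b = counts[list(comparison.group_b)].to_numpy(dtype=float)
    p = np.array(
        [
            nb_exact_test(a[i], b[i], dispersion, size_factors=sf)
            for i in range(counts.shape[0])
        ]
    )
    return pd.DataFrame(
        {
            "comparison": comparison.name,
            "p_value": p,
            "fdr_q": bh_adjust(p),
        },
        index=counts.index,
    )


def classify_highly_de(
    rpkm: pd.DataFrame,
    q_values: pd.Series,
    comparison: ComparisonSpec,
    fold: float = 5.0,
    min_rpkm: float = 5.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the three-part highly-DE rule per gene for one comparison.

    Returns a table indexed by gene with columns ``comparison fdr_q direction
    fold_criterion_met min_rpkm_criterion_met min_A max_A min_B max_B``; direction
    is ``higher_in_A``, ``lower_in_A`` or ``none`` and is non-none iff all three
    criteria hold.
    """
    for acc in comparison.group_a + comparison.group_b:
        if acc not in rpkm.columns:
            raise ValueError(f"accession {acc!r} absent from RPKM matrix")
    q = q_values.reindex(rpkm.index)
    if q.isna().any():
        raise ValueError("q-values missing for some genes")
    a = rpkm[list(comparison.group_a)]
    b = rpkm[list(comparison.group_b)]
    min_a, max_a = a.min(axis=1), a.max(axis=1)
    min_b, max_b = b.min(axis=1), b.max(axis=1)

    up_fold = min_a >= fold * max_b
    up_floor = min_a >= min_rpkm
    down_fold = min_b >= fold * max_a
    down_floor = min_b >= min_rpkm
    significant = q < alpha

    higher = up_fold & up_floor & significant
    lower = down_fold & down_floor & significant
    assert not (higher & lower).any(), "a gene cannot be DE in both directions"

    direction = np.where(higher, "higher_in_A", np.where(lower, "lower_in_A", "none"))
    return pd.DataFrame(
        {
            "comparison": comparison.name,
            "fdr_q": q,
            "direction": direction,
            "fold_criterion_met": (up_fold | down_fold),
            "min_rpkm_criterion_met": np.where(up_fold, up_floor, np.where(down_fold, down_floor, False)).astype(bool),
            "min_A": min_a,
            "max_A": max_a,
            "min_B": min_b,
            "max_B": max_b,
        },
        index=rpkm.index,
    )


def venn_counts(sets_by_name: Mapping[str, set]) -> dict[frozenset, int]:
    """Exclusive-region counts for three (or more) named gene sets.

    Returns a mapping from each non-empty name combination to the number of genes
    belonging to exactly those sets; region counts sum to the union size.
    """
    names = list(sets_by_name)
    universe = set().union(*sets_by_name.values()) if sets_by_name else set()
    regions: dict[frozenset, int] = {}
    for n_mask in range(1, 2 ** len(names)):
        combo = frozenset(n for i, n in enumerate(names) if n_mask >> i & 1)
        regions[combo] = 0
    for gene in universe:
        membership = frozenset(n for n in names if gene in sets_by_name[n])
        regions[membership] += 1
    return regions


def enrichment_test(
    hit_set: set,
    universe: set,
    annotation_sets: Mapping[str, set],
) -> pd.DataFrame:
    """Hypergeometric over-representation test per annotation term, BH-adjusted.

    For a term annotating K of the N universe genes, with n hits of which k carry
    the term, p = P(X >= k) for X ~ Hypergeometric(N, K, n). Returns a table with
    columns ``term_size hits_in_term p_value fdr_q`` indexed by term.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not hit_set <= universe:
        raise ValueError("hit_set must be a subset of the universe")
    big_n, n = len(universe), len(hit_set)
    rows = []
    for term, members in annotation_sets.items():
        if not members <= universe:
            raise ValueError(f"annotation set {term!r} is not a subset of the universe")
        big_k = len(members)
        k = len(members & hit_set)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((term, big_k, k, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term", "term_size", "hits_in_term", "p_value"]
    ).set_index("term")
    table["fdr_q"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    return table
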