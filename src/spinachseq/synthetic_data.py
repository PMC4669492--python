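"""Self-contained synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a small multi-species germplasm RNA-Seq design: a known
species tree with accessions hanging off the species nodes, biallelic homozygous
SNPs planted on tree branches (one mutation per site, infinite-sites), read
pileups with negative-binomial depth, uniform per-base sequencing error and exact
PCR-duplicate copies, negative-binomial expression counts with species-level fold
changes, and a planted fraction of antisense-dominated contigs for the strand
filter. Ground truth (genotype table, DE gene list, true tree) is retained so
parameter-recovery tests can score every downstream module.

The default scenario mirrors a nine-accession, three-species panel (three
cultivated *S. oleracea*, three wild *S. turkestanica*, three wild *S. tetrandra*)
including one accession whose nominal species label is wrong — its data are drawn
from a different species, so a correct analysis must place it outside its nominal
group in both the SNP tree and the expression dendrogram.

Determinism: every operation draws from its own stream seeded by
(config.seed, operation id), so a fixed config reproduces outputs byte for byte
regardless of which operations are invoked or in what order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genotyping

__all__ = [
    "SpeciesScenario",
    "SimulationConfig",
    "TruthSet",
    "UnigeneCatalog",
    "default_scenario",
    "generate_unigenes",
    "plant_genotypes",
    "simulate_pileups",
    "simulate_counts",
    "simulate_strand_counts",
    "write_fasta",
    "write_truth",
]

BASES = np.array(["A", "C", "G", "T"])

# per-operation RNG stream ids (combined with the config seed)
_S_UNIGENES, _S_GENOTYPES, _S_PILEUPS, _S_COUNTS, _S_STRAND = 1, 2, 3, 4, 5

DEFAULT_SPECIES_TREE = "((oleracea:0.010,turkestanica:0.010):0.040,tetrandra:0.050):0.0;"


def _parse_tree(newick: str):
    return Phylo.read(io.StringIO(newick), "newick")


@dataclass(frozen=True)
class UnigeneCatalog:
    """Assembled unigene identifiers and sequences — the shared coordinate frame."""

    ids: tuple[str, ...]
    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {cid: len(self.sequences[cid]) for cid in self.ids}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class SpeciesScenario:
    """Study design: species groups, accession membership and the species tree.

    ``mislabel = (accession_id, true_species)`` plants a documentation error: the
    accession keeps its nominal species label but all of its genotypes and
    expression are generated from ``true_species``.
    """

    species_labels: tuple[str, ...]
    accessions_per_species: tuple[int, ...]
    species_tree: str = DEFAULT_SPECIES_TREE
    accession_names: Optional[tuple[tuple[str, ...], ...]] = None
    accession_branch_length: float = 0.003
    mislabel: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if len(self.species_labels) < 2:
            raise ValueError("need at least 2 species")
        if len(self.accessions_per_species) != len(self.species_labels):
            raise ValueError("accessions_per_species must match species_labels")
        if any(n < 1 for n in self.accessions_per_species):
            raise ValueError("every species needs at least one accession")
        if self.accession_branch_length < 0:
            raise ValueError("accession_branch_length must be >= 0")
        if self.accession_names is not None:
            if tuple(len(g) for g in self.accession_names) != self.accessions_per_species:
                raise ValueError("accession_names shape must match accessions_per_species")
        ids = self.accession_ids
        if len(set(ids)) != len(ids):
            raise ValueError("accession ids must be unique")
        tree = _parse_tree(self.species_tree)
        leaves = {t.name for t in tree.get_terminals()}
        if leaves != set(self.species_labels):
            raise ValueError(
                f"species tree leaves {sorted(leaves)} do not match species labels"
            )
        for clade in tree.find_clades():
            if clade.branch_length is not None and clade.branch_length < 0:
                raise ValueError("species tree branch lengths must be >= 0")
        if self.mislabel is not None:
            acc, true_sp = self.mislabel
            if acc not in ids:
                raise ValueError(f"mislabel accession {acc!r} unknown")
            if true_sp not in self.species_labels:
                raise ValueError(f"mislabel species {true_sp!r} unknown")
            if true_sp == self.nominal_species[acc]:
                raise ValueError("mislabel must name a species other than the nominal one")

    @property
    def accession_ids(self) -> tuple[str, ...]:
        if self.accession_names is not None:
            return tuple(a for group in self.accession_names for a in group)
        return tuple(
            f"{sp}{i + 1}"
            for sp, n in zip(self.species_labels, self.accessions_per_species)
            for i in range(n)
        )

    @property
    def nominal_species(self) -> dict[str, str]:
        out: dict[str, str] = {}
        idx = 0
        ids = self.accession_ids
        for sp, n in zip(self.species_labels, self.accessions_per_species):
            for _ in range(n):
                out[ids[idx]] = sp
                idx += 1
        return out

    @property
    def true_species(self) -> dict[str, str]:
        out = dict(self.nominal_species)
        if self.mislabel is not None:
            acc, true_sp = self.mislabel
            out[acc] = true_sp
        return out

    def groups(self, true: bool = False) -> dict[str, tuple[str, ...]]:
        """Accession ids per species, by nominal label (default) or true origin."""
        mapping = self.true_species if true else self.nominal_species
        return {
            sp: tuple(a for a in self.accession_ids if mapping[a] == sp)
            for sp in self.species_labels
        }

    def accession_tree(self):
        """Species tree with species leaves replaced by their true accessions."""
        tree = _parse_tree(self.species_tree)
        by_true = self.groups(true=True)
        for leaf in tree.get_terminals():
            members = by_true[leaf.name]
            leaf.clades = [
                Phylo.BaseTree.Clade(
                    branch_length=self.accession_branch_length, name=acc
                )
                for acc in members
            ]
            leaf.name = None
        return tree


def default_scenario(mislabel: bool = True) -> SpeciesScenario:
    """The bundled nine-accession, three-species design (3/3/3 nominal groups).

    With ``mislabel`` (the default), one nominally *tetrandra* accession is
    genetically a *turkestanica* — the documentation-error case the pipeline must
    detect and exclude.
    """
    return SpeciesScenario(
        species_labels=("oleracea", "turkestanica", "tetrandra"),
        accessions_per_species=(3, 3, 3),
        species_tree=DEFAULT_SPECIES_TREE,
        accession_names=(
            ("Sp78", "Sp82", "Sp90"),
            ("Sp49", "Sp50", "Sp51"),
            ("Sp40", "Sp42", "Sp43"),
        ),
        accession_branch_length=0.003,
        mislabel=("Sp40", "turkestanica") if mislabel else None,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs; a fixed seed makes every output byte-identical.

    Defaults are the bundled study conditions: 2,000 unigenes around 650 bp at GC
    0.425, 1,000 planted biallelic SNP sites, mean deduplicated depth 30 with NB
    overdispersion 0.3, 0.5% per-base error, 10% PCR-duplicate rate, NB expression
    with dispersion 0.05 and 100 ten-fold species-effect genes, and 100
    antisense-artifact contigs.
    """

    n_unigenes: int = 2000
    length_distribution: tuple[int, int, float] = (200, 3000, 650)
    gc_target: float = 0.425
    n_snp_sites: int = 1000
    depth_distribution: tuple[float, float] = (30.0, 0.3)  # (mean, overdispersion)
    min_depth: int = 1
    read_length: int = 50
    base_error_rate: float = 0.005
    duplicate_rate: float = 0.1
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0
    baseline_sigma: float = 1.0
    n_de_genes: int = 100
    de_fold: float = 10.0
    de_min_baseline: float = 50.0
    antisense_fraction: float = 0.1
    n_artifact_contigs: int = 100
    strand_mean_reads: float = 200.0
    artifact_sense_share: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, mean = self.length_distribution
        if not (1 <= lo <= mean <= hi):
            raise ValueError(
                f"length_distribution must satisfy 1 <= min <= mean <= max, got "
                f"{self.length_distribution}"
            )
        for name in ("gc_target", "base_error_rate", "duplicate_rate",
                     "antisense_fraction", "artifact_sense_share"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_unigenes < 1:
            raise ValueError("n_unigenes must be >= 1")
        if self.depth_distribution[0] <= 0:
            raise ValueError("depth mean must be > 0")
        if self.depth_distribution[1] < 0 or self.nb_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if self.read_length < 1 or self.min_depth < 0:
            raise ValueError("read_length must be >= 1 and min_depth >= 0")
        if self.de_fold < 1:
            raise ValueError("de_fold must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Retained ground truth for parameter-recovery tests.

    ``planted_site_genotypes``: accessions x (contig, pos) allele table;
    ``site_alleles``: ancestral/derived allele per planted site;
    ``planted_de_genes``: filled by :func:`simulate_counts`;
    ``true_tree``: the accession-level generating tree (Bio.Phylo).
    """

    planted_site_genotypes: pd.DataFrame
    site_alleles: pd.DataFrame
    true_tree: object
    catalog: UnigeneCatalog
    scenario: SpeciesScenario
    planted_de_genes: Optional[pd.DataFrame] = None

    @property
    def planted_sites(self) -> list[tuple[str, int]]:
        return list(self.planted_site_genotypes.columns)


def generate_unigenes(config: SimulationConfig) -> UnigeneCatalog:
    """Generate the unigene catalog: random sequences at the target GC content.

    Lengths are minimum + an exponential tail matched to the requested mean,
    truncated at the maximum; each base is drawn independently with
    P(G) = P(C) = gc_target / 2.
    """
    rng = config.rng(_S_UNIGENES)
    lo, hi, mean = config.length_distribution
    if lo == hi:
        lengths = np.full(config.n_unigenes, lo, dtype=np.int64)
    else:
        tail = rng.exponential(scale=mean - lo, size=config.n_unigenes)
        lengths = np.minimum(lo + np.floor(tail).astype(np.int64), hi)
    gc = config.gc_target
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    total = int(lengths.sum())
    flat = rng.choice(4, size=total, p=p)
    chars = BASES[flat]
    ids = tuple(f"UN{i + 1:06d}" for i in range(config.n_unigenes))
    sequences: dict[str, str] = {}
    offset = 0
    for cid, ln in zip(ids, lengths):
        sequences[cid] = "".join(chars[offset : offset + ln])
        offset += ln
    return UnigeneCatalog(ids=ids, sequences=sequences)


def write_fasta(catalog: UnigeneCatalog, path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(catalog.sequences[cid]), id=cid, description="")
        for cid in catalog.ids
    ]
    SeqIO.write(records, str(path), "fasta")


def _tree_edges(tree, all_accessions: set[str]) -> list[tuple[frozenset, float]]:
    """(accessions below, branch length) per informative edge.

    Edges subtending no accession or every accession cannot create a polymorphic
    site and are excluded; zero-length edges get zero sampling weight.
    """
    edges = []
    root = tree.root
    for clade in tree.find_clades():
        if clade is root:
            continue
        below = frozenset(t.name for t in clade.get_terminals())
        if not below or below == frozenset(all_accessions):
            continue
        edges.append((below, float(clade.branch_length or 0.0)))
    return edges


def plant_genotypes(
    catalog: UnigeneCatalog,
    scenario: SpeciesScenario,
    config: SimulationConfig,
) -> TruthSet:
    """Plant biallelic homozygous SNPs on the accession tree (infinite-sites).

    Each site gets one mutation on an edge drawn with probability proportional to
    branch length; accessions below the edge carry the derived allele, the rest the
    ancestral. Ancestral alleles are uniform over {A, C, G, T}, the derived allele
    uniform over the other three. Site positions leave a full read window on both
    sides so simulated reads always fit inside the contig.
    """
    rng = config.rng(_S_GENOTYPES)
    tree = scenario.accession_tree()
    accessions = list(scenario.accession_ids)
    edges = _tree_edges(tree, set(accessions))
    weights = np.array([w for _, w in edges], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("species tree has no informative branch length")

    read_len = config.read_length
    capacities = {}
    for cid in catalog.ids:
        ln = len(catalog.sequences[cid])
        capacities[cid] = max(0, ln - 2 * read_len + 2)  # pos in [L, ln - L + 1]
    total_capacity = sum(capacities.values())
    if config.n_snp_sites > total_capacity:
        raise ValueError(
            f"requested {config.n_snp_sites} SNP sites but only {total_capacity} "
            "placeable positions exist"
        )

    flat = np.sort(rng.choice(total_capacity, size=config.n_snp_sites, replace=False))
    sites: list[tuple[str, int]] = []
    offset = 0
    it = iter(catalog.ids)
    cid = next(it)
    for index in flat:
        while index >= offset + capacities[cid]:
            offset += capacities[cid]
            cid = next(it)
        sites.append((cid, int(index - offset) + read_len))

    edge_idx = rng.choice(len(edges), size=len(sites), p=weights / weights.sum())
    anc_idx = rng.integers(0, 4, size=len(sites))
    der_shift = rng.integers(1, 4, size=len(sites))
    der_idx = (anc_idx + der_shift) % 4

    geno = np.empty((len(accessions), len(sites)), dtype=object)
    for s, (e, ai, di) in enumerate(zip(edge_idx, anc_idx, der_idx)):
        carriers = edges[e][0]
        for a, acc in enumerate(accessions):
            geno[a, s] = BASES[di] if acc in carriers else BASES[ai]

    columns = pd.MultiIndex.from_tuples(sites, names=["contig", "pos"])
    genotypes = pd.DataFrame(geno, index=accessions, columns=columns)
    site_alleles = pd.DataFrame(
        {
            "ancestral": BASES[anc_idx],
            "derived": BASES[der_idx],
            "n_carriers": [len(edges[e][0]) for e in edge_idx],
        },
        index=columns,
    )
    return TruthSet(
        planted_site_genotypes=genotypes,
        site_alleles=site_alleles,
        true_tree=tree,
        catalog=catalog,
        scenario=scenario,
    )


def simulate_pileups(
    truth: TruthSet, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw reads over every planted site and pile them up.

    Reads are ``read_length`` bp, sense strand, copied from the contig with the
    accession's planted alleles substituted at every planted site they span; each
    base is then miscalled with probability ``base_error_rate`` (uniform over the
    other three bases). Template start positions within a site's window are
    distinct, so deduplication removes exactly the PCR copies (each template is
    duplicated once with probability ``duplicate_rate``). Positions flanking the
    planted sites are covered too and come out monomorphic.

    Returns ``(alignment_records, observations)`` where observations are the
    deduplicated pileup (the package's own dedup + pileup applied to the records).
    """
    rng = config.rng(_S_PILEUPS)
    mean_depth, over = config.depth_distribution
    read_len = config.read_length
    accessions = list(truth.scenario.accession_ids)
    sites = truth.planted_sites
    genotypes = truth.planted_site_genotypes

    # accession-specific contig sequences with planted alleles substituted
    sites_by_contig: dict[str, list[tuple[int, int]]] = {}
    for s, (cid, pos) in enumerate(sites):
        sites_by_contig.setdefault(cid, []).append((pos, s))

    rows_acc, rows_contig, rows_start, rows_seq, rows_dup = [], [], [], [], []
    for acc in accessions:
        mutated: dict[str, str] = {}
        for cid, poslist in sites_by_contig.items():
            seq = list(truth.catalog.sequences[cid])
            for pos, s in poslist:
                seq[pos - 1] = genotypes.iloc[genotypes.index.get_loc(acc), s]
            mutated[cid] = "".join(seq)

        if over > 0:
            r = 1.0 / over
            depths = rng.negative_binomial(r, r / (r + mean_depth), size=len(sites))
        else:
            depths = rng.poisson(mean_depth, size=len(sites))
        depths = np.clip(depths, config.min_depth, read_len)

        for (cid, pos), depth in zip(sites, depths):
            if depth == 0:
                continue
            starts = rng.permutation(read_len)[:depth] + (pos - read_len + 1)
            seq = mutated[cid]
            n_err = rng.binomial(read_len, config.base_error_rate, size=depth)
            dup = rng.random(depth) < config.duplicate_rate
            for start, ne, isdup in zip(starts, n_err, dup):
                read = seq[start - 1 : start - 1 + read_len]
                if ne > 0:
                    chars = list(read)
                    for j in rng.choice(read_len, size=ne, replace=False):
                        chars[j] = BASES[
                            (np.searchsorted(BASES, chars[j]) + rng.integers(1, 4)) % 4
                        ]
                    read = "".join(chars)
                rows_acc.append(acc)
                rows_contig.append(cid)
                rows_start.append(int(start))
                rows_seq.append(read)
                rows_dup.append(False)
                if isdup:
                    rows_acc.append(acc)
                    rows_contig.append(cid)
                    rows_start.append(int(start))
                    rows_seq.append(read)
                    rows_dup.append(True)

    records = pd.DataFrame(
        {
            "accession": rows_acc,
            "contig": rows_contig,
            "start": rows_start,
            "strand": "+",
            "sequence": rows_seq,
            "is_duplicate": rows_dup,
        }
    )
    observations = genotyping.pileup(genotyping.deduplicate_reads(records))
    return records, observations


def simulate_counts(
    truth: TruthSet,
    scenario: SpeciesScenario,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB expression counts with planted species-level fold changes.

    Gene baselines are log-normal around ``baseline_mean``; for each of
    ``n_de_genes`` genes (baseline floored at ``de_min_baseline``) one randomly
    chosen species gets mean ``baseline * de_fold`` — the planted species is the
    elevated one, so the effect surfaces as "higher" or "lower" depending on which
    side of a comparison the species sits. Effects follow the accessions' TRUE
    species. Library-size factors are log-uniform in [0.5, 2]; ``nb_dispersion`` 0
    degenerates to Poisson. Fills ``truth.planted_de_genes``.

    Returns (counts matrix genes x accessions, library-size factors).
    """
    rng = config.rng(_S_COUNTS)
    genes = list(truth.catalog.ids)
    accessions = list(scenario.accession_ids)
    true_sp = scenario.true_species

    baseline = rng.lognormal(mean=np.log(config.baseline_mean),
                             sigma=config.baseline_sigma, size=len(genes))
    if baseline.min() < 0:
        raise ValueError("negative baseline")

    n_de = config.n_de_genes
    if n_de > len(genes):
        raise ValueError("n_de_genes exceeds the number of genes")
    de_pos = np.sort(rng.choice(len(genes), size=n_de, replace=False))
    baseline[de_pos] = np.maximum(baseline[de_pos], config.de_min_baseline)
    de_species = rng.choice(np.array(scenario.species_labels), size=n_de)

    factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(accessions)))
    lib_factors = pd.Series(factors, index=accessions, name="library_factor")

    mult = np.ones((len(genes), len(accessions)))
    for g, sp in zip(de_pos, de_species):
        for a, acc in enumerate(accessions):
            if true_sp[acc] == sp:
                mult[g, a] = config.de_fold

    mean = baseline[:, None] * mult * factors[None, :]
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)

    truth.planted_de_genes = pd.DataFrame(
        {
            "gene": [genes[g] for g in de_pos],
            "species": de_species,
            "direction": "up",  # the planted species is the elevated one
            "fold": config.de_fold,
        }
    ).set_index("gene")
    return pd.DataFrame(counts, index=genes, columns=accessions), lib_factors


def simulate_strand_counts(
    catalog: UnigeneCatalog, config: SimulationConfig
) -> pd.DataFrame:
    """Sense/antisense read counts per contig with a planted artifact subset.

    ``n_artifact_contigs`` contigs are made antisense-dominated (expected sense
    share ``artifact_sense_share``); the rest have expected antisense share
    ``antisense_fraction``. Draws are redrawn (bounded) until each contig's counts
    fall on the planted side of the 1/10 rule, so the filter's planted truth is
    recovered exactly at any seed. Returns columns ``contig_id sense_reads
    antisense_reads is_artifact``.
    """
    rng = config.rng(_S_STRAND)
    n = len(catalog.ids)
    if config.n_artifact_contigs > n:
        raise ValueError("more artifact contigs requested than contigs exist")
    artifact = np.zeros(n, dtype=bool)
    if config.n_artifact_contigs:
        artifact[rng.choice(n, size=config.n_artifact_contigs, replace=False)] = True

    totals = np.maximum(rng.poisson(config.strand_mean_reads, size=n), 30)
    sense = np.empty(n, dtype=np.int64)
    for i in range(n):
        p = config.artifact_sense_share if artifact[i] else 1.0 - config.antisense_fraction
        for _ in range(1000):
            s = int(rng.binomial(totals[i], p))
            discard = 10 * s < totals[i] - s
            if discard == artifact[i]:
                sense[i] = s
                break
        else:  # pragma: no cover - parameters would have to be adversarial
            raise RuntimeError("could not realize planted strand counts")
    return pd.DataFrame(
        {
            "contig_id": list(catalog.ids),
            "sense_reads": sense,
            "antisense_reads": totals - sense,
            "is_artifact": artifact,
        }
    )


def write_truth(truth: TruthSet, out_dir: Union[str, Path]) -> None:
    """Write the ground-truth tables as TSV (genotypes, site alleles, DE genes)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = truth.planted_site_genotypes.copy()
    geno.columns = [f"{c}:{p}" for c, p in geno.columns]
    geno.to_csv(out / "truth_genotypes.tsv", sep="\t")
    truth.site_alleles.to_csv(out / "truth_site_alleles.tsv", sep="\t")
    if truth.planted_de_genes is not None:
        truth.planted_de_genes.to_csv(out / "truth_de_genes.tsv", sep="\t")
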