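# Methods

This note documents the models and procedures the package implements, the
defaults of the synthetic-data generator (which define the conditions all
end-to-end tests run under), the numerical conventions, and known limitations.

## Study design emulated

A nine-accession panel from three spinach species — three cultivated
*S. oleracea*, three wild *S. turkestanica*, three wild *S. tetrandra* — each
sequenced as one strand-specific RNA-Seq library and analyzed against a de novo
unigene catalog. The default scenario plants a deliberate documentation error:
accession `Sp40`, nominally *S. tetrandra*, is generated from *S. turkestanica*.
A correct analysis must place it outside its nominal group in both the SNP tree
and the expression dendrogram; the pipeline flags it (an accession whose removal
restores its nominal group's monophyly in **both** analyses) and excludes it from
the diversity counts and the differential-expression comparisons, leaving 3/3/2
groups.

## Synthetic-data generator

### Genotypes

The species tree (newick, branch lengths in expected substitutions per site) is
expanded to an accession tree by attaching each accession under its **true**
species with a terminal branch (default 0.003). Each planted SNP receives one
mutation (infinite-sites) on an edge drawn with probability proportional to
branch length, restricted to edges subtending a strict, non-empty subset of
accessions, so every site is polymorphic in the panel; accessions below the edge
carry the derived allele. Ancestral alleles are uniform over {A,C,G,T}, the
derived allele uniform over the other three, so variant-site base composition is
unbiased. Pairwise allele-mismatch proportions are additive on the true tree in
expectation.

Default species tree:
`((oleracea:0.010, turkestanica:0.010):0.040, tetrandra:0.050)` — within-species
p-distances (~0.006 via terminal branches) are an order of magnitude below the
oleracea–turkestanica divergence (0.026) and far below divergence from
tetrandra (0.106), reproducing the strong cultivated-vs-wild diversity contrast
of the emulated panel.

### Reads and pileups

Reads are `read_length` = 50 bp, sense strand, copied from the contig sequence
with the accession's planted alleles substituted at every planted site the read
spans (so closely spaced SNPs do not contaminate each other). Per site and
accession, deduplicated depth is negative binomial (mean 30, overdispersion 0.3),
floored at `min_depth` (default 1; recovery tests that require a callable site at
every accession use 3) and capped at the window size. Template start positions
inside the 50-position window are drawn **without replacement**, so distinct
templates never collide and duplicate removal is exact; each template is
duplicated once with probability `duplicate_rate` (default 0.1), the copy being
byte-identical and flagged in the record as ground truth. Each read base is
miscalled with probability `base_error_rate` (default 0.005), uniformly to
another base. Flanking positions covered by the reads come out monomorphic and
serve as true negatives for SNP calling. There are no quality scores, indels or
splicing.

### Expression counts

Gene baselines are log-normal (median 100, σ = 1). For each of `n_de_genes`
(default 100 of 2,000) genes, one random species gets mean `baseline × de_fold`
(default 10); baselines of planted genes are floored at `de_min_baseline` = 50 so
the quieter side of every planted contrast still has ~50 expected counts.
Counts are NB with common dispersion 0.05 (0 degenerates to Poisson), scaled by
per-accession library factors drawn log-uniform in [0.5, 2] to exercise RPKM
normalization. Effects follow the accessions' true species, so the mislabeled
accession carries its true group's expression signature.

### Strand counts

Per-contig totals are Poisson (mean 200, floored at 30). `n_artifact_contigs`
(default 100 of 2,000) are antisense-dominated (expected sense share 0.04), the
rest have expected antisense share `antisense_fraction` (default 0.1). Because
the planted truth must be recoverable exactly at any seed, draws are redrawn
(bounded) until each contig falls on its planted side of the 1/10 rule; the
generator is therefore a truth-planting device, not an unconditional sampler of
the binomial model.

### Determinism

Every operation draws from `default_rng([seed, stream_id])` with a fixed stream
id per operation, so a fixed `SimulationConfig` reproduces all outputs byte for
byte, independent of which operations run or in what order.

## Analysis conventions

- **Genotype calling.** With M the majority-base count and T the site depth:
  called iff M ≥ 3 and M/T > 0.75 (both strict as worded: "at least three
  reads", "frequency > 75%"); missing iff T < 3; ambiguous otherwise. The
  support threshold applies to the majority allele — the stricter of the
  plausible readings. Ambiguous (heterozygous-like) calls are treated as missing
  downstream, since only homozygous, fully genotyped SNPs feed the diversity and
  phylogeny analyses. N/gap read bases are ignored before pileup. Coordinates
  are 1-based.
- **Completeness filter.** Keeps sites called in every required accession; sites
  monomorphic within the retained subset are kept (their polymorphism was
  established over the full panel), which is what makes union counts exceed
  member-group counts in the diversity table.
- **Tree.** p-distance with pairwise deletion (an explicit error names the first
  accession pair sharing zero called sites). NJ uses the standard Q criterion;
  Q-ties are broken by the lexicographically smallest pair of cluster
  representatives (smallest contained leaf label), so the result is independent
  of input order. A negative branch-length estimate is clamped to zero with the
  deficit moved to its sibling branch (pair totals preserved); the final
  three-star lengths are clamped only. The tree is NJ rather than
  maximum-likelihood: NJ is fully specified, desk-verifiable, and exact on
  additive inputs, which the test suite exploits.
- **Bootstrap.** Sites (tree) or genes (dendrogram) are resampled with
  replacement from one seeded generator; support is the percentage of replicates
  containing the same internal bipartition (tree) or the same exact accession
  subset (dendrogram). 1,000 replicates is the reference setting; the bundled
  pipeline default is 200, which bounds the Monte Carlo standard error of a
  support value by ~3.5 points while keeping the default run under half a
  minute.
- **Clustering.** Unweighted average linkage (UPGMA update) on 1 − r; ties are
  broken by smallest cluster label. Correlation is computed on log₂(RPKM + 1) by
  default — the transform is not dictated by the emulated protocol, but it
  stabilizes RPKM's heavy right tail; raw-RPKM correlation is exposed via a
  flag. A zero-variance profile yields NaN correlations and a warning, never a
  silent 0.
- **NB exact test.** Counts are scaled to a common effective library size
  (geometric-mean reference), rounded and summed per group; conditional on the
  total, the group-A sum's null law is the convolution of the groups' NB sums
  (size n_g/φ each), and the two-sided p-value accumulates outcomes whose
  conditional probability is ≤ the observed one (tolerance 1e-10 in log space
  for ties). This is a single-common-dispersion re-implementation of the
  two-group exact-test idea, not a wrapper: no quantile-adjusted CML, no tagwise
  shrinkage. Size factors default to library-size ratios, not TMM.
- **Dispersion.** Per gene and per group with ≥ 2 replicates, the moment
  estimate (s² − m)/m² on library-size-adjusted counts (arithmetic-mean
  reference, so equal libraries give factors of exactly 1); averaged within
  gene, clipped at 0, averaged over genes with positive mean. Unreplicated
  designs return 0 with a warning.
- **Highly-DE rule.** Boundaries follow the rule's wording: ≥ for the five-fold
  min/max criterion and the 5-RPKM floor ("at least"), strict < for the 0.05 FDR
  ("less than"). q-values are computed over all tested genes per comparison
  before the fold filter is applied. "Expression level" is RPKM throughout.
- **Enrichment.** Flat hypergeometric over-representation per term
  (P(X ≥ k)), BH-adjusted across terms; no ontology-graph propagation.
- **Percent rendering.** Half-away-from-zero rounding via decimal arithmetic, so
  printed percentages are convention-stable.
- **N50.** Smallest length L such that sequences ≥ L jointly cover at least half
  the total bases (descending cumulative sum); GC% excludes ambiguous bases from
  the denominator.

## Problem sizes

The bundled default scenario — 2,000 unigenes (~650 bp mean), 1,000 planted SNP
sites, 2,000-gene count matrix with 100 planted DE genes, 200 bootstrap
replicates for tree and dendrogram — was chosen so a full pipeline run completes
in well under a minute on one CPU while keeping every recovery statistic's
sampling error small relative to its acceptance margin. Unit tests use smaller
instances of the same generator.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis assumes —
tree-structured homozygous biallelic SNPs, NB depth and expression
heterogeneity, uniform base error, exact PCR copies, antisense-dominated
contigs — but not real data's alignment artifacts, paralog collapse during
assembly, mapping bias, heterozygosity, indels, splice forms or quality-score
structure. Recovery results therefore validate the pipeline's correctness under
its own model, not its robustness to assembly or alignment error. Two planted
quantities are deliberately easy by construction: strand-artifact recovery is
exact because the generator enforces the planted side of the filter rule, and
planted SNPs are recoverable wherever depth and error permit a call. The
planted-DE sensitivity is the genuinely tight statistic: at fold 10,
dispersion 0.05 and a 50-count floor, the min/max fold-5 criterion across the
post-exclusion 3/3/2 panel passes for ~96% of planted genes in expectation, so
measured values near the 95% margin fluctuate by a few points across seeds.

## Known limitations

- Genotypes are haploid-style single-allele calls; heterozygotes are never
  called, only marked ambiguous (the analysis scope is homozygous SNPs).
- The exact test enumerates the conditional support, so genes with very large
  scaled totals (≫ 10⁵) are slow; at the bundled scale this is irrelevant.
- Cluster support uses exact-subset matching, which is stricter than bipartition
  matching for dendrograms.
- The reported specificity of SNP recovery counts covered non-planted positions
  as negatives; uncovered positions are out of the universe by construction.
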