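# spinachseq

RNA-Seq SNP genotyping, phylogenetics and expression divergence for small
multi-species germplasm panels.

The package re-implements, as a tested and reusable library, the downstream
analysis of a comparative transcriptome study of cultivated and wild spinach
(*Spinacia oleracea*, *S. turkestanica*, *S. tetrandra*; nine accessions, three
per species): strand-specific antisense-artifact filtering of assembled contigs,
pileup-based SNP genotyping with homozygosity/completeness filters and group-wise
diversity counts, a neighbor-joining accession tree with site-bootstrap support,
RPKM expression profiles with average-linkage (UPGMA) correlation clustering and
gene-bootstrap support, a negative-binomial exact test with BH-FDR correction and
a three-part "highly differentially expressed" classification, plus the study's
accounting and assembly summary arithmetic. A synthetic-data generator emulates
the panel design — including one accession whose nominal species label is wrong —
and retains the ground truth, so every stage is validated end to end by
parameter recovery.

## The methods in brief

- **Strand filter.** A contig is discarded iff `10 · sense_reads <
  antisense_reads` (strict integer comparison; the boundary is kept) — spurious
  antisense contigs arise from incomplete second-strand digestion in
  strand-specific libraries.
- **Genotyping.** Exact read duplicates (accession, contig, start, strand,
  sequence) collapse to one; pileups give per-accession base counts; a homozygous
  call requires the majority base to have ≥ 3 supporting reads and frequency
  > 75% of the site depth. A site is a SNP when ≥ 2 distinct alleles are called
  across accessions; diversity counts use only sites genotyped in every retained
  accession.
- **Phylogeny.** Allele p-distance `d(i,j) = #differing / #shared sites`
  (pairwise deletion), Saitou–Nei neighbor joining (exact on additive matrices),
  and bootstrap support = % of site-resampled replicate trees containing each
  internal bipartition.
- **Expression.** `RPKM = count · 10⁹ / (length_bp · mapped_reads)`; accession
  similarity is the Pearson r of log₂(RPKM + 1) profiles; dendrograms use
  unweighted average linkage on 1 − r with gene-bootstrap cluster support.
- **Differential expression.** Two-group NB exact test (conditional on the total
  of library-size-scaled group sums, two-sided by the "as or less likely" rule;
  dispersion 0 reduces to the exact binomial split test), method-of-moments
  common dispersion, BH step-up FDR. A gene is *highly* DE when min RPKM in one
  species ≥ 5 × max RPKM in the other, min RPKM in the higher species ≥ 5, and
  q < 0.05.

## Worked example

```bash
spinachseq run --seed 0 --out-dir run0
```

runs the bundled nine-accession scenario (2,000 unigenes, 1,000 planted SNPs,
100 planted ten-fold DE genes, 100 antisense-artifact contigs) end to end and
prints the run metrics, including:

```
"strand_n_discarded": 100,          # exactly the planted artifact contigs
"snp_sensitivity": 0.999,           # planted SNP sites recovered
"snp_specificity": 1.0,
"group_snp_counts": {
    "oleracea": 61, "turkestanica": 55, "tetrandra": 42,
    "oleracea+turkestanica": 249, ..., "all": 938
},                                  # within-species diversity << between-species
"flagged_accessions": ["Sp40"],     # the mislabeled accession, detected and excluded
"true_group_supports": {"oleracea": 100.0, "turkestanica": 100.0, "tetrandra": 100.0},
"de_sensitivity": 0.98,             # planted DE genes recovered in the right direction
"de_false_flag_rate": 0.0
```

`run0/` then contains the generated FASTA, pileup/count TSVs, the VCF, the
bootstrap-annotated SNP tree and expression dendrogram (newick), per-comparison
DE tables, Venn region counts, a plain-text report and a checksummed manifest.
The accession `Sp40` is generated from *S. turkestanica* while nominally labeled
*S. tetrandra*; both the SNP tree and the expression dendrogram place it with its
true species, it is flagged, and the diversity/DE summaries are computed on the
remaining eight accessions (3/3/2) — reproducing how such a documentation error
surfaces and is handled in practice.

Each stage is also available separately (`simulate`, `filter-strand`,
`call-snps`, `tree`, `express`, `de`, `report`), all reading and writing plain
TSV/FASTA/VCF/newick.

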