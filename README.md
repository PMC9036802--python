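# kaspkit

Accession-specific SNP detection and KASP marker design for inbred crop
panels, from a joint-called multi-sample VCF and a reference genome.

## The problem

Seed producers and plant breeders need to verify that a seed lot is what
its label says: a pure parental line, or a genuine F1 hybrid of two known
parents. Grow-out tests answer this phenotypically but take a field season.
A panel of **accession-specific markers** answers it in a day: for each
accession in a collection, find SNPs that are fixed in that accession and
absent everywhere else, and turn the best of them into KASP (Kompetitive
Allele Specific PCR) assays.

An *accession-specific SNP* is a biallelic site where exactly one
accession is homozygous for the alternative allele (genotype aa) and every
other accession is homozygous reference (RR). On inbred or
doubled-haploid material this is the signature of a private fixed variant.
A marker built on such a site lights up (alt-homozygous) only in its
target accession, reads heterozygous in a true F1 of that accession, and
stays reference-homozygous in everything else.

## The pipeline

1. **Genotype filtering** — a genotype survives only with read depth
   DP > 3 and genotype quality GQ > 30; heterozygous calls are set to
   missing (inbred panel); multi-allelic sites are dropped.
2. **Specificity calling** — scan the filtered matrix for sites with
   exactly one alt-homozygous accession; by default every other accession
   must be explicitly ref-homozygous (a missing call could hide a shared
   allele).
3. **Flank design** — extract the 501-bp reference window with the
   variant at position 251; reject windows containing reference Ns,
   windows overlapping annotated repeats, and windows with an exact
   duplicated stretch of ≥ 100 bp elsewhere in the genome (either
   strand). Reconstruct each accession's window from its calls, and mask
   as `N` every position where more than 10% of accessions differ from
   the reference (missing counts as differing) — a hidden polymorphism
   under a primer kills the assay. Emit the consensus with the target
   SNP bracketed as `[REF/ALT]`.
4. **Panel selection** — per accession, rank candidates exon-first
   (conserved genic flanks amplify most reliably), then by DP and GQ
   descending; keep a shortlist of 5 and select the top 2 whose 501-bp
   windows do not overlap any previously selected marker.
5. **Evaluation** — given a marker × sample matrix of KASP calls:
   per-marker discrimination (target aa, all other core samples RR,
   outgroup RR/missing), parent/F1 distinction (aa / RR / Ra pairwise
   distinct), and seed purity (fraction of non-missing calls matching the
   expected genotype).

A synthetic-data generator (`kaspkit.synthetic_data`) plants
accession-specific SNPs and rule-violating confounders with a recorded
truth table, so the whole chain is testable without sequencing data.

## Worked example

```python
from kaspkit import synthetic_data, io_formats, run_pipeline

# 50 inbred accessions, ≥5 private SNPs each, 2 × 300 kb genome
sim = synthetic_data.simulate(synthetic_data.study_scale(seed=1), "sim")
genome  = io_formats.read_reference(sim.fasta)
matrix  = io_formats.read_population_vcf(sim.vcf)
genes   = io_formats.read_gene_models(sim.genes_gff)
repeats = io_formats.read_repeats(sim.repeats_gff)

result = run_pipeline(genome, matrix, genes, repeats)
print(len(result.specific_snps), len(result.panel))
```

prints `250 100`: all 250 planted private SNPs are detected, and the
selector keeps two markers per accession — a 100-marker panel with
pairwise non-overlapping windows. The first selected marker looks like

```
chr02_209764  (ACC001, non-synonymous)   ...TATGGCT[C/G]TGTCGCT...
```

i.e. marker ids are `<chrom>_<pos>`, and the submission sequence carries
exactly one `[REF/ALT]` token at sequence position 251.

The eight-accession worked example that ships with the package
(`synthetic_data.eight_accession_fixture()`) behaves the same way:

```python
from kaspkit import filter_genotypes, call_accession_specific
snps = call_accession_specific(filter_genotypes(synthetic_data.eight_accession_fixture()))
# 16 SNPs, two per accession, e.g.
#   A02_18369509  C>T  -> 26021
#   A07_20012970  G>A  -> CNU_11411
```

The same stages are available as a CLI
(`kaspkit simulate | filter | detect | annotate | run | evaluate | purity`);
see `kaspkit --help`.

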