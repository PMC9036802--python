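# Methods

This note records the model behind each pipeline stage, the defaults and
why they are what they are, what the synthetic data does and does not
emulate, and the numerical/design choices made where the design was
genuinely open.

## Population model and the specificity rule

The pipeline assumes a panel of inbred or doubled-haploid accessions
jointly genotyped against a single reference. Under full homozygosity a
diploid call is RR or aa; heterozygous calls are treated as genotyping
noise rather than biology. An accession-specific SNP is a biallelic SNV
with exactly one aa accession and all others RR.

**Missing-call policy.** A missing genotype in a non-target accession
could conceal a shared alternative allele, so the default
(`SpecificityConfig.max_missing_others = 0`) disqualifies the site unless
every other accession is explicitly RR. This is deliberately
conservative: it trades recall for the guarantee that a selected marker
cannot be invalidated by an unread sample. Relaxations admit a bounded
missing fraction among the others; a hom-alt call in any other accession
always disqualifies.

## Genotype filtering

Survival thresholds are strict inequalities: DP > 3 and GQ > 30
(`FilterConfig.min_depth_exclusive = 3`, `min_gq_exclusive = 30`), i.e. a
genotype needs DP ≥ 4 and GQ ≥ 31. Genotypes lacking a DP or GQ
annotation fail the corresponding check. Heterozygous calls become
missing rather than the site being deleted, so heterozygosity-rich
control material (F1 panels) can still be pushed through the evaluator.
Multi-allelic sites are removed entirely; indel records are skipped on
VCF load (SNV-only pipeline) but their intervals are retained so that
flank design can reject windows an indel carrier would misalign.
Upstream read-level QC (mapping quality, duplicate removal, realignment)
is assumed done by the variant caller that produced the VCF.

## Flank design

* **Window geometry**: 501 bp centred on the variant (positions
  pos − 250 … pos + 250), variant at window position 251. Sites within
  250 bp of a chromosome end are rejected (`edge`).
* **Reference-N screen**: any N in the reference window rejects the site
  — primer design cannot anchor on unsequenced reference.
* **Uniqueness screen**: a window fails if any stretch of
  ≥ `min_duplicate_match` bp (default 100) occurs exactly at a second
  genomic locus on either strand. This exact-substring criterion is a
  deterministic proxy for an alignment-based (BLAST-style) redundancy
  search; 100 bp was chosen as roughly the span that two PCR primers plus
  amplicon need to find an unbroken second home, and is configurable.
  Implementation: a k-mer index (k = 31, clamped to the threshold) over
  the forward genome, queried with the window and its reverse complement;
  seed hits are extended ungapped along their alignment diagonal, and
  several match runs on one diagonal are examined independently. The
  window's own forward placement is excluded. Tests pin equivalence to a
  naive quadratic substring scan on multi-chromosome toy genomes.
* **Repeat screen**: 1-based inclusive interval intersection with the
  repeat track; a single shared base counts as overlap (configurable via
  the track you supply — pre-trim intervals to relax).
* **Per-accession reconstruction**: each accession's window is the
  reference with its hom-alt SNVs substituted. Only SNVs are
  substituted, so the alignment across accessions is positional (no
  gaps) by construction; a window overlapped by any carried indel is
  dropped (`indel-in-window`) instead of gap-aligned. This replaces a
  multiple-alignment step with an exact construction and removes a
  nondeterministic dependency.
* **Consensus masking**: at every window position except 251, the
  fraction of accessions whose base differs from the reference — with a
  missing call counted as differing, since an unread base might differ —
  is compared with the mask threshold (default 0.10); strictly greater
  masks the position as N. Missing calls leave the reference base in the
  reconstructed sequence but are tallied through a separate mask, so no
  sequence is invented. Position 251 is exempt: the target SNP is
  variable by definition (one accession in the panel), and the exemption
  keeps the rule safe for small panels where 1/n exceeds the threshold.

## Effect annotation

Single-transcript gene models; one label per SNV from a fixed severity
order (stop-gained > start-lost > stop-lost > splice-acceptor >
splice-donor > non-synonymous > stop-retained > synonymous > intron >
upstream-5kb > downstream-5kb > intergenic), modelled on snpEff-style
impact tiers. Splice sites are the 2 intronic bases flanking each exon
junction. Upstream/downstream windows are 5,000 bp from the gene span,
strand-aware; a position upstream of one gene and downstream of another
is labelled upstream. Codons are evaluated on the spliced,
phase-trimmed coding sequence in transcript orientation (minus-strand
CDS reverse-complemented), so junction-spanning codons are handled
correctly; the standard nuclear genetic code is used. Genes whose CDS
length is not a multiple of 3 after phase adjustment are excluded from
coding classification with a warning; their interiors fall back to the
positional `intron` label, as does any non-coding gene interior (the
gene models this package generates have no UTRs, so that fallback is a
robustness measure, not a modelled category).

## Panel selection

Within an accession the sort key is (exonic first, DP descending, GQ
descending, coordinate ascending); the top 5 form the shortlist, from
which up to 2 markers are taken. "Unique genomic position" is enforced
at window level: two markers conflict when they lie on the same
chromosome within 500 bp (overlapping 501-bp windows = overlapping
amplicons, the stated failure mode). Selection is a greedy sweep in
sorted accession order; no global optimisation objective exists for this
problem, and the greedy rule is deterministic — identical inputs yield
byte-identical panels. Accessions left with fewer than 2 markers are
reported in a shortfall list rather than silently under-served.

## Panel evaluation

The evaluator consumes discrete calls (fluorescence clustering is
upstream of this package). A marker passes discrimination iff its
target sample is aa and every other core sample is RR; outgroup samples
may be RR or missing. An accession is identified if at least one of its
two markers passes. The F1 verdict requires the parents to be opposite
homozygotes and the hybrid heterozygous. Purity is the package's own
operationalisation (no standard statistic exists for it): matching
calls / non-missing calls, with missing counted separately and off-type
samples listed. No confidence interval is attached.

## Synthetic data

The generator emulates: an i.i.d.-uniform background genome (2 × 300 kb
at study scale), embedded two-exon genes with valid ORFs on both strands,
annotated repeat intervals, optional duplicated 2-kb segments, and a
VCF in which each target genotype is aa with DP = 12 / GQ = 60 and all
other accessions are RR. Boundary confounders sit exactly at DP = 3/4
and GQ = 30/31 so the strict inequalities are pinned end-to-end. Planted
SNPs keep ≥ 600 bp mutual spacing, so every clean candidate set is
pairwise window-disjoint by construction. Because the background is
i.i.d. uniform, a chance exact duplicate of ≥ 100 bp is impossible in
practice (probability < 10⁻⁴⁰ at these scales), which makes the
uniqueness screen's negative cases sound.

It does **not** emulate: linkage disequilibrium or population structure,
sequencing-error processes behind DP/GQ, real repeat families (repeat
intervals are annotation-only; their sequence is background), indels
beyond the indel-in-window flag, or multi-transcript gene models.
Passing tests therefore demonstrate the pipeline's logic and screens,
not robustness to correlated variation or annotation error in real
resequencing data.

Determinism: all randomness flows from one integer seed through
`numpy.random.default_rng` using integer draws only; a fixed config
reproduces byte-identical FASTA/VCF/GFF3/TSV outputs across platforms.

## Problem sizes

The study-scale simulation used by `scripts/acceptance.py` and the
acceptance tests is 50 accessions × 5 private SNPs on a 600-kb genome —
large enough that 250 non-overlapping windows, 60 genes and 20 repeats
coexist with room to spare, small enough that the k-mer uniqueness index
builds in seconds. Property suites (oracle comparisons, masking
monotonicity, determinism) run on eight-accession populations and toy
genomes of 20–100 kb.

## Known limitations

* Redundancy is exact-match only; a diverged paralog (e.g. 95% identity)
  passes the screen. The `DuplicateScreen` class is the hook to replace
  with an aligner-backed screen if that matters for your genome.
* One gene = one transcript; isoform-specific effects are out of scope.
* The specificity rule is single-accession; group-specific markers
  (shared by k accessions) are not supported.
* Primer thermodynamics (Tm, GC clamps, allele-specific tails) are the
  assay vendor's problem, downstream of the emitted candidate sequence.
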