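"""Variant effect classification against single-transcript gene models.

Each SNV receives exactly one label from a fixed vocabulary:

====================  ==========  =============================================
label                 region      meaning
====================  ==========  =============================================
non-synonymous        exon        codon change alters the amino acid
synonymous            exon        codon change preserves the amino acid
stop-gained           exon        codon change introduces a stop codon
start-lost            exon        first codon is no longer ATG
stop-lost             exon        stop codon becomes a coding codon
stop-retained         exon        stop codon becomes another stop codon
splice-acceptor       intron      last 2 intronic bases before an exon
splice-donor          intron      first 2 intronic bases after an exon
intron                intron      intronic, away from splice sites
upstream-5kb          non-coding  within 5,000 bp 5' of a gene (strand-aware)
downstream-5kb        non-coding  within 5,000 bp 3' of a gene (strand-aware)
intergenic            non-coding  none of the above
====================  ==========  =============================================

When several genes or features overlap a position, the most severe
label wins under :data:`SEVERITY_ORDER` (modelled on snpEff-style
impact tiers).  Codon evaluation is strand-aware: minus-strand CDS is
read as the reverse complement, and codons spanning splice junctions
are assembled from the spliced coding sequence.  The standard nuclear
genetic code is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from kaspkit.genotype_filtering import VariantSite
from kaspkit.io_formats import GeneModel, ReferenceGenome

#: Most severe first; ties between genes broken by gene id.
SEVERITY_ORDER = (
    "stop-gained",
    "start-lost",
    "stop-lost",
    "splice-acceptor",
    "splice-donor",
    "non-synonymous",
    "stop-retained",
    "synonymous",
    "intron",
    "upstream-5kb",
    "downstream-5kb",
    "intergenic",
)

REGION_OF_LABEL = {
    "non-synonymous": "exon",
    "synonymous": "exon",
    "stop-gained": "exon",
    "start-lost": "exon",
    "stop-lost": "exon",
    "stop-retained": "exon",
    "splice-acceptor": "intron",
    "splice-donor": "intron",
    "intron": "intron",
    "upstream-5kb": "non-coding",
    "downstream-5kb": "non-coding",
    "intergenic": "non-coding",
}

#: Flanking-window length for upstream/downstream classification, bp.
FLANK_BP = 5_000

#: Splice sites are the 2 intronic bases adjacent to each exon junction.
SPLICE_BP = 2

_RANK = {label: i for i, label in enumerate(SEVERITY_ORDER)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class EffectCategory:
    """Effect label with region class and coding detail where applicable."""

    label: str
    region: str
    gene_id: str | None = None
    codon_change: str | None = None  # e.g. "AAA>AAG"
    aa_change: str | None = None  # e.g. "K12K"

    def __post_init__(self) -> None:
        if REGION_OF_LABEL[self.label] != self.region:
            raise ValueError(f"label {self.label!r} maps to region {REGION_OF_LABEL[self.label]!r}")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


class EffectAnnotator:
    """Classifies SNVs against a set of gene models and a reference genome.

    Build once per annotation run; :func:`annotate_effect` is a
    convenience wrapper for single sites.
    """

    def __init__(self, genes: list[GeneModel], genome: ReferenceGenome):
        self.genome = genome
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._coding_ok: dict[str, bool] = {}
        for gene in genes:
            self._by_chrom.setdefault(gene.chrom, []).append(gene)
            ok = True
            if gene.cds:
                phase0 = self._first_phase(gene)
                if (gene.cds_length - phase0) % 3 != 0:
                    warnings.warn(
                        f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3 "
                        "after phase; skipping coding classification",
                        stacklevel=2,
                    )
                    ok = False
            else:
                ok = False
            self._coding_ok[gene.gene_id] = ok
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.span)

    @staticmethod
    def _first_phase(gene: GeneModel) -> int:
        ordered = sorted(gene.cds, key=lambda c: c[0], reverse=(gene.strand == "-"))
        return ordered[0][2]

    def _coding_sequence(self, gene: GeneModel) -> str:
        """Spliced CDS in transcript orientation, phase-trimmed."""
        segs = sorted(gene.cds, key=lambda c: c[0])
        seq = "".join(self.genome.fetch(gene.chrom, s, e) for s, e, _ in segs)
        if gene.strand == "-":
            seq = _revcomp(seq)
        return seq[self._first_phase(gene) :]

    def _coding_offset(self, gene: GeneModel, pos: int) -> int | None:
        """0-based offset of ``pos`` in the phase-trimmed coding sequence."""
        segs = sorted(gene.cds, key=lambda c: c[0], reverse=(gene.strand == "-"))
        offset = 0
        for s, e, _ in segs:
            if s <= pos <= e:
                within = (pos - s) if gene.strand == "+" else (e - pos)
                total = offset + within - self._first_phase(gene)
                return total if total >= 0 else None
            offset += e - s + 1
        return None

    def _classify_coding(self, gene: GeneModel, site: VariantSite) -> EffectCategory | None:
        if not self._coding_ok[gene.gene_id]:
            return None
        off = self._coding_offset(gene, site.pos)
        if off is None:
            return None
        coding = self._coding_sequence(gene)
        ci, within = divmod(off, 3)
        ref_codon = coding[ci * 3 : ci * 3 + 3]
        if len(ref_codon) < 3:
            return None
        alt_base = site.alt if gene.strand == "+" else site.alt.translate(_COMPLEMENT)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa, alt_aa = _translate(ref_codon), _translate(alt_codon)
        if ci == 0 and ref_codon == "ATG" and alt_codon != "ATG":
            label = "start-lost"
        elif ref_aa == "*" and alt_aa == "*":
            label = "stop-retained"
        elif ref_aa == "*":
            label = "stop-lost"
        elif alt_aa == "*":
            label = "stop-gained"
        elif ref_aa == alt_aa:
            label = "synonymous"
        else:
            label = "non-synonymous"
        return EffectCategory(
            label=label,
            region="exon",
            gene_id=gene.gene_id,
            codon_change=f"{ref_codon}>{alt_codon}",
            aa_change=f"{ref_aa}{ci + 1}{alt_aa}",
        )

    def _classify_intronic(self, gene: GeneModel, pos: int) -> str | None:
        """Splice-site / intron label if ``pos`` lies between exons."""
        for (s1, e1), (s2, _) in zip(gene.exons, gene.exons[1:]):
            i_start, i_end = e1 + 1, s2 - 1
            if not (i_start <= pos <= i_end):
                continue
            # donor = intronic bases at the transcriptional start of the intron
            if gene.strand == "+":
                donor = range(i_start, min(i_start + SPLICE_BP, i_end + 1))
                acceptor = range(max(i_end - SPLICE_BP + 1, i_start), i_end + 1)
            else:
                donor = range(max(i_end - SPLICE_BP + 1, i_start), i_end + 1)
                acceptor = range(i_start, min(i_start + SPLICE_BP, i_end + 1))
            if pos in donor:
                return "splice-donor"
            if pos in acceptor:
                return "splice-acceptor"
            return "intron"
        return None

    def _classify_gene(self, gene: GeneModel, site: VariantSite) -> EffectCategory | None:
        start, end = gene.span
        pos = site.pos
        if start <= pos <= end:
            in_cds = any(s <= pos <= e for s, e, _ in gene.cds)
            if in_cds:
                cat = self._classify_coding(gene, site)
                if cat is not None:
                    return cat
            label = self._classify_intronic(gene, pos)
            # gene interior outside CDS and outside any intron (e.g. the
            # phase-trimmed margin or non-coding exon) defaults to intron
            label = label or "intron"
            return EffectCategory(label=label, region=REGION_OF_LABEL[label], gene_id=gene.gene_id)
        if gene.strand == "+":
            upstream = start - FLANK_BP <= pos < start
            downstream = end < pos <= end + FLANK_BP
        else:
            upstream = end < pos <= end + FLANK_BP
            downstream = start - FLANK_BP <= pos < start
        if upstream:
            return EffectCategory(label="upstream-5kb", region="non-coding", gene_id=gene.gene_id)
        if downstream:
            return EffectCategory(label="downstream-5kb", region="non-coding", gene_id=gene.gene_id)
        return None

    def annotate(self, site: VariantSite) -> EffectCategory:
        """One label per SNV: the most severe across all overlapping genes."""
        if not site.is_snv:
            raise ValueError(f"site {site.chrom}:{site.pos} is not an SNV")
        if site.is_multiallelic:
            raise ValueError(f"site {site.chrom}:{site.pos} is multi-allelic")
        best: EffectCategory | None = None
        for gene in self._by_chrom.get(site.chrom, []):
            cat = self._classify_gene(gene, site)
            if cat is None:
                continue
            if best is None or (_RANK[cat.label], cat.gene_id) < (_RANK[best.label], best.gene_id):
                best = cat
        return best or EffectCategory(label="intergenic", region="non-coding")


def annotate_effect(
    site: VariantSite, genes: list[GeneModel], genome: ReferenceGenome
) -> EffectCategory:
    """Classify a single biallelic SNV; see :class:`EffectAnnotator`."""
    return EffectAnnotator(genes, genome).annotate(site)
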