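"""Detection of accession-specific SNPs.

An accession-specific SNP is a biallelic site at which exactly one
accession is homozygous for the alternative allele and every other
accession is homozygous reference.  On an inbred or doubled-haploid
panel this is the signature of a private, fixed variant, which makes
the site a candidate for a marker that singles the accession out of
the whole population.

The treatment of missing genotypes in the *other* accessions is
policy, not biology: a missing call could hide a shared alternative
allele.  The default (``max_missing_others = 0``) therefore requires
every other accession to be explicitly hom-ref; relaxations admit a
bounded fraction of missing calls among the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kaspkit.genotype_filtering import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)


@dataclass(frozen=True)
class SpecificityConfig:
    """Missing-genotype policy for the specificity rule.

    ``max_missing_others``: maximum tolerated fraction (in [0, 1]) of
    missing calls among the non-target accessions.  0 (default) means
    every other accession must be called hom-ref.
    """

    max_missing_others: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_others <= 1.0:
            raise ValueError("max_missing_others must be in [0, 1]")


@dataclass
class AccessionSpecificSNP:
    """A site attributed uniquely to one accession."""

    site: VariantSite
    accession: str
    depth: int
    gq: int
    effect: object | None = field(default=None)

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def marker_id(self) -> str:
        return f"{self.site.chrom}_{self.site.pos}"


def call_accession_specific(
    matrix: GenotypeMatrix, config: SpecificityConfig | None = None
) -> list[AccessionSpecificSNP]:
    """Scan a filtered genotype matrix for accession-specific SNPs.

    Requires the matrix to be pre-filtered (no het calls, biallelic
    sites only); raises ``ValueError`` otherwise.  Output carries the
    target accession's DP and GQ (used later for ranking) and is sorted
    by accession, then chromosome, then position.  A site with two
    hom-alt accessions yields nothing, so no site can be attributed to
    two accessions.
    """
    config = config or SpecificityConfig()
    if np.any(matrix.calls == HET):
        raise ValueError(
            "matrix contains heterozygous calls; run filter_genotypes "
            "(homozygous_only=True) before calling accession-specific SNPs"
        )
    if any(s.is_multiallelic for s in matrix.sites):
        raise ValueError(
            "matrix contains multi-allelic sites; run filter_genotypes "
            "(drop_multiallelic=True) first"
        )
    n_others = matrix.n_accessions - 1
    out: list[AccessionSpecificSNP] = []
    for i, site in enumerate(matrix.sites):
        row = matrix.calls[i]
        alt_idx = np.flatnonzero(row == HOM_ALT)
        if alt_idx.size != 1:
            continue
        j = int(alt_idx[0])
        missing_others = int(np.sum(row == MISSING))
        if n_others > 0 and missing_others / n_others > config.max_missing_others:
            continue
        # remaining others must be hom-ref (guaranteed: no het, one hom-alt)
        out.append(
            AccessionSpecificSNP(
                site=site,
                accession=matrix.accessions[j],
                depth=int(matrix.depth[i, j]),
                gq=int(matrix.quality[i, j]),
            )
        )
    out.sort(key=lambda r: (r.accession, r.chrom, r.pos))
    return out
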