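"""Population genotype matrix and quality filtering.

The central object of the pipeline is :class:`GenotypeMatrix`: a
site x accession grid of diploid genotype calls with per-genotype read
depth (DP) and genotype quality (GQ).  Calls are encoded as small
integers (:data:`HOM_REF`, :data:`HET`, :data:`HOM_ALT`,
:data:`MISSING`).

Filtering follows the marker-development protocol for inbred panels:
a genotype survives only with read depth strictly greater than 3 and
genotype quality strictly greater than 30, heterozygous calls are set
to missing (the accessions are inbred or doubled haploid, so a het call
is treated as unreliable rather than discarding the site), and
multi-allelic sites are dropped entirely.  All thresholds are
configurable through :class:`FilterConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

CALL_NAMES = {HOM_REF: "hom-ref", HET: "het", HOM_ALT: "hom-alt", MISSING: "missing"}


@dataclass(frozen=True)
class VariantSite:
    """A variant position: chromosome, 1-based position, REF and ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def alt(self) -> str:
        """The single ALT allele of a biallelic site."""
        if self.is_multiallelic:
            raise ValueError(f"site {self.chrom}:{self.pos} is multi-allelic: {self.alts}")
        return self.alts[0]

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class GenotypeMatrix:
    """Site x accession diploid genotype calls with DP/GQ metadata.

    Parameters
    ----------
    sites
        One :class:`VariantSite` per row.
    accessions
        Ordered sample identifiers (columns).
    calls
        ``(n_sites, n_accessions)`` int8 array of call codes.
    depth, quality
        Same-shape int32 arrays; ``-1`` marks an absent DP/GQ annotation.
    indels
        ``(chrom, start, end, any_carrier)`` records for indel VCF rows
        that were skipped on load (the pipeline is SNV-only); kept so
        flank design can drop windows that an indel overlaps.
    """

    sites: list[VariantSite]
    accessions: list[str]
    calls: np.ndarray
    depth: np.ndarray
    quality: np.ndarray
    indels: list[tuple[str, int, int, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n, m = len(self.sites), len(self.accessions)
        for name in ("calls", "depth", "quality"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        if len(set(self.accessions)) != m:
            raise ValueError("duplicate accession ids")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def accession_index(self, accession: str) -> int:
        try:
            return self.accessions.index(accession)
        except ValueError:
            raise KeyError(
                f"accession {accession!r} not in matrix; available: {self.accessions}"
            ) from None

    def sites_in_window(self, chrom: str, start: int, end: int) -> list[int]:
        """Row indices of sites on ``chrom`` with ``start <= pos <= end``."""
        return [
            i
            for i, s in enumerate(self.sites)
            if s.chrom == chrom and start <= s.pos <= end
        ]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites=list(self.sites),
            accessions=list(self.accessions),
            calls=self.calls.copy(),
            depth=self.depth.copy(),
            quality=self.quality.copy(),
            indels=list(self.indels),
        )


@dataclass(frozen=True)
class FilterConfig:
    """Genotype/site survival thresholds.

    ``min_depth_exclusive=3`` means a genotype needs DP > 3 (i.e. DP >= 4)
    to survive, matching the strict inequality of the protocol; likewise
    GQ > 30.  Absent DP/GQ annotations (stored as -1) always fail.
    """

    min_depth_exclusive: int = 3
    min_gq_exclusive: int = 30
    homozygous_only: bool = True
    drop_multiallelic: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0 or self.min_gq_exclusive < 0:
            raise ValueError("thresholds must be non-negative")


def filter_genotypes(matrix: GenotypeMatrix, config: FilterConfig | None = None) -> GenotypeMatrix:
    """Apply genotype- and site-level quality filters.

    Genotypes with DP <= ``min_depth_exclusive`` or GQ <= ``min_gq_exclusive``
    are set to missing; heterozygous calls are set to missing when
    ``homozygous_only``; multi-allelic sites are removed entirely when
    ``drop_multiallelic``.  Site order is preserved.  Filtering is total
    (never raises on data content) and idempotent.
    """
    config = config or FilterConfig()
    out = matrix.copy()
    called = out.calls != MISSING
    fail = called & ((out.depth <= config.min_depth_exclusive) | (out.quality <= config.min_gq_exclusive))
    if config.homozygous_only:
        fail |= out.calls == HET
    out.calls[fail] = MISSING
    if config.drop_multiallelic:
        keep = [i for i, s in enumerate(out.sites) if not s.is_multiallelic]
        out.sites = [out.sites[i] for i in keep]
        out.calls = out.calls[keep]
        out.depth = out.depth[keep]
        out.quality = out.quality[keep]
    return out


def site_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site tallies of hom-ref / het / hom-alt / missing calls.

    Returns a DataFrame with one row per site (``chrom``, ``pos``,
    ``ref``, ``alt``, ``hom_ref``, ``het``, ``hom_alt``, ``missing``);
    tallies at every site sum to the accession count.
    """
    rows = []
    for i, s in enumerate(matrix.sites):
        row = matrix.calls[i]
        rows.append(
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": ",".join(s.alts),
                "hom_ref": int(np.sum(row == HOM_REF)),
                "het": int(np.sum(row == HET)),
                "hom_alt": int(np.sum(row == HOM_ALT)),
                "missing": int(np.sum(row == MISSING)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "hom_ref", "het", "hom_alt", "missing"],
    )


def relaxed(config: FilterConfig, **changes) -> FilterConfig:
    """Return a copy of ``config`` with fields replaced."""
    return replace(config, **changes)
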