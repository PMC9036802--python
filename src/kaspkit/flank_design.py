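"""KASP candidate-sequence design around accession-specific SNPs.

For each accession-specific SNP the designer extracts the 501-bp
reference window centred on the variant (position 251 of the window),
screens the window for reference Ns, genome-wide sequence redundancy
and repeat overlap, reconstructs each accession's window sequence from
its genotype calls, builds a population consensus in which positions
with more than 10% non-reference (or missing) alleles are masked as N,
and finally emits the candidate sequence with the target SNP written
as a single ``[REF/ALT]`` token at position 251.

Masking exists because a hidden polymorphism under a primer destroys
the assay: any position variable in more than 10% of the panel is
replaced by N so that the downstream primer designer avoids it.  The
target position itself is exempt — it is variable by definition (one
accession out of the panel) and carries the allele-specific primers.

Redundancy is defined here as an exact repeated substring: a window
fails if any stretch of at least ``min_duplicate_match`` bp (default
100) also occurs at a second genomic locus on either strand.  This is
a deterministic proxy for an alignment-based uniqueness search and is
implemented with a k-mer seed index plus ungapped extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kaspkit.genotype_filtering import (
    HET,
    HOM_ALT,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)
from kaspkit.io_formats import ReferenceGenome, RepeatTrack

WINDOW_LENGTH = 501
FLANK = 250
SNP_INDEX = 251  # 1-based position of the variant within the window

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SiteRejected(Exception):
    """A site failed a design screen; ``reason`` is the drop code."""

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass(frozen=True)
class FlankWindow:
    """501-bp reference window with the variant at 1-based index 251."""

    site: VariantSite
    start: int
    end: int
    sequence: str
    snp_index: int = SNP_INDEX

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("window coordinates inconsistent with sequence length")
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(f"window must be {WINDOW_LENGTH} bp, got {len(self.sequence)}")
        if self.sequence[self.snp_index - 1] != self.site.ref:
            raise ValueError(
                f"window base at index {self.snp_index} is "
                f"{self.sequence[self.snp_index - 1]!r}, expected REF {self.site.ref!r}"
            )

    @property
    def chrom(self) -> str:
        return self.site.chrom


@dataclass(frozen=True)
class RedundancyConfig:
    """Exact-duplicate threshold for the uniqueness screen, in bp."""

    min_duplicate_match: int = 100
    seed_k: int = 31

    def __post_init__(self) -> None:
        if not 1 <= self.min_duplicate_match <= WINDOW_LENGTH:
            raise ValueError("min_duplicate_match must be in [1, 501]")


@dataclass
class KaspCandidate:
    """Masked consensus window ready for assay submission."""

    window: FlankWindow
    accession: str
    consensus: str
    masked_count: int
    flags: set[str] = field(default_factory=set)

    @property
    def chrom(self) -> str:
        return self.window.site.chrom

    @property
    def pos(self) -> int:
        return self.window.site.pos

    @property
    def ref(self) -> str:
        return self.window.site.ref

    @property
    def alt(self) -> str:
        return self.window.site.alt

    @property
    def marker_id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    @property
    def candidate_sequence(self) -> str:
        i = self.window.snp_index - 1
        return f"{self.consensus[:i]}[{self.ref}/{self.alt}]{self.consensus[i + 1:]}"


def extract_flank(site: VariantSite, genome: ReferenceGenome) -> FlankWindow:
    """Extract the 501-bp window [pos-250, pos+250] around an SNV.

    Raises :class:`SiteRejected` with reason ``"edge"`` when the window
    would extend past a chromosome end.
    """
    length = genome.lengths[site.chrom]
    if site.pos <= FLANK or site.pos > length - FLANK:
        raise SiteRejected(
            "edge", f"{site.chrom}:{site.pos} within {FLANK} bp of a chromosome end"
        )
    start, end = site.pos - FLANK, site.pos + FLANK
    seq = genome.fetch(site.chrom, start, end)
    if seq[SNP_INDEX - 1] != site.ref:
        raise ValueError(
            f"reference base at {site.chrom}:{site.pos} is {seq[SNP_INDEX - 1]!r}, "
            f"VCF REF is {site.ref!r}"
        )
    return FlankWindow(site=site, start=start, end=end, sequence=seq)


def screen_reference_n(window: FlankWindow) -> bool:
    """Pass iff the reference window contains no N."""
    return "N" not in window.sequence


class DuplicateScreen:
    """Genome-wide exact-duplicate index (k-mer seeds + ungapped extension).

    A window is redundant if some substring of length >=
    ``min_duplicate_match`` occurs at a second locus of the genome on
    either strand; the window's own forward-strand placement is
    excluded.  Build once per genome, query per window.
    """

    def __init__(self, genome: ReferenceGenome, config: RedundancyConfig | None = None):
        self.genome = genome
        self.config = config or RedundancyConfig()
        self.k = min(self.config.seed_k, self.config.min_duplicate_match)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            k = self.k
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def _match_run(self, query: str, qpos: int, target: str, tpos: int) -> tuple[int, int]:
        """Maximal exact ungapped match through the seed: (query start, length)."""
        k = self.k
        left = 0
        while (
            qpos - left - 1 >= 0
            and tpos - left - 1 >= 0
            and query[qpos - left - 1] == target[tpos - left - 1]
            and query[qpos - left - 1] != "N"
        ):
            left += 1
        right = 0
        while (
            qpos + k + right < len(query)
            and tpos + k + right < len(target)
            and query[qpos + k + right] == target[tpos + k + right]
            and query[qpos + k + right] != "N"
        ):
            right += 1
        return qpos - left, left + k + right

    def is_redundant(self, window: FlankWindow) -> bool:
        min_match = self.config.min_duplicate_match
        own_chrom, own_offset = window.chrom, window.start - 1
        for strand, query in (("+", window.sequence), ("-", _revcomp(window.sequence))):
            # per-diagonal list of already-examined match runs (query coords);
            # a diagonal may carry several runs separated by mismatches
            runs: dict[tuple[str, int], list[tuple[int, int]]] = {}
            for qpos in range(len(query) - self.k + 1):
                kmer = query[qpos : qpos + self.k]
                if "N" in kmer:
                    continue
                for chrom, tpos in self._index.get(kmer, ()):
                    diag = tpos - qpos
                    if strand == "+" and chrom == own_chrom and diag == own_offset:
                        continue  # the window's own locus
                    key = (chrom, diag)
                    examined = runs.setdefault(key, [])
                    if any(s <= qpos and qpos + self.k <= s + n for s, n in examined):
                        continue
                    start, length = self._match_run(
                        query, qpos, self.genome.sequences[chrom], tpos
                    )
                    examined.append((start, length))
                    if length >= min_match:
                        return True
        return False


def screen_redundancy(
    window: FlankWindow,
    genome: ReferenceGenome,
    config: RedundancyConfig | None = None,
    screen: DuplicateScreen | None = None,
) -> bool:
    """Pass iff the window has no duplicated stretch elsewhere in the genome.

    Pass a prebuilt :class:`DuplicateScreen` to amortize the index over
    many windows.
    """
    if screen is None:
        screen = DuplicateScreen(genome, config)
    return not screen.is_redundant(window)


def screen_repeats(window: FlankWindow, repeats: RepeatTrack) -> bool:
    """Pass iff the window shares no base with any annotated repeat."""
    return not repeats.overlaps(window.chrom, window.start, window.end)


@dataclass
class FlankAlignment:
    """Per-accession window sequences plus a per-position missing mask.

    ``sequences[acc]`` is the reference window with that accession's
    hom-alt SNVs substituted; ``missing[i, j]`` is True where accession
    ``i`` has no reliable call at window offset ``j`` (the reference
    base is kept in the sequence but the position counts as variable
    during masking).
    """

    window: FlankWindow
    accessions: list[str]
    sequences: dict[str, str]
    missing: np.ndarray  # (n_accessions, 501) bool


def reconstruct_accession_flanks(window: FlankWindow, matrix: GenotypeMatrix) -> FlankAlignment:
    """Substitute each accession's hom-alt SNVs into the reference window.

    Missing (and any residual het) genotypes leave the reference base in
    place but are recorded in the missing mask.  If an indel record in
    the matrix overlaps the window and is carried by any accession, the
    site is rejected with reason ``"indel-in-window"`` — indels would
    break the positional (gap-free) alignment the consensus relies on.
    """
    for chrom, s, e, carrier in matrix.indels:
        if carrier and chrom == window.chrom and s <= window.end and e >= window.start:
            raise SiteRejected(
                "indel-in-window",
                f"indel {chrom}:{s}-{e} overlaps window {window.chrom}:{window.start}-{window.end}",
            )
    n_acc = matrix.n_accessions
    missing = np.zeros((n_acc, WINDOW_LENGTH), dtype=bool)
    seqs = {acc: list(window.sequence) for acc in matrix.accessions}
    for i in matrix.sites_in_window(window.chrom, window.start, window.end):
        site = matrix.sites[i]
        if not site.is_snv or site.is_multiallelic:
            continue
        offset = site.pos - window.start
        for j, acc in enumerate(matrix.accessions):
            call = matrix.calls[i, j]
            if call == HOM_ALT:
                seqs[acc][offset] = site.alts[0]
            elif call in (MISSING, HET):
                missing[j, offset] = True
    return FlankAlignment(
        window=window,
        accessions=list(matrix.accessions),
        sequences={acc: "".join(chars) for acc, chars in seqs.items()},
        missing=missing,
    )


def build_consensus(
    flanks: FlankAlignment | dict[str, str],
    reference: str | None = None,
    mask_threshold: float = 0.10,
    missing: np.ndarray | None = None,
    snp_index: int = SNP_INDEX,
) -> tuple[str, int]:
    """Mask variable positions of the window with N.

    For every position except ``snp_index``, the fraction of accessions
    whose base differs from the reference base — a missing call counts
    as differing — is compared with ``mask_threshold``; strictly greater
    masks the position as N.  Returns ``(consensus, masked_count)``.
    """
    if isinstance(flanks, FlankAlignment):
        reference = flanks.window.sequence
        missing = flanks.missing
        order = flanks.accessions
        seqs = [flanks.sequences[a] for a in order]
    else:
        if reference is None:
            raise ValueError("reference sequence required when passing a plain mapping")
        seqs = list(flanks.values())
    n = len(seqs)
    if n == 0:
        raise ValueError("no accession sequences to build a consensus from")
    length = len(reference)
    for s in seqs:
        if len(s) != length:
            raise ValueError("sequences of unequal length; alignment is positional")
    if missing is None:
        missing = np.zeros((n, length), dtype=bool)
    consensus = list(reference)
    masked = 0
    for j in range(length):
        if j == snp_index - 1:
            continue
        differing = sum(
            1 for i, s in enumerate(seqs) if s[j] != reference[j] or missing[i, j]
        )
        if differing / n > mask_threshold:
            consensus[j] = "N"
            masked += 1
    return "".join(consensus), masked


def make_candidate(
    window: FlankWindow,
    consensus: str,
    accession: str,
    masked_count: int,
    flags: set[str] | None = None,
) -> KaspCandidate:
    """Assemble the final candidate; refuses to emit if any screen flag is set."""
    flags = set(flags or ())
    if flags:
        raise SiteRejected(
            ",".join(sorted(flags)),
            f"{window.chrom}:{window.site.pos} failed screens: {sorted(flags)}",
        )
    if len(consensus) != WINDOW_LENGTH:
        raise ValueError("consensus length must be 501")
    if consensus[window.snp_index - 1] != window.site.ref:
        raise ValueError("consensus must keep the reference base at the SNP position")
    return KaspCandidate(
        window=window, accession=accession, consensus=consensus, masked_count=masked_count
    )
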