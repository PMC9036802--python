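"""End-to-end orchestration: VCF + reference + annotations -> marker panel.

The pipeline chains the stage modules in their canonical order and
records, for every accession-specific SNP that does not survive, the
first screen it failed (the drop log).  Screens are order-invariant on
the surviving set; the fixed order here only determines which reason a
multiply-failing site is logged under (edge, ref-N, repeat, redundant,
indel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from kaspkit.effect_annotation import EffectAnnotator
from kaspkit.flank_design import (
    DuplicateScreen,
    RedundancyConfig,
    SiteRejected,
    build_consensus,
    extract_flank,
    make_candidate,
    reconstruct_accession_flanks,
    screen_reference_n,
    screen_repeats,
)
from kaspkit.genotype_filtering import FilterConfig, GenotypeMatrix, filter_genotypes
from kaspkit.io_formats import GeneModel, ReferenceGenome, RepeatTrack
from kaspkit.panel_selection import (
    DEFAULT_CAP,
    DEFAULT_MIN_SEPARATION,
    DEFAULT_SHORTLIST,
    MarkerCandidate,
    MarkerPanel,
    rank_candidates,
    select_panel,
)
from kaspkit.specificity import AccessionSpecificSNP, SpecificityConfig, call_accession_specific


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    specificity: SpecificityConfig = field(default_factory=SpecificityConfig)
    redundancy: RedundancyConfig = field(default_factory=RedundancyConfig)
    mask_threshold: float = 0.10
    cap: int = DEFAULT_CAP
    shortlist: int = DEFAULT_SHORTLIST
    min_separation: int = DEFAULT_MIN_SEPARATION


@dataclass
class PipelineResult:
    panel: MarkerPanel
    candidates: list[MarkerCandidate]
    specific_snps: list[AccessionSpecificSNP]
    drop_log: pd.DataFrame  # chrom, pos, accession, reason
    filtered_matrix: GenotypeMatrix

    @property
    def detected_positions(self) -> set[tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.specific_snps}


def design_candidates(
    snps: list[AccessionSpecificSNP],
    genome: ReferenceGenome,
    matrix: GenotypeMatrix,
    repeats: RepeatTrack | None = None,
    config: PipelineConfig | None = None,
    annotator: EffectAnnotator | None = None,
) -> tuple[list[MarkerCandidate], list[dict]]:
    """Run the flank-design screens over detected SNPs.

    Returns surviving candidates (with effect annotations when an
    annotator is supplied) and the drop log.
    """
    config = config or PipelineConfig()
    repeats = repeats or RepeatTrack()
    screen = DuplicateScreen(genome, config.redundancy)
    survivors: list[MarkerCandidate] = []
    dropped: list[dict] = []
    for snp in snps:
        try:
            window = extract_flank(snp.site, genome)
            if not screen_reference_n(window):
                raise SiteRejected("ref-n")
            if not screen_repeats(window, repeats):
                raise SiteRejected("repeat")
            if screen.is_redundant(window):
                raise SiteRejected("redundant")
            alignment = reconstruct_accession_flanks(window, matrix)
            consensus, masked = build_consensus(alignment, mask_threshold=config.mask_threshold)
            candidate = make_candidate(window, consensus, snp.accession, masked)
        except SiteRejected as exc:
            dropped.append(
                {"chrom": snp.chrom, "pos": snp.pos, "accession": snp.accession,
                 "reason": exc.reason}
            )
            continue
        effect = annotator.annotate(snp.site) if annotator is not None else None
        survivors.append(
            MarkerCandidate(candidate=candidate, effect=effect, depth=snp.depth, gq=snp.gq)
        )
    return survivors, dropped


def run_pipeline(
    genome: ReferenceGenome,
    matrix: GenotypeMatrix,
    genes: list[GeneModel] | None = None,
    repeats: RepeatTrack | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Filter -> detect -> design -> annotate -> rank -> select."""
    config = config or PipelineConfig()
    filtered = filter_genotypes(matrix, config.filter)
    specific = call_accession_specific(filtered, config.specificity)
    annotator = EffectAnnotator(genes or [], genome)
    candidates, dropped = design_candidates(
        specific, genome, filtered, repeats, config, annotator
    )
    ranked = rank_candidates(candidates, shortlist_size=config.shortlist)
    panel = select_panel(ranked, cap=config.cap, min_separation=config.min_separation)
    drop_log = pd.DataFrame(dropped, columns=["chrom", "pos", "accession", "reason"])
    return PipelineResult(
        panel=panel,
        candidates=candidates,
        specific_snps=specific,
        drop_log=drop_log,
        filtered_matrix=filtered,
    )
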