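"""Marker ranking and panel assembly.

Candidates surviving the design screens are ranked within each
accession — exonic variants first (a variant fixed inside a conserved
genic region is the most reliably amplifiable target), then by read
depth and genotype quality descending, with genomic coordinate as the
final tie-break — and the top ``shortlist_size`` (default 5) are kept.
The panel is then assembled greedily: accessions in sorted order, each
contributing its best-ranked candidates up to ``cap`` (default 2),
skipping any candidate whose 501-bp window overlaps a marker already
selected.  Overlapping windows are the stated failure mode for a
mixed-population assay (two markers reading the same amplicon), so
"position uniqueness" is enforced at window rather than point level:
two markers conflict when they sit on the same chromosome within
``min_separation`` (default 500) bp of each other.

The procedure is deterministic: identical inputs give byte-identical
panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from kaspkit.effect_annotation import EffectCategory
from kaspkit.flank_design import KaspCandidate

DEFAULT_CAP = 2
DEFAULT_SHORTLIST = 5
DEFAULT_MIN_SEPARATION = 500


@dataclass
class MarkerCandidate:
    """A screened candidate with its effect annotation and support stats."""

    candidate: KaspCandidate
    effect: EffectCategory
    depth: int
    gq: int

    @property
    def accession(self) -> str:
        return self.candidate.accession

    @property
    def marker_id(self) -> str:
        return self.candidate.marker_id

    @property
    def sort_key(self):
        exonic = 0 if self.effect.region == "exon" else 1
        return (exonic, -self.depth, -self.gq, self.candidate.chrom, self.candidate.pos)


@dataclass
class SelectedMarker:
    marker_id: str
    accession: str
    candidate: KaspCandidate
    effect: EffectCategory
    rank: int  # 1-based rank within the accession's panel


@dataclass
class MarkerPanel:
    """The selected, position-unique marker set (<= cap per accession)."""

    markers: list[SelectedMarker]
    cap: int = DEFAULT_CAP
    min_separation: int = DEFAULT_MIN_SEPARATION
    shortfall: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def per_accession(self) -> dict[str, list[SelectedMarker]]:
        out: dict[str, list[SelectedMarker]] = {}
        for m in self.markers:
            out.setdefault(m.accession, []).append(m)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "marker_id": m.marker_id,
                "accession": m.accession,
                "chrom": m.candidate.chrom,
                "pos": m.candidate.pos,
                "ref": m.candidate.ref,
                "alt": m.candidate.alt,
                "effect": m.effect.label,
                "region": m.effect.region,
                "rank": m.rank,
            }
            for m in self.markers
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "marker_id", "accession", "chrom", "pos", "ref", "alt",
                "effect", "region", "rank",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_candidates(
    candidates: list[MarkerCandidate], shortlist_size: int = DEFAULT_SHORTLIST
) -> dict[str, list[MarkerCandidate]]:
    """Per-accession ordered shortlists (exon priority, then DP, GQ desc)."""
    by_acc: dict[str, list[MarkerCandidate]] = {}
    for c in candidates:
        by_acc.setdefault(c.accession, []).append(c)
    return {
        acc: sorted(lst, key=lambda c: c.sort_key)[:shortlist_size]
        for acc, lst in sorted(by_acc.items())
    }


def _conflicts(c: KaspCandidate, selected: list[SelectedMarker], min_separation: int) -> bool:
    return any(
        m.candidate.chrom == c.chrom and abs(m.candidate.pos - c.pos) <= min_separation
        for m in selected
    )


def select_panel(
    ranked: dict[str, list[MarkerCandidate]],
    cap: int = DEFAULT_CAP,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> MarkerPanel:
    """Greedy sweep in accession order, then rank order, skipping window overlaps.

    Accessions ending with fewer than ``cap`` markers are listed in
    ``panel.shortfall``.
    """
    selected: list[SelectedMarker] = []
    shortfall: list[str] = []
    for acc in sorted(ranked):
        taken = 0
        for cand in ranked[acc]:
            if taken >= cap:
                break
            if _conflicts(cand.candidate, selected, min_separation):
                continue
            taken += 1
            selected.append(
                SelectedMarker(
                    marker_id=cand.marker_id,
                    accession=acc,
                    candidate=cand.candidate,
                    effect=cand.effect,
                    rank=taken,
                )
            )
        if taken < cap:
            shortfall.append(acc)
    return MarkerPanel(
        markers=selected, cap=cap, min_separation=min_separation, shortfall=shortfall
    )
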