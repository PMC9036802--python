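"""Evaluation of a marker panel against KASP genotype calls.

The evaluator consumes *discrete* genotype calls (the fluorescence
clustering that produces them is upstream): a marker x sample matrix
using the same call codes as the genotype matrix.  Three questions are
answered:

* **Discrimination** — does each marker light up (alt-hom) in its
  target accession and stay reference-homozygous in every other core
  sample, and do outgroup samples stay negative?
* **Parent/F1 distinction** — for a marker specific to one parent of a
  cross, are parent-of-origin (alt-hom), the other parent (ref-hom)
  and the F1 (het) pairwise distinct with the expected calls?
* **Seed purity** — what fraction of a seed lot matches the expected
  hybrid genotype?  Purity = matching / non-missing; missing calls are
  excluded from the denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from kaspkit.genotype_filtering import HET, HOM_ALT, HOM_REF, MISSING, CALL_NAMES
from kaspkit.panel_selection import MarkerPanel

_CODE_OF_NAME = {v: k for k, v in CALL_NAMES.items()}


@dataclass(frozen=True)
class MarkerInfo:
    marker_id: str
    ref: str
    alt: str


@dataclass
class CallMatrix:
    """Marker x sample discrete genotype calls with optional group labels.

    ``groups`` maps sample id to one of {"core", "outgroup", "parent1",
    "parent2", "F1", "seedlot"}; unlabelled samples default to "core".
    """

    markers: list[MarkerInfo]
    samples: list[str]
    calls: np.ndarray  # (n_markers, n_samples) int8
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.markers), len(self.samples)):
            raise ValueError("calls grid inconsistent with marker/sample lists")

    def group(self, sample: str) -> str:
        return self.groups.get(sample, "core")

    def marker_index(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(f"marker {marker_id!r} not in call matrix")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.calls, index=[m.marker_id for m in self.markers], columns=self.samples
        )
        return df.replace(CALL_NAMES)

    def write_tsv(self, path: str | Path) -> None:
        out = self.to_frame()
        out.index.name = "marker_id"
        out.to_csv(path, sep="\t")


def read_call_matrix(path: str | Path, groups: dict[str, str] | None = None) -> CallMatrix:
    """Read a marker x sample TSV of call names (hom-ref/het/hom-alt/missing).

    Marker ids are expected as ``<chrom>_<pos>``; REF/ALT columns are
    optional (``ref``/``alt`` columns before the sample block).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    ref = df.pop("ref") if "ref" in df.columns else None
    alt = df.pop("alt") if "alt" in df.columns else None
    markers = [
        MarkerInfo(
            marker_id=str(mid),
            ref=str(ref.loc[mid]) if ref is not None else "N",
            alt=str(alt.loc[mid]) if alt is not None else "N",
        )
        for mid in df.index
    ]
    calls = np.array(
        [[_CODE_OF_NAME[str(v)] for v in df.loc[mid]] for mid in df.index], dtype=np.int8
    )
    return CallMatrix(
        markers=markers, samples=[str(c) for c in df.columns], calls=calls, groups=groups or {}
    )


@dataclass
class F1Verdict:
    marker_id: str
    passed: bool
    parent_of_origin: str
    calls: dict[str, int]
    reason: str = ""


@dataclass
class PurityResult:
    purity: float
    off_types: list[tuple[str, str]]  # (sample, call name)
    n_missing: int
    n_scored: int


@dataclass
class EvaluationReport:
    """Discrimination summary for a panel against a call matrix."""

    marker_passed: dict[str, bool]
    accession_identified: dict[str, bool]
    confusion: list[tuple[str, str, str]]  # (marker, sample, call name)
    f1_verdicts: list[F1Verdict] = field(default_factory=list)
    purity: PurityResult | None = None

    @property
    def n_markers_passed(self) -> int:
        return sum(self.marker_passed.values())

    @property
    def n_accessions_identified(self) -> int:
        return sum(self.accession_identified.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"marker_id": m, "passed": p} for m, p in sorted(self.marker_passed.items())]
        )


def evaluate_discrimination(panel: MarkerPanel, calls: CallMatrix) -> EvaluationReport:
    """Check that each marker singles out exactly its target accession.

    A marker passes iff its target accession's sample is alt-hom and
    every other core sample is ref-hom.  Outgroup samples must be
    ref-hom or missing at every marker; violations are recorded in the
    confusion list (marker, sample, observed call).  An accession is
    identified iff at least one of its markers passes.
    """
    missing = [m.marker_id for m in panel.markers if not any(
        cm.marker_id == m.marker_id for cm in calls.markers
    )]
    if missing:
        raise KeyError(f"panel markers absent from call matrix: {missing}")
    marker_passed: dict[str, bool] = {}
    confusion: list[tuple[str, str, str]] = []
    for marker in panel.markers:
        i = calls.marker_index(marker.marker_id)
        ok = True
        target_seen = False
        for j, sample in enumerate(calls.samples):
            call = int(calls.calls[i, j])
            grp = calls.group(sample)
            if grp == "core" and sample == marker.accession:
                target_seen = True
                if call != HOM_ALT:
                    ok = False
                    confusion.append((marker.marker_id, sample, CALL_NAMES[call]))
            elif grp == "core":
                if call != HOM_REF:
                    ok = False
                    confusion.append((marker.marker_id, sample, CALL_NAMES[call]))
            elif grp == "outgroup":
                if call not in (HOM_REF, MISSING):
                    ok = False
                    confusion.append((marker.marker_id, sample, CALL_NAMES[call]))
        marker_passed[marker.marker_id] = ok and target_seen
    accession_identified: dict[str, bool] = {}
    for acc, markers in panel.per_accession().items():
        accession_identified[acc] = any(marker_passed[m.marker_id] for m in markers)
    return EvaluationReport(
        marker_passed=marker_passed,
        accession_identified=accession_identified,
        confusion=confusion,
    )


def evaluate_f1(calls: CallMatrix, marker_id: str) -> F1Verdict:
    """Verdict for parent/F1 distinction at one marker.

    Requires samples labelled parent1, parent2 and F1.  Passes iff one
    parent is alt-hom, the other ref-hom and the F1 heterozygous (the
    three calls are then pairwise distinct by construction).  Both
    parents ref-hom means the marker is uninformative for the cross and
    raises ``ValueError``.
    """
    i = calls.marker_index(marker_id)
    roles: dict[str, tuple[str, int]] = {}
    for j, sample in enumerate(calls.samples):
        grp = calls.group(sample)
        if grp in ("parent1", "parent2", "F1"):
            roles[grp] = (sample, int(calls.calls[i, j]))
    missing_roles = [r for r in ("parent1", "parent2", "F1") if r not in roles]
    if missing_roles:
        raise ValueError(f"call matrix lacks samples for roles: {missing_roles}")
    p1, p2, f1 = roles["parent1"][1], roles["parent2"][1], roles["F1"][1]
    if p1 == HOM_REF and p2 == HOM_REF:
        raise ValueError(f"marker {marker_id} is not informative for this cross (both parents hom-ref)")
    if p1 == HOM_ALT and p2 == HOM_REF:
        origin = roles["parent1"][0]
    elif p2 == HOM_ALT and p1 == HOM_REF:
        origin = roles["parent2"][0]
    else:
        return F1Verdict(
            marker_id=marker_id, passed=False, parent_of_origin="",
            calls={r: c for r, (_, c) in roles.items()},
            reason="parents are not opposite homozygotes",
        )
    passed = f1 == HET
    return F1Verdict(
        marker_id=marker_id,
        passed=passed,
        parent_of_origin=origin,
        calls={r: c for r, (_, c) in roles.items()},
        reason="" if passed else f"F1 called {CALL_NAMES[f1]}, expected het",
    )


def assess_purity(expected_call: int, seedlot_calls: list[tuple[str, int]]) -> PurityResult:
    """Fraction of a seed lot matching the expected genotype.

    ``purity = matching / non-missing``; missing calls are excluded from
    the denominator and counted in ``n_missing``.  Off-type seeds are
    returned with their observed calls.
    """
    if expected_call not in (HOM_REF, HET, HOM_ALT):
        raise ValueError("expected_call must be hom-ref, het or hom-alt")
    if not seedlot_calls:
        raise ValueError("empty seed lot")
    scored = [(s, c) for s, c in seedlot_calls if c != MISSING]
    n_missing = len(seedlot_calls) - len(scored)
    if not scored:
        raise ValueError("all seed-lot calls are missing")
    off = [(s, CALL_NAMES[c]) for s, c in scored if c != expected_call]
    purity = (len(scored) - len(off)) / len(scored)
    return PurityResult(purity=purity, off_types=off, n_missing=n_missing, n_scored=len(scored))
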