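"""Readers and writers for the standard formats the pipeline touches.

FASTA (reference genome) is read through pyfaidx, multi-sample VCF
through cyvcf2, gene-model GFF3 through gffutils, and flat repeat
tracks (GFF3 or BED) through pandas.  All genomic coordinates at these
interfaces are 1-based inclusive (VCF/GFF3 convention).

The KASP candidate table is the submission-style format consumed by
assay designers: one row per marker with the 501-bp masked consensus
in which the target SNP appears as a single ``[REF/ALT]`` token.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
from intervaltree import IntervalTree

from kaspkit.genotype_filtering import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeMatrix,
    VariantSite,
)

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
_BRACKET_RE = re.compile(r"\[([ACGT])/([ACGT])\]")


class FormatError(ValueError):
    """A file violated its format contract."""


@dataclass
class ReferenceGenome:
    """Uppercase reference sequences keyed by chromosome id."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"record {name!r} contains invalid characters {sorted(bad)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive substring of ``chrom``."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome (len {len(seq)})")
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model: exons and CDS with phase, one strand.

    ``exons`` are 1-based inclusive ``(start, end)`` pairs sorted by
    start; ``cds`` are ``(start, end, phase)`` triples.  CDS intervals
    must lie within the exon span.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        starts = [s for s, _ in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"gene {self.gene_id}: exons not sorted")
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        span = self.span
        for s, e, _ in self.cds:
            if not (span[0] <= s <= e <= span[1]):
                raise ValueError(f"gene {self.gene_id}: CDS outside exon span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


@dataclass
class RepeatTrack:
    """Per-chromosome repeat intervals (1-based inclusive) with class labels."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, label: str = "repeat") -> None:
        if start > end:
            raise ValueError(f"repeat interval {chrom}:{start}-{end} inverted")
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, label)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if any repeat shares >= 1 bp with [start, end] on ``chrom``."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end + 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def read_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference; sequences are uppercased on load.

    Duplicate record ids and malformed records raise :class:`FormatError`
    naming the offending record.
    """
    path = str(path)
    seen: dict[str, str] = {}
    try:
        fasta = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True, build_index=True)
    except (pyfaidx.FastaIndexingError, ValueError) as exc:
        raise FormatError(f"malformed FASTA {path}: {exc}") from exc
    try:
        for name in fasta.keys():
            seen[name] = str(fasta[name][:])
    finally:
        fasta.close()
    return ReferenceGenome(sequences=seen)


def read_population_vcf(path: str | Path, sample_ids: list[str] | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    One matrix row per SNV site (indel records are skipped with a logged
    count and retained as interval flags for flank design); missing
    genotypes (./.) become missing cells; sample order follows the VCF
    header, or ``sample_ids`` when given.  Multi-allelic SNVs are
    retained and flagged on the site (they are removed by filtering).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    available = list(vcf.samples)
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in available]
        if missing:
            raise KeyError(f"samples {missing} not in VCF; available: {available}")
        vcf.set_samples(sample_ids)
        accessions = list(vcf.samples)
    else:
        accessions = available

    sites: list[VariantSite] = []
    calls_rows, dp_rows, gq_rows = [], [], []
    indels: list[tuple[str, int, int, bool]] = []
    n_indels = 0
    for rec in vcf:
        alts = tuple(rec.ALT)
        if not alts:
            continue
        is_snv = len(rec.REF) == 1 and all(len(a) == 1 for a in alts)
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        calls = np.where(gt == 3, MISSING, np.where(gt == 2, HOM_ALT, gt)).astype(np.int8)
        if not is_snv:
            n_indels += 1
            end = rec.POS + max(len(rec.REF), max(len(a) for a in alts)) - 1
            any_carrier = bool(np.any((calls == HET) | (calls == HOM_ALT)))
            indels.append((rec.CHROM, rec.POS, end, any_carrier))
            continue
        dp_raw = rec.format("DP")
        dp = (
            np.full(len(accessions), -1, dtype=np.int32)
            if dp_raw is None
            else np.where(dp_raw[:, 0] < 0, -1, dp_raw[:, 0]).astype(np.int32)
        )
        gq_raw = rec.format("GQ")
        gq = (
            np.full(len(accessions), -1, dtype=np.int32)
            if gq_raw is None
            else np.where(gq_raw[:, 0] < 0, -1, np.floor(gq_raw[:, 0])).astype(np.int32)
        )
        sites.append(VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alts=alts))
        calls_rows.append(calls)
        dp_rows.append(dp)
        gq_rows.append(gq)
    vcf.close()
    if n_indels:
        logger.info("skipped %d indel records (SNV-only pipeline)", n_indels)
    n, m = len(sites), len(accessions)
    shape = (n, m)
    return GenotypeMatrix(
        sites=sites,
        accessions=accessions,
        calls=np.array(calls_rows, dtype=np.int8).reshape(shape),
        depth=np.array(dp_rows, dtype=np.int32).reshape(shape),
        quality=np.array(gq_rows, dtype=np.int32).reshape(shape),
        indels=indels,
    )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene/exon/CDS hierarchy) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        cds = sorted(
            (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
            for f in db.children(gene, featuretype="CDS")
        )
        if not exons:
            exons = [(s, e) for s, e, _ in cds]
        if not exons:
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return genes


def read_repeats(path: str | Path) -> RepeatTrack:
    """Read a repeat annotation track from GFF3 or BED (by extension)."""
    path = Path(path)
    track = RepeatTrack()
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        for _, row in df.iterrows():
            label = str(row[3]) if df.shape[1] > 3 else "repeat"
            track.add(str(row[0]), int(row[1]) + 1, int(row[2]), label)  # BED is 0-based half-open
    else:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 9:
            raise FormatError(f"{path}: expected 9-column GFF3")
        for _, row in df.iterrows():
            track.add(str(row[0]), int(row[3]), int(row[4]), str(row[2]))
    return track


@dataclass(frozen=True)
class CandidateRecord:
    """One row of the KASP candidate submission table."""

    marker_id: str
    chrom: str
    pos: int
    accession: str
    ref: str
    alt: str
    sequence: str


CANDIDATE_COLUMNS = ["marker_id", "chrom", "pos", "accession", "ref", "alt", "sequence"]


def _as_record(candidate) -> CandidateRecord:
    if isinstance(candidate, CandidateRecord):
        return candidate
    return CandidateRecord(
        marker_id=candidate.marker_id,
        chrom=candidate.chrom,
        pos=candidate.pos,
        accession=candidate.accession,
        ref=candidate.ref,
        alt=candidate.alt,
        sequence=candidate.candidate_sequence,
    )


def write_kasp_candidates(candidates, path: str | Path) -> None:
    """Write candidate sequences as a TSV with one ``[REF/ALT]`` token per row."""
    records = [_as_record(c) for c in candidates]
    for rec in records:
        if len(_BRACKET_RE.findall(rec.sequence)) != 1:
            raise FormatError(
                f"candidate {rec.marker_id}: sequence must contain exactly one [REF/ALT] token"
            )
    df = pd.DataFrame([rec.__dict__ for rec in records], columns=CANDIDATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_kasp_candidates(path: str | Path) -> list[CandidateRecord]:
    """Read a candidate TSV back into :class:`CandidateRecord` rows."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "accession": str})
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        rec = CandidateRecord(
            marker_id=str(row.marker_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            accession=str(row.accession),
            ref=str(row.ref),
            alt=str(row.alt),
            sequence=str(row.sequence),
        )
        if len(_BRACKET_RE.findall(rec.sequence)) != 1:
            raise FormatError(f"{path}: row {rec.marker_id} lacks a single [REF/ALT] token")
        records.append(rec)
    return records


GENOTYPE_TSV_FIXED = ["chrom", "pos", "ref", "alt"]


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as TSV (per-accession cells ``call:DP:GQ``)."""
    from kaspkit.genotype_filtering import CALL_NAMES

    with open(path, "w") as fh:
        fh.write("\t".join(GENOTYPE_TSV_FIXED + matrix.accessions) + "\n")
        for i, s in enumerate(matrix.sites):
            cells = [
                f"{CALL_NAMES[int(matrix.calls[i, j])]}:{int(matrix.depth[i, j])}:{int(matrix.quality[i, j])}"
                for j in range(matrix.n_accessions)
            ]
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Inverse of :func:`write_genotype_tsv`."""
    from kaspkit.genotype_filtering import CALL_NAMES

    code_of = {v: k for k, v in CALL_NAMES.items()}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    accessions = [c for c in df.columns if c not in GENOTYPE_TSV_FIXED]
    sites, calls, dps, gqs = [], [], [], []
    for _, row in df.iterrows():
        sites.append(
            VariantSite(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alts=tuple(str(row.alt).split(",")),
            )
        )
        c_row, d_row, g_row = [], [], []
        for acc in accessions:
            call, dp, gq = str(row[acc]).split(":")
            c_row.append(code_of[call])
            d_row.append(int(dp))
            g_row.append(int(gq))
        calls.append(c_row)
        dps.append(d_row)
        gqs.append(g_row)
    n, m = len(sites), len(accessions)
    return GenotypeMatrix(
        sites=sites,
        accessions=accessions,
        calls=np.array(calls, dtype=np.int8).reshape((n, m)),
        depth=np.array(dps, dtype=np.int32).reshape((n, m)),
        quality=np.array(gqs, dtype=np.int32).reshape((n, m)),
    )


def write_bed(intervals, path: str | Path) -> None:
    """Write ``(chrom, start_1based, end_1based, name)`` rows as BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
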