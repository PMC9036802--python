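"""Synthetic populations with planted ground truth.

The generator emulates the study design the pipeline targets: a panel
of inbred / doubled-haploid accessions jointly genotyped against one
reference genome, where each accession carries a handful of private,
fixed SNPs (the planted "accession-specific" truth) on a background of
confounders that should each be eliminated at a known pipeline stage:

* ``shared`` — hom-alt in two accessions (never specific),
* ``het_target`` — heterozygous in the target (filtered to missing),
* ``multiallelic`` — two ALT alleles (site dropped by the filter),
* ``low_depth`` / ``low_gq`` — target genotype exactly at the failing
  boundary (DP=3 / GQ=30),
* ``boundary_pass`` — target genotype exactly at the surviving
  boundary (DP=4, GQ=31); expected to be *detected*,
* ``in_repeat`` — window overlaps an annotated repeat,
* ``in_duplication`` — window lies inside a duplicated genomic segment
  (fails the uniqueness screen),
* ``near_edge`` — SNP within 250 bp of a chromosome end,
* ``ref_n_flank`` — an N in the reference inside the window.

The background genome is i.i.d. uniform A/C/G/T, so at these scales a
spurious >= 100 bp exact duplicate cannot arise by chance and the
uniqueness screen's negative cases are sound.  All randomness flows
from one integer seed through ``numpy.random.default_rng`` using
integer draws only, so a fixed seed reproduces byte-identical files.

:func:`eight_accession_fixture` packages the worked eight-accession example
(16 published SNPs, two per accession) as a ready-made
:class:`~kaspkit.genotype_filtering.GenotypeMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from kaspkit.genotype_filtering import (
    HET,
    HOM_ALT,
    HOM_REF,
    GenotypeMatrix,
    VariantSite,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = sorted(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Confounders:
    """Counts of planted rule-violating SNPs (one violated rule each)."""

    shared: int = 0
    het_target: int = 0
    multiallelic: int = 0
    low_depth: int = 0
    low_gq: int = 0
    boundary_pass: int = 0
    in_repeat: int = 0
    in_duplication: int = 0
    near_edge: int = 0
    ref_n_flank: int = 0

    @property
    def total(self) -> int:
        return sum(asdict(self).values())


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one simulated population."""

    seed: int = 1
    n_accessions: int = 50
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    specific_per_accession: int = 5
    n_genes: int = 60
    n_repeats: int = 20
    repeat_length: int = 400
    confounders: Confounders = field(default_factory=Confounders)
    depth: int = 12  # DP given to ordinary passing genotypes
    gq: int = 60  # GQ given to ordinary passing genotypes

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least two accessions")
        if self.chrom_length < 2_000:
            raise ValueError("chromosomes must be at least 2 kb")


def study_scale(seed: int = 1, **overrides) -> SimulationConfig:
    """50 accessions, 5 private SNPs each, no confounders."""
    return SimulationConfig(seed=seed, **overrides)


def tiny(seed: int = 1, confounders: Confounders | None = None, **overrides) -> SimulationConfig:
    """Eight accessions with two private SNPs each, on a 2 x 40 kb genome."""
    kwargs = dict(
        n_accessions=8,
        n_chromosomes=2,
        chrom_length=40_000,
        specific_per_accession=2,
        n_genes=8,
        n_repeats=4,
        repeat_length=300,
    )
    kwargs.update(overrides)
    return SimulationConfig(seed=seed, confounders=confounders or Confounders(), **kwargs)


@dataclass
class _PlantedSite:
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    target: int  # accession index
    klass: str
    expected_fate: str
    extra_carrier: int | None = None  # second hom-alt accession (shared class)
    target_call: int = HOM_ALT
    target_dp: int = 0
    target_gq: int = 0


@dataclass
class SimulationResult:
    """File paths, the truth table, and the generating config."""

    config: SimulationConfig
    accessions: list[str]
    fasta: Path
    vcf: Path
    genes_gff: Path
    repeats_gff: Path
    truth_tsv: Path
    truth: pd.DataFrame


class _Genome:
    def __init__(self, rng: np.random.Generator, n_chrom: int, length: int):
        self.names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        self.arrays = {
            name: lut[rng.integers(0, 4, size=length, dtype=np.int64)].copy()
            for name in self.names
        }

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.arrays[chrom][pos - 1])

    def write_segment(self, chrom: str, start: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        self.arrays[chrom][start - 1 : start - 1 + len(seq)] = arr

    def segment(self, chrom: str, start: int, end: int) -> str:
        return self.arrays[chrom][start - 1 : end].tobytes().decode()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(arr) for name, arr in self.arrays.items()}


class _Placer:
    """Non-overlapping interval placement with retry-based sampling."""

    def __init__(self, rng: np.random.Generator, genome: _Genome):
        self.rng = rng
        self.genome = genome
        self.reserved = {name: IntervalTree() for name in genome.names}
        self.dirty = {name: IntervalTree() for name in genome.names}  # repeats/dups/Ns
        self.snp_guard = {name: IntervalTree() for name in genome.names}

    def place(self, length: int, margin: int, max_tries: int = 2_000) -> tuple[str, int]:
        names = self.genome.names
        for _ in range(max_tries):
            chrom = names[int(self.rng.integers(0, len(names)))]
            lim = self.genome.lengths[chrom] - length - margin
            if lim <= margin + 1:
                continue
            start = int(self.rng.integers(margin + 1, lim))
            if self.reserved[chrom].overlap(start - margin, start + length + margin):
                continue
            self.reserved[chrom].addi(start, start + length)
            return chrom, start
        raise ValueError("infeasible config: could not place a segment; genome too small")

    def snp_ok(self, chrom: str, pos: int, clean_window: bool) -> bool:
        length = self.genome.lengths[chrom]
        if pos < 1 or pos > length:
            return False
        if self.snp_guard[chrom].overlap(pos, pos + 1):
            return False
        if clean_window:
            if pos <= 300 or pos > length - 300:
                return False
            if self.dirty[chrom].overlap(pos - 250, pos + 251):
                return False
        return True

    def claim_snp(self, chrom: str, pos: int, spacing: int = 601) -> None:
        self.snp_guard[chrom].addi(pos - spacing, pos + spacing + 1)

    def sample_snp(self, clean_window: bool = True, max_tries: int = 5_000) -> tuple[str, int]:
        names = self.genome.names
        for _ in range(max_tries):
            chrom = names[int(self.rng.integers(0, len(names)))]
            pos = int(self.rng.integers(301, self.genome.lengths[chrom] - 300))
            if self.snp_ok(chrom, pos, clean_window):
                self.claim_snp(chrom, pos)
                return chrom, pos
        raise ValueError("infeasible config: could not place a SNP with required spacing")


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n)
    return "".join(_CODONS[int(i)] for i in idx)


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]


def _build_gene(rng: np.random.Generator, placer: _Placer, genome: _Genome, idx: int) -> _Gene:
    cds_len = 3 * int(rng.integers(150, 250))
    e1 = int(rng.integers(200, min(400, cds_len - 50)))
    e2 = cds_len - e1
    intron_len = 150
    total = cds_len + intron_len
    strand = "+" if idx % 2 == 0 else "-"
    chrom, start = placer.place(total, margin=60)
    coding = "ATG" + _random_codons(rng, cds_len // 3 - 2) + "TAA"
    intron_core = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=intron_len - 4))
    pre_mrna = coding[:e1] + "GT" + intron_core + "AG" + coding[e1:]
    phase2 = (3 - e1 % 3) % 3
    if strand == "+":
        genome.write_segment(chrom, start, pre_mrna)
        exon1 = (start, start + e1 - 1)
        exon2 = (start + e1 + intron_len, start + total - 1)
        exons = [exon1, exon2]
        cds = [(exon1[0], exon1[1], 0), (exon2[0], exon2[1], phase2)]
    else:
        genome.write_segment(chrom, start, _revcomp(pre_mrna))
        exon2 = (start, start + e2 - 1)  # transcript-order second exon, low coords
        exon1 = (start + e2 + intron_len, start + total - 1)
        exons = [exon2, exon1]
        cds = [(exon2[0], exon2[1], phase2), (exon1[0], exon1[1], 0)]
    return _Gene(gene_id=f"gene{idx + 1:03d}", chrom=chrom, strand=strand, exons=exons, cds=cds)


def _other_base(rng: np.random.Generator, ref: str, exclude: tuple[str, ...] = ()) -> str:
    choices = [b for b in _BASES if b != ref and b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def simulate(config: SimulationConfig, outdir: str | Path) -> SimulationResult:
    """Generate FASTA + VCF + gene/repeat GFF3 + truth table under ``outdir``.

    Deterministic: the same config (including seed) produces
    byte-identical files.  Raises ``ValueError`` before writing anything
    when the requested features cannot fit in the genome.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)
    genome = _Genome(rng, config.n_chromosomes, config.chrom_length)
    placer = _Placer(rng, genome)
    accessions = [f"ACC{i + 1:03d}" for i in range(config.n_accessions)]
    conf = config.confounders

    genes = [_build_gene(rng, placer, genome, i) for i in range(config.n_genes)]

    repeats: list[tuple[str, int, int]] = []
    for _ in range(config.n_repeats):
        chrom, start = placer.place(config.repeat_length, margin=300)
        end = start + config.repeat_length - 1
        repeats.append((chrom, start, end))
        placer.dirty[chrom].addi(start, end + 1)

    dup_sources: list[tuple[str, int, int]] = []
    for _ in range(conf.in_duplication):
        src_chrom, src_start = placer.place(2_001, margin=320)
        src_end = src_start + 2_000
        dst_chrom, dst_start = placer.place(2_001, margin=320)
        genome.write_segment(dst_chrom, dst_start, genome.segment(src_chrom, src_start, src_end))
        dup_sources.append((src_chrom, src_start, src_end))
        placer.dirty[src_chrom].addi(src_start, src_end + 1)
        placer.dirty[dst_chrom].addi(dst_start, dst_start + 2_001)

    sites: list[_PlantedSite] = []
    dp, gq = config.depth, config.gq

    def plant(chrom, pos, target, klass, fate, *, alts=None, extra=None,
              call=HOM_ALT, tdp=dp, tgq=gq):
        ref = genome.base(chrom, pos)
        if alts is None:
            alts = (_other_base(rng, ref),)
        sites.append(
            _PlantedSite(
                chrom=chrom, pos=pos, ref=ref, alts=alts, target=target, klass=klass,
                expected_fate=fate, extra_carrier=extra, target_call=call,
                target_dp=tdp, target_gq=tgq,
            )
        )

    # --- clean accession-specific SNPs (first one exonic where genes allow) ---
    gene_cursor = 0
    for i in range(config.n_accessions):
        placed_exonic = False
        if gene_cursor < len(genes):
            gene = genes[gene_cursor]
            gene_cursor += 1
            for _ in range(80):
                seg = gene.cds[int(rng.integers(0, len(gene.cds)))]
                pos = int(rng.integers(seg[0], seg[1] + 1))
                if placer.snp_ok(gene.chrom, pos, clean_window=True):
                    placer.claim_snp(gene.chrom, pos)
                    plant(gene.chrom, pos, i, "specific-exonic", "detected")
                    placed_exonic = True
                    break
        n_rest = config.specific_per_accession - (1 if placed_exonic else 0)
        for _ in range(n_rest):
            chrom, pos = placer.sample_snp()
            plant(chrom, pos, i, "specific", "detected")

    # --- confounders ---
    def pick_target(k: int) -> int:
        return k % config.n_accessions

    k = 0
    for _ in range(conf.shared):
        chrom, pos = placer.sample_snp()
        t = pick_target(k); k += 1
        plant(chrom, pos, t, "shared", "dropped:shared", extra=(t + 1) % config.n_accessions)
    for _ in range(conf.het_target):
        chrom, pos = placer.sample_snp()
        plant(chrom, pos, pick_target(k), "het-target", "dropped:het", call=HET); k += 1
    for _ in range(conf.multiallelic):
        chrom, pos = placer.sample_snp()
        ref = genome.base(chrom, pos)
        a1 = _other_base(rng, ref)
        a2 = _other_base(rng, ref, exclude=(a1,))
        plant(chrom, pos, pick_target(k), "multiallelic", "dropped:multiallelic",
              alts=(a1, a2)); k += 1
    for _ in range(conf.low_depth):
        chrom, pos = placer.sample_snp()
        plant(chrom, pos, pick_target(k), "low-depth", "dropped:depth", tdp=3); k += 1
    for _ in range(conf.low_gq):
        chrom, pos = placer.sample_snp()
        plant(chrom, pos, pick_target(k), "low-gq", "dropped:gq", tgq=30); k += 1
    for _ in range(conf.boundary_pass):
        chrom, pos = placer.sample_snp()
        plant(chrom, pos, pick_target(k), "boundary-pass", "detected", tdp=4, tgq=31); k += 1
    for ri in range(conf.in_repeat):
        chrom, r_start, r_end = repeats[ri % len(repeats)]
        placed = False
        for _ in range(200):
            pos = int(rng.integers(r_start, r_end + 1))
            length = genome.lengths[chrom]
            if 300 < pos <= length - 300 and placer.snp_ok(chrom, pos, clean_window=False):
                placer.claim_snp(chrom, pos)
                plant(chrom, pos, pick_target(k), "in-repeat", "dropped:repeat"); k += 1
                placed = True
                break
        if not placed:
            raise ValueError("infeasible config: no room for an in-repeat SNP")
    for di in range(conf.in_duplication):
        chrom, s, e = dup_sources[di]
        pos = (s + e) // 2
        if not placer.snp_ok(chrom, pos, clean_window=False):
            raise ValueError("infeasible config: duplication centre already claimed")
        placer.claim_snp(chrom, pos)
        plant(chrom, pos, pick_target(k), "in-duplication", "dropped:redundant"); k += 1
    for _ in range(conf.near_edge):
        for _ in range(200):
            chrom = genome.names[int(rng.integers(0, len(genome.names)))]
            pos = int(rng.integers(1, 251))
            if placer.snp_ok(chrom, pos, clean_window=False):
                placer.claim_snp(chrom, pos)
                plant(chrom, pos, pick_target(k), "near-edge", "dropped:edge"); k += 1
                break
        else:
            raise ValueError("infeasible config: no room for a near-edge SNP")
    for _ in range(conf.ref_n_flank):
        for _ in range(200):
            chrom, pos = placer.sample_snp()
            n_pos = pos + 37
            # keep the planted N clear of gene models
            if any(g.chrom == chrom and g.exons[0][0] - 10 <= n_pos <= g.exons[-1][1] + 10
                   for g in genes):
                continue
            genome.arrays[chrom][n_pos - 1] = ord("N")
            placer.dirty[chrom].addi(n_pos, n_pos + 1)
            plant(chrom, pos, pick_target(k), "ref-n-flank", "dropped:ref-n"); k += 1
            break
        else:
            raise ValueError("infeasible config: no room for a ref-N confounder")

    sites.sort(key=lambda s: (s.chrom, s.pos))

    # --- write files ---
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "reference.fasta"
    vcf = outdir / "population.vcf"
    genes_gff = outdir / "genes.gff3"
    repeats_gff = outdir / "repeats.gff3"
    truth_tsv = outdir / "truth.tsv"

    with open(fasta, "w") as fh:
        for name in genome.names:
            fh.write(f">{name}\n")
            seq = genome.arrays[name].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kaspkit-simulate\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(accessions) + "\n")
        for s in sites:
            cells = []
            for j in range(config.n_accessions):
                if j == s.target:
                    gt = {HOM_ALT: "1/1", HET: "0/1", HOM_REF: "0/0"}[s.target_call]
                    cells.append(f"{gt}:{s.target_dp}:{s.target_gq}")
                elif s.extra_carrier is not None and j == s.extra_carrier:
                    cells.append(f"1/1:{dp}:{gq}")
                else:
                    cells.append(f"0/0:{dp}:{gq}")
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{','.join(s.alts)}\t100\tPASS\t.\tGT:DP:GQ\t"
                + "\t".join(cells) + "\n"
            )

    with open(genes_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.exons[0][0])):
            start, end = g.exons[0][0], g.exons[-1][1]
            fh.write(f"{g.chrom}\tsim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            for n, (es, ee) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsim\texon\t{es}\t{ee}\t.\t{g.strand}\t.\tID={mrna}.exon{n};Parent={mrna}\n")
            for n, (cs, ce, phase) in enumerate(g.cds, 1):
                fh.write(f"{g.chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t{phase}\tID={mrna}.cds{n};Parent={mrna}\n")

    with open(repeats_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for n, (chrom, start, end) in enumerate(
            sorted(repeats, key=lambda r: (r[0], r[1])), 1
        ):
            fh.write(f"{chrom}\tsim\trepeat_region\t{start}\t{end}\t.\t.\t.\tID=rep{n:03d};class=simulated\n")

    truth = pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref,
                "alt": ",".join(s.alts),
                "accession": accessions[s.target],
                "class": s.klass,
                "expected_fate": s.expected_fate,
            }
            for s in sites
        ],
        columns=["chrom", "pos", "ref", "alt", "accession", "class", "expected_fate"],
    )
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return SimulationResult(
        config=config,
        accessions=accessions,
        fasta=fasta,
        vcf=vcf,
        genes_gff=genes_gff,
        repeats_gff=repeats_gff,
        truth_tsv=truth_tsv,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Worked eight-accession fixture
# ---------------------------------------------------------------------------

EXAMPLE_ACCESSIONS = [
    "CNU_11479",
    "CNU_11480",
    "26021",
    "26022",
    "28059",
    "28061",
    "CNU_11411",
    "CNU_11412",
]

#: (target accession, chrom, pos, REF, ALT) — two published SNPs per accession.
EXAMPLE_SITES: list[tuple[str, str, int, str, str]] = [
    ("CNU_11479", "A03", 21_060_850, "A", "C"),
    ("CNU_11479", "A06", 3_079_806, "A", "G"),
    ("CNU_11480", "A02", 15_635_917, "C", "T"),
    ("CNU_11480", "A03", 10_121_108, "G", "A"),
    ("26021", "A02", 18_369_509, "C", "T"),
    ("26021", "A06", 6_118_599, "G", "A"),
    ("26022", "A01", 6_548_614, "A", "T"),
    ("26022", "A03", 3_737_651, "A", "C"),
    ("28059", "A07", 21_078_330, "G", "T"),
    ("28059", "A07", 23_181_319, "G", "T"),
    ("28061", "A03", 22_285_257, "G", "A"),
    ("28061", "A10", 450_622, "A", "C"),
    ("CNU_11411", "A07", 20_012_970, "G", "A"),
    ("CNU_11411", "A09", 37_233_481, "C", "T"),
    ("CNU_11412", "A07", 21_781_162, "C", "G"),
    ("CNU_11412", "A09", 42_427_036, "C", "G"),
]


def eight_accession_fixture(depth: int = 12, gq: int = 60) -> GenotypeMatrix:
    """The published eight-accession worked example as a genotype matrix.

    Sixteen SNPs (two per accession), each homozygous-alternative in its
    target accession and homozygous-reference in the other seven.  The
    published table prints no DP/GQ; synthetic nominal passing values
    are filled in (``depth``, ``gq``).
    """
    n = len(EXAMPLE_ACCESSIONS)
    sites = [
        VariantSite(chrom=chrom, pos=pos, ref=ref, alts=(alt,))
        for _, chrom, pos, ref, alt in EXAMPLE_SITES
    ]
    calls = np.full((len(sites), n), HOM_REF, dtype=np.int8)
    for i, (target, *_rest) in enumerate(EXAMPLE_SITES):
        calls[i, EXAMPLE_ACCESSIONS.index(target)] = HOM_ALT
    return GenotypeMatrix(
        sites=sites,
        accessions=list(EXAMPLE_ACCESSIONS),
        calls=calls,
        depth=np.full((len(sites), n), depth, dtype=np.int32),
        quality=np.full((len(sites), n), gq, dtype=np.int32),
    )
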