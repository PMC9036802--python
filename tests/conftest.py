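"""Shared fixtures: synthetic populations and small hand-built objects."""

from __future__ import annotations

import numpy as np
import pytest

from kaspkit import io_formats, synthetic_data
from kaspkit.genotype_filtering import GenotypeMatrix, VariantSite
from kaspkit.io_formats import ReferenceGenome

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=length))


def make_matrix(
    sites: list[tuple[str, int, str, tuple[str, ...]]],
    accessions: list[str],
    calls,
    depth: int = 12,
    gq: int = 60,
) -> GenotypeMatrix:
    """Build a matrix from (chrom, pos, ref, alts) rows and a call grid."""
    calls = np.asarray(calls, dtype=np.int8)
    shape = calls.shape
    return GenotypeMatrix(
        sites=[VariantSite(chrom=c, pos=p, ref=r, alts=a) for c, p, r, a in sites],
        accessions=accessions,
        calls=calls,
        depth=np.full(shape, depth, dtype=np.int32),
        quality=np.full(shape, gq, dtype=np.int32),
    )


def toy_genome(**seqs: str) -> ReferenceGenome:
    return ReferenceGenome(sequences={k: v.upper() for k, v in seqs.items()})


ALL_CONFOUNDERS = synthetic_data.Confounders(
    shared=2,
    het_target=2,
    multiallelic=2,
    low_depth=2,
    low_gq=2,
    boundary_pass=2,
    in_repeat=2,
    in_duplication=1,
    near_edge=2,
    ref_n_flank=2,
)


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """Confounder-free eight-accession simulation plus loaded objects."""
    outdir = tmp_path_factory.mktemp("tiny_sim")
    result = synthetic_data.simulate(synthetic_data.tiny(seed=7), outdir)
    return _load(result)


@pytest.fixture(scope="session")
def confounded_sim(tmp_path_factory):
    """Eight-accession simulation with every confounder class planted."""
    outdir = tmp_path_factory.mktemp("confounded_sim")
    result = synthetic_data.simulate(
        synthetic_data.tiny(seed=11, confounders=ALL_CONFOUNDERS), outdir
    )
    return _load(result)


def _load(result):
    return {
        "result": result,
        "genome": io_formats.read_reference(result.fasta),
        "matrix": io_formats.read_population_vcf(result.vcf),
        "genes": io_formats.read_gene_models(result.genes_gff),
        "repeats": io_formats.read_repeats(result.repeats_gff),
    }
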