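"""Window extraction, design screens, consensus masking, candidate assembly."""

import numpy as np
import pytest

from kaspkit.flank_design import (
    SNP_INDEX,
    WINDOW_LENGTH,
    DuplicateScreen,
    FlankWindow,
    RedundancyConfig,
    SiteRejected,
    build_consensus,
    extract_flank,
    make_candidate,
    reconstruct_accession_flanks,
    screen_redundancy,
    screen_reference_n,
    screen_repeats,
)
from kaspkit.genotype_filtering import HOM_ALT, HOM_REF, MISSING, VariantSite
from kaspkit.io_formats import ReferenceGenome, RepeatTrack

from conftest import make_matrix, random_sequence, revcomp, toy_genome


def site_at(chrom, pos, genome, alt="C"):
    ref = genome.base(chrom, pos)
    alt = "C" if ref != "C" else "G"
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alts=(alt,))


class TestExtractFlank:
    def test_whole_contig_window(self):
        rng = np.random.default_rng(0)
        genome = toy_genome(ctg=random_sequence(rng, 501))
        w = extract_flank(site_at("ctg", 251, genome), genome)
        assert (w.start, w.end) == (1, 501)
        assert w.sequence == genome.sequences["ctg"]
        assert w.snp_index == SNP_INDEX

    def test_interior_window_coordinates(self):
        rng = np.random.default_rng(1)
        genome = toy_genome(ctg=random_sequence(rng, 1000))
        w = extract_flank(site_at("ctg", 300, genome), genome)
        assert (w.start, w.end) == (50, 550)
        assert len(w.sequence) == WINDOW_LENGTH
        assert w.sequence[SNP_INDEX - 1] == w.site.ref

    @pytest.mark.parametrize("pos", [100, 250, 751, 900])
    def test_edge_sites_rejected(self, pos):
        rng = np.random.default_rng(2)
        genome = toy_genome(ctg=random_sequence(rng, 1000))
        with pytest.raises(SiteRejected) as exc:
            extract_flank(site_at("ctg", pos, genome), genome)
        assert exc.value.reason == "edge"


class TestReferenceNScreen:
    def _window(self, seq):
        site = VariantSite(chrom="c", pos=251, ref=seq[250], alts=("C" if seq[250] != "C" else "G",))
        return FlankWindow(site=site, start=1, end=501, sequence=seq)

    def test_single_n_fails(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 501)
        seq = seq[:10] + "N" + seq[11:]
        assert screen_reference_n(self._window(seq)) is False

    def test_n_free_passes(self):
        rng = np.random.default_rng(4)
        assert screen_reference_n(self._window(random_sequence(rng, 501))) is True

    def test_all_n_fails(self):
        seq = "N" * 501
        site = VariantSite(chrom="c", pos=251, ref="N", alts=("C",))
        assert screen_reference_n(FlankWindow(site=site, start=1, end=501, sequence=seq)) is False


def naive_redundancy_oracle(window: FlankWindow, genome: ReferenceGenome, min_match: int) -> bool:
    """Quadratic scan: does any length-``min_match`` substring of the window
    occur at a second locus (forward, any position but its own; or reverse)?"""
    for i in range(len(window.sequence) - min_match + 1):
        sub = window.sequence[i : i + min_match]
        if "N" in sub:
            continue
        own = window.start - 1 + i
        for chrom, seq in genome.sequences.items():
            start = seq.find(sub)
            while start != -1:
                if not (chrom == window.chrom and start == own):
                    return True
                start = seq.find(sub, start + 1)
            if revcomp(sub) in seq:
                return True
    return False


def _genome_with_window(seed, genome_len=30_000, snp_pos=5_000):
    rng = np.random.default_rng(seed)
    genome = toy_genome(chrA=random_sequence(rng, genome_len))
    window = extract_flank(site_at("chrA", snp_pos, genome), genome)
    return genome, window


class TestRedundancyScreen:
    def test_random_genome_window_is_unique(self):
        genome, window = _genome_with_window(10)
        assert screen_redundancy(window, genome) is True
        assert naive_redundancy_oracle(window, genome, 100) is False

    @pytest.mark.parametrize("copy_len,expect_redundant", [(200, True), (100, True), (90, False)])
    def test_forward_duplicate(self, copy_len, expect_redundant):
        genome, window = _genome_with_window(11)
        seqs = dict(genome.sequences)
        piece = window.sequence[150 : 150 + copy_len]
        seqs["chrA"] = seqs["chrA"][:20_000] + piece + seqs["chrA"][20_000 + copy_len :]
        genome2 = ReferenceGenome(sequences=seqs)
        window2 = extract_flank(window.site, genome2)
        assert screen_redundancy(window2, genome2) is (not expect_redundant)
        assert naive_redundancy_oracle(window2, genome2, 100) is expect_redundant

    def test_reverse_strand_duplicate_detected(self):
        genome, window = _genome_with_window(12)
        seqs = dict(genome.sequences)
        piece = revcomp(window.sequence[100:300])
        seqs["chrB"] = random_sequence(np.random.default_rng(99), 5_000)[:2_000] + piece
        genome2 = ReferenceGenome(sequences=seqs)
        window2 = extract_flank(window.site, genome2)
        assert screen_redundancy(window2, genome2) is False
        assert naive_redundancy_oracle(window2, genome2, 100) is True

    def test_split_runs_on_one_diagonal(self):
        """A short match and a long match on the same alignment diagonal:
        the long one must still be found."""
        genome, window = _genome_with_window(13)
        seqs = dict(genome.sequences)
        dest = list(random_sequence(np.random.default_rng(50), 501))
        dest[50:90] = window.sequence[50:90]  # 40 bp, below threshold
        dest[150:290] = window.sequence[150:290]  # 140 bp, above threshold
        seqs["chrA"] = seqs["chrA"][:20_000] + "".join(dest) + seqs["chrA"][20_501:]
        genome2 = ReferenceGenome(sequences=seqs)
        window2 = extract_flank(window.site, genome2)
        assert screen_redundancy(window2, genome2) is False
        assert naive_redundancy_oracle(window2, genome2, 100) is True

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_naive_oracle_on_planted_scenarios(self, seed):
        rng = np.random.default_rng(seed + 400)
        genome, window = _genome_with_window(seed + 300, genome_len=20_000)
        seqs = dict(genome.sequences)
        scenario = seed % 3
        if scenario == 1:  # plant a forward copy of random length
            n = int(rng.integers(60, 250))
            at = int(rng.integers(8_000, 15_000))
            piece = window.sequence[100 : 100 + n]
            seqs["chrA"] = seqs["chrA"][:at] + piece + seqs["chrA"][at + n :]
        elif scenario == 2:  # reverse-strand copy
            n = int(rng.integers(60, 250))
            piece = revcomp(window.sequence[200 : 200 + n])
            seqs["chrA"] = seqs["chrA"][:12_000] + piece + seqs["chrA"][12_000 + n :]
        genome2 = ReferenceGenome(sequences=seqs)
        window2 = extract_flank(window.site, genome2)
        assert screen_redundancy(window2, genome2) == (
            not naive_redundancy_oracle(window2, genome2, 100)
        )


class TestRepeatScreen:
    def _window(self, start=1001):
        rng = np.random.default_rng(20)
        seq = random_sequence(rng, 501)
        site = VariantSite(chrom="c1", pos=start + 250, ref=seq[250],
                           alts=("C" if seq[250] != "C" else "G",))
        return FlankWindow(site=site, start=start, end=start + 500, sequence=seq)

    def test_single_bp_touch_fails(self):
        repeats = RepeatTrack()
        repeats.add("c1", 1501, 1600)
        assert screen_repeats(self._window(), repeats) is False

    def test_adjacent_interval_passes(self):
        repeats = RepeatTrack()
        repeats.add("c1", 1502, 1600)
        assert screen_repeats(self._window(), repeats) is True

    def test_other_chromosome_ignored(self):
        repeats = RepeatTrack()
        repeats.add("c2", 1001, 1501)
        assert screen_repeats(self._window(), repeats) is True

    def test_agrees_with_brute_force_intersection(self):
        rng = np.random.default_rng(21)
        repeats = RepeatTrack()
        intervals = []
        for _ in range(300):
            s = int(rng.integers(1, 50_000))
            e = s + int(rng.integers(0, 400))
            intervals.append((s, e))
            repeats.add("c1", s, e)
        for _ in range(300):
            ws = int(rng.integers(1, 50_000))
            w = self._window(ws)
            expected = any(s <= w.end and e >= w.start for s, e in intervals)
            assert screen_repeats(w, repeats) == (not expected)


@pytest.fixture
def window_and_matrix():
    rng = np.random.default_rng(30)
    genome = toy_genome(chr1=random_sequence(rng, 2_000))
    site = site_at("chr1", 1_000, genome)
    window = extract_flank(site, genome)
    accs = ["A1", "A2", "A3"]
    in_win = window.start + 100  # another SNV inside the window
    sites = [
        (site.chrom, site.pos, site.ref, site.alts),
        ("chr1", in_win, genome.base("chr1", in_win),
         ("G" if genome.base("chr1", in_win) != "G" else "T",)),
    ]
    calls = [[HOM_ALT, HOM_REF, HOM_REF], [HOM_REF, HOM_ALT, MISSING]]
    return genome, window, make_matrix(sites, accs, calls)


class TestReconstruction:
    def test_target_differs_only_at_snp(self, window_and_matrix):
        genome, window, matrix = window_and_matrix
        aln = reconstruct_accession_flanks(window, matrix)
        diffs = [i for i, (a, b) in enumerate(zip(aln.sequences["A1"], window.sequence)) if a != b]
        assert diffs == [SNP_INDEX - 1]
        assert aln.sequences["A1"][SNP_INDEX - 1] == window.site.alt

    def test_no_variant_accession_equals_reference(self, window_and_matrix):
        genome, window, matrix = window_and_matrix
        matrix.calls[1, 2] = HOM_REF  # A3 now carries nothing
        aln = reconstruct_accession_flanks(window, matrix)
        assert aln.sequences["A3"] == window.sequence

    def test_missing_keeps_reference_but_is_recorded(self, window_and_matrix):
        genome, window, matrix = window_and_matrix
        aln = reconstruct_accession_flanks(window, matrix)
        offset = matrix.sites[1].pos - window.start
        assert aln.sequences["A3"][offset] == window.sequence[offset]
        assert aln.missing[2, offset]

    def test_random_planted_snvs_match_diff_oracle(self):
        rng = np.random.default_rng(31)
        genome = toy_genome(chr1=random_sequence(rng, 3_000))
        site = site_at("chr1", 1_500, genome)
        window = extract_flank(site, genome)
        accs = [f"A{i}" for i in range(6)]
        positions = sorted(int(p) for p in rng.choice(np.arange(1_250, 1_751), 12, replace=False))
        sites, calls = [], []
        planted = {a: set() for a in accs}
        for p in positions:
            ref = genome.base("chr1", p)
            alt = [x for x in "ACGT" if x != ref][int(rng.integers(0, 3))]
            sites.append(("chr1", p, ref, (alt,)))
            row = []
            for a in accs:
                if rng.random() < 0.3:
                    row.append(HOM_ALT)
                    planted[a].add(p - window.start)
                else:
                    row.append(HOM_REF)
            calls.append(row)
        matrix = make_matrix(sites, accs, calls)
        aln = reconstruct_accession_flanks(window, matrix)
        for a in accs:
            diffs = {i for i, (x, y) in enumerate(zip(aln.sequences[a], window.sequence)) if x != y}
            assert diffs == planted[a]

    def test_indel_carrier_in_window_rejected(self, window_and_matrix):
        genome, window, matrix = window_and_matrix
        matrix.indels.append(("chr1", window.start + 10, window.start + 12, True))
        with pytest.raises(SiteRejected) as exc:
            reconstruct_accession_flanks(window, matrix)
        assert exc.value.reason == "indel-in-window"

    def test_non_carried_indel_ignored(self, window_and_matrix):
        genome, window, matrix = window_and_matrix
        matrix.indels.append(("chr1", window.start + 10, window.start + 12, False))
        reconstruct_accession_flanks(window, matrix)  # no exception


class TestConsensusMasking:
    def _flanks(self, n_alt, n_total=20, alt_offset=100):
        rng = np.random.default_rng(40)
        ref = random_sequence(rng, 501)
        alt_base = "G" if ref[alt_offset] != "G" else "T"
        seqs = {}
        for i in range(n_total):
            s = ref
            if i < n_alt:
                s = s[:alt_offset] + alt_base + s[alt_offset + 1 :]
            seqs[f"A{i}"] = s
        return seqs, ref, alt_offset

    def test_above_threshold_masked(self):
        seqs, ref, off = self._flanks(3)  # 15% > 10%
        consensus, masked = build_consensus(seqs, ref)
        assert consensus[off] == "N"
        assert masked == 1

    def test_exactly_threshold_unmasked(self):
        seqs, ref, off = self._flanks(2)  # 10%, not strictly greater
        consensus, masked = build_consensus(seqs, ref)
        assert consensus[off] == ref[off]
        assert masked == 0

    def test_no_variation_identity(self):
        seqs, ref, _ = self._flanks(0)
        consensus, masked = build_consensus(seqs, ref)
        assert consensus == ref and masked == 0

    def test_snp_position_exempt(self):
        rng = np.random.default_rng(41)
        ref = random_sequence(rng, 501)
        alt = "G" if ref[SNP_INDEX - 1] != "G" else "T"
        seqs = {f"A{i}": ref[: SNP_INDEX - 1] + alt + ref[SNP_INDEX:] for i in range(5)}
        consensus, masked = build_consensus(seqs, ref)
        assert consensus[SNP_INDEX - 1] == ref[SNP_INDEX - 1]
        assert masked == 0

    def test_missing_counts_as_differing(self):
        seqs, ref, off = self._flanks(0)
        missing = np.zeros((20, 501), dtype=bool)
        missing[:3, off] = True  # 15% missing
        consensus, masked = build_consensus(seqs, ref, missing=missing)
        assert consensus[off] == "N" and masked == 1

    def test_unequal_lengths_rejected(self):
        seqs, ref, _ = self._flanks(0)
        seqs["A0"] = seqs["A0"][:-1]
        with pytest.raises(ValueError, match="unequal"):
            build_consensus(seqs, ref)

    def test_masking_monotone_in_alt_carriers(self):
        """Adding an accession that carries the alternative base never
        unmasks a position."""
        for n in range(0, 19):
            seqs_n, ref, off = self._flanks(n)
            seqs_n1, _, _ = self._flanks(n + 1)
            c_n, _ = build_consensus(seqs_n, ref)
            # n+1 carriers among n_total+1 accessions: superset population
            c_n1, _ = build_consensus(self._flanks(n + 1, n_total=21)[0], ref)
            if c_n[off] == "N":
                assert c_n1[off] == "N"


class TestMakeCandidate:
    def _pieces(self):
        rng = np.random.default_rng(50)
        ref = random_sequence(rng, 501)
        ref = ref[:250] + "A" + ref[251:]
        site = VariantSite(chrom="c", pos=1_250, ref="A", alts=("C",))
        window = FlankWindow(site=site, start=1_000, end=1_500, sequence=ref)
        return window, ref

    def test_bracket_at_position_251(self):
        window, ref = self._pieces()
        cand = make_candidate(window, ref, "ACC1", 0)
        assert cand.candidate_sequence[250:255] == "[A/C]"
        assert len(cand.candidate_sequence) == WINDOW_LENGTH + 4
        assert cand.candidate_sequence.count("[") == 1

    def test_masked_neighbor_adjacent_to_bracket(self):
        window, ref = self._pieces()
        consensus = ref[:249] + "N" + ref[250:]
        cand = make_candidate(window, consensus, "ACC1", 1)
        assert "N[A/C]" in cand.candidate_sequence

    def test_flagged_candidate_refused(self):
        window, ref = self._pieces()
        with pytest.raises(SiteRejected):
            make_candidate(window, ref, "ACC1", 0, flags={"redundant"})

    def test_marker_id_is_chrom_pos(self):
        window, ref = self._pieces()
        assert make_candidate(window, ref, "ACC1", 0).marker_id == "c_1250"


def test_screen_order_invariance(confounded_sim):
    """Applying the three screens in any order yields the same survivor set."""
    import itertools

    from kaspkit.genotype_filtering import filter_genotypes
    from kaspkit.specificity import call_accession_specific

    genome = confounded_sim["genome"]
    repeats = confounded_sim["repeats"]
    matrix = filter_genotypes(confounded_sim["matrix"])
    snps = call_accession_specific(matrix)
    dup = DuplicateScreen(genome)
    screens = {
        "n": lambda w: screen_reference_n(w),
        "rep": lambda w: screen_repeats(w, repeats),
        "dup": lambda w: not dup.is_redundant(w),
    }
    windows = []
    for s in snps:
        try:
            windows.append(extract_flank(s.site, genome))
        except SiteRejected:
            pass
    reference = None
    for order in itertools.permutations(screens):
        surviving = {
            (w.chrom, w.site.pos) for w in windows if all(screens[name](w) for name in order)
        }
        reference = surviving if reference is None else reference
        assert surviving == reference
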