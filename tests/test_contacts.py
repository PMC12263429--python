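"""Fragment maps, multi-way reads, three-way matrices and pairwise profiles."""

import itertools
import re

import numpy as np
import pytest
from scipy.stats import spearmanr

from chromhub.contacts import (
    ContactError,
    MultiwayRead,
    build_pairwise_profile,
    build_threeway_matrix,
    fragment_map_from_sequence,
    mask_viewpoint_proximity,
    normalize_profile,
    simulate_multiway_reads,
    synthetic_fragment_map,
)
from chromhub.locus import GenomicInterval, LocusAnnotation
from chromhub.polymer import Conformation


def scan_oracle(seq):
    """Independent CATG scan via regex."""
    cuts = [m.start() + 4 for m in re.finditer("CATG", seq) if m.start() + 4 < len(seq)]
    edges = [0] + cuts + [len(seq)]
    return list(zip(edges, edges[1:]))


class TestFragmentMap:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", [(0, 4)]),
            ("AACATGAA", [(0, 6), (6, 8)]),
            ("CATGAAAACATGAAAACATG", [(0, 4), (4, 12), (12, 20)]),
        ],
    )
    def test_known_digests(self, seq, expected):
        fm = fragment_map_from_sequence(seq)
        assert [(f.start, f.end) for f in fm.fragments] == expected

    def test_random_sequences_match_scan_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 500))))
            fm = fragment_map_from_sequence(seq)
            assert [(f.start, f.end) for f in fm.fragments] == scan_oracle(seq)
            # fragments tile the sequence exactly
            assert fm.fragments[0].start == 0
            assert fm.fragments[-1].end == len(seq)
            assert sum(len(f) for f in fm.fragments) == len(seq)

    def test_empty_sequence_raises(self):
        with pytest.raises(ContactError):
            fragment_map_from_sequence("")

    def test_synthetic_map_tiles_region(self):
        region = GenomicInterval("c", 1_000, 101_000)
        fm = synthetic_fragment_map(region, seed=3)
        assert fm.fragments[0].start == region.start
        assert fm.fragments[-1].end == region.end
        assert sum(len(f) for f in fm.fragments) == len(region)
        for a, b in zip(fm.fragments, fm.fragments[1:]):
            assert a.end == b.start


@pytest.fixture(scope="module")
def small_locus():
    region = GenomicInterval("c", 0, 100_000)
    return LocusAnnotation(
        region=region, bead_size=2_000, elements=[], tads=[], genes=[],
        ctcf_orientations={},
    )


@pytest.fixture(scope="module")
def small_fragment_map(small_locus):
    return synthetic_fragment_map(small_locus.region, seed=11)


class TestSimulateReads:
    def _conformations(self, n, n_beads, seed=0, spread=1.0):
        rng = np.random.default_rng(seed)
        return [
            Conformation(rng.normal(scale=spread, size=(n_beads, 3)), [])
            for _ in range(n)
        ]

    def test_zero_radius_gives_zero_reads(self, small_locus, small_fragment_map):
        confs = self._conformations(5, small_locus.n_beads)
        vp = GenomicInterval("c", 50_000, 52_000)
        reads = simulate_multiway_reads(
            confs, vp, small_fragment_map, small_locus, capture_radius=0.0, seed=0
        )
        assert reads == []

    def test_deterministic_under_fixed_seed(self, small_locus, small_fragment_map):
        confs = self._conformations(10, small_locus.n_beads, seed=4, spread=2.0)
        vp = GenomicInterval("c", 50_000, 52_000)
        kw = dict(capture_radius=2.0, max_reporters=4, seed=99)
        r1 = simulate_multiway_reads(confs, vp, small_fragment_map, small_locus, **kw)
        r2 = simulate_multiway_reads(confs, vp, small_fragment_map, small_locus, **kw)
        assert [(r.reporters, r.sample_id) for r in r1] == [
            (r.reporters, r.sample_id) for r in r2
        ]
        assert all(len(r.reporters) <= 4 for r in r1)

    def test_reporters_exclude_viewpoint_neighborhood(self, small_locus, small_fragment_map):
        confs = self._conformations(10, small_locus.n_beads, seed=4, spread=0.5)
        vp = GenomicInterval("c", 50_000, 52_000)
        vpf = small_fragment_map.fragment_of(vp.midpoint)
        reads = simulate_multiway_reads(
            confs, vp, small_fragment_map, small_locus,
            capture_radius=3.0, exclusion_fragments=2, seed=1,
        )
        assert reads, "expected reads at this radius"
        for r in reads:
            assert all(abs(f - vpf) > 2 for f in r.reporters)

    def test_viewpoint_outside_locus_raises(self, small_locus, small_fragment_map):
        with pytest.raises(ContactError):
            simulate_multiway_reads(
                [], GenomicInterval("x", 0, 100), small_fragment_map, small_locus
            )


def brute_force_matrix(reads, frag_bin, n_bins):
    """O(reads * k^2) enumeration of all reporter pairs per read."""
    m = np.zeros((n_bins, n_bins))
    for r in reads:
        if len(r.reporters) < 2:
            continue
        bins = [frag_bin[f] for f in r.reporters if frag_bin[f] >= 0]
        for i, j in itertools.combinations(bins, 2):
            m[i, j] += 1
            if i != j:
                m[j, i] += 1
    return m


class TestThreeWayMatrix:
    region = GenomicInterval("c", 0, 200_000)

    @pytest.fixture(scope="class")
    @staticmethod
    def fm(request):
        return synthetic_fragment_map(request.cls.region, seed=5)

    def _frag_bin(self, matrix, fm):
        mids = fm.midpoints()
        fb = np.full(fm.n_fragments, -1, dtype=int)
        win = (mids >= matrix.bin_start) & (
            mids < matrix.bin_start + matrix.n_bins * matrix.bin_size
        )
        fb[win] = ((mids[win] - matrix.bin_start) // matrix.bin_size).astype(int)
        return fb

    def test_single_read_two_reporters(self, fm):
        vp = GenomicInterval("c", 100_000, 100_100)
        # choose reporters in distinct bins
        reads = [MultiwayRead(fm.fragment_of(100_050), (10, 200), 0)]
        m = build_threeway_matrix(reads, fm, vp, bin_size=2_000, region=self.region,
                                  normalize=False)
        fb = self._frag_bin(m, fm)
        i, j = fb[10], fb[200]
        assert m.counts[i, j] == 1 and m.counts[j, i] == 1
        assert m.counts.sum() == (2 if i != j else 1)

    def test_three_reporters_give_all_three_pairs(self, fm):
        vp = GenomicInterval("c", 100_000, 100_100)
        reads = [MultiwayRead(fm.fragment_of(100_050), (10, 200, 400), 0)]
        m = build_threeway_matrix(reads, fm, vp, bin_size=2_000, region=self.region,
                                  normalize=False)
        fb = self._frag_bin(m, fm)
        for a, b in itertools.combinations([10, 200, 400], 2):
            assert m.counts[fb[a], fb[b]] == 1

    def test_random_reads_match_brute_force(self, fm):
        rng = np.random.default_rng(2)
        vp = GenomicInterval("c", 100_000, 100_100)
        vpf = fm.fragment_of(100_050)
        reads = []
        for k in range(300):
            n_rep = int(rng.integers(1, 7))
            reps = tuple(
                int(x)
                for x in rng.choice(fm.n_fragments, size=n_rep, replace=False)
                if x != vpf
            )
            reads.append(MultiwayRead(vpf, reps, k))
        m = build_threeway_matrix(reads, fm, vp, bin_size=1_500, region=self.region,
                                  normalize=False)
        expected = brute_force_matrix(reads, self._frag_bin(m, fm), m.n_bins)
        np.testing.assert_array_equal(m.counts, expected)

    def test_normalized_matrix_sums_to_one_and_symmetric(self, fm):
        rng = np.random.default_rng(3)
        vp = GenomicInterval("c", 100_000, 100_100)
        vpf = fm.fragment_of(100_050)
        reads = [
            MultiwayRead(
                vpf,
                tuple(int(x) for x in rng.choice(fm.n_fragments, 4, replace=False)),
                k,
            )
            for k in range(200)
        ]
        m = build_threeway_matrix(reads, fm, vp, bin_size=2_000, region=self.region)
        assert m.normalization == "window_normalized"
        assert abs(m.counts.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(m.counts, m.counts.T)
        assert m.counts[m.masked_bins, :].sum() == 0

    def test_empty_reads_flagged(self, fm):
        vp = GenomicInterval("c", 100_000, 100_100)
        m = build_threeway_matrix([], fm, vp, bin_size=2_000, region=self.region)
        assert m.empty

    def test_bad_bin_size_rejected(self, fm):
        vp = GenomicInterval("c", 100_000, 100_100)
        with pytest.raises(ContactError):
            build_threeway_matrix([], fm, vp, bin_size=500, region=self.region)


class TestPairwiseProfile:
    region = GenomicInterval("c", 0, 50_000)

    @pytest.fixture(scope="class")
    @staticmethod
    def fm(request):
        return synthetic_fragment_map(request.cls.region, seed=9)

    def _reads(self, fm, n, seed=0):
        # distance-decaying reporter probabilities give the profile structure
        rng = np.random.default_rng(seed)
        vpf = fm.fragment_of(25_000)
        w = 1.0 / (1.0 + np.abs(np.arange(fm.n_fragments) - vpf))
        w /= w.sum()
        return [
            MultiwayRead(
                vpf,
                tuple(int(x) for x in rng.choice(fm.n_fragments, 3, replace=False, p=w)),
                k,
            )
            for k in range(n)
        ]

    def test_scaling_to_chromosome_total(self, fm):
        vp = GenomicInterval("c", 25_000, 25_100)
        p = build_pairwise_profile(
            self._reads(fm, 50), fm, vp, self.region, chromosome_total=100_000.0
        )
        assert abs(p.coverage.sum() - 100_000.0) < 1e-6

    def test_different_capture_efficiencies_normalize_identically(self, fm):
        vp = GenomicInterval("c", 25_000, 25_100)
        few = build_pairwise_profile(self._reads(fm, 20, seed=1), fm, vp, self.region)
        many = build_pairwise_profile(self._reads(fm, 400, seed=2), fm, vp, self.region)
        assert abs(few.coverage.sum() - many.coverage.sum()) < 1e-6

    def test_scale_factor_value(self, fm):
        vp = GenomicInterval("c", 25_000, 25_100)
        raw = build_pairwise_profile(
            self._reads(fm, 10), fm, vp, self.region, normalize=False
        )
        total = raw.coverage.sum()
        norm = normalize_profile(raw, 100_000.0)
        assert norm.scale == pytest.approx(100_000.0 / total)

    def test_zero_coverage_raises(self, fm):
        vp = GenomicInterval("c", 25_000, 25_100)
        raw = build_pairwise_profile([], fm, vp, self.region, normalize=False)
        with pytest.raises(ContactError):
            normalize_profile(raw)

    def test_shape_invariant_to_downsampling(self, fm):
        vp = GenomicInterval("c", 25_000, 25_100)
        reads = self._reads(fm, 4000, seed=5)
        rng = np.random.default_rng(6)
        sub = [reads[i] for i in rng.choice(len(reads), 2000, replace=False)]
        full = build_pairwise_profile(reads, fm, vp, self.region)
        half = build_pairwise_profile(sub, fm, vp, self.region)
        # compare per-fragment means to avoid zero-inflated bp ties
        mids = [int(f.midpoint) for f in fm.fragments]
        rho = spearmanr(full.coverage[mids], half.coverage[mids]).statistic
        assert rho > 0.9


class TestMasking:
    region = GenomicInterval("c", 0, 50_000)

    def _profile(self):
        cov = np.ones(len(self.region))
        from chromhub.contacts import PairwiseProfile

        return PairwiseProfile(
            viewpoint=GenomicInterval("c", 25_000, 25_100),
            region=self.region,
            coverage=cov,
        )

    def test_zero_exclusion_is_identity(self):
        p = self._profile()
        q = mask_viewpoint_proximity(p, 0)
        np.testing.assert_array_equal(p.coverage, q.coverage)

    def test_mask_conserves_total(self):
        p = self._profile()
        q = mask_viewpoint_proximity(p, 1_000)
        masked_total = p.coverage.sum() - q.coverage.sum()
        assert masked_total == pytest.approx(2_001)  # +/-1 kb inclusive
        assert q.coverage.sum() + masked_total == pytest.approx(p.coverage.sum())

    def test_full_span_mask_flags_empty_matrix(self):
        fm = synthetic_fragment_map(self.region, seed=1)
        vp = GenomicInterval("c", 25_000, 25_100)
        vpf = fm.fragment_of(25_050)
        reads = [MultiwayRead(vpf, (2, fm.n_fragments - 3), 0)]
        m = build_threeway_matrix(reads, fm, vp, bin_size=2_000, region=self.region,
                                  normalize=False)
        full = mask_viewpoint_proximity(m, len(self.region))
        assert full.empty
        assert full.masked_bins.all()
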