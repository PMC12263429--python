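"""Virtual capture experiments on conformation ensembles.

Turns sampled 3D conformations into the two data types the downstream
quantification consumes:

* pairwise, viewpoint-anchored interaction profiles (Micro-Capture-C style),
  normalized to a fixed number of interactions on the viewpoint chromosome;
* multi-way reads and three-way contact matrices (Tri-C style): reads with
  two or more cis reporters contribute every unordered reporter pair, the
  matrix is binned (1,500-4,000 bp), corrected for the number of restriction
  fragments per bin, masked around the viewpoint and normalized to unit
  total within a 2-Mb window.

Restriction-fragment maps are NlaIII (CATG) digests of a supplied sequence,
or synthetic maps with exponentially distributed fragment lengths (mean
256 bp, the expectation for a 4-cutter) when no sequence is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .locus import GenomicInterval, LocusAnnotation

NLAIII_SITE = "CATG"
DEFAULT_WINDOW = 2_000_000
DEFAULT_CHROMOSOME_TOTAL = 100_000.0


class ContactError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fragment maps
# ---------------------------------------------------------------------------


@dataclass
class FragmentMap:
    fragments: list  # ordered GenomicInterval, tiling the region
    enzyme: str = "NlaIII"

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([f.start for f in self.fragments] + [self.fragments[-1].end])

    def fragment_of(self, pos: float) -> int:
        """Index of the fragment containing genomic position pos."""
        idx = int(np.searchsorted(self.boundaries, pos, side="right")) - 1
        if not 0 <= idx < self.n_fragments:
            raise ContactError(f"position {pos} outside fragment map")
        return idx

    def midpoints(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments])


def fragment_map_from_sequence(
    sequence: str, chrom: str = "chrS", offset: int = 0
) -> FragmentMap:
    """NlaIII digest: cut positions at the end of each CATG occurrence."""
    seq = str(sequence).upper()
    if not seq:
        raise ContactError("empty sequence")
    cuts = []
    i = seq.find(NLAIII_SITE)
    while i != -1:
        cuts.append(i + len(NLAIII_SITE))
        i = seq.find(NLAIII_SITE, i + 1)
    edges = [0] + [c for c in cuts if c < len(seq)] + [len(seq)]
    edges = sorted(set(edges))
    frags = [
        GenomicInterval(chrom, offset + a, offset + b)
        for a, b in zip(edges, edges[1:])
    ]
    return FragmentMap(fragments=frags)


def fragment_map_from_fasta(path, chrom: str | None = None) -> FragmentMap:
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if chrom is None or rec.id == chrom:
            return fragment_map_from_sequence(str(rec.seq), chrom=rec.id)
    raise ContactError(f"no sequence named {chrom} in {path}")


def synthetic_fragment_map(
    region: GenomicInterval, mean_length: float = 256.0, seed: int = 0
) -> FragmentMap:
    """Synthetic digest with exponential fragment lengths (no sequence needed)."""
    rng = np.random.default_rng(seed)
    edges = [region.start]
    pos = region.start
    while pos < region.end:
        pos += max(1, int(round(rng.exponential(mean_length))))
        edges.append(min(pos, region.end))
    frags = [
        GenomicInterval(region.chrom, a, b) for a, b in zip(edges, edges[1:]) if b > a
    ]
    return FragmentMap(fragments=frags)


# ---------------------------------------------------------------------------
# multi-way reads
# ---------------------------------------------------------------------------


@dataclass
class MultiwayRead:
    viewpoint_fragment: int
    reporters: tuple  # fragment indices, viewpoint excluded
    sample_id: int


def simulate_multiway_reads(
    conformations: list,
    viewpoint: GenomicInterval,
    fragment_map: FragmentMap,
    locus: LocusAnnotation,
    capture_radius: float = 1.5,
    max_reporters: int = 6,
    exclusion_fragments: int = 1,
    reads_per_conformation: int = 1,
    seed: int = 0,
) -> list:
    """Virtual proximity-ligation reads from a conformation ensemble.

    Fragments whose beads lie within ``capture_radius`` of the viewpoint bead
    are candidate reporters; each read samples up to ``max_reporters`` of
    them without replacement.  ``reads_per_conformation`` independent reads
    are drawn per structure (distinct ligation events on the same captured
    contact set).  The viewpoint fragment and its ``exclusion_fragments``
    neighbors on each side are never reporters.
    """
    if not viewpoint.overlaps(locus.region):
        raise ContactError("viewpoint outside locus")
    rng = np.random.default_rng(seed)
    vp_frag = fragment_map.fragment_of(viewpoint.midpoint)
    if len(fragment_map.fragments[vp_frag]) >= 300:
        warnings.warn(
            "viewpoint fragment is >= 300 bp; capture efficiency of real "
            "viewpoints assumes small fragments",
            stacklevel=2,
        )
    vp_bead = locus.bead_of(viewpoint.midpoint)
    mids = fragment_map.midpoints()
    frag_bead = np.clip(
        ((mids - locus.region.start) // locus.bead_size).astype(int),
        0,
        locus.n_beads - 1,
    )
    excluded = set(
        range(vp_frag - exclusion_fragments, vp_frag + exclusion_fragments + 1)
    )
    r2 = capture_radius * capture_radius
    reads = []
    for sample_id, conf in enumerate(conformations):
        coords = conf.coordinates if hasattr(conf, "coordinates") else conf
        d2 = np.sum((coords - coords[vp_bead]) ** 2, axis=1)
        prox_beads = np.flatnonzero(d2 <= r2)
        prox = set(prox_beads) - {vp_bead}
        candidates = [
            f
            for f in np.flatnonzero(np.isin(frag_bead, list(prox)))
            if f not in excluded
        ]
        if not candidates:
            continue
        k = min(max_reporters, len(candidates))
        for _ in range(reads_per_conformation):
            reporters = tuple(
                sorted(int(x) for x in rng.choice(candidates, size=k, replace=False))
            )
            reads.append(MultiwayRead(vp_frag, reporters, sample_id))
    return reads


def write_reads_tsv(reads: list, path):
    with open(path, "w") as fh:
        fh.write("read_id\tviewpoint_fragment\treporters\n")
        for i, r in enumerate(reads):
            fh.write(f"{i}\t{r.viewpoint_fragment}\t{','.join(map(str, r.reporters))}\n")


def read_reads_tsv(path) -> list:
    reads = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, vp, reps = line.rstrip("\n").split("\t")
            reporters = tuple(int(x) for x in reps.split(",")) if reps else ()
            reads.append(MultiwayRead(int(vp), reporters, int(rid)))
    return reads


# ---------------------------------------------------------------------------
# three-way matrices
# ---------------------------------------------------------------------------


@dataclass
class ThreeWayMatrix:
    viewpoint: GenomicInterval
    bin_size: int
    bin_start: int  # genomic start of bin 0
    counts: np.ndarray  # (n_bins, n_bins), symmetric
    fragment_counts_per_bin: np.ndarray
    normalization: str = "raw"  # raw | fragment_corrected | window_normalized
    masked_bins: np.ndarray = None  # bool per bin
    empty: bool = False

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: float) -> int:
        b = int((pos - self.bin_start) // self.bin_size)
        if not 0 <= b < self.n_bins:
            raise ContactError(f"position {pos} outside matrix window")
        return b

    def write_tsv(self, dense_path=None, triplet_path=None):
        if dense_path is not None:
            np.savetxt(dense_path, self.counts, delimiter="\t", fmt="%.8g")
        if triplet_path is not None:
            with open(triplet_path, "w") as fh:
                fh.write("bin_i\tbin_j\tvalue\n")
                ii, jj = np.nonzero(np.triu(self.counts))
                for i, j in zip(ii, jj):
                    fh.write(f"{i}\t{j}\t{self.counts[i, j]:.8g}\n")


def build_threeway_matrix(
    reads: list,
    fragment_map: FragmentMap,
    viewpoint: GenomicInterval,
    bin_size: int = 2_000,
    window: int = DEFAULT_WINDOW,
    region: GenomicInterval | None = None,
    exclusion_bins: int = 2,
    normalize: bool = True,
) -> ThreeWayMatrix:
    """Bin all three-way reporter combinations into a symmetric matrix.

    Every unordered reporter pair of every read with >= 2 cis reporters
    increments its cell (all combinations from reads with > 3 reporters are
    included).  Cells are then divided by the geometric mean of the two
    bins' fragment counts, viewpoint-proximal bins are masked, and the
    matrix is scaled to unit total within the window.
    """
    if not 1_500 <= bin_size <= 4_000:
        raise ContactError("bin_size must be within [1500, 4000] bp")
    half = window // 2
    lo = int(viewpoint.midpoint) - half
    hi = int(viewpoint.midpoint) + half
    if region is not None:
        lo = max(lo, region.start)
        hi = min(hi, region.end)
    n_bins = max(1, math.ceil((hi - lo) / bin_size))

    frag_mids = fragment_map.midpoints()
    in_win = (frag_mids >= lo) & (frag_mids < lo + n_bins * bin_size)
    frag_bin = np.full(fragment_map.n_fragments, -1, dtype=int)
    frag_bin[in_win] = ((frag_mids[in_win] - lo) // bin_size).astype(int)
    fragment_counts = np.bincount(frag_bin[frag_bin >= 0], minlength=n_bins)

    counts = np.zeros((n_bins, n_bins))
    multiway = [r for r in reads if len(r.reporters) >= 2]
    for read in multiway:
        bins = [frag_bin[f] for f in read.reporters]
        bins = [b for b in bins if b >= 0]
        for a in range(len(bins)):
            for b in range(a + 1, len(bins)):
                i, j = bins[a], bins[b]
                counts[i, j] += 1
                if i != j:
                    counts[j, i] += 1

    vp_bin = int((viewpoint.midpoint - lo) // bin_size)
    masked = np.zeros(n_bins, dtype=bool)
    for b in range(vp_bin - exclusion_bins, vp_bin + exclusion_bins + 1):
        if 0 <= b < n_bins:
            masked[b] = True

    mat = ThreeWayMatrix(
        viewpoint=viewpoint,
        bin_size=bin_size,
        bin_start=lo,
        counts=counts,
        fragment_counts_per_bin=fragment_counts,
        masked_bins=masked,
        empty=not multiway,
    )
    if not normalize:
        return mat
    if mat.empty:
        return mat

    # fragment-count correction (geometric mean keeps the matrix symmetric)
    fc = fragment_counts.astype(float)
    denom = np.sqrt(np.outer(fc, fc))
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(denom > 0, counts / denom, 0.0)
    corrected[masked, :] = 0.0
    corrected[:, masked] = 0.0
    total = corrected.sum()
    if total > 0:
        corrected /= total
        mat.normalization = "window_normalized"
    else:
        mat.empty = True
    mat.counts = corrected
    return mat


# ---------------------------------------------------------------------------
# pairwise profiles
# ---------------------------------------------------------------------------


@dataclass
class PairwiseProfile:
    viewpoint: GenomicInterval
    region: GenomicInterval
    coverage: np.ndarray  # per-bp over the region
    scale: float = 1.0
    normalized: bool = False

    def signal_at(self, iv: GenomicInterval) -> float:
        a = max(0, iv.start - self.region.start)
        b = min(len(self.coverage), iv.end - self.region.start)
        if b <= a:
            return 0.0
        return float(self.coverage[a:b].mean())

    def to_bedgraph(self, path):
        cov = self.coverage
        with open(path, "w") as fh:
            start = 0
            for i in range(1, len(cov) + 1):
                if i == len(cov) or cov[i] != cov[start]:
                    if cov[start] != 0:
                        fh.write(
                            f"{self.region.chrom}\t{self.region.start + start}"
                            f"\t{self.region.start + i}\t{cov[start]:.6g}\n"
                        )
                    start = i


def build_pairwise_profile(
    reads: list,
    fragment_map: FragmentMap,
    viewpoint: GenomicInterval,
    region: GenomicInterval,
    chromosome_total: float = DEFAULT_CHROMOSOME_TOTAL,
    normalize: bool = True,
) -> PairwiseProfile:
    """Per-bp reporter coverage, scaled to a fixed chromosome-wide total.

    Every reporter fragment of every read (including single-reporter reads)
    adds one unit of coverage over its span; the profile is then scaled so
    the sum over the viewpoint chromosome equals ``chromosome_total``,
    making profiles comparable across viewpoints with different capture
    efficiencies.
    """
    cov = np.zeros(len(region))
    for read in reads:
        for f in read.reporters:
            frag = fragment_map.fragments[f]
            a = max(0, frag.start - region.start)
            b = min(len(cov), frag.end - region.start)
            if b > a:
                cov[a:b] += 1.0
    profile = PairwiseProfile(viewpoint=viewpoint, region=region, coverage=cov)
    if normalize:
        profile = normalize_profile(profile, chromosome_total)
    return profile


def normalize_profile(
    profile: PairwiseProfile, chromosome_total: float = DEFAULT_CHROMOSOME_TOTAL
) -> PairwiseProfile:
    total = profile.coverage.sum()
    if total <= 0:
        raise ContactError("cannot normalize a zero-coverage profile")
    scale = chromosome_total / total
    return PairwiseProfile(
        viewpoint=profile.viewpoint,
        region=profile.region,
        coverage=profile.coverage * scale,
        scale=scale,
        normalized=True,
    )


def mask_viewpoint_proximity(obj, exclusion_bp: int):
    """Zero and flag positions/bins within +/- exclusion_bp of the viewpoint."""
    if exclusion_bp < 0:
        raise ContactError("exclusion_bp must be >= 0")
    if isinstance(obj, PairwiseProfile):
        cov = obj.coverage.copy()
        mid = int(obj.viewpoint.midpoint) - obj.region.start
        a = max(0, mid - exclusion_bp)
        b = min(len(cov), mid + exclusion_bp + 1)
        if exclusion_bp > 0:
            cov[a:b] = 0.0
        return PairwiseProfile(
            viewpoint=obj.viewpoint,
            region=obj.region,
            coverage=cov,
            scale=obj.scale,
            normalized=obj.normalized,
        )
    if isinstance(obj, ThreeWayMatrix):
        masked = obj.masked_bins.copy()
        counts = obj.counts.copy()
        if exclusion_bp > 0:
            vp = int(obj.viewpoint.midpoint)
            for b in range(obj.n_bins):
                b_lo = obj.bin_start + b * obj.bin_size
                b_hi = b_lo + obj.bin_size
                if b_lo <= vp + exclusion_bp and b_hi >= vp - exclusion_bp:
                    masked[b] = True
            counts[masked, :] = 0.0
            counts[:, masked] = 0.0
        return ThreeWayMatrix(
            viewpoint=obj.viewpoint,
            bin_size=obj.bin_size,
            bin_start=obj.bin_start,
            counts=counts,
            fragment_counts_per_bin=obj.fragment_counts_per_bin,
            normalization=obj.normalization,
            masked_bins=masked,
            empty=bool(obj.empty or not counts.any()),
        )
    raise TypeError(f"unsupported type {type(obj)!r}")
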