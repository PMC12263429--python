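"""Synthetic locus annotations on a bead lattice.

A ~2-Mb locus is represented as a chain of equal-sized beads (default 2 kb of
chromatin per bead).  Each bead carries one of four classes:

* ``machinery_binding`` -- promoters and enhancers, i.e. beads bound by the
  transcription machinery (Mediator/RNAPII);
* ``ctcf_bound``        -- CTCF-binding sites (CBSs), with a motif orientation;
* ``genic``             -- transcribed gene bodies of active genes;
* ``neutral``           -- none of the above.

The generator produces loci with the statistical structure the downstream
analysis assumes: TADs delimited by convergent CTCF sites (forward motif at
the left boundary, reverse at the right), one active gene per TAD, clustered
enhancers (one promoter-proximal and one distal cluster per TAD), and
optional promoter-proximal CBSs (ppCBSs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

# bead classes
NEUTRAL = "neutral"
GENIC = "genic"
MACHINERY = "machinery_binding"
CTCF = "ctcf_bound"

# element classes
ENHANCER = "enhancer"
PROMOTER = "promoter"
CBS = "cbs"

FORWARD = "forward"
REVERSE = "reverse"

_BEAD_PRECEDENCE = (CTCF, MACHINERY, GENIC)  # highest first; else neutral


class LocusConfigError(ValueError):
    """Raised when a locus configuration cannot be realized."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional strand/orientation."""

    chrom: str
    start: int
    end: int
    strand: str = "none"  # '+', '-' or 'none'

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Gene:
    interval: GenomicInterval
    strand: str
    active: bool
    name: str


@dataclass
class LocusAnnotation:
    """Bead-level annotation of one modeled locus."""

    region: GenomicInterval
    bead_size: int
    elements: list  # (GenomicInterval, element class) pairs
    tads: list  # GenomicInterval
    genes: list  # Gene
    ctcf_orientations: dict = field(default_factory=dict)  # bead index -> forward/reverse
    bead_classes: np.ndarray = None  # filled by __post_init__

    def __post_init__(self):
        if len(self.region) % self.bead_size != 0:
            raise LocusConfigError(
                "region length must be divisible by bead_size "
                f"({len(self.region)} % {self.bead_size} != 0)"
            )
        if self.bead_classes is None:
            self.bead_classes = beads_from_elements(self)

    @property
    def n_beads(self) -> int:
        return len(self.region) // self.bead_size

    def bead_of(self, pos: float) -> int:
        """Bead index containing genomic position ``pos``."""
        b = int((pos - self.region.start) // self.bead_size)
        if not 0 <= b < self.n_beads:
            raise ValueError(f"position {pos} outside locus region")
        return b

    def bead_interval(self, bead: int) -> GenomicInterval:
        s = self.region.start + bead * self.bead_size
        return GenomicInterval(self.region.chrom, s, s + self.bead_size)

    def beads_of_interval(self, iv: GenomicInterval) -> range:
        lo = self.bead_of(iv.start)
        hi = self.bead_of(iv.end - 1)
        return range(lo, hi + 1)

    def elements_of_class(self, cls: str) -> list:
        return [iv for iv, c in self.elements if c == cls]

    def machinery_beads(self) -> np.ndarray:
        return np.flatnonzero(self.bead_classes == MACHINERY)

    def ctcf_beads(self) -> np.ndarray:
        return np.flatnonzero(self.bead_classes == CTCF)


def beads_from_elements(locus: LocusAnnotation) -> np.ndarray:
    """Per-bead class labels with precedence ctcf_bound > machinery_binding > genic.

    A bead overlapped by several annotation layers gets the highest-precedence
    class, mirroring the peak-annotation order used for element calls (CBSs
    first, enhancers last among the remainder).
    """
    classes = np.full(locus.n_beads, NEUTRAL, dtype=object)
    for gene in locus.genes:
        if not gene.active:
            continue
        for b in locus.beads_of_interval(gene.interval):
            classes[b] = GENIC
    for iv, cls in locus.elements:
        if not (locus.region.start <= iv.start and iv.end <= locus.region.end):
            raise LocusConfigError(f"element {iv} outside locus region")
        label = CTCF if cls == CBS else MACHINERY
        for b in locus.beads_of_interval(iv):
            if label == CTCF:
                classes[b] = CTCF
            elif classes[b] != CTCF:
                classes[b] = MACHINERY
    return classes


# ---------------------------------------------------------------------------
# element classification (ppCBS / bCBS, proximal / distal enhancers)
# ---------------------------------------------------------------------------

PPCBS_WINDOW = 5_000  # ppCBS iff within +/-5 kb of a targeted promoter
DISTAL_THRESHOLD = 150_000  # enhancers farther than 150 kb are distal


@dataclass(frozen=True)
class ElementClassification:
    cbs_subtype: str = "other"  # ppCBS | bCBS | other (CBS elements only)
    enhancer_distance_class: str = "none"  # proximal | distal (enhancers only)
    distance_to_promoter: float = math.inf


def _boundary_beads(locus: LocusAnnotation) -> set:
    beads = set()
    for tad in locus.tads:
        beads.add(locus.bead_of(tad.start))
        beads.add(locus.bead_of(tad.end - 1))
    return beads


def classify_elements(locus: LocusAnnotation, targeted_promoters: list) -> dict:
    """Classify CBSs as ppCBS/bCBS/other and enhancers as proximal/distal.

    Distances are measured between interval midpoints.  A CBS proximal to
    both a targeted promoter and a TAD boundary is classified ppCBS (ppCBS
    wins over bCBS).  Enhancers farther than 150 kb from the nearest targeted
    promoter are distal.
    """
    boundary = _boundary_beads(locus)
    promoter_mids = [p.midpoint for p in targeted_promoters]
    out = {}
    for iv, cls in locus.elements:
        d = (
            min(abs(iv.midpoint - m) for m in promoter_mids)
            if promoter_mids
            else math.inf
        )
        if cls == CBS:
            if d <= PPCBS_WINDOW:
                sub = "ppCBS"
            elif locus.bead_of(iv.midpoint) in boundary:
                sub = "bCBS"
            else:
                sub = "other"
            out[iv] = ElementClassification(cbs_subtype=sub, distance_to_promoter=d)
        elif cls == ENHANCER:
            dist_cls = "distal" if d > DISTAL_THRESHOLD else "proximal"
            out[iv] = ElementClassification(
                enhancer_distance_class=dist_cls, distance_to_promoter=d
            )
        else:
            out[iv] = ElementClassification(distance_to_promoter=d)
    return out


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@dataclass
class LocusConfig:
    """Parameters of the synthetic locus generator.

    The defaults emulate a 2-Mb region around a differentiation-regulated
    gene: three TADs with convergent-CTCF boundaries, one active gene per
    TAD, a promoter-proximal and a distal enhancer cluster per TAD, and a
    ppCBS next to the middle ("upregulated") gene's promoter.
    """

    chrom: str = "chrS"
    region_start: int = 0
    region_length: int = 2_000_000
    bead_size: int = 2_000
    n_tads: int = 3
    genes_per_tad: int = 1
    gene_length: int = 60_000
    enh_clusters_per_tad: int = 2
    enhancers_per_cluster: int = 2
    internal_cbs_per_tad: int = 1
    cbs_flank_enhancers: bool = True  # CBS bead next to each enhancer cluster
    ppcbs_tads: tuple = (1,)  # TAD indices whose promoter gets a ppCBS
    element_width: int | None = None  # default: one bead
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {"ppcbs_tads": list(self.ppcbs_tads)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "LocusConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise LocusConfigError(f"unknown locus config fields: {sorted(unknown)}")
        if "ppcbs_tads" in d:
            d["ppcbs_tads"] = tuple(d["ppcbs_tads"])
        return cls(**d)


def generate_locus(config: LocusConfig) -> LocusAnnotation:
    """Deterministically generate a synthetic locus from a config and seed."""
    cfg = config
    if cfg.region_length % cfg.bead_size != 0:
        raise LocusConfigError("region_length must be divisible by bead_size")
    rng = np.random.default_rng(cfg.seed)
    bs = cfg.bead_size
    width = cfg.element_width or bs
    region = GenomicInterval(
        cfg.chrom, cfg.region_start, cfg.region_start + cfg.region_length
    )
    n_beads = cfg.region_length // bs
    tad_beads = n_beads // max(cfg.n_tads, 1)
    if cfg.n_tads > 0 and tad_beads < 20:
        raise LocusConfigError("region too small for the requested TAD count")

    used = set()

    def bead_start(b):
        return region.start + b * bs

    def place(bead, n_el=1):
        """Claim ``n_el`` consecutive beads starting at ``bead``; None if taken."""
        beads = range(bead, bead + n_el)
        if any(b in used or not 0 <= b < n_beads for b in beads):
            return None
        used.update(beads)
        return bead

    def place_near(bead, n_el=1, max_shift=20):
        for shift in range(max_shift):
            for cand in (bead + shift, bead - shift):
                got = place(cand, n_el)
                if got is not None:
                    return got
        raise LocusConfigError("could not place element; region too crowded")

    elements = []
    tads = []
    genes = []
    orientations = {}

    def add_cbs(bead, orient):
        s = bead_start(bead)
        elements.append((GenomicInterval(cfg.chrom, s, s + width), CBS))
        orientations[bead] = orient

    for t in range(cfg.n_tads):
        lo = t * tad_beads
        hi = (t + 1) * tad_beads if t < cfg.n_tads - 1 else n_beads
        tads.append(GenomicInterval(cfg.chrom, bead_start(lo), bead_start(hi)))
        # convergent boundary CBSs: forward on the left edge, reverse on the right
        add_cbs(place_near(lo), FORWARD)
        add_cbs(place_near(hi - 1), REVERSE)

        gene_beads = max(1, cfg.gene_length // bs)
        gene_end = lo + int(0.2 * (hi - lo))  # cluster anchor when no genes
        for g in range(cfg.genes_per_tad):
            gstart = lo + int((0.15 + 0.1 * g) * (hi - lo)) + int(rng.integers(0, 4))
            gstart = place_near(gstart, gene_beads + 1)
            prom_iv = GenomicInterval(
                cfg.chrom, bead_start(gstart), bead_start(gstart) + width
            )
            elements.append((prom_iv, PROMOTER))
            gene_iv = GenomicInterval(
                cfg.chrom,
                bead_start(gstart + 1),
                bead_start(gstart + 1 + gene_beads),
            )
            genes.append(Gene(gene_iv, "+", True, f"gene_t{t}_{g}"))
            if g == 0 and t in cfg.ppcbs_tads:
                # ppCBS: bead adjacent to the promoter (midpoint distance =
                # bead size); forward motif locks leftward-extruding anchors
                # right next to the promoter
                b = place_near(gstart - 1)
                add_cbs(b, FORWARD)
            gene_end = gstart + 1 + gene_beads
        for c in range(cfg.enh_clusters_per_tad):
            if c == 0:  # promoter-proximal cluster just downstream of the gene
                base = gene_end + max(2, int(0.03 * (hi - lo)))
            else:  # distal cluster deep in the TAD
                base = lo + int((0.70 + 0.12 * (c - 1)) * (hi - lo))
            base += int(rng.integers(0, 4))
            for e in range(cfg.enhancers_per_cluster):
                b = place_near(base + 2 * e)
                s = bead_start(b)
                elements.append((GenomicInterval(cfg.chrom, s, s + width), ENHANCER))
            if cfg.cbs_flank_enhancers:
                # CBS-dense loci carry convergent CTCF sites flanking their
                # enhancer clusters; extruded loops lock on both sides and
                # hold the cluster at the loop base
                b = place_near(base - 2)
                add_cbs(b, FORWARD)
                b = place_near(base + 2 * cfg.enhancers_per_cluster)
                add_cbs(b, REVERSE)

        for _ in range(cfg.internal_cbs_per_tad):
            for _try in range(200):
                b = int(rng.integers(lo + 2, hi - 2))
                if place(b) is not None:
                    add_cbs(b, FORWARD if rng.random() < 0.5 else REVERSE)
                    break
            else:
                raise LocusConfigError("could not place internal CBS")

    return LocusAnnotation(
        region=region,
        bead_size=bs,
        elements=elements,
        tads=tads,
        genes=genes,
        ctcf_orientations=orientations,
    )


def relabel_ctcf_neutral(locus: LocusAnnotation) -> LocusAnnotation:
    """Copy of the locus with CBS elements removed from the bead annotation.

    Used as a control for in-silico depletion experiments: the CBS intervals
    are dropped entirely, so former CTCF beads become neutral.
    """
    elements = [(iv, c) for iv, c in locus.elements if c != CBS]
    return LocusAnnotation(
        region=locus.region,
        bead_size=locus.bead_size,
        elements=elements,
        tads=list(locus.tads),
        genes=list(locus.genes),
        ctcf_orientations={},
    )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_STRAND = {FORWARD: "+", REVERSE: "-"}
_ORIENT = {"+": FORWARD, "-": REVERSE}


def write_locus_bed(locus: LocusAnnotation, elements_bed, tads_bed, genes_bed):
    """Write elements (BED6; CTCF orientation in the strand column), TADs
    (BED3) and genes (BED6; active flag in the score column)."""
    with open(elements_bed, "w") as fh:
        for iv, cls in locus.elements:
            strand = "."
            if cls == CBS:
                strand = _STRAND[locus.ctcf_orientations[locus.bead_of(iv.midpoint)]]
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\t0\t{strand}\n")
    with open(tads_bed, "w") as fh:
        for tad in locus.tads:
            fh.write(f"{tad.chrom}\t{tad.start}\t{tad.end}\n")
    with open(genes_bed, "w") as fh:
        for g in locus.genes:
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}"
                f"\t{g.name}\t{int(g.active)}\t{g.strand}\n"
            )


def read_locus_bed(
    elements_bed, tads_bed, genes_bed, region: GenomicInterval, bead_size: int
) -> LocusAnnotation:
    elements = []
    orientations = {}
    n_beads = len(region) // bead_size
    with open(elements_bed) as fh:
        for line in fh:
            chrom, start, end, cls, _score, strand = line.split("\t")
            iv = GenomicInterval(chrom, int(start), int(end))
            elements.append((iv, cls))
            if cls == CBS:
                bead = int((iv.midpoint - region.start) // bead_size)
                orientations[bead] = _ORIENT[strand.strip()]
    tads = []
    with open(tads_bed) as fh:
        for line in fh:
            chrom, start, end = line.split("\t")
            tads.append(GenomicInterval(chrom, int(start), int(end)))
    genes = []
    with open(genes_bed) as fh:
        for line in fh:
            chrom, start, end, name, score, strand = line.split("\t")
            genes.append(
                Gene(
                    GenomicInterval(chrom, int(start), int(end)),
                    strand.strip(),
                    bool(int(score)),
                    name,
                )
            )
    return LocusAnnotation(
        region=region,
        bead_size=bead_size,
        elements=elements,
        tads=tads,
        genes=genes,
        ctcf_orientations=orientations,
    )
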