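"""Stochastic 1D dynamics of cohesin loop extrusion and RNAPII translocation.

The bead lattice of a :class:`~chromhub.locus.LocusAnnotation` is traversed by
extruding cohesin complexes (two anchors per complex, each translocating away
from the load site) and RNAPII molecules (loading at active promoters and
translocating along gene bodies).  The update scheme is fixed-time-step
kinetic Monte Carlo: each rate ``k`` becomes a per-step event probability
``1 - exp(-k dt)`` and each translocation speed ``v`` a per-step hop
probability ``v dt / bead_size``.

Obstacle rules
--------------
* A cohesin anchor that steps onto a CTCF-bound bead whose motif faces the
  oncoming anchor (forward motifs block leftward-moving anchors, reverse
  motifs block rightward-moving ones) becomes stalled there and can only
  resume -- passing the site -- at rate ``k_ctcf_release``.  With
  ``ctcf_present=False`` (in-silico depletion) CTCF beads lose all stalling;
  their annotation is kept for scoring.
* Anchors cannot enter a bead engaged by the transcription machinery
  (promoter/enhancer beads, or a bead currently occupied by RNAPII); they
  stall in front of it and cross at rate ``k_cross_rp``.
* Anchors cannot enter a bead occupied by another cohesin anchor; they cross
  (hop past) at rate ``k_cross_cc``.  RNAPII crossing a cohesin anchor uses
  ``k_cross_rp`` symmetrically.

Cohesins unbind at rate ``k_unload`` and immediately rebind at a random bead,
with loading weight ``load_bias`` at machinery-binding beads (preference for
enhancers and promoters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .locus import CTCF, FORWARD, GENIC, MACHINERY, REVERSE, LocusAnnotation

# stall codes
STALL_NONE = 0
STALL_CTCF = 1
STALL_MACHINERY = 2
STALL_COHESIN = 3
STALL_RNAP = 4

STALL_NAMES = {
    STALL_NONE: "none",
    STALL_CTCF: "ctcf",
    STALL_MACHINERY: "machinery",
    STALL_COHESIN: "cohesin",
    STALL_RNAP: "rnap",
}


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Kinetic parameters of the 1D extrusion model.

    Speeds are in kb/min (RNAPII 1-5, cohesin 15-30 per anchor), crossing
    rates in s^-1 (RNAPII-cohesin 1.5, cohesin-cohesin 0.15), unloading /
    release / loading rates in min^-1.  ``dt`` (seconds) must keep every
    per-step event probability below 0.2.
    """

    v_rnap: float = 2.0  # kb/min
    v_cohesin: float = 20.0  # kb/min, per anchor
    k_cross_rp: float = 1.5  # s^-1
    k_cross_cc: float = 0.15  # s^-1
    n_cohesin: int | None = None  # default 1 per 200 kb
    k_unload: float = 0.05  # min^-1  (processivity ~400 kb at 20 kb/min)
    load_bias: float = 10.0  # loading weight at machinery beads
    ctcf_present: bool = True
    k_ctcf_release: float = 0.02  # min^-1 (long-lived CTCF residence)
    k_machinery_release: float = 90.0  # min^-1 (= 1.5 s^-1); stalls at
    #   Mediator-bound E/P beads are brief -- far less stable than at CBSs
    k_rnap_load: float = 0.5  # min^-1 per active promoter
    dt: float = 0.1  # s
    seed: int = 0
    initial_load_bead: int | None = None  # fix the first load site (analytics)
    edge_unload: bool = True  # anchors extruding past the modeled window
    #   leave it: the cohesin unloads instead of piling up at the edge beads

    def resolved_n_cohesin(self, locus: LocusAnnotation) -> int:
        if self.n_cohesin is not None:
            return self.n_cohesin
        return max(1, int(round(len(locus.region) / 200_000)))

    def probabilities(self, locus: LocusAnnotation) -> dict:
        """Per-step event probabilities implied by dt and the bead size."""
        dt_min = self.dt / 60.0
        bead_kb = locus.bead_size / 1000.0
        return {
            "move_anchor": self.v_cohesin * dt_min / bead_kb,
            "move_rnap": self.v_rnap * dt_min / bead_kb,
            "cross_rp": 1.0 - math.exp(-self.k_cross_rp * self.dt),
            "cross_cc": 1.0 - math.exp(-self.k_cross_cc * self.dt),
            "unload": 1.0 - math.exp(-self.k_unload * dt_min),
            "ctcf_release": 1.0 - math.exp(-self.k_ctcf_release * dt_min),
            "machinery_release": 1.0 - math.exp(-self.k_machinery_release * dt_min),
            "rnap_load": 1.0 - math.exp(-self.k_rnap_load * dt_min),
        }

    def validate(self, locus: LocusAnnotation):
        for name, value in vars(self).items():
            if isinstance(value, (int, float)) and name not in ("seed",) and value is not None:
                if value < 0:
                    raise SimulationConfigError(f"{name} must be >= 0")
        for name, p in self.probabilities(locus).items():
            if p >= 0.2:
                raise SimulationConfigError(
                    f"per-step probability for {name} is {p:.3f} >= 0.2; reduce dt"
                )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(vars(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise SimulationConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CohesinEnsembleState:
    """Snapshot of all cohesins and RNAPII molecules at one time point."""

    left: np.ndarray  # per-cohesin left anchor bead
    right: np.ndarray
    stall_left: np.ndarray  # stall codes, see STALL_NAMES
    stall_right: np.ndarray
    generation: np.ndarray  # incremented at each reload (tracks residence epochs)
    rnap_pos: np.ndarray
    rnap_dir: np.ndarray
    rnap_gene: np.ndarray
    time: float  # minutes

    def loop_bonds(self) -> list:
        return [
            (int(l), int(r)) for l, r in zip(self.left, self.right) if l < r
        ]


@dataclass
class FlowTrack:
    """Net signed cohesin-anchor passages per minute at each inter-bead
    boundary, assigned to the bead right of the boundary (sense positive)."""

    flow: np.ndarray  # per bead, min^-1

    def to_bedgraph(self, locus: LocusAnnotation, path):
        with open(path, "w") as fh:
            for b, v in enumerate(self.flow):
                iv = locus.bead_interval(b)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:.6g}\n")


@dataclass
class Trajectory:
    locus: LocusAnnotation
    config: SimulationConfig
    samples: list  # CohesinEnsembleState
    unload_events: list = field(default_factory=list)  # (time_min, loop_size_beads)
    n_load_events: int = 0
    n_unload_events: int = 0


class ExtrusionEngine:
    """Mutable simulation state with a fixed-dt kinetic Monte Carlo stepper."""

    def __init__(self, locus: LocusAnnotation, config: SimulationConfig):
        config.validate(locus)
        self.locus = locus
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.n_beads = locus.n_beads
        self.p = config.probabilities(locus)
        self.dt_min = config.dt / 60.0
        self.time = 0.0

        classes = locus.bead_classes
        self.is_machinery = classes == MACHINERY
        self.is_genic = classes == GENIC
        # orientation-specific CTCF blocking: forward motifs face left, i.e.
        # block anchors extruding leftwards; reverse motifs block rightwards.
        self.blocks_left = np.zeros(self.n_beads, dtype=bool)
        self.blocks_right = np.zeros(self.n_beads, dtype=bool)
        if config.ctcf_present:
            for bead, orient in locus.ctcf_orientations.items():
                if classes[bead] != CTCF:
                    continue
                if orient == FORWARD:
                    self.blocks_left[bead] = True
                elif orient == REVERSE:
                    self.blocks_right[bead] = True

        # loading weights
        w = np.ones(self.n_beads)
        w[self.is_machinery] = config.load_bias
        self.load_weights = w / w.sum()

        # genes: (first body bead, last body bead, promoter bead, direction)
        self.genes = []
        for g in locus.genes:
            if not g.active:
                continue
            beads = locus.beads_of_interval(g.interval)
            if g.strand == "-":
                self.genes.append((beads[-1], beads[0], beads[-1], -1))
            else:
                self.genes.append((beads[0], beads[-1], beads[0], +1))

        n = config.resolved_n_cohesin(locus)
        self.left = np.zeros(n, dtype=np.int64)
        self.right = np.zeros(n, dtype=np.int64)
        self.stall_left = np.zeros(n, dtype=np.int64)
        self.stall_right = np.zeros(n, dtype=np.int64)
        self.generation = np.zeros(n, dtype=np.int64)
        self.anchor_occ = np.zeros(self.n_beads, dtype=np.int64)
        self.rnap = []  # [pos, direction, gene index]
        self.rnap_occ = np.zeros(self.n_beads, dtype=np.int64)
        self.unload_events = []
        self.n_load_events = 0
        self.n_unload_events = 0
        for c in range(n):
            self._load(c, initial=True)

    # -- loading -----------------------------------------------------------

    def _draw_load_bead(self) -> int:
        for _ in range(50):
            b = int(self.rng.choice(self.n_beads, p=self.load_weights))
            if self.anchor_occ[b] == 0:
                return b
        free = np.flatnonzero(self.anchor_occ == 0)
        return int(self.rng.choice(free))

    def _load(self, c: int, initial: bool = False):
        if initial and self.config.initial_load_bead is not None:
            b = int(self.config.initial_load_bead)
        else:
            b = self._draw_load_bead()
        self.left[c] = self.right[c] = b
        self.anchor_occ[b] += 2
        self.stall_left[c] = self.stall_right[c] = STALL_NONE
        self._maybe_lock_ctcf(c, -1)
        self._maybe_lock_ctcf(c, +1)
        self.n_load_events += 1
        if not initial:
            self.generation[c] += 1

    def _unload(self, c: int):
        size = int(self.right[c] - self.left[c])
        self.unload_events.append((self.time, size))
        self.n_unload_events += 1
        self.anchor_occ[self.left[c]] -= 1
        self.anchor_occ[self.right[c]] -= 1

    def _maybe_lock_ctcf(self, c: int, direction: int):
        if direction < 0:
            if self.blocks_left[self.left[c]]:
                self.stall_left[c] = STALL_CTCF
        else:
            if self.blocks_right[self.right[c]]:
                self.stall_right[c] = STALL_CTCF

    # -- stepping ----------------------------------------------------------

    def _try_move_anchor(self, c: int, direction: int):
        """Attempt to advance one anchor of cohesin ``c`` one bead outwards.

        An unstalled anchor hops with probability v*dt/bead_size; an anchor
        stalled at an obstacle attempts the corresponding crossing event at
        its own rate (not gated by the hop probability); a CTCF-locked anchor
        passes the site at the release rate.
        """
        rng = self.rng
        p = self.p
        anchors = self.left if direction < 0 else self.right
        stalls = self.stall_left if direction < 0 else self.stall_right
        cur = int(anchors[c])
        t = cur + direction

        if stalls[c] == STALL_CTCF:
            # locked on a CTCF bead: release lets the anchor pass the site
            if rng.random() >= p["ctcf_release"]:
                return
            if 0 <= t < self.n_beads and self._enterable(t):
                self._move_anchor_to(c, direction, t)
            return

        if not 0 <= t < self.n_beads:
            return  # locus edge

        blocked_by_anchor = self.anchor_occ[t] > 0
        blocked_by_mach = self.is_machinery[t] or self.rnap_occ[t] > 0

        if stalls[c] == STALL_NONE:
            if rng.random() >= p["move_anchor"]:
                return
            if blocked_by_anchor:
                stalls[c] = STALL_COHESIN
            elif blocked_by_mach:
                stalls[c] = STALL_RNAP if self.rnap_occ[t] > 0 else STALL_MACHINERY
            else:
                self._move_anchor_to(c, direction, t)
            return

        # already stalled at an obstacle: attempt the crossing event
        if blocked_by_anchor:
            stalls[c] = STALL_COHESIN
            blocked_ctcf = self.blocks_left[t] if direction < 0 else self.blocks_right[t]
            if rng.random() < p["cross_cc"] and not blocked_ctcf:
                # hop past the blocking anchor -- unless it is parked on a
                # CTCF bead whose motif blocks this direction (no leapfrog
                # through the barrier)
                t2 = t + direction
                if 0 <= t2 < self.n_beads and self._enterable(t2):
                    self._move_anchor_to(c, direction, t2)
        elif blocked_by_mach:
            # RNAPII molecules are crossed at the RNAPII-cohesin rate;
            # stalls at machinery-binding (Mediator-bound) beads release
            # more slowly
            if self.rnap_occ[t] > 0:
                stalls[c] = STALL_RNAP
                if rng.random() < p["cross_rp"]:
                    self._move_anchor_to(c, direction, t)
            else:
                stalls[c] = STALL_MACHINERY
                if rng.random() < p["machinery_release"]:
                    self._move_anchor_to(c, direction, t)
        else:
            # obstacle is gone; resume normal stepping
            stalls[c] = STALL_NONE
            if rng.random() < p["move_anchor"]:
                self._move_anchor_to(c, direction, t)

    def _enterable(self, t: int) -> bool:
        return self.anchor_occ[t] == 0 and self.rnap_occ[t] == 0 and not self.is_machinery[t]

    def _move_anchor_to(self, c: int, direction: int, t: int):
        anchors = self.left if direction < 0 else self.right
        stalls = self.stall_left if direction < 0 else self.stall_right
        self.anchor_occ[anchors[c]] -= 1
        anchors[c] = t
        self.anchor_occ[t] += 1
        stalls[c] = STALL_NONE
        self._maybe_lock_ctcf(c, direction)

    def _step_rnap(self):
        rng = self.rng
        p = self.p
        # loading at active promoters
        for gi, (start, end, prom, direction) in enumerate(self.genes):
            if rng.random() < p["rnap_load"] and self.rnap_occ[prom] == 0:
                self.rnap.append([prom, direction, gi])
                self.rnap_occ[prom] += 1
        # translocation
        keep = []
        for mol in self.rnap:
            pos, direction, gi = mol
            start, end, prom, _d = self.genes[gi]
            if rng.random() < p["move_rnap"]:
                t = pos + direction
                past_end = (direction > 0 and t > end) or (direction < 0 and t < end)
                if past_end:
                    self.rnap_occ[pos] -= 1
                    continue  # termination
                if self.anchor_occ[t] > 0:
                    if rng.random() < p["cross_rp"]:
                        t2 = t + direction
                        past2 = (direction > 0 and t2 > end) or (
                            direction < 0 and t2 < end
                        )
                        if past2:
                            self.rnap_occ[pos] -= 1
                            continue
                        if self.anchor_occ[t2] == 0 and self.rnap_occ[t2] == 0:
                            self.rnap_occ[pos] -= 1
                            mol[0] = t2
                            self.rnap_occ[t2] += 1
                elif self.rnap_occ[t] == 0:
                    self.rnap_occ[pos] -= 1
                    mol[0] = t
                    self.rnap_occ[t] += 1
            keep.append(mol)
        self.rnap = keep

    def step(self):
        rng = self.rng
        p = self.p
        self._step_rnap()
        n = len(self.left)
        for c in range(n):
            if rng.random() < p["unload"]:
                self._unload(c)
                self._load(c)
        # competing anchor moves resolved in random order
        order = rng.permutation(2 * n)
        for k in order:
            c, side = divmod(int(k), 2)
            self._try_move_anchor(c, -1 if side == 0 else +1)
        if self.config.edge_unload:
            # an anchor reaching the window edge has extruded out of the
            # modeled region; the cohesin leaves and rebinds
            for c in range(n):
                if self.left[c] == 0 or self.right[c] == self.n_beads - 1:
                    self._unload(c)
                    self._load(c)
        self.time += self.dt_min

    def snapshot(self) -> CohesinEnsembleState:
        rn = np.array([m[0] for m in self.rnap], dtype=np.int64)
        rd = np.array([m[1] for m in self.rnap], dtype=np.int64)
        rg = np.array([m[2] for m in self.rnap], dtype=np.int64)
        return CohesinEnsembleState(
            left=self.left.copy(),
            right=self.right.copy(),
            stall_left=self.stall_left.copy(),
            stall_right=self.stall_right.copy(),
            generation=self.generation.copy(),
            rnap_pos=rn,
            rnap_dir=rd,
            rnap_gene=rg,
            time=self.time,
        )


def run(
    locus: LocusAnnotation,
    config: SimulationConfig,
    t_total: float,
    sample_every: float,
    burn_in: float = 0.0,
) -> Trajectory:
    """Simulate for ``t_total`` minutes and return post-burn-in samples taken
    every ``sample_every`` minutes (the state at burn-in itself included)."""
    if t_total <= burn_in:
        raise SimulationConfigError("t_total must exceed burn_in")
    eng = ExtrusionEngine(locus, config)
    n_steps = int(round(t_total * 60.0 / config.dt))
    steps_per_sample = max(1, int(round(sample_every * 60.0 / config.dt)))
    burn_steps = int(round(burn_in * 60.0 / config.dt))
    samples = []
    for s in range(n_steps + 1):
        if s >= burn_steps and (s - burn_steps) % steps_per_sample == 0:
            samples.append(eng.snapshot())
        if s < n_steps:
            eng.step()
    return Trajectory(
        locus=locus,
        config=config,
        samples=samples,
        unload_events=eng.unload_events,
        n_load_events=eng.n_load_events,
        n_unload_events=eng.n_unload_events,
    )


def cohesin_flow(trajectory_or_samples, locus: LocusAnnotation) -> FlowTrack:
    """Net signed anchor passages per minute at each inter-bead boundary.

    For each pair of consecutive samples and each cohesin whose residence
    epoch (generation) is unchanged, the net number of crossings of the
    boundary left of bead ``b`` is determined by the anchor's start and end
    positions alone; reload teleports are excluded.  Sense (rightward)
    passages count positive.
    """
    samples = (
        trajectory_or_samples.samples
        if isinstance(trajectory_or_samples, Trajectory)
        else list(trajectory_or_samples)
    )
    if len(samples) < 2:
        raise ValueError("cohesin flow needs at least two samples")
    counts = np.zeros(locus.n_beads)
    for s0, s1 in zip(samples, samples[1:]):
        same = s0.generation == s1.generation
        for anchors0, anchors1 in ((s0.left, s1.left), (s0.right, s1.right)):
            for c in np.flatnonzero(same):
                a, b = int(anchors0[c]), int(anchors1[c])
                if b > a:
                    counts[a + 1 : b + 1] += 1
                elif a > b:
                    counts[b + 1 : a + 1] -= 1
    minutes = samples[-1].time - samples[0].time
    if minutes <= 0:
        raise ValueError("samples span zero time")
    return FlowTrack(flow=counts / minutes)


def barrier_boundary_indices(locus: LocusAnnotation) -> list:
    """FlowTrack indices of the barrier-side boundary of each CTCF bead.

    A forward motif blocks leftward-moving anchors at the bead's left edge
    (flow index b); a reverse motif blocks rightward movers at its right
    edge (flow index b+1).  Flow at these boundaries reflects passage
    through the barrier, not arrival at it.
    """
    out = []
    for bead, orient in sorted(locus.ctcf_orientations.items()):
        if locus.bead_classes[bead] != CTCF:
            continue
        idx = bead if orient == FORWARD else bead + 1
        if 0 < idx < locus.n_beads:
            out.append(idx)
    return out


def write_trajectory_tsv(traj: Trajectory, path):
    with open(path, "w") as fh:
        fh.write("time_min\tcohesin\tleft\tright\tstall_left\tstall_right\tgeneration\n")
        for s in traj.samples:
            for c in range(len(s.left)):
                fh.write(
                    f"{s.time:.4f}\t{c}\t{s.left[c]}\t{s.right[c]}"
                    f"\t{STALL_NAMES[int(s.stall_left[c])]}"
                    f"\t{STALL_NAMES[int(s.stall_right[c])]}\t{s.generation[c]}\n"
                )
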