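"""End-to-end in-silico CTCF-depletion experiment.

Runs seed-matched control and CTCF-depleted simulations of the default
synthetic locus, extracts Tri-C-style matrices from an enhancer viewpoint
and a boundary-CBS viewpoint, MCC-style pairwise profiles from the enhancer
viewpoint, cohesin flow tracks and cohesin spatial cluster-size
distributions, and aggregates them into per-replicate summaries plus paired
condition comparisons.  This is the pipeline behind the ``deplete-compare``
command and the reproduction scripts.

Problem sizes default to a 2-Mb locus coarse-grained to 10-kb beads (200
beads), which keeps a full >= 20-replicate paired experiment comfortably
within a desktop run while preserving the locus architecture (three TADs,
convergent boundary CBSs, genes, enhancer clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import contacts, extrusion, hubs, polymer
from .locus import (
    CBS,
    ENHANCER,
    GenomicInterval,
    LocusAnnotation,
    LocusConfig,
    generate_locus,
)


def pad_interval(iv, pad_bp: int, region: GenomicInterval) -> GenomicInterval:
    """Expand an interval by pad_bp on each side, clipped to the region."""
    return GenomicInterval(
        iv.chrom,
        max(region.start, iv.start - pad_bp),
        min(region.end, iv.end + pad_bp),
    )


@dataclass
class ExperimentConfig:
    n_replicates: int = 20
    seed: int = 0
    locus_seed: int = 0  # the canonical synthetic locus is fixed across runs
    bead_size: int = 10_000
    t_total: float = 75.0  # min
    burn_in: float = 15.0  # min
    sample_every: float = 1.5  # min
    n_init_relax: int = 4_000
    n_relax_per_sample: int = 1_200
    bin_size: int = 4_000
    capture_radius: float = 2.5  # virtual crosslinking radius for reads
    cluster_radius: float = 1.5  # spatial cluster calling
    max_reporters: int = 6
    reads_per_conformation: int = 25
    profile_exclusion_bp: int = 1_000
    sim: extrusion.SimulationConfig = field(default_factory=extrusion.SimulationConfig)
    polymer_cfg: polymer.PolymerConfig = field(default_factory=polymer.PolymerConfig)
    locus_cfg: LocusConfig | None = None

    def make_locus(self) -> LocusAnnotation:
        cfg = self.locus_cfg or LocusConfig(
            bead_size=self.bead_size, seed=self.locus_seed
        )
        return generate_locus(cfg)


def select_viewpoints(locus: LocusAnnotation) -> dict:
    """Default viewpoints in the middle TAD: the distal enhancer (hub and
    pairwise viewpoint) and the left boundary CBS (C-hub viewpoint)."""
    mid_tad = locus.tads[len(locus.tads) // 2]
    enh = [iv for iv in locus.elements_of_class(ENHANCER) if mid_tad.overlaps(iv)]
    cbs = [iv for iv in locus.elements_of_class(CBS) if mid_tad.overlaps(iv)]
    if not enh or not cbs:
        raise ValueError("default locus lacks enhancer/CBS viewpoints")
    prom = [iv for iv in locus.elements_of_class("promoter") if mid_tad.overlaps(iv)][0]
    enh_vp = max(enh, key=lambda iv: abs(iv.midpoint - prom.midpoint))
    cbs_vp = min(cbs, key=lambda iv: iv.start)
    return {"enhancer_vp": (enh_vp, ENHANCER), "cbs_vp": (cbs_vp, CBS)}


@dataclass
class ReplicateResult:
    condition: str
    replicate: int
    cluster_frac_ge3: float
    mean_abs_flow_ctcf: float
    promoter_signal: float
    matrices: dict  # viewpoint_id -> ThreeWayMatrix
    reads: dict = None  # viewpoint_id -> list of MultiwayRead


def _simulate_replicate(
    locus: LocusAnnotation,
    fragment_map: contacts.FragmentMap,
    viewpoints: dict,
    cfg: ExperimentConfig,
    condition: str,
    replicate: int,
    cognate_promoter,
) -> ReplicateResult:
    sim_cfg = replace(
        cfg.sim,
        ctcf_present=(condition == "control"),
        seed=cfg.seed * 100_003 + replicate,
    )
    traj = extrusion.run(
        locus, sim_cfg, t_total=cfg.t_total, sample_every=cfg.sample_every,
        burn_in=cfg.burn_in,
    )

    # 3D conformations chained across extrusion samples
    pol_cfg = replace(cfg.polymer_cfg, capture_radius=cfg.cluster_radius)
    rng = np.random.default_rng(sim_cfg.seed + 1)
    coords = None
    conformations = []
    frac_ge3 = []
    for k, state in enumerate(traj.samples):
        n_steps = cfg.n_init_relax if k == 0 else cfg.n_relax_per_sample
        conf = polymer.relax_conformation(
            locus, state, n_steps=n_steps, config=pol_cfg, coords=coords,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        coords = conf.coordinates
        conformations.append(conf)
        dist = polymer.cohesin_clusters(conf, state, cfg.cluster_radius)
        frac_ge3.append(dist.fraction_at_least(3))

    # cohesin flow through the barrier-side boundaries of (former) CTCF beads
    flow = extrusion.cohesin_flow(traj, locus)
    barrier_idx = extrusion.barrier_boundary_indices(locus)
    mean_abs_flow = float(np.mean(np.abs(flow.flow[barrier_idx])))

    matrices = {}
    read_sets = {}
    for vp_id, (vp_iv, _cls) in viewpoints.items():
        reads = contacts.simulate_multiway_reads(
            conformations, vp_iv, fragment_map, locus,
            capture_radius=cfg.capture_radius, max_reporters=cfg.max_reporters,
            reads_per_conformation=cfg.reads_per_conformation,
            seed=sim_cfg.seed + 7,
        )
        read_sets[vp_id] = reads
        if vp_id != "ep_vp":  # the pairwise viewpoint needs no hub matrix
            matrices[vp_id] = contacts.build_threeway_matrix(
                reads, fragment_map, vp_iv, bin_size=cfg.bin_size,
                region=locus.region,
            )

    # pairwise profile from the cognate-enhancer viewpoint; signal at the
    # promoter region
    pairwise_id = "ep_vp" if "ep_vp" in viewpoints else "enhancer_vp"
    pw_iv, _ = viewpoints[pairwise_id]
    profile = contacts.build_pairwise_profile(
        read_sets[pairwise_id], fragment_map, pw_iv, locus.region, normalize=False
    )
    profile = contacts.mask_viewpoint_proximity(profile, cfg.profile_exclusion_bp)
    profile = contacts.normalize_profile(profile)
    prom_signal = profile.signal_at(cognate_promoter)

    return ReplicateResult(
        condition=condition,
        replicate=replicate,
        cluster_frac_ge3=float(np.mean(frac_ge3)),
        mean_abs_flow_ctcf=mean_abs_flow,
        promoter_signal=prom_signal,
        matrices=matrices,
        reads=read_sets,
    )


@dataclass
class DepletionResult:
    summary: pd.DataFrame  # per replicate x condition
    hub_scores: pd.DataFrame  # tidy (viewpoint, category, condition, replicate, value)
    hub_tests: pd.DataFrame  # one-sided paired Wilcoxon depleted < control
    promoter_signal: dict  # condition -> pooled-signal mean over replicates
    locus: LocusAnnotation = None
    viewpoints: dict = None

    def category_values(self, category: str, condition: str) -> pd.Series:
        s = self.hub_scores
        sel = s[(s.category == category) & (s.condition == condition)]
        return sel.set_index("replicate")["value"]


def run_depletion_experiment(cfg: ExperimentConfig | None = None) -> DepletionResult:
    """Paired control-vs-CTCF-depleted simulation of the default locus."""
    cfg = cfg or ExperimentConfig()
    locus = cfg.make_locus()
    # the digest belongs to the locus, not to the replicate draw
    fragment_map = contacts.synthetic_fragment_map(
        locus.region, seed=cfg.locus_seed + 13
    )
    viewpoints = select_viewpoints(locus)
    mid_tad = locus.tads[len(locus.tads) // 2]
    prom_iv = [
        iv for iv in locus.elements_of_class("promoter") if mid_tad.overlaps(iv)
    ][0]
    # promoter-region signal: the promoter bead plus one bead each side --
    # at coarse bead sizes the interaction peak spans the neighborhood
    cognate_promoter = pad_interval(prom_iv, locus.bead_size, locus.region)

    rows = []
    matrices = {}
    pooled_reads = {"control": [], "depleted": []}
    for replicate in range(cfg.n_replicates):
        for condition in ("control", "depleted"):
            res = _simulate_replicate(
                locus, fragment_map, viewpoints, cfg, condition, replicate,
                cognate_promoter,
            )
            rows.append(
                {
                    "condition": condition,
                    "replicate": replicate,
                    "cluster_frac_ge3": res.cluster_frac_ge3,
                    "mean_abs_flow_ctcf": res.mean_abs_flow_ctcf,
                    "promoter_signal": res.promoter_signal,
                }
            )
            pooled_reads[condition].extend(res.reads["enhancer_vp"])
            for vp_id, m in res.matrices.items():
                matrices[(condition, replicate, vp_id)] = m

    summary = pd.DataFrame(rows)
    scores = hubs.hub_scores(matrices, locus.elements, viewpoints)
    tests = hubs.compare_conditions(
        scores, "depleted", "control", alternative="less"
    )
    # pooled (condition-level) promoter signal: one profile per condition
    enh_iv, _ = viewpoints["enhancer_vp"]
    prom = {}
    for cond, rds in pooled_reads.items():
        profile = contacts.build_pairwise_profile(
            rds, fragment_map, enh_iv, locus.region, normalize=False
        )
        profile = contacts.mask_viewpoint_proximity(profile, cfg.profile_exclusion_bp)
        profile = contacts.normalize_profile(profile)
        prom[cond] = float(profile.signal_at(cognate_promoter))
    return DepletionResult(
        summary=summary,
        hub_scores=scores,
        hub_tests=tests,
        promoter_signal=prom,
        locus=locus,
        viewpoints=viewpoints,
    )
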