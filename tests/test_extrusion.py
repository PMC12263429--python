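"""1D extrusion dynamics: loop growth, barriers, crossing, flow bookkeeping."""

import numpy as np
import pytest

from chromhub.extrusion import (
    STALL_CTCF,
    CohesinEnsembleState,
    ExtrusionEngine,
    SimulationConfig,
    SimulationConfigError,
    Trajectory,
    barrier_boundary_indices,
    cohesin_flow,
    run,
)
from chromhub.locus import (
    CBS,
    FORWARD,
    REVERSE,
    GenomicInterval,
    LocusAnnotation,
    LocusConfig,
    generate_locus,
)


def neutral_locus(n_beads=1000, bead_size=2000):
    region = GenomicInterval("c", 0, n_beads * bead_size)
    return LocusAnnotation(
        region=region, bead_size=bead_size, elements=[], tads=[], genes=[],
        ctcf_orientations={},
    )


def ctcf_pair_locus(n_beads=100, left=30, right=70, bead_size=2000):
    """Convergent CTCF pair: forward at `left`, reverse at `right`."""
    region = GenomicInterval("c", 0, n_beads * bead_size)
    els = [
        (GenomicInterval("c", left * bead_size, (left + 1) * bead_size), CBS),
        (GenomicInterval("c", right * bead_size, (right + 1) * bead_size), CBS),
    ]
    return LocusAnnotation(
        region=region, bead_size=bead_size, elements=els, tads=[], genes=[],
        ctcf_orientations={left: FORWARD, right: REVERSE},
    )


class TestConfig:
    def test_dt_violating_probability_bound_rejected(self):
        loc = neutral_locus(100)
        with pytest.raises(SimulationConfigError):
            SimulationConfig(dt=1.0).validate(loc)  # crossing prob 0.78 at dt=1

    def test_negative_rate_rejected(self):
        with pytest.raises(SimulationConfigError):
            SimulationConfig(k_unload=-1.0).validate(neutral_locus(100))

    def test_default_density_one_per_200kb(self):
        loc = neutral_locus(1000)  # 2 Mb
        assert SimulationConfig().resolved_n_cohesin(loc) == 10

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=3, v_cohesin=25.0, ctcf_present=False)
        cfg.to_yaml(tmp_path / "sim.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "sim.yaml") == cfg


class TestLoopGrowth:
    def test_barrier_free_mean_loop_size_is_2vt(self):
        """Analytic oracle: each anchor advances v*t, so the loop spans 2*v*t."""
        loc = neutral_locus(1000)
        sizes = []
        for rep in range(50):
            cfg = SimulationConfig(
                n_cohesin=1, k_unload=0.0, v_cohesin=20.0, seed=rep,
                initial_load_bead=500,
            )
            traj = run(loc, cfg, t_total=5.0, sample_every=5.0)
            s = traj.samples[-1]
            sizes.append((s.right[0] - s.left[0]) * loc.bead_size / 1000.0)
        assert np.mean(sizes) == pytest.approx(200.0, rel=0.05)

    def test_unloading_loop_size_mean_is_2v_over_k(self):
        """Exponential residence: mean loop size at unloading = 2 v / k_unload."""
        loc = neutral_locus(1000)
        cfg = SimulationConfig(
            n_cohesin=10, k_unload=0.5, v_cohesin=20.0, seed=3, dt=0.1,
            edge_unload=False,
        )
        traj = run(loc, cfg, t_total=120.0, sample_every=120.0)
        sizes = np.array([s for _t, s in traj.unload_events]) * loc.bead_size / 1000.0
        assert len(sizes) >= 500
        assert sizes.mean() == pytest.approx(2 * 20.0 / 0.5, rel=0.1)


class TestBarriers:
    def test_convergent_pair_absorbs_single_cohesin(self):
        """With no release, anchors end exactly on the convergent CTCF beads."""
        loc = ctcf_pair_locus()
        for rep in range(20):
            cfg = SimulationConfig(
                n_cohesin=1, k_unload=0.0, k_ctcf_release=0.0, seed=rep,
                initial_load_bead=50,
            )
            traj = run(loc, cfg, t_total=30.0, sample_every=30.0)
            s = traj.samples[-1]
            assert (int(s.left[0]), int(s.right[0])) == (30, 70)
            assert s.stall_left[0] == STALL_CTCF
            assert s.stall_right[0] == STALL_CTCF

    def test_ctcf_transparent_when_depleted(self):
        loc = ctcf_pair_locus()
        cfg = SimulationConfig(
            n_cohesin=1, k_unload=0.0, k_ctcf_release=0.0, ctcf_present=False,
            seed=1, initial_load_bead=50, edge_unload=False,
        )
        traj = run(loc, cfg, t_total=60.0, sample_every=60.0)
        s = traj.samples[-1]
        assert int(s.left[0]) == 0 and int(s.right[0]) == loc.n_beads - 1

    def test_depleted_stall_fraction_matches_relabeled_neutral_locus(self):
        """With ctcf_present=False, former CTCF beads behave like neutral ones."""
        loc = ctcf_pair_locus()
        neutral = neutral_locus(100)

        def stalled_frac(locus, ctcf_present):
            cfg = SimulationConfig(
                n_cohesin=4, seed=5, ctcf_present=ctcf_present, initial_load_bead=None
            )
            traj = run(locus, cfg, t_total=40.0, sample_every=1.0)
            hits = total = 0
            for s in traj.samples:
                for c in range(4):
                    total += 2
                    hits += int(s.left[c]) in (30, 70) and s.stall_left[c] != 0
                    hits += int(s.right[c]) in (30, 70) and s.stall_right[c] != 0
            return hits / total

        depleted = stalled_frac(loc, ctcf_present=False)
        background = stalled_frac(neutral, ctcf_present=True)
        assert depleted == pytest.approx(background, abs=0.02)

    def test_inner_anchors_never_cross_with_crossing_off(self):
        loc = neutral_locus(200)
        cfg = SimulationConfig(n_cohesin=2, k_cross_cc=0.0, k_unload=0.0, seed=9,
                               edge_unload=False)
        eng = ExtrusionEngine(loc, cfg)
        # force adjacent loading
        for c, b in enumerate((100, 101)):
            eng.anchor_occ[eng.left[c]] -= 1
            eng.anchor_occ[eng.right[c]] -= 1
            eng.left[c] = eng.right[c] = b
            eng.anchor_occ[b] += 2
        for _ in range(6000):
            eng.step()
            assert eng.right[0] < eng.left[1] or eng.right[0] <= 101


class TestConservationAndState:
    def test_bound_count_changes_only_via_load_unload(self):
        loc = generate_locus(LocusConfig(seed=4, bead_size=10_000))
        cfg = SimulationConfig(seed=2)
        traj = run(loc, cfg, t_total=30.0, sample_every=5.0)
        n = cfg.resolved_n_cohesin(loc)
        for s in traj.samples:
            assert len(s.left) == n
        assert traj.n_load_events == n + traj.n_unload_events

    def test_anchors_stay_inside_and_ordered(self):
        loc = generate_locus(LocusConfig(seed=4, bead_size=10_000))
        traj = run(loc, SimulationConfig(seed=7), t_total=30.0, sample_every=1.0)
        for s in traj.samples:
            assert np.all(s.left <= s.right)
            assert np.all(s.left >= 0) and np.all(s.right < loc.n_beads)

    def test_same_seed_identical_trajectories(self):
        loc = generate_locus(LocusConfig(seed=4, bead_size=10_000))
        t1 = run(loc, SimulationConfig(seed=11), t_total=10.0, sample_every=1.0)
        t2 = run(loc, SimulationConfig(seed=11), t_total=10.0, sample_every=1.0)
        for a, b in zip(t1.samples, t2.samples):
            assert np.array_equal(a.left, b.left)
            assert np.array_equal(a.right, b.right)
            assert np.array_equal(a.rnap_pos, b.rnap_pos)

    def test_zero_cohesins_give_empty_samples(self):
        loc = neutral_locus(100)
        traj = run(loc, SimulationConfig(n_cohesin=0, seed=0), t_total=5.0,
                   sample_every=1.0)
        assert all(len(s.left) == 0 for s in traj.samples)


def _state(left, right, generation, time):
    n = len(left)
    z = np.zeros(n, dtype=np.int64)
    e = np.array([], dtype=np.int64)
    return CohesinEnsembleState(
        left=np.array(left), right=np.array(right), stall_left=z.copy(),
        stall_right=z.copy(), generation=np.array(generation),
        rnap_pos=e, rnap_dir=e.copy(), rnap_gene=e.copy(), time=time,
    )


class TestFlow:
    def test_single_crossing_gives_tenth_per_minute(self):
        loc = neutral_locus(100)
        b = 40
        samples = [_state([10], [b - 1], [0], 0.0), _state([10], [b], [0], 10.0)]
        flow = cohesin_flow(samples, loc)
        assert flow.flow[b] == pytest.approx(0.1)
        assert flow.flow[: b].sum() == 0 and flow.flow[b + 1 :].sum() == 0

    def test_single_sample_raises(self):
        loc = neutral_locus(100)
        with pytest.raises(ValueError):
            cohesin_flow([_state([1], [2], [0], 0.0)], loc)

    def test_reload_teleports_are_excluded(self):
        loc = neutral_locus(100)
        samples = [_state([10], [20], [0], 0.0), _state([70], [80], [1], 10.0)]
        flow = cohesin_flow(samples, loc)
        assert np.all(flow.flow == 0)

    def test_flow_sums_telescope_to_displacement(self):
        """Bookkeeping identity: summed signed passages equal net anchor moves."""
        loc = generate_locus(LocusConfig(seed=4, bead_size=10_000))
        traj = run(loc, SimulationConfig(seed=13), t_total=30.0, sample_every=2.0)
        flow = cohesin_flow(traj, loc)
        minutes = traj.samples[-1].time - traj.samples[0].time
        expected = 0.0
        for s0, s1 in zip(traj.samples, traj.samples[1:]):
            same = s0.generation == s1.generation
            expected += (s1.left[same] - s0.left[same]).sum()
            expected += (s1.right[same] - s0.right[same]).sum()
        assert flow.flow.sum() * minutes == pytest.approx(expected)

    def test_mirror_symmetric_locus_has_antisymmetric_mean_flow(self):
        """Ensemble-mean flow is antisymmetric about the locus center."""
        loc = ctcf_pair_locus(n_beads=60, left=15, right=44)
        asym = []
        for rep in range(100):
            cfg = SimulationConfig(n_cohesin=2, seed=rep, dt=0.2, k_cross_rp=0.0,
                                   k_cross_cc=0.0, k_machinery_release=0.0)
            traj = run(loc, cfg, t_total=20.0, sample_every=2.0)
            f = cohesin_flow(traj, loc).flow
            mirrored = -f[::-1]  # boundary b maps to boundary n-b; sense flips
            asym.append(np.mean(f[1:] + mirrored[:-1]))
        asym = np.array(asym)
        se = asym.std(ddof=1) / np.sqrt(len(asym))
        assert abs(asym.mean()) < 4 * max(se, 1e-12)

    def test_depletion_increases_flow_through_barrier_boundaries(self):
        loc = ctcf_pair_locus(n_beads=100, left=30, right=70)
        idx = barrier_boundary_indices(loc)
        assert idx == [30, 71]
        ctrl, depl = [], []
        for rep in range(15):
            for flag, out in ((True, ctrl), (False, depl)):
                cfg = SimulationConfig(n_cohesin=5, seed=rep, ctcf_present=flag)
                traj = run(loc, cfg, t_total=40.0, sample_every=2.0)
                f = cohesin_flow(traj, loc).flow
                out.append(np.abs(f[idx]).mean())
        assert np.mean(depl) > np.mean(ctrl)


class TestRNAPII:
    def test_rnapii_translocates_gene_bodies(self):
        loc = generate_locus(LocusConfig(seed=4, bead_size=10_000))
        traj = run(loc, SimulationConfig(seed=1, n_cohesin=0), t_total=40.0,
                   sample_every=1.0)
        positions = np.concatenate([s.rnap_pos for s in traj.samples])
        assert positions.size > 0
        genic_or_promoter = {
            b
            for g in loc.genes
            for b in loc.beads_of_interval(g.interval)
        } | {loc.bead_of(iv.midpoint) for iv in loc.elements_of_class("promoter")}
        assert set(positions.tolist()) <= genic_or_promoter
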