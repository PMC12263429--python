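"""3D conformations of the bead chain and cohesin spatial clustering.

The chromatin fiber is a bead-spring chain relaxed by overdamped Langevin
dynamics in an implicit solvent: harmonic backbone springs, a purely
repulsive (WCA) excluded-volume potential, harmonic bonds between the two
anchors of every extruding cohesin, and a short-range attraction between
machinery-engaged beads (promoters, enhancers, RNAPII-occupied beads) that
mimics condensate-forming affinity among transcription-machinery components.

All lengths are in bead diameters, energies in kT, mobility 1; the WCA sigma
is chosen so that the repulsion cutoff equals the backbone rest length
(consecutive beads at rest feel no net force).

A fast surrogate (``loop_graph_distances``) replaces 3D sampling by shortest
path distances on the backbone-plus-loop-shortcut graph, with contact
probability p = min(1, d_eff^(-3/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .locus import LocusAnnotation


class IntegrationError(RuntimeError):
    """Langevin integration produced non-finite coordinates."""


@dataclass
class PolymerConfig:
    k_backbone: float = 10.0  # kT / diameter^2
    k_loop: float = 10.0
    rest_length: float = 1.0  # diameters
    repulsion: bool = True
    eps_repulsion: float = 1.0  # kT
    machinery_eps: float = 4.5  # kT, attraction between machinery-engaged beads
    machinery_cutoff: float = 2.5  # diameters
    temperature: float = 1.0  # kT
    dt: float = 0.02  # tau (k_backbone * dt must stay well below 1)
    capture_radius: float = 1.5  # diameters; spatial-contact definition
    n_relax_steps: int = 5_000
    seed: int = 0

    excluded_volume_factor: float = 0.8  # WCA cutoff as a fraction of rest_length

    @property
    def sigma(self) -> float:
        # WCA minimum (= cutoff) at 2^(1/6) sigma == factor * rest_length, so
        # consecutive beads at rest feel no repulsion and bonds stay near rest
        return self.excluded_volume_factor * self.rest_length / 2 ** (1 / 6)


@dataclass
class Conformation:
    coordinates: np.ndarray  # (n_beads, 3), bead diameters
    loop_bonds: list  # (left_anchor, right_anchor)
    affinity_pairs: np.ndarray = None  # machinery bead indices (engaged set)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates[i] - self.coordinates[j]))


@njit(cache=True)
def _langevin(coords, bond_i, bond_j, bond_k, bond_r0, is_mach, repulsion,
              eps_rep, sigma, mach_eps, mach_cut, kT, dt, n_steps, seed):
    np.random.seed(seed)
    n = coords.shape[0]
    nb = bond_i.shape[0]
    forces = np.zeros((n, 3))
    sig2 = sigma * sigma
    rc2_rep = 2.0 ** (1.0 / 3.0) * sig2  # (2^(1/6) sigma)^2
    mach_cut2 = mach_cut * mach_cut
    amp = np.sqrt(2.0 * kT * dt)
    f_cap = 0.3 / dt  # per-pair force cap: displacement <= 0.3 diam per step
    for _ in range(n_steps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        for b in range(nb):
            i = bond_i[b]
            j = bond_j[b]
            dx = coords[j, 0] - coords[i, 0]
            dy = coords[j, 1] - coords[i, 1]
            dz = coords[j, 2] - coords[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-9:
                f = bond_k[b] * (r - bond_r0[b]) / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz
        if repulsion:
            for i in range(n - 1):
                for j in range(i + 1, n):
                    dx = coords[j, 0] - coords[i, 0]
                    dy = coords[j, 1] - coords[i, 1]
                    dz = coords[j, 2] - coords[i, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    both_mach = is_mach[i] and is_mach[j]
                    cut2 = mach_cut2 if both_mach else rc2_rep
                    if r2 >= cut2 or r2 < 1e-6:
                        continue
                    eps = mach_eps if both_mach else eps_rep
                    sr2 = sig2 / r2
                    sr6 = sr2 * sr2 * sr2
                    # f/r; positive = repulsive (pushes apart)
                    fr = 24.0 * eps * sr6 * (2.0 * sr6 - 1.0) / r2
                    fmag = abs(fr) * np.sqrt(r2)
                    if fmag > f_cap:  # soft-core: cap overlap kicks
                        fr *= f_cap / fmag
                    forces[i, 0] -= fr * dx
                    forces[i, 1] -= fr * dy
                    forces[i, 2] -= fr * dz
                    forces[j, 0] += fr * dx
                    forces[j, 1] += fr * dy
                    forces[j, 2] += fr * dz
        for i in range(n):
            coords[i, 0] += forces[i, 0] * dt + amp * np.random.normal()
            coords[i, 1] += forces[i, 1] * dt + amp * np.random.normal()
            coords[i, 2] += forces[i, 2] * dt + amp * np.random.normal()
    return coords


def _engaged_beads(locus: LocusAnnotation, state) -> np.ndarray:
    """Machinery-engaged beads: machinery-binding beads plus RNAPII positions."""
    mask = locus.bead_classes == "machinery_binding"
    engaged = mask.copy()
    if state is not None and len(state.rnap_pos):
        engaged[state.rnap_pos] = True
    return engaged


def initial_conformation(n_beads: int, rng, step: float = 1.0) -> np.ndarray:
    """Random-walk initial chain with unit step length."""
    steps = rng.normal(size=(n_beads, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.cumsum(steps * step, axis=0)
    return coords - coords.mean(axis=0)


def relax_conformation(
    locus: LocusAnnotation,
    state,
    n_steps: int | None = None,
    config: PolymerConfig | None = None,
    coords: np.ndarray | None = None,
    seed: int | None = None,
) -> Conformation:
    """Relax the chain by overdamped Langevin dynamics.

    ``state`` may be None (no loop bonds, no RNAPII).  Passing ``coords``
    continues from a previous conformation, which is how consecutive
    extrusion samples are chained into a quasi-continuous 3D trajectory.
    """
    cfg = config or PolymerConfig()
    n_steps = cfg.n_relax_steps if n_steps is None else n_steps
    seed = cfg.seed if seed is None else seed
    n = locus.n_beads
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = initial_conformation(n, rng, step=cfg.rest_length)
    coords = np.ascontiguousarray(np.array(coords, dtype=np.float64))

    loops = state.loop_bonds() if state is not None else []
    bi = list(range(n - 1)) + [l for l, _ in loops]
    bj = list(range(1, n)) + [r for _, r in loops]
    bk = [cfg.k_backbone] * (n - 1) + [cfg.k_loop] * len(loops)
    br = [cfg.rest_length] * (n - 1) + [cfg.rest_length] * len(loops)
    engaged = _engaged_beads(locus, state)

    coords = _langevin(
        coords,
        np.array(bi, dtype=np.int64),
        np.array(bj, dtype=np.int64),
        np.array(bk, dtype=np.float64),
        np.array(br, dtype=np.float64),
        engaged,
        cfg.repulsion,
        cfg.eps_repulsion,
        cfg.sigma,
        cfg.machinery_eps,
        cfg.machinery_cutoff,
        cfg.temperature,
        cfg.dt,
        int(n_steps),
        int(rng.integers(0, 2**31 - 1)),
    )
    if not np.all(np.isfinite(coords)):
        bad = int(np.flatnonzero(~np.isfinite(coords).all(axis=1))[0])
        raise IntegrationError(
            f"non-finite coordinates (first bad bead {bad}); reduce dt or spring constants"
        )
    return Conformation(
        coordinates=coords, loop_bonds=loops, affinity_pairs=np.flatnonzero(engaged)
    )


# ---------------------------------------------------------------------------
# loop-graph fast mode
# ---------------------------------------------------------------------------


@dataclass
class LoopGraph:
    n_beads: int
    loop_bonds: list
    d_eff: np.ndarray  # (n, n) shortest-path distances

    def contact_probability(self) -> np.ndarray:
        """p(i,j) = min(1, d_eff^(-3/2)); p = 1 on the diagonal."""
        with np.errstate(divide="ignore"):
            p = np.minimum(1.0, np.power(np.maximum(self.d_eff, 1e-12), -1.5))
        np.fill_diagonal(p, 1.0)
        return p


def loop_graph_distances(locus: LocusAnnotation, state) -> LoopGraph:
    """Effective distances on the backbone graph with loop-anchor shortcuts.

    Backbone edges (i, i+1) and one unit-weight shortcut per extruded loop;
    d_eff is the all-pairs shortest-path (breadth-first) distance.
    """
    n = locus.n_beads
    loops = state.loop_bonds() if state is not None else []
    ii = list(range(n - 1)) + [l for l, _ in loops]
    jj = list(range(1, n)) + [r for _, r in loops]
    data = np.ones(len(ii))
    g = coo_matrix((data, (ii, jj)), shape=(n, n))
    d = shortest_path(g, method="D", directed=False, unweighted=True)
    return LoopGraph(n_beads=n, loop_bonds=loops, d_eff=d)


# ---------------------------------------------------------------------------
# cohesin clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterSizeDistribution:
    """Fraction of all cohesin molecules residing in clusters of each size."""

    fractions: dict  # size -> fraction of molecules

    def fraction_at_least(self, size: int) -> float:
        return sum(f for s, f in self.fractions.items() if s >= size)


def cohesin_clusters(
    conformation: Conformation, state, capture_radius: float = 1.5
) -> ClusterSizeDistribution:
    """Cluster cohesins by spatial proximity of their anchors.

    Two cohesin molecules are linked if any of their anchor beads lie within
    ``capture_radius`` (3D, bead diameters); clusters are the connected
    components, and the distribution is weighted by molecules.
    """
    n = len(state.left)
    if n == 0:
        raise ValueError("no cohesins bound")
    coords = conformation.coordinates
    anchors = np.stack([state.left, state.right])  # (2, n)
    r2 = capture_radius * capture_radius
    rows, cols = [], []
    for a in range(n - 1):
        for b in range(a + 1, n):
            linked = False
            for pa in (int(anchors[0, a]), int(anchors[1, a])):
                for pb in (int(anchors[0, b]), int(anchors[1, b])):
                    d = coords[pa] - coords[pb]
                    if float(d @ d) <= r2:
                        linked = True
                        break
                if linked:
                    break
            if linked:
                rows.append(a)
                cols.append(b)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    fractions = {}
    for s in np.unique(sizes[sizes > 0]):
        fractions[int(s)] = float(np.sum(sizes[sizes == s])) / n
    return ClusterSizeDistribution(fractions=fractions)


def write_xyz(conformations: list, path, comment: str = "chromhub"):
    """Write conformations as multi-frame XYZ text."""
    with open(path, "w") as fh:
        for frame, conf in enumerate(conformations):
            coords = conf.coordinates if isinstance(conf, Conformation) else conf
            fh.write(f"{len(coords)}\n{comment} frame {frame}\n")
            for x, y, z in coords:
                fh.write(f"C {x:.4f} {y:.4f} {z:.4f}\n")
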