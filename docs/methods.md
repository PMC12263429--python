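# Methods

## Scope and model overview

chromhub simulates the 1D dynamics of cohesin-mediated loop extrusion and
RNAPII transcription on an annotated chromatin fiber, samples 3D polymer
conformations consistent with the instantaneous extrusion state, converts
conformation ensembles into the two assay-shaped data types used in
viewpoint-based chromosome-conformation studies — base-pair-resolution
pairwise interaction profiles (Micro-Capture-C-like) and binned multi-way
contact matrices (Tri-C-like) — and quantifies higher-order "chromatin hub"
interactions between enhancers (E), promoters (P) and CTCF-binding sites
(CBS/C).  Its central in-silico experiment compares seed-matched control and
CTCF-depleted simulations of a synthetic 2-Mb locus.

## The bead lattice

A locus is a chain of equal-sized beads (default 2 kb of chromatin per
bead).  Each bead carries one of four classes with the precedence
`ctcf_bound > machinery_binding > genic > neutral` when annotation layers
overlap; the precedence mirrors the order used to annotate interaction peaks
(CBSs first, enhancers last among the remainder).  CTCF beads carry a motif
orientation.  Element classification follows the conventions of the
downstream quantification: a CBS within ±5 kb of a targeted promoter is a
promoter-proximal CBS (ppCBS, taking precedence over the boundary-CBS
label), and enhancers farther than 150 kb from their promoter are distal.

### The synthetic locus generator

`generate_locus` produces loci with the statistical structure the analysis
assumes, standing in for real differentiation-regulated gene loci:

* 2 Mb, three TADs, each delimited by convergent CTCF sites (forward motif
  at the left boundary, reverse at the right);
* one active ~60-kb gene per TAD with a one-bead promoter; the middle TAD
  hosts the "upregulated" gene of interest and its promoter carries a ppCBS
  (forward motif, one bead upstream);
* two enhancer clusters of two beads per TAD, one promoter-proximal and one
  distal; each cluster is flanked by a *convergent* pair of CTCF sites
  (forward left of the cluster, reverse right of it).  This emulates the
  CBS-dense architecture of loci in which hub formation is strongest:
  extruding cohesin locks on both sides of an enhancer cluster and holds
  the cluster at the base of a loop;
* one additional internal CBS per TAD at a random position with a random
  orientation.

Placement uses deterministic anchors plus small seeded jitter; all
randomness flows through one `numpy` generator seeded from a single
integer, and identical seeds give byte-identical annotations.  Element
counts per locus are free parameters: published annotations do not fix how
many enhancers or CBSs were modeled per locus, so the defaults above are
the package's own choice of a "realistic CBS-dense locus".

## 1D extrusion dynamics

Fixed-time-step kinetic Monte Carlo with `dt` = 0.1 s: a rate k becomes a
per-step probability 1 − exp(−k·dt), and a speed v a hop probability
v·dt/bead_size.  The configuration validator requires every per-step
probability to stay below 0.2; the published crossing rate of 1.5 s⁻¹
forces dt well below 1 s, which is why the default is 0.1 s.

Parameters (defaults in brackets):

* RNAPII speed `v_rnap` [2 kb/min; experimentally deduced range 1–5] and
  cohesin anchor speed `v_cohesin` [20 kb/min; range 15–30].  Each anchor
  translocates at `v_cohesin`, so a barrier-free loop grows at 2·v·t.
* RNAPII–cohesin and cohesin–cohesin crossing rates [1.5 s⁻¹ and
  0.15 s⁻¹].  Crossing is implemented symmetrically for both molecules.
* Unloading `k_unload` [0.05 min⁻¹ → mean residence 20 min, mean loop size
  at unloading 2·v/k = 800 kb] with instant rebinding; loading is biased
  `load_bias` [10×] toward machinery-binding beads (cohesin prefers loading
  at enhancers/promoters).  Cohesin density defaults to one complex per
  200 kb.  Neither density nor residence is fixed by published
  measurements at this locus scale; both are exposed in the configuration.
* CTCF stalling: an anchor that steps onto a CTCF bead whose motif faces it
  (forward motifs block leftward extrusion, reverse block rightward) locks
  there and passes only at `k_ctcf_release` [0.02 min⁻¹, i.e. ~50-min
  residence — CTCF stalls are long-lived].  In-silico depletion
  (`ctcf_present=False`) removes stalling only; CBS annotations are kept
  for scoring, mirroring acute protein depletion with elements intact.
* Machinery stalling: anchors cannot enter a machinery-binding bead; the
  stall releases at `k_machinery_release` [90 min⁻¹ = 1.5 s⁻¹, matching the
  RNAPII–cohesin crossing rate].  Stalls at enhancers/promoters are thus
  brief — far less stable than at CBSs — so cohesin accumulates strongly at
  CBSs and only weakly at active elements.
* Anchors that extrude past the edge of the modeled window unload and
  rebind (`edge_unload`, default on).  Without this, depleted simulations
  accumulate non-physical stacks of anchors at the window edges.  Analytic
  tests that need a closed system switch it off.

Competing moves within a step are resolved in a random order drawn from the
run's generator.  Simultaneous occupancy of one bead by two anchors is
forbidden except transiently during a crossing hop.

### Cohesin flow

`cohesin_flow` reports, for every inter-bead boundary, the net signed number
of anchor passages per minute (sense positive), computed from consecutive
trajectory samples: for a continuous path the net number of crossings of a
boundary depends only on the endpoint positions, so sampling loses nothing;
intervals in which a cohesin reloaded are excluded (a reload is a teleport,
not a passage).  For barrier-level summaries the package evaluates flow at
the *barrier-side* boundary of each CTCF bead — the left edge for forward
motifs, the right edge for reverse motifs — which measures passage through
the barrier rather than arrival at it.

## 3D conformations

Overdamped (first-order) Langevin dynamics in implicit solvent; only
conformational statistics are consumed, so inertial dynamics would add cost
without benefit.  Units: bead diameter 1, kT 1, mobility 1.

* Backbone springs and loop-anchor bonds: harmonic, k = 10 kT/d², rest
  length 1.  Each extruding cohesin contributes one anchor–anchor bond.
* Excluded volume: WCA (purely repulsive Lennard-Jones) with σ chosen so
  the cutoff is 0.8 bond lengths.  Keeping the repulsion cutoff below the
  rest length leaves bonds relaxed near their rest length and makes a
  straight rest-spaced chain an exact zero-temperature fixed point.
* Machinery affinity: machinery-engaged beads (promoter/enhancer beads and
  beads currently occupied by RNAPII) attract each other through a full
  Lennard-Jones well, depth 4.5 kT, cutoff 2.5 diameters, emulating
  condensate-forming affinity between transcription-machinery components.
  The well depth was chosen so that pairwise enhancer–promoter association
  is dominated by this CTCF-independent channel (see "Depletion
  experiment" below); at ≲3 kT the attraction is kinetically invisible at
  the sampling times used, at ≳5 kT runaway condensation makes depleted
  ensembles cluster more than control ones.
* Integration: Euler–Maruyama with dt = 0.02 τ (k·dt = 0.2) and a per-pair
  force cap limiting any single pair's displacement to 0.3 diameters per
  step.  The cap only activates for transient overlaps (soft-core
  behavior); divergence (non-finite coordinates) raises an error with the
  first offending bead.
* Consecutive extrusion samples are relaxed starting from the previous
  conformation (4,000 steps for the first sample, 1,200 between samples in
  the depletion pipeline), giving a quasi-continuous 3D trajectory whose
  loop bonds track the extrusion state.

Note the bond-length "invariant": with k = 10 kT/d² the equilibrium
consecutive-bead distance is ~1.3 ± 0.33 diameters (excluded-volume
crowding pushes the median above the rest length), and ~97 % of bonds lie
within [0.5, 2.0].  The range is therefore asserted statistically (bulk
fraction and median), not on the maximum; stiffer springs would tighten it
at the cost of the integration step size.

### Fast loop-graph mode

`loop_graph_distances` computes all-pairs shortest-path distances on the
graph of backbone edges plus unit-weight loop-anchor shortcuts and converts
them to a contact-probability surrogate p = min(1, d_eff^(−3/2)), the
ideal-chain return probability exponent.  On the default 200-bead locus the
ensemble-mean surrogate correlates with 3D contact frequencies at Spearman
ρ > 0.6 (tested); the mode exists for quick scans, not for the depletion
pipeline.

### Cohesin clusters

Two cohesins are linked when any of their anchor beads lie within the
capture radius (1.5 diameters) in 3D; clusters are connected components,
and the size distribution is weighted by molecules (fractions sum to 1).
Whether clustering should use anchors or whole molecules is not fixed by
any published definition; anchors are used because the anchor positions are
the physically bonded loci.

## Virtual capture experiments

* **Fragment maps.** NlaIII digests: cut after every CATG occurrence.
  Without a sequence, synthetic maps draw exponential fragment lengths with
  mean 256 bp (the 4-cutter expectation), flagged as synthetic mode.
* **Multi-way reads.** Per conformation, fragments whose beads lie within
  the capture radius of the viewpoint bead are candidate reporters; each
  read samples up to 6 of them without replacement, and several reads are
  drawn per conformation (25 in the pipeline) to emulate sequencing depth
  over a finite structural ensemble.  The viewpoint fragment and its
  immediate neighbors are excluded.  The *read capture radius* defaults to
  2.5 diameters in the pipeline — a crosslinking-scale radius, deliberately
  larger than the 1.5-diameter contact radius used for cluster calling,
  because proximity ligation captures a neighborhood, not only direct
  molecular contact.
* **Three-way matrices.** Reads with ≥2 cis reporters contribute *every*
  unordered reporter pair (including all combinations from reads with >3
  reporters).  Counts are binned (1,500–4,000 bp; the pipeline uses
  4,000), divided by the geometric mean of the two bins' restriction-
  fragment counts (the geometric mean keeps the correction symmetric),
  masked within ±2 bins of the viewpoint, and scaled to unit total within
  a 2-Mb window around the viewpoint.  The masking width for published
  matrices is not stated; ±2 bins is the package default and is exposed.
* **Pairwise profiles.** Every reporter fragment of every read adds one
  unit of per-bp coverage over its span; the profile is scaled so the sum
  over the viewpoint chromosome equals a fixed constant (100,000),
  making viewpoints with different capture efficiencies comparable.  The
  ±1-kb viewpoint-proximity mask is applied before normalization.

## Hub quantification

Triplet categories from the viewpoint's class and its two partners:
E–E–P (enhancer viewpoint; enhancer + promoter partners), E–C–X (enhancer
viewpoint; a CBS partner plus any other element — takes precedence over
E–E–P), C–C–C (CBS viewpoint; two CBS partners) and C–E/P (CBS viewpoint;
partners only enhancers/promoters).  A pair of regions is quantified as the
mean of the 3×3 neighborhood centered on their bins in the normalized
matrix (clipped at matrix edges; a masked center yields a flagged missing
value).  Elements spanning several bins are represented by their central
bin.

Triplet colocalization beyond pairwise expectation uses the phi-style
correlation

    corr(A, B) = (P_vp,A,B − P_vp,A·P_vp,B)
                 / sqrt(P_vp,A(1−P_vp,A)·P_vp,B(1−P_vp,B)),

which is 0 under independence and 1 under perfect coupling of
equal-probability events, is symmetric in A and B, and is bounded in
[−1, 1] for all probability triples satisfying the Fréchet bounds.

Condition comparisons use the paired two-sided (or one-sided where a
direction is pre-specified) Wilcoxon signed-rank test: zero differences
dropped, exact null distribution for n ≤ 25 without ties, normal
approximation with continuity correction otherwise.  The reported statistic
is the signed rank sum W⁺ − W⁻.  When more than a handful of tests are run
the tidy output also carries Benjamini–Hochberg adjusted p values next to
the raw ones.

## MCC-style peak quantification

* `top_fraction_mean`: mean of the ceil(0.7·n) largest per-bp coverage
  values over a peak (ties broken by stable sort; fraction 1.0 reduces to
  the arithmetic mean).
* `filter_peaks`: retain peaks inside ±2 Mb and outside ±1 kb of the
  viewpoint (midpoint distances).
* `annotate_peaks`: precedence CBS > promoter > enhancer > unassigned;
  the promoter rule requires both an ATAC overlap and an expressed-gene TSS
  within ±500 bp.
* Transient enhancers: flagged when any later Mediator time point exceeds
  1.5× the baseline signal.  The 1.5× factor operationalizes a criterion
  stated only qualitatively ("increased occupancy") and is a config
  constant.
* Total EP score: sum of enhancer-annotated peak signals per targeted
  promoter; differential analyses use log2 ratios with a pseudo-count of
  1 signal unit.
* Spearman correlations of differential signals: tie-corrected ranks, t
  approximation for n > 20, seeded Monte-Carlo permutation null (9,999
  permutations) for n ≤ 20.  The product of EP score and promoter
  accessibility is handled in log space (the log2 change of a product is
  the sum of the log2 changes).
* TAD pairing: promoter–enhancer pairs within one TAD whose mRNA/eRNA
  time-course Spearman correlation exceeds 0.4.
* A naive threshold peak caller is included for generating fixtures from
  synthetic coverage; it is not a substitute for model-based peak calling,
  which is out of scope.

## The depletion experiment

`run_depletion_experiment` runs seed-matched control and CTCF-depleted
replicates of the canonical locus (fixed generator seed; the locus plays
the role of "the studied gene locus", so it does not vary with the
replicate seed) at 10-kb beads (200 beads for 2 Mb — the coarse-graining
keeps a ≥20-replicate paired experiment at desktop scale).  75 simulated
minutes per replicate, 15 min burn-in, samples every 2 min (31
conformations per replicate).  Per replicate it records:

* the fraction of cohesin molecules in spatial clusters of size ≥3;
* mean |cohesin flow| through the barrier-side boundaries of (former)
  CTCF beads;
* Tri-C-style matrices from two viewpoints — the middle TAD's distal
  enhancer and its left-boundary CBS — scored into hub categories;
* the pairwise profile from the enhancer viewpoint; the enhancer–promoter
  signal at the cognate promoter is quantified on reads pooled across
  replicates per condition (one deeply sampled profile per condition).

The expected phenotype, which the acceptance suite tests, is: C–C–C and
E–C–X hub scores and the ≥3 cluster fraction drop after depletion, flow
through former CTCF sites rises severalfold, and the pairwise
enhancer–promoter signal changes only modestly — pairwise E–P contacts are
carried by the machinery-affinity channel, which depletion does not touch,
while the higher-order hub structure is carried by CTCF-anchored loop
stacking, which depletion removes.

## What the synthetic data do and do not show

The generator and simulator reproduce the *mechanistic architecture* —
oriented-CTCF stalling, biased loading, condensate-like machinery affinity,
assay-shaped read extraction and normalization — not any real locus's
sequence, element spacing, fragment map, or measured contact counts.
Passing tests demonstrate that the implementation realizes the intended
mechanisms and that the analysis pipeline detects their consequences; they
do not validate parameter values against real chromatin.  Real data
features deliberately absent: technical ligation artifacts and PCR
duplicates, mappability structure in fragment maps, cell-cycle and
replication effects, nucleosome-scale structure, and CTCF binding/unbinding
kinetics (depletion is all-or-none).

## Numerical choices and degenerate inputs

* All stochastic components accept one integer seed; derived seeds are
  drawn below 2³¹.  Fixed seeds give bit-identical trajectories,
  annotations and reads.
* Normalization of an all-zero profile, correlation of a constant vector,
  a Wilcoxon test with all-zero differences, and an empty multiway-read
  set all return flagged degenerate results or raise typed errors rather
  than silently producing numbers.
* Window-normalized matrix totals are exact to 1e-9; profile totals to
  float accumulation error (~1e-6 of the total).
* The 3×3 quantification at a matrix edge averages the existing cells.

## Known limitations

* The 1D engine is event-simple: no explicit CTCF exchange, no
  nucleosomes, no supercoiling, no replication; RNAPII does not push
  cohesin (they only cross or block).
* The 3D sampler is kinetically limited at the default budgets; condensate
  nucleation is stochastic across replicates, which is why condition
  comparisons are paired and replicate counts matter.  The pooled pairwise
  enhancer–promoter signal is the noisiest summary: contact episodes
  persist across consecutive samples, so a 20-replicate ensemble contains
  only tens of independent enhancer–promoter contact episodes per
  condition and the condition ratio carries roughly ±30 % sampling error.
  Its expectation is stable under depletion; single runs scatter around
  that.
* Hub scores from 200-bead loci with 4-kb bins are coarse: several bins
  fall inside one bead, so sub-bead structure is interpolation, not
  information.
* The loop-graph mode ignores excluded volume and affinity entirely; its
  contact surrogate is rank-faithful, not calibrated.
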