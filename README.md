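# chromhub

Loop-extrusion polymer simulation and multi-way chromatin-contact
quantification for studying enhancer–promoter hubs and their dependence on
CTCF.

## The problem

Tissue-specific gene loci organize into *chromatin hubs*: cooperative,
simultaneous spatial clusters of enhancers (E), promoters (P) and
CTCF-binding sites (CBS/C) on one allele.  Targeted multi-way
chromosome-conformation assays (Tri-C-style: reads with two or more cis
reporter fragments from a small viewpoint fragment) can detect these
three-way contacts, while base-pair-resolution pairwise assays
(Micro-Capture-C-style) quantify ordinary enhancer–promoter interactions.
A central mechanistic question is what acute CTCF depletion does to each
layer: hubs collapse, but pairwise enhancer–promoter contacts — and gene
expression — are largely maintained.

chromhub implements the computational arm of such a study end to end on
synthetic loci, with no external data dependencies:

1. **synthetic loci** (`chromhub.locus`) — 2-Mb bead lattices (2-kb beads
   by default) with convergent-CTCF TAD boundaries, active genes, clustered
   enhancers flanked by CTCF sites, and promoter-proximal CBSs (ppCBSs);
2. **1D extrusion dynamics** (`chromhub.extrusion`) — kinetic Monte Carlo
   of cohesin loop extrusion (anchor speed 15–30 kb/min) and RNAPII
   translocation (1–5 kb/min), with orientation-specific CTCF stalling,
   RNAPII–cohesin and cohesin–cohesin crossing at 1.5 and 0.15 s⁻¹, biased
   loading at E/P elements, and an in-silico CTCF-depletion switch;
3. **3D conformations** (`chromhub.polymer`) — overdamped Langevin
   bead-spring chains with loop-anchor bonds and condensate-like affinity
   between machinery-bound beads, plus a fast loop-graph surrogate and
   cohesin spatial-cluster statistics;
4. **virtual capture** (`chromhub.contacts`) — NlaIII fragment maps,
   multi-way read simulation, fragment-corrected window-normalized
   three-way matrices, chromosome-normalized pairwise profiles;
5. **hub quantification** (`chromhub.hubs`) — E–E–P / E–C–X / C–C–C /
   C–E/P triplet categories, 3×3 pair quantification, the triplet
   colocalization correlation
   `corr(A,B) = (P_vp,A,B − P_vp,A P_vp,B) / sqrt(P_vp,A(1−P_vp,A) P_vp,B(1−P_vp,B))`,
   and paired Wilcoxon condition tests;
6. **peak-level statistics** (`chromhub.mcc`) — top-70% coverage means,
   ±2 Mb / ±1 kb peak filtering, CBS > promoter > enhancer annotation
   precedence, transient-enhancer flags, total enhancer–promoter
   interaction scores, Spearman correlation of differential signals, and
   TAD-restricted promoter–enhancer pairing (ρ > 0.4).

The paired control-vs-depleted experiment is wired together in
`chromhub.experiment` and exposed on the command line as
`chromhub deplete-compare`.

## Worked example

```python
from chromhub.experiment import ExperimentConfig, run_depletion_experiment

res = run_depletion_experiment(ExperimentConfig(n_replicates=20, seed=0))

m = res.summary.groupby("condition")[["cluster_frac_ge3",
                                      "mean_abs_flow_ctcf"]].mean()
print(m.round(3))
print(res.hub_tests[["viewpoint", "category", "p_value"]])
print({k: round(v, 4) for k, v in res.promoter_signal.items()})
```

Output from this exact call:

```
           cluster_frac_ge3  mean_abs_flow_ctcf
condition
control               0.488               0.016
depleted              0.347               0.072
     viewpoint category   p_value
0       cbs_vp    C-C-C  0.000993
1       cbs_vp    C-E/P  0.310757
2  enhancer_vp    E-C-X  0.000002
3  enhancer_vp    E-E-P  0.943007
{'control': 0.0789, 'depleted': 0.0743}
```

Reading it: without CTCF, the fraction of cohesin molecules in spatial
clusters of three or more drops (0.49 → 0.35) and cohesin flows ~4× more
freely through former CTCF sites (net passages 0.016 → 0.072 per minute).
The hub categories that directly involve CBSs score much lower in the
depleted condition (one-sided paired Wilcoxon, depleted < control:
C–C–C p = 1e-3, E–C–X p = 2e-6), while the purely E/P categories are not
significantly reduced in this model — their contacts ride on the
CTCF-independent machinery affinity.  Consistently, the pairwise
enhancer–promoter signal at the cognate promoter barely moves
(0.0789 → 0.0743, a 6 % change): higher-order hubs are CTCF-dependent,
ordinary enhancer–promoter contacts are not.

The same pipeline from a shell:

```
chromhub deplete-compare --seed 0 --replicates 20 --out results/depletion
```

writes `summary.tsv`, `hub_scores.tsv`, `hub_tests.tsv`,
`promoter_signal.json` and a run manifest.  `chromhub make-locus` and
`chromhub simulate` expose the earlier pipeline stages (BED/bedGraph/XYZ
outputs); `chromhub correlate` computes Spearman correlations on
differential-signal tables.

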