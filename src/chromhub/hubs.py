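"""Quantification of multi-way (hub) interactions and condition comparisons.

Three-way interactions are categorized by the element classes of the
viewpoint and its two simultaneous partners:

* E-E-P:  enhancer viewpoint with an enhancer and a promoter partner;
* E-C-X:  enhancer viewpoint with a CBS and any other cis-regulatory
  element (takes precedence over E-E-P when both could apply);
* C-C-C:  CBS viewpoint with two CBS partners;
* C-E/P:  CBS viewpoint with partners drawn only from enhancers/promoters.

Pairs of regions are quantified as the mean of the 3x3 neighborhood centered
on their bins in the normalized three-way matrix.  Conditions (time points,
control vs CTCF-depleted) are compared with the paired two-sided Wilcoxon
signed-rank test, and triplet colocalization above pairwise expectation is
measured with the phi-style correlation

    corr(A, B) = (P_vp,A,B - P_vp,A P_vp,B)
                 / sqrt(P_vp,A (1 - P_vp,A) P_vp,B (1 - P_vp,B)).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ThreeWayMatrix
from .locus import CBS, ENHANCER, PROMOTER, GenomicInterval

CATEGORIES = ("E-E-P", "E-C-X", "C-C-C", "C-E/P")
_VALID_CLASSES = {ENHANCER, PROMOTER, CBS, "none"}


def classify_triplet(viewpoint_class: str, class_a: str, class_b: str) -> str | None:
    """Hub category of a (viewpoint, partner, partner) triplet, or None."""
    for c in (viewpoint_class, class_a, class_b):
        if c not in _VALID_CLASSES:
            raise ValueError(f"unknown element class {c!r}")
    partners = {class_a, class_b}
    multiset = sorted((class_a, class_b))
    if viewpoint_class == ENHANCER:
        if CBS in partners and partners <= {CBS, ENHANCER, PROMOTER}:
            return "E-C-X"  # precedence over E-E-P
        if multiset == [ENHANCER, PROMOTER]:
            return "E-E-P"
        return None
    if viewpoint_class == CBS:
        if multiset == [CBS, CBS]:
            return "C-C-C"
        if partners and partners <= {ENHANCER, PROMOTER}:
            return "C-E/P"
        return None
    return None


def quantify_pair(
    matrix: ThreeWayMatrix, region_a: GenomicInterval, region_b: GenomicInterval
) -> float:
    """Mean of the 3x3 cells centered on (bin(region_a), bin(region_b)).

    Returns NaN (flagged missing) when a center bin is masked.  At matrix
    edges the neighborhood is clipped to existing cells.
    """
    ia = matrix.bin_of(region_a.midpoint)
    ib = matrix.bin_of(region_b.midpoint)
    if matrix.masked_bins is not None and (
        matrix.masked_bins[ia] or matrix.masked_bins[ib]
    ):
        return math.nan
    n = matrix.n_bins
    sl_a = slice(max(0, ia - 1), min(n, ia + 2))
    sl_b = slice(max(0, ib - 1), min(n, ib + 2))
    return float(matrix.counts[sl_a, sl_b].mean())


@dataclass(frozen=True)
class TripletProbabilities:
    """Contact probabilities of a viewpoint with two regions A and B."""

    p_vp_a: float
    p_vp_b: float
    p_vp_ab: float  # probability of simultaneous viewpoint-A and viewpoint-B

    def __post_init__(self):
        pa, pb, pab = self.p_vp_a, self.p_vp_b, self.p_vp_ab
        if not (0 <= pa <= 1 and 0 <= pb <= 1 and 0 <= pab <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if pab > min(pa, pb) + 1e-12 or pab < max(0.0, pa + pb - 1.0) - 1e-12:
            raise ValueError("p_vp_ab violates the Frechet bounds")


def triplet_correlation(p: TripletProbabilities) -> float:
    """Triplet colocalization beyond the pairwise expectation, in [-1, 1].

    Zero under independence; 1 under perfect coupling of equal-probability
    events.  Undefined (raises) for boundary marginals 0 or 1.
    """
    pa, pb, pab = p.p_vp_a, p.p_vp_b, p.p_vp_ab
    if not (0 < pa < 1 and 0 < pb < 1):
        raise ValueError("triplet correlation undefined for boundary probabilities")
    return (pab - pa * pb) / math.sqrt(pa * (1 - pa) * pb * (1 - pb))


def triplet_probabilities_from_conformations(
    conformations, vp_bead: int, bead_a: int, bead_b: int, capture_radius: float = 1.5
) -> TripletProbabilities:
    """Estimate P(vp-A), P(vp-B) and P(vp-A and vp-B) from an ensemble."""
    r2 = capture_radius * capture_radius
    hits_a = hits_b = hits_ab = 0
    n = 0
    for conf in conformations:
        coords = conf.coordinates if hasattr(conf, "coordinates") else conf
        da = np.sum((coords[vp_bead] - coords[bead_a]) ** 2) <= r2
        db = np.sum((coords[vp_bead] - coords[bead_b]) ** 2) <= r2
        hits_a += da
        hits_b += db
        hits_ab += da and db
        n += 1
    if n == 0:
        raise ValueError("no conformations")
    return TripletProbabilities(hits_a / n, hits_b / n, hits_ab / n)


# ---------------------------------------------------------------------------
# hub scores
# ---------------------------------------------------------------------------


def hub_scores(
    matrices: dict,
    elements: list,
    viewpoints: dict,
    min_separation_bp: int = 0,
) -> pd.DataFrame:
    """Score every eligible triplet in every matrix and aggregate by category.

    Parameters
    ----------
    matrices : {(condition, replicate, viewpoint_id): ThreeWayMatrix}
    elements : [(GenomicInterval, element class)]
    viewpoints : {viewpoint_id: (GenomicInterval, element class)}

    Returns a tidy frame (viewpoint, category, condition, replicate, value,
    n_triplets) where value is the mean 3x3-quantified signal over the
    category's triplets (NaN-masked triplets dropped).
    """
    bin_sizes = {m.bin_size for m in matrices.values()}
    if len(bin_sizes) > 1:
        raise ValueError(f"inconsistent bin sizes across conditions: {bin_sizes}")
    rows = []
    for (condition, replicate, vp_id), matrix in matrices.items():
        vp_iv, vp_class = viewpoints[vp_id]
        in_window = [
            (iv, cls)
            for iv, cls in elements
            if matrix.bin_start
            <= iv.midpoint
            < matrix.bin_start + matrix.n_bins * matrix.bin_size
            and not iv.overlaps(vp_iv)
            and abs(iv.midpoint - vp_iv.midpoint) >= min_separation_bp
        ]
        per_cat = {c: [] for c in CATEGORIES}
        for (iv_a, cls_a), (iv_b, cls_b) in itertools.combinations(in_window, 2):
            cat = classify_triplet(vp_class, cls_a, cls_b)
            if cat is None:
                continue
            v = quantify_pair(matrix, iv_a, iv_b)
            if not math.isnan(v):
                per_cat[cat].append(v)
        for cat, values in per_cat.items():
            if values:
                rows.append(
                    {
                        "viewpoint": vp_id,
                        "category": cat,
                        "condition": condition,
                        "replicate": replicate,
                        "value": float(np.mean(values)),
                        "n_triplets": len(values),
                    }
                )
    return pd.DataFrame(
        rows, columns=["viewpoint", "category", "condition", "replicate", "value", "n_triplets"]
    )


# ---------------------------------------------------------------------------
# paired testing
# ---------------------------------------------------------------------------


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def paired_wilcoxon(
    values_a, values_b, alternative: str = "two-sided"
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (zero differences dropped).

    Uses the exact null distribution for n <= 25 and the normal
    approximation with continuity correction above.  All-zero differences
    give a degenerate-flagged result rather than a p value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return WilcoxonResult(math.nan, math.nan, 0, degenerate=True)
    if nz.size < 5:
        raise ValueError("need >= 5 nonzero differences")
    method = "exact" if (nz.size <= 25 and len(np.unique(np.abs(nz))) == nz.size) else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"),
        alternative=alternative, method=method,
    )
    # signed-rank statistic W+ - W- (negates under swapping the samples)
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    w_minus = float(ranks[nz < 0].sum())
    return WilcoxonResult(w_plus - w_minus, float(res.pvalue), int(nz.size))


def adjust_pvalues_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(ranked)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_conditions(
    scores: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-(viewpoint, category) paired Wilcoxon between two conditions,
    pairing replicates; emits raw and BH-adjusted p values."""
    rows = []
    for (vp, cat), grp in scores.groupby(["viewpoint", "category"]):
        pa = grp[grp.condition == condition_a].set_index("replicate")["value"]
        pb = grp[grp.condition == condition_b].set_index("replicate")["value"]
        common = pa.index.intersection(pb.index)
        if len(common) < 5:
            continue
        try:
            res = paired_wilcoxon(pa[common], pb[common], alternative=alternative)
        except ValueError:  # too few nonzero differences to test
            res = WilcoxonResult(np.nan, np.nan, 0, degenerate=True)
        rows.append(
            {
                "viewpoint": vp,
                "category": cat,
                "n_pairs": res.n,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
                "median_a": float(pa[common].median()),
                "median_b": float(pb[common].median()),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        valid = ~out["degenerate"]
        out["p_adjusted"] = np.nan
        if valid.any():
            out.loc[valid, "p_adjusted"] = adjust_pvalues_bh(out.loc[valid, "p_value"])
    return out
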