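"""Downstream quantification of pairwise (MCC-style) interaction profiles.

Implements the peak-level statistics used on base-pair-resolution capture
profiles: the top-70% coverage statistic, viewpoint-centred peak filtering
(inside +/-2 Mb, outside +/-1 kb), peak annotation with the precedence
CBS > promoter > enhancer, transient-enhancer flagging, total
enhancer-promoter interaction scores per targeted promoter, Spearman
correlation of differential signals, and TAD-restricted promoter-enhancer
pairing by mRNA/eRNA co-expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .locus import GenomicInterval

PEAK_WINDOW = 2_000_000  # +/-2 Mb retention window around the viewpoint
PEAK_EXCLUSION = 1_000  # +/-1 kb proximity exclusion
TSS_WINDOW = 500  # promoter rule: ATAC peak within +/-500 bp of an expressed TSS
TAD_PAIRING_RHO = 0.4  # mRNA/eRNA Spearman threshold for same-TAD pairing
TRANSIENT_FOLD = 1.5  # "increased Mediator occupancy": later signal > 1.5x baseline
PSEUDOCOUNT = 1.0  # added before log2 ratios


@dataclass
class PeakCall:
    interval: GenomicInterval
    annotation: str = "unassigned"  # cbs | promoter | enhancer | transient_enhancer
    signal: float = 0.0  # top-70% mean coverage
    viewpoint: str = ""


def top_fraction_mean(values, fraction: float = 0.7) -> float:
    """Mean of the ceil(fraction * n) largest per-position coverage values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty coverage values")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * v.size)
    top = np.sort(v, kind="stable")[::-1][:k]
    return float(top.mean())


def filter_peaks(peaks: list, viewpoint: GenomicInterval) -> list:
    """Retain peaks inside +/-2 Mb and outside +/-1 kb of the viewpoint
    (midpoint distances)."""
    vp = viewpoint.midpoint
    out = []
    for p in peaks:
        iv = p.interval if isinstance(p, PeakCall) else p
        d = abs(iv.midpoint - vp)
        if PEAK_EXCLUSION < d <= PEAK_WINDOW:
            out.append(p)
    return out


def _overlaps_any(iv: GenomicInterval, others: list) -> bool:
    return any(iv.overlaps(o) for o in others)


def annotate_peaks(
    peaks: list,
    ctcf_peaks: list,
    atac_peaks: list,
    expressed_tss: list,
    h3k27ac_peaks: list,
) -> list:
    """Annotate peaks with precedence cbs > promoter > enhancer > unassigned.

    CBS: overlap with a CTCF peak.  Promoter: overlap with an ATAC peak AND
    within +/-500 bp of an expressed-gene TSS.  Enhancer: among remaining
    peaks, overlap with an H3K27ac peak.
    """
    tss_mids = [t.midpoint for t in expressed_tss]
    out = []
    for p in peaks:
        iv = p.interval if isinstance(p, PeakCall) else p
        if isinstance(p, PeakCall):
            peak = PeakCall(iv, p.annotation, p.signal, p.viewpoint)
        else:
            peak = PeakCall(iv)
        if _overlaps_any(iv, ctcf_peaks):
            peak.annotation = "cbs"
        elif _overlaps_any(iv, atac_peaks) and tss_mids and (
            min(abs(iv.midpoint - m) for m in tss_mids) <= TSS_WINDOW
        ):
            peak.annotation = "promoter"
        elif _overlaps_any(iv, h3k27ac_peaks):
            peak.annotation = "enhancer"
        else:
            peak.annotation = "unassigned"
        out.append(peak)
    return out


def flag_transient_enhancers(
    enhancer_peaks: list, mediator_timecourse: dict, fold: float = TRANSIENT_FOLD
) -> dict:
    """Flag enhancers (of downregulated-gene loci) whose Mediator occupancy
    increases over the time course: any later time point > fold x baseline.

    ``mediator_timecourse`` maps peak key -> sequence of signals ordered in
    time (baseline first, >= 2 points).
    """
    flags = {}
    for peak in enhancer_peaks:
        key = peak if not isinstance(peak, PeakCall) else peak.interval
        series = np.asarray(mediator_timecourse[key], dtype=float)
        if series.size < 2:
            raise ValueError("need >= 2 time points of Mediator signal")
        flags[key] = bool(np.any(series[1:] > fold * series[0]))
        if isinstance(peak, PeakCall) and flags[key] and peak.annotation == "enhancer":
            peak.annotation = "transient_enhancer"
    return flags


def peak_signals(profile_coverage: np.ndarray, region_start: int, peaks: list,
                 fraction: float = 0.7) -> list:
    """Fill each peak's signal with the top-fraction mean over its span."""
    for p in peaks:
        a = p.interval.start - region_start
        b = p.interval.end - region_start
        p.signal = top_fraction_mean(profile_coverage[max(0, a):max(0, b)], fraction)
    return peaks


def total_ep_score(enhancer_peaks: list) -> float:
    """Total enhancer-promoter interaction score for a targeted promoter:
    the sum of enhancer-annotated peak signals in its interaction profile."""
    enh = [
        p
        for p in enhancer_peaks
        if p.annotation in ("enhancer", "transient_enhancer")
    ]
    if not enh:
        warnings.warn("no enhancer peaks; total EP score is 0", stacklevel=2)
        return 0.0
    return float(sum(p.signal for p in enh))


# ---------------------------------------------------------------------------
# differential signals and correlation analyses
# ---------------------------------------------------------------------------


def log2_change(later, baseline, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """log2 fold change with a pseudo-count guarding zero signals."""
    later = np.asarray(later, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    return np.log2((later + pseudocount) / (baseline + pseudocount))


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def differential_correlation(x, y, seed: int = 0) -> CorrelationResult:
    """Spearman rank correlation between paired differential signals.

    Tie-corrected ranks; p value from the t approximation for n > 20 and
    from a seeded Monte-Carlo permutation null for n <= 20.  Constant input
    is flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, math.nan, n, degenerate=True)
    rho = float(stats.spearmanr(x, y).statistic)
    if n > 20:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(9999)
        for i in range(null.size):
            null[i] = stats.spearmanr(x, rng.permutation(y)).statistic
        p = float((1 + np.sum(np.abs(null) >= abs(rho) - 1e-12)) / (1 + null.size))
    return CorrelationResult(rho, p, n)


def expression_prediction_score(
    delta_expression, delta_total_ep, delta_accessibility, seed: int = 0
) -> tuple:
    """Correlate expression changes with EP-score changes alone and with the
    change of the product (EP score x promoter accessibility).

    All deltas are log2 changes, so the product's change is the sum of the
    two log2 changes.  Returns (rho_ep_only, rho_product) results.
    """
    d_expr = np.asarray(delta_expression, dtype=float)
    d_ep = np.asarray(delta_total_ep, dtype=float)
    d_acc = np.asarray(delta_accessibility, dtype=float)
    if not (d_expr.shape == d_ep.shape == d_acc.shape):
        raise ValueError("gene lists must be matched")
    r_ep = differential_correlation(d_ep, d_expr, seed=seed)
    r_prod = differential_correlation(d_ep + d_acc, d_expr, seed=seed)
    return r_ep, r_prod


def pair_by_tad(
    promoters: list,
    enhancers: list,
    tads: list,
    mrna_counts: dict,
    erna_counts: dict,
    rho_threshold: float = TAD_PAIRING_RHO,
) -> pd.DataFrame:
    """Pair promoters and enhancers within the same TAD whose mRNA/eRNA
    time-course Spearman correlation exceeds the threshold (0.4)."""
    rows = []
    for prom in promoters:
        mrna = np.asarray(mrna_counts[prom], dtype=float)
        if mrna.size < 3:
            raise ValueError("need counts over >= 3 time points")
        prom_tads = [t for t in tads if t.overlaps(prom)]
        for enh in enhancers:
            if not any(t.overlaps(enh) for t in prom_tads):
                continue
            erna = np.asarray(erna_counts[enh], dtype=float)
            rho = float(stats.spearmanr(mrna, erna).statistic)
            if rho > rho_threshold:
                rows.append(
                    {
                        "promoter": f"{prom.chrom}:{prom.start}-{prom.end}",
                        "enhancer": f"{enh.chrom}:{enh.start}-{enh.end}",
                        "rho": rho,
                        "distance": abs(prom.midpoint - enh.midpoint),
                    }
                )
    return pd.DataFrame(rows, columns=["promoter", "enhancer", "rho", "distance"])


def call_peaks_threshold(
    coverage: np.ndarray,
    region: GenomicInterval,
    threshold: float,
    min_width: int = 100,
) -> list:
    """Naive threshold-based peak caller for synthetic fixtures.

    Contiguous runs of coverage above ``threshold`` at least ``min_width``
    wide become peaks.  This is a convenience for generated data and is not
    equivalent to a model-based caller (MACS2-style calling is out of
    scope).
    """
    above = np.asarray(coverage) > threshold
    peaks = []
    start = None
    for i, flag in enumerate(list(above) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_width:
                peaks.append(
                    PeakCall(
                        GenomicInterval(
                            region.chrom, region.start + start, region.start + i
                        )
                    )
                )
            start = None
    return peaks


def write_peaks_bed(peaks: list, path):
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.annotation}\t{p.signal:.6g}\t.\n"
            )
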