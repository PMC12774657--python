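"""CpG methylation versus transcription-factor occupancy.

Covers the peak-level methylation workflow: coverage filtering (>10x per
site), per-peak mean methylation with unmethylated (<10%) / methylated
(>90%) classes, binned methylation-vs-peak-score regression, and the
rank-based two-group comparison (Mann-Whitney / Wilcoxon rank-sum), exact
under ties for small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_validation import ScoredRegionSet
from .io_formats import GenomicInterval, MethylationCall

__all__ = ["PeakMethylation", "filter_coverage", "merge_cpg_strands",
           "peak_methylation", "methylation_score_regression",
           "compare_groups", "methylation_class_peak_score"]

UNMETHYLATED_BELOW = 10.0   # % threshold for the unmethylated (CpG) class
METHYLATED_ABOVE = 90.0     # % threshold for the methylated (mCpG) class


@dataclass
class PeakMethylation:
    interval: GenomicInterval
    n_sites: int
    mean_percent: float       # NaN when n_sites == 0
    meth_class: str           # unmethylated | intermediate | methylated | no_data


def classify_percent(mean_percent: float) -> str:
    if np.isnan(mean_percent):
        return "no_data"
    if mean_percent < UNMETHYLATED_BELOW:
        return "unmethylated"
    if mean_percent > METHYLATED_ABOVE:
        return "methylated"
    return "intermediate"


def filter_coverage(calls: Sequence[MethylationCall],
                    min_cov: int = 11) -> list[MethylationCall]:
    """Keep sites with coverage >= min_cov (default 11, i.e. strictly >10x)."""
    return [c for c in calls if c.coverage >= min_cov]


def merge_cpg_strands(calls: Sequence[MethylationCall]) -> list[MethylationCall]:
    """Merge opposite-strand calls of one CpG dinucleotide (counts summed).

    A minus-strand CpG call at position p reports the cytosine opposite the
    plus-strand C at p-1; merged calls are reported on the plus strand at
    the dinucleotide's C position. Non-CpG contexts pass through unchanged.
    """
    merged: dict[tuple, list[int]] = {}
    passthrough: list[MethylationCall] = []
    for c in calls:
        if c.context != "CpG":
            passthrough.append(c)
            continue
        pos = c.position if c.strand == "+" else c.position - 1
        key = (c.chrom, pos)
        entry = merged.setdefault(key, [0, 0])
        entry[0] += c.n_methylated
        entry[1] += c.n_unmethylated
    out = [MethylationCall(chrom, pos, "+", "CpG", m, u)
           for (chrom, pos), (m, u) in sorted(merged.items())]
    return out + passthrough


def peak_methylation(peaks: Sequence[GenomicInterval],
                     calls: Sequence[MethylationCall],
                     merge_strands: bool = True,
                     coverage_weighted: bool = False) -> list[PeakMethylation]:
    """Per-peak mean of site methylation percentages with class labels.

    Sites must already be coverage-filtered. The peak mean is unweighted
    across sites by default (coverage_weighted switches to a
    coverage-weighted mean). Peaks without sites get class no_data.
    """
    if merge_strands:
        calls = merge_cpg_strands(calls)
    trees: dict[str, IntervalTree] = {}
    for j, c in enumerate(calls):
        if c.coverage == 0:
            continue
        # data carries the call index: duplicate sites stay distinct in the
        # tree (identical Interval triples would otherwise collapse)
        trees.setdefault(c.chrom, IntervalTree())[c.position:c.position + 1] = (j, c)
    out: list[PeakMethylation] = []
    for peak in peaks:
        hits = trees.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end)
        sites = [h.data[1] for h in hits]
        if not sites:
            out.append(PeakMethylation(peak, 0, float("nan"), "no_data"))
            continue
        pct = np.array([s.percent for s in sites], dtype=float)
        if coverage_weighted:
            w = np.array([s.coverage for s in sites], dtype=float)
            mean = float(np.average(pct, weights=w))
        else:
            mean = float(pct.mean())
        out.append(PeakMethylation(peak, len(sites), mean, classify_percent(mean)))
    return out


@dataclass
class MethylationRegression:
    slope: float
    stderr: float
    pvalue: float
    bins: pd.DataFrame


def _scores_for(peak_meth: Sequence[PeakMethylation], scored) -> np.ndarray:
    """Align a score vector / ScoredRegionSet 1:1 with peak_meth."""
    if isinstance(scored, ScoredRegionSet):
        if len(scored) != len(peak_meth):
            raise ValueError("scored set and peak methylation differ in length")
        for pm, iv in zip(peak_meth, scored.intervals):
            if (pm.interval.chrom, pm.interval.start, pm.interval.end) != \
                    (iv.chrom, iv.start, iv.end):
                raise ValueError("scored intervals do not match peaks 1:1")
        return scored.scores
    arr = np.asarray(scored, dtype=float)
    if arr.size != len(peak_meth):
        raise ValueError("score vector and peaks differ in length")
    return arr


def methylation_score_regression(peak_meth: Sequence[PeakMethylation],
                                 scored, n_bins: int = 10) -> MethylationRegression:
    """OLS of mean peak score on binned % methylation (0-100, equal width).

    The sign of the slope is the headline statistic: methylation-attenuated
    occupancy gives a negative slope. Fewer than 3 non-empty bins is an
    error.
    """
    scores = _scores_for(peak_meth, scored)
    pct = np.array([pm.mean_percent for pm in peak_meth])
    mask = np.isfinite(pct) & np.isfinite(scores)
    if mask.sum() < 3:
        raise ValueError("need at least 3 peaks with methylation and scores")
    pct, scores = pct[mask], scores[mask]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, pct, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.sum() == 0:
            continue
        rows.append({"bin": b, "midpoint": (edges[b] + edges[b + 1]) / 2,
                     "mean_score": float(scores[sel].mean()), "n": int(sel.sum())})
    bins = pd.DataFrame(rows)
    if len(bins) < 3:
        raise ValueError(f"only {len(bins)} non-empty methylation bins; need >= 3")
    fit = stats.linregress(bins["midpoint"], bins["mean_score"])
    return MethylationRegression(slope=float(fit.slope), stderr=float(fit.stderr),
                                 pvalue=float(fit.pvalue), bins=bins)


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def _exact_u_distribution(ranks: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Permutation distribution of 2*U over group-label assignments.

    Convolution over the pooled (average, tie-aware) ranks; ranks are
    half-integers so 2*rank is integral. Returns (support of 2U, counts).
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    max_w2 = int(np.sort(r2)[-n1:].sum())
    # dp[c, w2] = number of ways to pick c items with doubled rank-sum w2
    dp = np.zeros((n1 + 1, max_w2 + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        new = dp.copy()
        new[1:, r:] += dp[:-1, :max_w2 + 1 - r]
        dp = new
    counts = dp[n1]
    offset = n1 * (n1 + 1)  # 2 * n1(n1+1)/2
    support_2u = np.arange(max_w2 + 1) - offset
    keep = counts > 0
    return support_2u[keep], counts[keep]


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   exact_limit: int = 10_000) -> tuple[float, float]:
    """Mann-Whitney U (ties count half) with a two-sided p-value.

    Exact permutation p (tie-aware rank-sum convolution) when
    n1*n2 <= exact_limit, otherwise the tie-corrected normal approximation.
    Two-sided p is P(|U - n1 n2/2| >= |u - n1 n2 / 2|).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 * n2 <= exact_limit:
        support_2u, counts = _exact_u_distribution(ranks, n1)
        total = counts.sum()
        dev = np.abs(support_2u - n1 * n2)          # |2U - n1 n2|
        obs_dev = abs(2 * u - n1 * n2)
        p = float(counts[dev >= obs_dev - 1e-9].sum() / total)
    else:
        tie_counts = np.unique(ranks, return_counts=True)[1]
        n = n1 + n2
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var == 0:
            return u, 1.0
        z = (abs(u - n1 * n2 / 2) - 0.5) / np.sqrt(var)
        p = float(2 * stats.norm.sf(max(z, 0.0)))
    return u, min(p, 1.0)


@dataclass
class ClassScoreComparison:
    class_means: dict[str, float]   # class -> mean log10 score
    class_n: dict[str, int]
    u_statistic: Optional[float]
    pvalue: Optional[float]


def methylation_class_peak_score(peak_meth: Sequence[PeakMethylation],
                                 scored) -> ClassScoreComparison:
    """Mean log10 peak score per methylation class, extremes compared.

    Compares unmethylated (<10%) versus methylated (>90%) peaks with the
    rank-sum test; when either extreme class is empty the test is skipped
    with a warning.
    """
    scores = _scores_for(peak_meth, scored)
    groups: dict[str, list[float]] = {}
    for pm, s in zip(peak_meth, scores):
        if not np.isfinite(s) or s <= 0:
            continue
        groups.setdefault(pm.meth_class, []).append(np.log10(s))
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    ns = {k: len(v) for k, v in groups.items()}
    lo = groups.get("unmethylated", [])
    hi = groups.get("methylated", [])
    if not lo or not hi:
        warnings.warn("an extreme methylation class is empty; test skipped")
        return ClassScoreComparison(means, ns, None, None)
    u, p = compare_groups(lo, hi)
    return ClassScoreComparison(means, ns, u, p)
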