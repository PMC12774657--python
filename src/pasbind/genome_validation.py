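"""Score genomic intervals with an energy model and validate against peaks.

Implements the in-vivo validation statistics: AUROC of model scores for
peaks versus random regions, binned motif-score vs peak-intensity
regression (0-10 score bins), per-model regression coefficients for model
comparison, and peak-set intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .energy_model import EnergyModel, score_sequences, window_weight
from .io_formats import GenomicInterval

__all__ = ["ScoredRegionSet", "score_bed", "sample_random_regions", "auroc",
           "binned_score_regression", "model_peak_regression", "intersect_peaks"]


def get_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch a genome slice from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    if not isinstance(seq, str):  # pyfaidx FastaRecord slice
        seq = str(seq)
    return seq.upper()


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


@dataclass
class ScoredRegionSet:
    """Per-interval model scores (one score per interval, mode recorded)."""

    intervals: list[GenomicInterval]
    scores: np.ndarray
    model_id: str = ""
    aggregation: str = "max"
    best_sites: Optional[list] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.intervals) != self.scores.size:
            raise ValueError("one score per interval required")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([np.nan if iv.score is None else iv.score
                         for iv in self.intervals])

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [iv.chrom for iv in self.intervals],
            "start": [iv.start for iv in self.intervals],
            "end": [iv.end for iv in self.intervals],
            "intensity": self.intensities,
            "score": self.scores,
        })


def score_bed(model: EnergyModel, genome, intervals: Sequence[GenomicInterval],
              aggregation: str = "max", model_id: str = "") -> ScoredRegionSet:
    """Score each interval's extracted sequence on both strands.

    Windows overlapping N score nothing (an all-N interval gets -inf and is
    flagged by valid_mask). Missing chromosomes are reported together.
    """
    from .energy_model import _eps_ext, _flanked, _revcomp_codes_int, \
        _window_energy_matrix
    from ._seq import encode_many

    missing = sorted({iv.chrom for iv in intervals if iv.chrom not in genome})
    if missing:
        raise KeyError(f"chromosomes absent from genome: {missing}")
    scores = np.full(len(intervals), -np.inf)
    best_sites: list = [None] * len(intervals)
    # batch intervals of equal length for vectorised window scoring
    by_length: dict[int, list[int]] = {}
    seqs = []
    for j, iv in enumerate(intervals):
        seq = get_sequence(genome, iv.chrom, iv.start, iv.end)
        seqs.append(seq)
        by_length.setdefault(len(seq), []).append(j)
    eps = _eps_ext(model)
    for length, idxs in by_length.items():
        codes = encode_many([seqs[j] for j in idxs])
        codes_f = _flanked(codes, model)
        if codes_f.shape[1] < model.L:
            raise ValueError(f"interval of length {length} shorter than the "
                             f"footprint {model.L} even with flanks")
        codes_r = _revcomp_codes_int(codes_f)
        E = _window_energy_matrix(codes_f, codes_r, eps)
        a = -np.clip(E, None, 1e30)
        amax = a.max(axis=1)
        valid = amax > -1e29
        if aggregation == "max":
            vals = amax.copy()
        else:
            vals = np.full(len(idxs), -np.inf)
            if valid.any():
                vals[valid] = amax[valid] + np.log(
                    np.exp(a[valid] - amax[valid, None]).sum(axis=1))
        best_cols = np.argmin(E, axis=1)
        for row, j in enumerate(idxs):
            if not valid[row]:
                continue
            scores[j] = vals[row]
            col = int(best_cols[row])
            best_sites[j] = (col // 2 - len(model.left_flank),
                             "+" if col % 2 == 0 else "-")
    return ScoredRegionSet(list(intervals), scores, model_id=model_id,
                           aggregation=aggregation, best_sites=best_sites)


def sample_random_regions(genome, template: Sequence[GenomicInterval],
                          seed: int = 0, max_retries: int = 50,
                          match_gc: bool = False) -> list[GenomicInterval]:
    """Length-matched random regions, uniformly placed outside N gaps.

    One region per template interval (same length), placed uniformly over
    chromosomes weighted by length. Placements avoid N runs and overlap with
    already-placed regions for up to max_retries draws, then are accepted
    with a warning. match_gc additionally requires GC content within 10
    points of the template interval. Deterministic per seed.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    chroms = list(genome.keys())
    lengths = np.array([_chrom_length(genome, c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, IntervalTree] = {c: IntervalTree() for c in chroms}
    out: list[GenomicInterval] = []
    for t_idx, tmpl in enumerate(template):
        size = len(tmpl)
        want_gc = None
        if match_gc:
            seq_t = get_sequence(genome, tmpl.chrom, tmpl.start, tmpl.end)
            want_gc = (seq_t.count("G") + seq_t.count("C")) / max(len(seq_t), 1)
        chosen = None
        for attempt in range(max_retries + 1):
            c = chroms[rng.choice(len(chroms), p=weights)]
            limit = _chrom_length(genome, c) - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            seq = get_sequence(genome, c, start, start + size)
            if "N" in seq:
                continue
            if want_gc is not None:
                gc = (seq.count("G") + seq.count("C")) / size
                if abs(gc - want_gc) > 0.10:
                    continue
            if placed[c].overlap(start, start + size):
                chosen = (c, start)  # keep as fallback, try again for no overlap
                continue
            chosen = (c, start)
            break
        else:
            pass
        if chosen is None:
            raise RuntimeError("could not place a random region (genome too small?)")
        c, start = chosen
        if placed[c].overlap(start, start + size):
            warnings.warn("random region overlaps a previous placement")
        placed[c][start:start + size] = True
        out.append(GenomicInterval(c, start, start + size, name=f"rand{t_idx}"))
    return out


def auroc(pos_scores: Sequence[float], neg_scores: Sequence[float]):
    """Rank-based AUROC with Hanley-McNeil standard error.

    Ties count one half; the statistic equals Mann-Whitney U / (n1*n2).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score collections must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:pos.size].sum()
    n1, n2 = pos.size, neg.size
    u = r_pos - n1 * (n1 + 1) / 2
    auc = u / (n1 * n2)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n2 - 1) * (q2 - auc**2)) / (n1 * n2)
    return float(auc), float(np.sqrt(max(var, 0.0)))


def rescale_scores_0_10(scores: np.ndarray,
                        lo: Optional[float] = None,
                        hi: Optional[float] = None) -> tuple[np.ndarray, float, float]:
    """Min-max rescale finite scores to [0, 10]; returns (scaled, lo, hi)."""
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise ValueError("no finite scores to rescale")
    lo = float(finite.min()) if lo is None else lo
    hi = float(finite.max()) if hi is None else hi
    if hi <= lo:
        raise ValueError("degenerate score range")
    return 10.0 * (scores - lo) / (hi - lo), lo, hi


@dataclass
class BinnedRegression:
    slope: float
    stderr: float
    pvalue: float
    intercept: float
    bins: pd.DataFrame       # columns: bin, midpoint, mean_intensity, n
    score_range: tuple[float, float]


def binned_score_regression(scored: ScoredRegionSet, n_bins: int = 10,
                            score_range: Optional[tuple[float, float]] = None
                            ) -> BinnedRegression:
    """OLS of mean peak intensity on binned motif score (0-10 scale).

    Model scores are min-max rescaled to [0, 10] (range recorded for
    reproducibility; pass score_range to reuse a previous rescaling, e.g.
    one computed over peaks plus random regions), cut into integer-width
    bins, and mean intensity per bin is regressed on the bin midpoint.
    """
    mask = scored.valid_mask() & np.isfinite(scored.intensities)
    if mask.sum() < 3:
        raise ValueError("need at least 3 scored intervals with intensities")
    lo, hi = (None, None) if score_range is None else score_range
    scaled, lo, hi = rescale_scores_0_10(scored.scores[mask], lo, hi)
    intensity = scored.intensities[mask]
    bin_idx = np.clip(np.floor(scaled).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.sum() == 0:
            continue
        rows.append({"bin": b, "midpoint": b + 0.5,
                     "mean_intensity": float(intensity[sel].mean()),
                     "n": int(sel.sum())})
    bins = pd.DataFrame(rows)
    if len(bins) < 3:
        raise ValueError(f"only {len(bins)} non-empty score bins; need >= 3")
    fit = stats.linregress(bins["midpoint"], bins["mean_intensity"])
    return BinnedRegression(slope=float(fit.slope), stderr=float(fit.stderr),
                            pvalue=float(fit.pvalue), intercept=float(fit.intercept),
                            bins=bins, score_range=(lo, hi))


def model_peak_regression(scored_by_model: dict[str, ScoredRegionSet]) -> pd.DataFrame:
    """Per-model regression of peak intensity on standardised model score.

    All models must be scored on the same interval set (coefficients are
    comparable across models after score standardisation). Returns a frame
    with model, coefficient, stderr, pvalue, n.
    """
    keys = None
    for name, srs in scored_by_model.items():
        k = [(iv.chrom, iv.start, iv.end) for iv in srs.intervals]
        if keys is None:
            keys = k
        elif k != keys:
            raise ValueError("models were scored on different interval sets")
    rows = []
    for name, srs in scored_by_model.items():
        mask = srs.valid_mask() & np.isfinite(srs.intensities)
        if mask.sum() < 3:
            raise ValueError(f"model {name!r}: fewer than 3 usable intervals")
        x = srs.scores[mask]
        if x.std(ddof=1) == 0:
            raise ValueError(f"model {name!r}: constant scores")
        x = (x - x.mean()) / x.std(ddof=1)
        fit = stats.linregress(x, srs.intensities[mask])
        rows.append({"model": name, "coefficient": float(fit.slope),
                     "stderr": float(fit.stderr), "pvalue": float(fit.pvalue),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows)


@dataclass
class PeakIntersection:
    shared_a: list[GenomicInterval]
    unique_a: list[GenomicInterval]
    shared_b: list[GenomicInterval]
    unique_b: list[GenomicInterval]


def intersect_peaks(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval],
                    min_overlap: int = 1) -> PeakIntersection:
    """Partition two peak sets by >= min_overlap bp reciprocal overlap.

    Each interval lands in exactly one of shared/unique for its own set.
    """
    def build(items):
        trees: dict[str, IntervalTree] = {}
        for iv in items:
            trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = iv
        return trees

    def split(items, other_trees):
        shared, unique = [], []
        for iv in items:
            hits = other_trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
            ok = any(min(iv.end, h.end) - max(iv.start, h.begin) >= min_overlap
                     for h in hits)
            (shared if ok else unique).append(iv)
        return shared, unique

    trees_a, trees_b = build(a), build(b)
    shared_a, unique_a = split(a, trees_b)
    shared_b, unique_b = split(b, trees_a)
    return PeakIntersection(shared_a, unique_a, shared_b, unique_b)
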