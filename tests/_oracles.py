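"""Independent brute-force oracles used by unit and acceptance tests.

Every function here recomputes a quantity by direct enumeration, without
touching the implementation paths it is used to check.
"""

from collections import Counter
from itertools import combinations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def kmer_counts_bruteforce(reads, k: int) -> Counter:
    """Sliding-window k-mer counts by string slicing (N reads excluded)."""
    counts: Counter = Counter()
    for read in reads:
        if "N" in read:
            continue
        for i in range(len(read) - k + 1):
            counts[read[i:i + k]] += 1
    return counts


def window_weight_bruteforce(eps: np.ndarray, seq: str,
                             left: str = "", right: str = ""):
    """Exhaustive per-window weight sum over both strands.

    Returns (W, max_log_weight). eps is the (4, L) energy matrix.
    """
    L = eps.shape[1]
    full = left + seq + right
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    weights = []
    for s in (full, revcomp(full)):
        for o in range(len(s) - L + 1):
            win = s[o:o + L]
            if "N" in win:
                continue
            e = sum(eps[base_idx[b], i] for i, b in enumerate(win))
            weights.append(-e)
    if not weights:
        return 0.0, -np.inf
    return float(np.sum(np.exp(weights))), float(max(weights))


def auroc_bruteforce(pos, neg) -> float:
    """All-pairs comparison; ties count one half."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def intersect_bruteforce(a, b, min_overlap: int = 1):
    """O(n*m) shared/unique partition of interval lists."""
    def overlaps(x, y):
        return (x.chrom == y.chrom and
                min(x.end, y.end) - max(x.start, y.start) >= min_overlap)

    shared_a = [x for x in a if any(overlaps(x, y) for y in b)]
    unique_a = [x for x in a if x not in shared_a]
    shared_b = [y for y in b if any(overlaps(y, x) for x in a)]
    unique_b = [y for y in b if y not in shared_b]
    return shared_a, unique_a, shared_b, unique_b


def peak_methylation_bruteforce(peaks, calls):
    """Quadratic interval join: per-peak unweighted mean site percentage."""
    out = []
    for peak in peaks:
        pcts = [100.0 * c.n_methylated / (c.n_methylated + c.n_unmethylated)
                for c in calls
                if c.chrom == peak.chrom and peak.start <= c.position < peak.end
                and (c.n_methylated + c.n_unmethylated) > 0]
        out.append((len(pcts), float(np.mean(pcts)) if pcts else float("nan")))
    return out


def mannwhitney_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    idx_all = range(len(pooled))

    def u_of(indices):
        grp = [pooled[i] for i in indices]
        rest = [pooled[i] for i in idx_all if i not in indices]
        u = 0.0
        for x in grp:
            for y in rest:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(n1)))
    n1n2 = n1 * (len(pooled) - n1)
    dev_obs = abs(u_obs - n1n2 / 2)
    total = hits = 0
    for comb in combinations(idx_all, n1):
        total += 1
        if abs(u_of(comb) - n1n2 / 2) >= dev_obs - 1e-9:
            hits += 1
    return u_obs, hits / total
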