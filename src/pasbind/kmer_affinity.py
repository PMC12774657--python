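"""Markov-background-corrected k-mer enrichment and relative affinities.

The relative affinity of a k-mer after r rounds of selection is its
enrichment over the unselected (round 0) library, E = observed/expected,
exponentiated by 1/r and rescaled so the best k-mer has affinity 1. The
expectation comes from a Markov model of the round-0 library, which absorbs
library composition bias (including a designed fixed core when the model
order can express it).

Core annotation follows the field's convention for E-box-like elements:
the 6-mer core NNCGTG is numbered c1..c6 and flanking positions are counted
outward as f-1, f-2, ... upstream and f+1, f+2, ... downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import (BASES, decode, encode, encode_many, index_to_kmer,
                   indices_to_kmers, iupac_code, revcomp_codes)
from .io_formats import SelexReadSet

__all__ = [
    "MarkovBackground", "PositionalBackground", "KmerAffinityTable",
    "KmerAnnotation", "fit_positional_background", "select_markov_order",
    "fit_markov_background", "expected_kmer_count", "count_kmers",
    "build_affinity_table", "annotate_kmer", "normalize_zscore",
    "derive_consensus", "compare_tables",
]

CORE = "CGTG"

# Fig 1B-style bHLH core taxonomy: 6-mer boxes checked in priority order
# after the NNCGTG search.
_BOX_CLASSES = [("CACCTG", "CACC-box"), ("CAGCTG", "CAG-box"), ("CATATG", "CAT-box")]


# ---------------------------------------------------------------------------
# Markov background
# ---------------------------------------------------------------------------

@dataclass
class MarkovBackground:
    """Markov model of the unselected library, estimated from round-0 reads.

    Stores m-mer occurrence counts for m = 1..order+1 over all read windows.
    The probability of a k-mer uses the effective order min(order, k-1), so
    the model is exact for k <= order+1 when smoothing is 0.
    """

    order: int
    smoothing: float
    mmer_counts: dict[int, np.ndarray]  # m -> counts over all 4^m m-mers
    read_length: int
    n_reads: int

    def _pair_table(self, o: int) -> tuple[np.ndarray, np.ndarray]:
        """(pi over 4^o contexts, T of shape (4^o, 4)), smoothed."""
        counts = self.mmer_counts[o + 1].reshape(4**o, 4).astype(float)
        s = self.smoothing
        ctx_tot = counts.sum(axis=1)
        T = (counts + s) / (ctx_tot + 4 * s)[:, None]
        pi = (ctx_tot + 4 * s) / (ctx_tot.sum() + s * 4 ** (o + 1))
        return pi, T

    @property
    def initial_distribution(self) -> pd.Series:
        pi, _ = self._pair_table(self.order)
        return pd.Series(pi, index=[index_to_kmer(i, self.order) for i in range(4**self.order)]
                         if self.order > 0 else [""])

    @property
    def transition_probabilities(self) -> pd.DataFrame:
        pi, T = self._pair_table(self.order)
        idx = ([index_to_kmer(i, self.order) for i in range(4**self.order)]
               if self.order > 0 else [""])
        return pd.DataFrame(T, index=idx, columns=list(BASES))

    def log_prob_codes(self, codes: np.ndarray) -> np.ndarray:
        """Log background probability of each row of a (n, k) code matrix."""
        codes = np.asarray(codes)
        if codes.ndim != 2:
            raise ValueError("expected a 2-D code matrix")
        k = codes.shape[1]
        o = min(self.order, k - 1)
        pi, T = self._pair_table(o)
        with np.errstate(divide="ignore"):
            log_pi, log_T = np.log(pi), np.log(T)
        pow4 = 4**o
        ctx = np.zeros(codes.shape[0], dtype=np.int64)
        for j in range(o):
            ctx = ctx * 4 + codes[:, j]
        logp = log_pi[ctx] if o > 0 else np.zeros(codes.shape[0])
        if o == 0:
            # order 0: every base independent from pi over single bases
            log_single = np.log(self._pair_table(0)[1][0])
            return log_single[codes].sum(axis=1)
        for j in range(o, k):
            b = codes[:, j]
            logp = logp + log_T[ctx, b]
            ctx = (ctx * 4 + b) % pow4
        return logp

    def log_prob(self, kmer: str) -> float:
        return float(self.log_prob_codes(encode(kmer)[None, :])[0])

    def expected_counts(self, kcodes: np.ndarray, n_reads: int,
                        read_length: int) -> np.ndarray:
        k = kcodes.shape[1]
        n_windows = n_reads * (read_length - k + 1)
        return n_windows * np.exp(self.log_prob_codes(kcodes))

    def sample_codes(self, n: int, length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n sequences of `length` from the chain (vectorised)."""
        o = min(self.order, length - 1) if length > 1 else 0
        pi, T = self._pair_table(o)
        out = np.empty((n, length), dtype=np.int8)
        if o == 0:
            p = self._pair_table(0)[1][0]
            cum = np.cumsum(p)
            u = rng.random((n, length))
            out[:] = np.searchsorted(cum, u).astype(np.int8)
            return np.clip(out, 0, 3)
        ctx = rng.choice(4**o, size=n, p=pi / pi.sum())
        for j in range(o):
            out[:, o - 1 - j] = (ctx // 4**j) % 4
        cumT = np.cumsum(T, axis=1)
        for j in range(o, length):
            u = rng.random(n)
            b = (u[:, None] > cumT[ctx]).sum(axis=1).astype(np.int8)
            b = np.clip(b, 0, 3)
            out[:, j] = b
            ctx = (ctx * 4) % 4**o + b
        return out


@dataclass
class PositionalBackground:
    """Position-specific independent-base model of the unselected library.

    The homogeneous Markov chain misrepresents libraries with positional
    structure (a designed fixed core): it either misses the core (low
    order) or develops register-mixing artefacts (high order). For such
    libraries the round-0 generative process is independent bases with
    per-position frequencies, which this model estimates exactly.
    Expected k-mer counts sum the per-offset window probabilities.
    """

    position_frequencies: np.ndarray  # (read_length, 4), rows sum to 1
    n_reads: int
    smoothing: float = 0.5

    @property
    def read_length(self) -> int:
        return self.position_frequencies.shape[0]

    def expected_counts(self, kcodes: np.ndarray, n_reads: int,
                        read_length: int) -> np.ndarray:
        if read_length != self.read_length:
            raise ValueError("read length differs from the fitted library")
        k = kcodes.shape[1]
        expected = np.zeros(kcodes.shape[0])
        for o in range(read_length - k + 1):
            p = np.ones(kcodes.shape[0])
            for i in range(k):
                p *= self.position_frequencies[o + i][kcodes[:, i]]
            expected += p
        return n_reads * expected

    def sample_codes(self, n: int, length: int,
                     rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, length), dtype=np.int8)
        for j in range(min(length, self.read_length)):
            out[:, j] = rng.choice(4, size=n, p=self.position_frequencies[j])
        for j in range(self.read_length, length):
            out[:, j] = rng.integers(0, 4, size=n)
        return out


def fit_positional_background(reads_round0: SelexReadSet,
                              smoothing: float = 0.5) -> PositionalBackground:
    """Per-position base frequencies from round-0 reads (add-`smoothing`)."""
    clean = [r for r in reads_round0.reads if "N" not in r]
    if not clean:
        raise ValueError("no usable round-0 reads")
    codes = encode_many(clean)
    freqs = np.stack([
        (np.bincount(codes[:, j], minlength=4) + smoothing) /
        (codes.shape[0] + 4 * smoothing)
        for j in range(codes.shape[1])])
    return PositionalBackground(freqs, n_reads=len(clean), smoothing=smoothing)


def select_markov_order(reads_round0: SelexReadSet, max_order: int = 8,
                        smoothing: float = 1.0) -> int:
    """Choose the Markov order by held-out read log-likelihood.

    Round-0 reads are split deterministically (even/odd); models of
    increasing order are fitted on one half and scored on the other, and the
    order with the best mean held-out log-probability wins. Libraries with
    positional structure (e.g. a fixed core) push the selected order up,
    because only a longer context can partially express them.
    """
    clean = [r for r in reads_round0.reads if "N" not in r]
    if len(clean) < 200:
        return min(2, max(len(clean[0]) - 1 if clean else 0, 0))
    train = SelexReadSet(0, clean[0::2])
    test = clean[1::2]
    codes = encode_many(test)
    best_order, best_ll = 0, -np.inf
    length = len(clean[0])
    for order in range(0, min(max_order, length - 1) + 1):
        bg = fit_markov_background(train, order=order, smoothing=max(smoothing, 1e-3))
        ll = float(bg.log_prob_codes(codes).mean())
        if ll > best_ll + 1e-9:
            best_order, best_ll = order, ll
    return best_order


def fit_markov_background(reads_round0: SelexReadSet, order: Optional[int] = None,
                          smoothing: float = 1.0) -> MarkovBackground:
    """Maximum-likelihood Markov background with add-one smoothing.

    `order=None` selects the order by held-out likelihood on a round-0
    split (the behaviour of the reference SELEX analysis tooling), which
    matters for fixed-core libraries that a short context cannot express.
    `smoothing` is the pseudo-count added to every transition cell (1.0 is
    classic add-one; 0 gives the unsmoothed MLE). Reads containing N are
    ignored for counting. order >= read length is an error.
    """
    if order is None:
        order = select_markov_order(reads_round0, smoothing=smoothing)
    if order < 0:
        raise ValueError("order must be >= 0")
    length = reads_round0.read_length()
    if order >= length:
        raise ValueError(f"order {order} >= read length {length}")
    clean = [r for r in reads_round0.reads if "N" not in r]
    codes = encode_many(clean)
    mmer_counts: dict[int, np.ndarray] = {}
    for m in range(1, order + 2):
        idx = np.zeros((codes.shape[0], length - m + 1), dtype=np.int64)
        for j in range(m):
            idx = idx * 4 + codes[:, j:length - m + 1 + j]
        mmer_counts[m] = np.bincount(idx.ravel(), minlength=4**m).astype(np.int64)
    return MarkovBackground(order=order, smoothing=smoothing,
                            mmer_counts=mmer_counts, read_length=length,
                            n_reads=len(clean))


def expected_kmer_count(bg: MarkovBackground, k: int, n_reads: int,
                        read_length: int) -> pd.Series:
    """Expected count of every k-mer: n_reads * (read_length-k+1) * P_bg.

    Enumerates all 4^k k-mers, so k is capped at 10 here; affinity tables
    compute expectations lazily per observed k-mer instead.
    """
    if k > read_length:
        raise ValueError("k exceeds read length")
    if k > 10:
        raise ValueError("full enumeration limited to k <= 10; "
                         "use build_affinity_table for longer k-mers")
    n_windows = n_reads * (read_length - k + 1)
    all_codes = np.empty((4**k, k), dtype=np.int8)
    idx = np.arange(4**k)
    for j in range(k - 1, -1, -1):
        all_codes[:, j] = idx % 4
        idx = idx // 4
    probs = np.exp(bg.log_prob_codes(all_codes))
    return pd.Series(n_windows * probs, index=indices_to_kmers(np.arange(4**k), k))


# ---------------------------------------------------------------------------
# k-mer counting and affinity tables
# ---------------------------------------------------------------------------

def count_kmers(reads: Sequence[str] | SelexReadSet, k: int,
                aggregate_revcomp: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window k-mer counts over reads (N-containing reads excluded).

    Returns (kmer_indices, counts) with base-4 integer k-mer encoding.
    Counting is forward-strand by default; aggregate_revcomp adds each
    window's reverse complement as well.
    """
    seqs = reads.reads if isinstance(reads, SelexReadSet) else list(reads)
    seqs = [s for s in seqs if "N" not in s]
    if not seqs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = encode_many(seqs)
    length = codes.shape[1]
    if k > length:
        raise ValueError(f"k={k} > read length {length}")
    mats = [codes]
    if aggregate_revcomp:
        mats.append(revcomp_codes(codes))
    chunks = []
    for mat in mats:
        idx = np.zeros((mat.shape[0], length - k + 1), dtype=np.int64)
        for j in range(k):
            idx = idx * 4 + mat[:, j:length - k + 1 + j]
        chunks.append(idx.ravel())
    return np.unique(np.concatenate(chunks), return_counts=True)


@dataclass
class KmerAffinityTable:
    """Observed/expected counts, enrichment and relative affinity per k-mer.

    enrichment = (obs + pseudocount) / (expected + pseudocount);
    affinity = enrichment^(1/r), rescaled so the maximum is 1.
    """

    k: int
    round_index: int
    df: pd.DataFrame  # columns: kmer, obs, expected, enrichment, affinity
    pseudocount: float = 0.5
    n_reads: int = 0
    read_length: Optional[int] = None

    def __len__(self) -> int:
        return len(self.df)

    def affinity(self, kmer: str) -> float:
        row = self.df.loc[self.df["kmer"] == kmer, "affinity"]
        if row.empty:
            raise KeyError(kmer)
        return float(row.iloc[0])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.df["kmer"], self.df["affinity"]))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def build_affinity_table(reads_round_r: SelexReadSet, bg,
                         k: int, r: Optional[int] = None,
                         pseudocount: float = 0.5,
                         aggregate_revcomp: bool = False) -> KmerAffinityTable:
    """Build the round-r k-mer affinity table against the round-0 background.

    Deterministic given its inputs. r defaults to the read set's round index
    and must be >= 1 (round 0 may be passed explicitly with r=1 as a
    self-consistency control).
    """
    if r is None:
        r = reads_round_r.round_index
    if r < 1:
        raise ValueError("selection round r must be >= 1")
    length = reads_round_r.read_length()
    if k > length:
        raise ValueError(f"k={k} > read length {length}")
    idx, obs = count_kmers(reads_round_r, k, aggregate_revcomp=aggregate_revcomp)
    n_clean = len([s for s in reads_round_r.reads if "N" not in s])
    # lazy expectation: decode unique k-mer indices straight to a code matrix
    kcodes = np.empty((idx.size, k), dtype=np.int8)
    rem = idx.copy()
    for j in range(k - 1, -1, -1):
        kcodes[:, j] = rem % 4
        rem //= 4
    expected = bg.expected_counts(kcodes, n_clean, length)
    if aggregate_revcomp:
        expected = 2 * expected
    enrichment = (obs + pseudocount) / (expected + pseudocount)
    affinity = enrichment ** (1.0 / r)
    affinity = affinity / affinity.max()
    df = pd.DataFrame({
        "kmer": indices_to_kmers(idx, k),
        "obs": obs,
        "expected": expected,
        "enrichment": enrichment,
        "affinity": affinity,
    }).sort_values("affinity", ascending=False, ignore_index=True)
    return KmerAffinityTable(k=k, round_index=r, df=df,
                             pseudocount=pseudocount,
                             n_reads=len(reads_round_r), read_length=length)


def compare_tables(a: KmerAffinityTable, b: KmerAffinityTable,
                   min_obs: int = 1) -> tuple[float, pd.DataFrame]:
    """Pearson r of affinities over k-mers observed >= min_obs in both tables.

    All shared k-mers are compared by default (the reference tooling reports
    every k-mer); raise min_obs to restrict to well-counted k-mers.
    Returns (r, merged frame). Used for round-to-round consistency checks.
    """
    if a.k != b.k:
        raise ValueError("tables have different k")
    merged = a.df.merge(b.df, on="kmer", suffixes=("_a", "_b"))
    merged = merged[(merged["obs_a"] >= min_obs) & (merged["obs_b"] >= min_obs)]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared k-mers above the count floor")
    r = float(np.corrcoef(merged["affinity_a"], merged["affinity_b"])[0, 1])
    return r, merged


# ---------------------------------------------------------------------------
# annotation, z-scores, consensus
# ---------------------------------------------------------------------------

@dataclass
class KmerAnnotation:
    kmer: str
    core_offset: Optional[int]  # offset of the NNCGTG (or box) 6-mer start
    core_class: str
    c1c2: Optional[str]
    flank_labels: dict[str, str] = field(default_factory=dict)


def annotate_kmer(kmer: str) -> KmerAnnotation:
    """Locate the leftmost NNCGTG core and classify it.

    Classes follow the bHLH taxonomy: E-box (CACGTG), E-box-like (DNCGTG,
    D = A/T/G), and the non-CGTG boxes CACC-box (CACCTG), CAG-box (CAGCTG),
    CAT-box (CATATG). Flank labels count outward from the 6-mer core
    (f-1..f-4 upstream, f+1..f+8 downstream, where present).
    """
    kmer = kmer.upper()
    if len(kmer) < 6:
        raise ValueError("k-mer must be at least 6 bp to annotate a core")
    core_offset = None
    for i in range(2, len(kmer) - len(CORE) + 1):
        if kmer.startswith(CORE, i):
            core_offset = i - 2  # start of the NNCGTG 6-mer
            break
    core_class = "none"
    c1c2 = None
    if core_offset is not None:
        c1c2 = kmer[core_offset:core_offset + 2]
        if c1c2 == "CA":
            core_class = "E-box"
        elif c1c2[0] in "ATG":
            core_class = "E-box-like"
    else:
        for box, cls in _BOX_CLASSES:
            pos = kmer.find(box)
            if pos >= 0:
                core_offset, core_class, c1c2 = pos, cls, box[:2]
                break
    flanks: dict[str, str] = {}
    if core_offset is not None:
        for d in range(1, 5):
            p = core_offset - d
            if p >= 0:
                flanks[f"f-{d}"] = kmer[p]
        for d in range(1, 9):
            p = core_offset + 6 + d - 1
            if p < len(kmer):
                flanks[f"f+{d}"] = kmer[p]
    return KmerAnnotation(kmer=kmer, core_offset=core_offset,
                          core_class=core_class, c1c2=c1c2, flank_labels=flanks)


def normalize_zscore(values: Sequence[float]) -> np.ndarray:
    """Z-score normalise (mean 0, sample SD 1); zero variance warns -> zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; z-scores set to 0")
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def derive_consensus(table: KmerAffinityTable, top_n: int = 50,
                     threshold: float = 0.25) -> str:
    """IUPAC consensus over the top_n core-aligned k-mers.

    k-mers are aligned on the start of their NNCGTG core; per aligned
    position the IUPAC code covers every base whose frequency among covering
    k-mers reaches `threshold`. Positions covered by fewer than half of the
    aligned k-mers are dropped from the ends.
    """
    if len(table) == 0:
        raise ValueError("empty affinity table")
    if len(table) == 1:
        return str(table.df["kmer"].iloc[0])
    aligned: list[tuple[str, int]] = []
    for kmer in table.df["kmer"].head(top_n):
        ann = annotate_kmer(kmer)
        if ann.core_offset is not None and ann.core_class in {"E-box", "E-box-like"}:
            aligned.append((kmer, ann.core_offset))
    if not aligned:
        raise ValueError("no core-containing k-mers among the top entries")
    max_left = max(off for _, off in aligned)
    max_right = max(len(km) - off for km, off in aligned)
    counts = np.zeros((max_left + max_right, 4), dtype=int)
    cover = np.zeros(max_left + max_right, dtype=int)
    for km, off in aligned:
        start = max_left - off
        for j, base in enumerate(km):
            counts[start + j, "ACGT".index(base)] += 1
            cover[start + j] += 1
    keep = cover >= max(1, len(aligned) // 2)
    first, last = np.argmax(keep), len(keep) - np.argmax(keep[::-1])
    out = []
    for p in range(first, last):
        if cover[p] == 0:
            out.append("N")
            continue
        freqs = counts[p] / cover[p]
        bases = [BASES[i] for i in range(4) if freqs[i] >= threshold]
        if not bases:
            bases = [BASES[int(np.argmax(freqs))]]
        out.append(iupac_code(bases))
    return "".join(out)
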