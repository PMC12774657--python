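"""Pentamer-lookup DNA shape features and affinity-stratified profiles.

Shape parameters follow the pentamer-query convention: minor groove width
(MGW, Angstrom) and propeller twist (ProT, degrees) are properties of the
central base of a 5-mer window; helical twist (HelT) and roll (degrees) are
properties of the two central base steps, so each genomic step is averaged
over the (up to two) pentamers whose central steps cover it. The first and
last two positions of any sequence have no complete pentamer and are
undefined (NaN).

The packaged table (data/synthetic_pentamer_shape.tsv) is SYNTHETIC: it is
regenerated deterministically by build_synthetic_shape_table() from an
additive model (weighted AT content and W|W step fraction with a
pentamer-specific deterministic perturbation, plus dinucleotide step means
for HelT/Roll). It reproduces the qualitative behaviour that matters for
profile analysis - A/T-rich sequence narrows the minor groove and drives
propeller twist more negative, with exact reverse-complement symmetry - but
its absolute values are not derived from molecular simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp

__all__ = ["ShapeTable", "ShapeProfile", "build_synthetic_shape_table",
           "load_shape_table", "shape_features", "affinity_binned_shape",
           "codependency_heatmap"]

SHAPE_PARAMS = ("MGW", "ProT", "HelT1", "HelT2", "Roll1", "Roll2")

# Reverse-complement symmetric dinucleotide step means (degrees), in the
# style of crystallographic step averages: rigid A-tract steps high HelT /
# low Roll, pyrimidine-purine steps the reverse.
_HELT_STEP = {
    "AA": 35.6, "AC": 34.1, "AG": 33.3, "AT": 35.3,
    "CA": 34.5, "CC": 33.7, "CG": 29.8, "CT": 33.3,
    "GA": 36.3, "GC": 33.6, "GG": 33.7, "GT": 34.1,
    "TA": 36.0, "TC": 36.3, "TG": 34.5, "TT": 35.6,
}
_ROLL_STEP = {
    "AA": 0.7, "AC": 0.7, "AG": 4.5, "AT": 1.1,
    "CA": 4.7, "CC": 3.6, "CG": 5.4, "CT": 4.5,
    "GA": 1.9, "GC": 0.3, "GG": 3.6, "GT": 0.7,
    "TA": 3.3, "TC": 1.9, "TG": 4.7, "TT": 0.7,
}

_POS_WEIGHTS = np.array([0.6, 1.0, 1.6, 1.0, 0.6])
_STEP_WEIGHTS = np.array([0.8, 1.2, 1.2, 0.8])


def _canonical(pentamer: str) -> str:
    rc = revcomp(pentamer)
    return pentamer if pentamer <= rc else rc


def _jitter(key: str, sd: float) -> float:
    """Deterministic pentamer-specific perturbation (seeded by CRC of key)."""
    rng = np.random.default_rng(zlib.crc32(key.encode()))
    return float(rng.normal(0.0, sd))


def _at_score(pentamer: str) -> float:
    w = np.array([b in "AT" for b in pentamer], dtype=float)
    return float((w * _POS_WEIGHTS).sum() / _POS_WEIGHTS.sum())


def _ww_step_frac(pentamer: str) -> float:
    steps = [pentamer[i:i + 2] for i in range(4)]
    w = np.array([s[0] in "AT" and s[1] in "AT" for s in steps], dtype=float)
    return float((w * _STEP_WEIGHTS).sum() / _STEP_WEIGHTS.sum())


def build_synthetic_shape_table() -> pd.DataFrame:
    """Regenerate the packaged synthetic pentamer table (all 1024 rows).

    MGW and ProT are functions of the canonical pentamer (exact
    reverse-complement symmetry); HelT/Roll step values satisfy
    value(p, step1) == value(revcomp(p), step2).
    """
    rows = []
    for tup in product(BASES, repeat=5):
        p = "".join(tup)
        canon = _canonical(p)
        at = _at_score(p)           # rc-invariant by construction
        ww = _ww_step_frac(p)
        mgw = 5.7 - 1.4 * at - 0.35 * ww + _jitter("MGW:" + canon, 0.12)
        mgw = max(mgw, 2.8)
        prot = -6.5 - 7.5 * at - 1.5 * ww + _jitter("ProT:" + canon, 0.5)
        steps = []
        for s in (0, 1):           # central steps: bases (1,2) and (2,3)
            dinuc = p[s + 1:s + 3]
            key = min((p, s), (revcomp(p), 1 - s))
            helt = _HELT_STEP[dinuc] + _jitter(f"HelT:{key[0]}:{key[1]}", 0.4)
            roll = _ROLL_STEP[dinuc] + _jitter(f"Roll:{key[0]}:{key[1]}", 0.4)
            steps.append((helt, roll))
        rows.append({"pentamer": p,
                     "MGW": round(mgw, 3), "ProT": round(prot, 3),
                     "HelT1": round(steps[0][0], 3), "HelT2": round(steps[1][0], 3),
                     "Roll1": round(steps[0][1], 3), "Roll2": round(steps[1][1], 3)})
    return pd.DataFrame(rows)


@dataclass
class ShapeTable:
    """Pentamer -> (MGW, ProT, HelT x2, Roll x2) lookup with provenance."""

    df: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.df) != 1024 or self.df["pentamer"].nunique() != 1024:
            raise ValueError("shape table must cover all 1024 pentamers exactly once")
        if (self.df["MGW"] <= 0).any():
            raise ValueError("MGW must be positive")
        self._lut = {row.pentamer: (row.MGW, row.ProT, row.HelT1, row.HelT2,
                                    row.Roll1, row.Roll2)
                     for row in self.df.itertuples(index=False)}

    def lookup(self, pentamer: str):
        return self._lut[pentamer.upper()]


_cached_table: Optional[ShapeTable] = None


def load_shape_table(path=None) -> ShapeTable:
    """Load the packaged synthetic table (or a user TSV of the same layout)."""
    global _cached_table
    if path is None:
        if _cached_table is None:
            with resources.files("pasbind.data").joinpath(
                    "synthetic_pentamer_shape.tsv").open() as fh:
                _cached_table = ShapeTable(pd.read_csv(fh, sep="\t"),
                                           provenance="pasbind synthetic v1")
        return _cached_table
    return ShapeTable(pd.read_csv(path, sep="\t"), provenance=str(path))


def shape_features(sequence: str, table: Optional[ShapeTable] = None
                   ) -> dict[str, np.ndarray]:
    """Per-position shape values for one sequence.

    Returns arrays MGW/ProT of length n (NaN at the two terminal positions
    on each side and wherever a covering pentamer contains N) and HelT/Roll
    of length n-1 (per base step, mean of the overlapping pentamers' step
    values).
    """
    if table is None:
        table = load_shape_table()
    seq = sequence.upper()
    n = len(seq)
    if n < 5:
        raise ValueError("sequence must be at least 5 bp")
    mgw = np.full(n, np.nan)
    prot = np.full(n, np.nan)
    helt_sum = np.zeros(n - 1)
    helt_n = np.zeros(n - 1)
    roll_sum = np.zeros(n - 1)
    roll_n = np.zeros(n - 1)
    for i in range(n - 4):
        p = seq[i:i + 5]
        if "N" in p:
            continue
        m, pt, h1, h2, r1, r2 = table.lookup(p)
        mgw[i + 2] = m
        prot[i + 2] = pt
        for s, (h, r) in enumerate(((h1, r1), (h2, r2))):
            step = i + 1 + s  # step between positions step, step+1
            helt_sum[step] += h
            helt_n[step] += 1
            roll_sum[step] += r
            roll_n[step] += 1
    with np.errstate(invalid="ignore"):
        helt = np.where(helt_n > 0, helt_sum / np.maximum(helt_n, 1), np.nan)
        roll = np.where(roll_n > 0, roll_sum / np.maximum(roll_n, 1), np.nan)
    return {"MGW": mgw, "ProT": prot, "HelT": helt, "Roll": roll}


@dataclass
class ShapeProfile:
    """Mean/SD shape per position, stratified by affinity bin.

    positions are 0-based within the aligned span; bin labels run low -> high
    affinity. occupancy conserves the input count.
    """

    positions: np.ndarray
    bins: list[int]
    mean: dict[str, np.ndarray]   # param -> (n_bins, n_positions)
    sd: dict[str, np.ndarray]
    occupancy: np.ndarray
    align: str = "left"


def _align_sequences(seqs: Sequence[str], align: str) -> list[str]:
    if align == "left":
        spans = {len(s) for s in seqs}
        if len(spans) != 1:
            raise ValueError("sequences of unequal length with align='left'")
        return list(seqs)
    if align != "core_CGTG":
        raise ValueError(f"unknown alignment {align!r}")
    offsets = []
    for s in seqs:
        pos = s.find("CGTG")
        if pos < 0:
            raise ValueError(f"no CGTG core in {s!r} (align='core_CGTG')")
        offsets.append(pos)
    spans = {(off, len(s) - off) for s, off in zip(seqs, offsets)}
    if len(spans) != 1:
        raise ValueError("core-aligned sequences have unequal aligned spans")
    return list(seqs)


def affinity_binned_shape(affinities: Mapping[str, float],
                          align: str = "core_CGTG",
                          n_bins: int = 10,
                          equal_width: bool = False,
                          table: Optional[ShapeTable] = None) -> ShapeProfile:
    """Affinity-stratified mean shape profiles.

    Sequences are assigned to affinity bins (equal-count deciles by default;
    equal_width uses equal-width bins over the affinity range) and per-bin,
    per-position means and SDs of each shape parameter are computed. With
    align='core_CGTG' all sequences must place their leftmost CGTG at the
    same offset (the layout of core-aligned fixed-library k-mer tables).
    """
    if table is None:
        table = load_shape_table()
    seqs = list(affinities.keys())
    vals = np.array([affinities[s] for s in seqs], dtype=float)
    if len(seqs) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} sequences")
    _align_sequences(seqs, align)
    if n_bins == 1:
        bin_idx = np.zeros(len(seqs), dtype=int)
    elif equal_width:
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
        bin_idx = np.clip(np.searchsorted(edges, vals, side="right") - 1,
                          0, n_bins - 1)
    else:
        order = np.argsort(vals, kind="stable")
        bin_idx = np.empty(len(seqs), dtype=int)
        bin_idx[order] = np.minimum(
            np.arange(len(seqs)) * n_bins // len(seqs), n_bins - 1)
    length = len(seqs[0])
    feats = {p: np.empty((len(seqs), length)) for p in ("MGW", "ProT")}
    feats.update({p: np.empty((len(seqs), length - 1)) for p in ("HelT", "Roll")})
    for i, s in enumerate(seqs):
        f = shape_features(s, table)
        for p in feats:
            feats[p][i] = f[p]
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    occupancy = np.array([(bin_idx == b).sum() for b in range(n_bins)])
    for p, mat in feats.items():
        mean[p] = np.full((n_bins, mat.shape[1]), np.nan)
        sd[p] = np.full((n_bins, mat.shape[1]), np.nan)
        for b in range(n_bins):
            rows = mat[bin_idx == b]
            if rows.size == 0:
                continue
            defined = np.isfinite(rows).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                s = np.nansum(rows, axis=0)
                m = np.where(defined > 0, s / np.maximum(defined, 1), np.nan)
                sq = np.nansum((rows - m) ** 2, axis=0)
                v = np.where(defined > 0, sq / np.maximum(defined, 1), np.nan)
            mean[p][b] = m
            sd[p][b] = np.sqrt(v)
    return ShapeProfile(positions=np.arange(length), bins=list(range(n_bins)),
                        mean=mean, sd=sd, occupancy=occupancy, align=align)


def codependency_heatmap(table, row_positions: Sequence[int],
                         col_positions: Sequence[int],
                         aggregator: str = "mean") -> pd.DataFrame:
    """Aggregate affinity over base identities at two disjoint position sets.

    `table` is a KmerAffinityTable or mapping kmer -> affinity; positions are
    RELATIVE TO THE CORE: 0 is c1 of the leftmost NNCGTG, negative values are
    upstream flank. The classic configuration compares the core dinucleotide
    (rows, positions (0, 1) -> 16 labels) against the upstream trinucleotide
    (cols, positions (-3, -2, -1) -> 64 labels). Cells with no matching k-mer
    are NaN, not zero. Mean aggregation marginalises consistently: the
    occupancy-weighted mean over cells equals the global mean affinity.
    """
    if aggregator not in {"mean", "max"}:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    if set(row_positions) & set(col_positions):
        raise ValueError("row and column positions must be disjoint")
    if hasattr(table, "df"):
        items = list(zip(table.df["kmer"], table.df["affinity"]))
    else:
        items = list(table.items())
    records = []
    for kmer, aff in items:
        core = kmer.find("CGTG")
        if core < 2:
            continue
        anchor = core - 2  # position of c1
        try:
            row_label = "".join(kmer[anchor + p] for p in row_positions)
            col_label = "".join(kmer[anchor + p] for p in col_positions)
        except IndexError:
            continue
        if any(anchor + p < 0 for p in list(row_positions) + list(col_positions)):
            continue
        records.append((row_label, col_label, aff))
    if not records:
        raise ValueError("no core-containing k-mers cover the requested positions")
    df = pd.DataFrame(records, columns=["row", "col", "affinity"])
    agg = df.groupby(["row", "col"])["affinity"].agg(aggregator).unstack("col")
    row_labels = ["".join(t) for t in product(BASES, repeat=len(row_positions))]
    col_labels = ["".join(t) for t in product(BASES, repeat=len(col_positions))]
    return agg.reindex(index=row_labels, columns=col_labels)
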