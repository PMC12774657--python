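"""Biophysical mononucleotide binding-energy models fitted to SELEX rounds.

The model assigns each base b at footprint position i an energy penalty
eps(b, i) >= 0 (natural-log units of relative affinity, gauge-fixed so the
per-position minimum is 0). A probe S is bound through any length-L window
of flank+S+flank on either strand, with total statistical weight

    W(S) = sum over windows v, strands of exp(-sum_i eps(base_v[i], i)).

Fitting maximises the penalised selection log-likelihood

    sum_reads r * log W(S) - N_r * log Z_r - lambda * ||eps||^2,

where Z_r = E_0[W^r] is approximated by importance sampling over a fixed
pool of unselected-library sequences. The read-probability factor p_bg(S)
does not depend on eps and is dropped.

W is invariant under reverse-complement flipping of the energy matrix, so a
fitted model is only identified up to orientation; use
EnergyModel.oriented_like before comparing matrices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._seq import BASES, encode, encode_many, expand_iupac, revcomp
from .io_formats import SelexReadSet
from .kmer_affinity import KmerAffinityTable, MarkovBackground

__all__ = ["EnergyModel", "window_weight", "score_sequence", "score_sequences",
           "score_kmer_space", "fit_energy_model", "goodness_of_fit",
           "energy_logo", "plot_energy_logo", "sweep_footprint"]

_BIG = 1e30  # energy of an N base: weight exactly 0 after exp(-E)


@dataclass
class EnergyModel:
    """Mononucleotide energy matrix over a footprint of length L.

    energies has shape (4, L), rows in A, C, G, T order. flank sequences are
    the constant probe context prepended/appended when windowing.
    """

    energies: np.ndarray
    left_flank: str = ""
    right_flank: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[0] != 4:
            raise ValueError("energies must have shape (4, L)")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite")

    @property
    def L(self) -> int:
        return self.energies.shape[1]

    def gauged(self) -> "EnergyModel":
        """Fix the gauge: subtract the per-position minimum (min becomes 0)."""
        eps = self.energies - self.energies.min(axis=0, keepdims=True)
        return EnergyModel(eps, self.left_flank, self.right_flank, dict(self.metadata))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmin(self.energies, axis=0))

    def revcomp_flipped(self) -> "EnergyModel":
        """The strand-flipped model (identical W for every sequence)."""
        eps = self.energies[::-1, ::-1].copy()
        return EnergyModel(eps, revcomp(self.right_flank), revcomp(self.left_flank),
                           dict(self.metadata))

    def oriented_like(self, reference: "EnergyModel") -> "EnergyModel":
        """Resolve the strand degeneracy against a reference matrix."""
        flipped = self.revcomp_flipped()
        r_fwd = np.corrcoef(self.energies.ravel(), reference.energies.ravel())[0, 1]
        r_rev = np.corrcoef(flipped.energies.ravel(), reference.energies.ravel())[0, 1]
        return self if r_fwd >= r_rev else flipped

    def alignment_correlation(self, reference: "EnergyModel",
                              max_shift: int = 3) -> tuple[float, int, str]:
        """Best Pearson r of energies vs a reference over strand and offset.

        The sum-over-windows likelihood is nearly invariant to translating
        the matrix along the footprint (and exactly invariant to strand
        flips), so matrices are compared the way motif-comparison tools do:
        maximise the correlation of overlapping columns over shifts in
        [-max_shift, max_shift] and both orientations. Returns
        (r, shift, strand).
        """
        best = (-np.inf, 0, "+")
        for strand, mat in (("+", self.energies),
                            ("-", self.revcomp_flipped().energies)):
            for shift in range(-max_shift, max_shift + 1):
                lo = max(0, shift)
                hi = min(self.L, reference.L + shift)
                if hi - lo < max(4, self.L // 2):
                    continue
                a = mat[:, lo:hi].ravel()
                b = reference.energies[:, lo - shift:hi - shift].ravel()
                if a.std() == 0 or b.std() == 0:
                    continue
                r = float(np.corrcoef(a, b)[0, 1])
                if r > best[0]:
                    best = (r, shift, strand)
        return best

    def shuffled(self, seed: int = 0) -> "EnergyModel":
        """Decoy model: energies permuted across positions and bases."""
        rng = np.random.default_rng(seed)
        flat = self.energies.ravel().copy()
        rng.shuffle(flat)
        return EnergyModel(flat.reshape(4, self.L), self.left_flank,
                           self.right_flank, {"decoy_of": self.metadata.get("name")})

    # --- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "L": self.L,
            "energies": {b: list(map(float, self.energies[i]))
                         for i, b in enumerate(BASES)},
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EnergyModel":
        from pathlib import Path
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            with open(source) as fh:
                payload = json.load(fh)
        elif isinstance(source, str):
            payload = json.loads(source)
        else:
            payload = json.load(source)
        eps = np.array([payload["energies"][b] for b in BASES], dtype=float)
        return cls(eps, payload.get("left_flank", ""), payload.get("right_flank", ""),
                   payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# window scoring engine
# ---------------------------------------------------------------------------

def _eps_ext(model: EnergyModel) -> np.ndarray:
    """(5, L) energy table with an N row of effectively infinite energy."""
    return np.vstack([model.energies, np.full(model.L, _BIG)])


def _flanked(codes: np.ndarray, model: EnergyModel) -> np.ndarray:
    parts = []
    if model.left_flank:
        parts.append(np.tile(encode(model.left_flank), (codes.shape[0], 1)))
    parts.append(codes)
    if model.right_flank:
        parts.append(np.tile(encode(model.right_flank), (codes.shape[0], 1)))
    return np.hstack(parts) if len(parts) > 1 else codes


def _window_energy_matrix(codes_f: np.ndarray, codes_r: np.ndarray,
                          eps: np.ndarray) -> np.ndarray:
    """Energies of every window x strand, shape (n, 2*n_off).

    Column 2*o is the forward window at offset o, column 2*o+1 the reverse
    window covering the same offset, so argmin tie-breaking by first column
    implements "smallest offset, then forward strand".
    """
    n, length = codes_f.shape
    L = eps.shape[1]
    n_off = length - L + 1
    if n_off < 1:
        raise ValueError(f"sequence of length {length} shorter than footprint {L}")
    E = np.empty((n, 2 * n_off))
    eps_T = [np.ascontiguousarray(eps[:, i]) for i in range(L)]
    for o in range(n_off):
        acc_f = np.zeros(n)
        acc_r = np.zeros(n)
        o_r = length - L - o
        for i in range(L):
            acc_f += eps_T[i][codes_f[:, o + i]]
            acc_r += eps_T[i][codes_r[:, o_r + i]]
        E[:, 2 * o] = acc_f
        E[:, 2 * o + 1] = acc_r
    return E


def _revcomp_codes_int(codes: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=codes.dtype)
    return np.ascontiguousarray(comp[codes][:, ::-1])


def window_weight(model: EnergyModel, sequence: str):
    """Total weight W(S) and the arg-max window.

    Returns (W, (offset, strand)) with the offset measured from the start of
    `sequence` (negative offsets reach into the left flank). Ties go to the
    smallest offset, then the forward strand.
    """
    codes = encode(sequence.upper())[None, :]
    codes_f = _flanked(codes, model)
    if codes_f.shape[1] < model.L:
        raise ValueError("flanked sequence shorter than the footprint")
    codes_r = _revcomp_codes_int(codes_f)
    E = _window_energy_matrix(codes_f, codes_r, _eps_ext(model))[0]
    weights = np.exp(-np.clip(E, None, 700.0))
    W = float(weights.sum())
    best_col = int(np.argmin(E))
    offset = best_col // 2 - len(model.left_flank)
    strand = "+" if best_col % 2 == 0 else "-"
    return W, (offset, strand)


def score_sequences(model: EnergyModel, sequences, aggregation: str = "max") -> np.ndarray:
    """Vectorised scores for equal-length sequences.

    max: best single-window log-weight (-min energy); sum: log W(S).
    Sequences whose windows are all N-blocked score -inf.
    """
    if aggregation not in {"max", "sum"}:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    codes = sequences if isinstance(sequences, np.ndarray) else encode_many(
        [s.upper() for s in sequences])
    codes_f = _flanked(codes, model)
    codes_r = _revcomp_codes_int(codes_f)
    E = _window_energy_matrix(codes_f, codes_r, _eps_ext(model))
    if aggregation == "max":
        out = -E.min(axis=1)
        out[out <= -_BIG / 2] = -np.inf
        return out
    a = -np.clip(E, None, _BIG)
    amax = a.max(axis=1)
    safe = amax > -_BIG / 2
    out = np.full(codes.shape[0], -np.inf)
    if safe.any():
        shifted = np.exp(a[safe] - amax[safe, None])
        out[safe] = amax[safe] + np.log(shifted.sum(axis=1))
    return out


def score_sequence(model: EnergyModel, sequence: str, aggregation: str = "max") -> float:
    """Score one sequence; sum mode equals log window_weight."""
    return float(score_sequences(model, [sequence], aggregation)[0])


def score_kmers_in_context(model: EnergyModel, kmers) -> np.ndarray:
    """log W of k-mers embedded in a background-averaged context.

    Positions of a window that overhang the k-mer contribute the position's
    log-mean Boltzmann weight over bases (a neutral flanking base), so
    k-mers shorter than the footprint can still be scored, as when
    predicting k-mer table enrichments from a longer model.
    """
    codes = kmers if isinstance(kmers, np.ndarray) else encode_many(
        [s.upper() for s in kmers])
    L = model.L
    pad = np.full((codes.shape[0], L - 1), 4, dtype=codes.dtype)
    padded = np.hstack([pad, codes, pad])
    avg_row = -np.log(np.mean(np.exp(-model.energies), axis=0))
    eps = np.vstack([model.energies, avg_row])
    codes_r = _revcomp_codes_int(padded)
    E = _window_energy_matrix(padded, codes_r, eps)
    a = -E
    amax = a.max(axis=1)
    return amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))


def score_kmer_space(model: EnergyModel, pattern: str,
                     aggregation: str = "max") -> pd.DataFrame:
    """Score every expansion of an IUPAC pattern, sorted descending.

    A pattern with no degenerate letter yields a single row equal to
    score_sequence. Expansion beyond 10^7 sequences raises with advice to
    chunk the pattern.
    """
    seqs = expand_iupac(pattern)
    scores = score_sequences(model, seqs, aggregation=aggregation)
    return (pd.DataFrame({"kmer": seqs, "score": scores})
            .sort_values("score", ascending=False, ignore_index=True))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _unique_rows(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical reads; returns (unique code rows, counts)."""
    if codes.shape[0] == 0:
        return codes, np.empty(0)
    view = np.ascontiguousarray(codes).view(
        np.dtype((np.void, codes.dtype.itemsize * codes.shape[1]))).ravel()
    _, first, counts = np.unique(view, return_index=True, return_counts=True)
    return codes[first], counts.astype(float)


class _Dataset:
    """Pre-encoded forward/reverse code matrices plus per-sequence weights."""

    def __init__(self, codes: np.ndarray, counts: np.ndarray, model_like: EnergyModel):
        self.codes_f = _flanked(codes, model_like)
        self.codes_r = _revcomp_codes_int(self.codes_f)
        self.counts = counts
        self.n_total = float(counts.sum())
        self.L = model_like.L
        self.n_off = self.codes_f.shape[1] - self.L + 1

    def logW_and_post(self, eps: np.ndarray):
        E = _window_energy_matrix(self.codes_f, self.codes_r, eps)
        a = -E
        amax = a.max(axis=1)
        expa = np.exp(a - amax[:, None])
        sums = expa.sum(axis=1)
        logW = amax + np.log(sums)
        post = expa / sums[:, None]  # per-window responsibilities
        return logW, post

    def accumulate(self, post: np.ndarray, weights: np.ndarray, grad: np.ndarray) -> None:
        """grad[b, i] += sum_seq weights * sum_windows post * [base == b]."""
        L, n_off = self.L, self.n_off
        length = self.codes_f.shape[1]
        for o in range(n_off):
            w_f = post[:, 2 * o] * weights
            w_r = post[:, 2 * o + 1] * weights
            o_r = length - L - o
            for i in range(L):
                grad[:, i] += np.bincount(self.codes_f[:, o + i], weights=w_f,
                                          minlength=5)[:4]
                grad[:, i] += np.bincount(self.codes_r[:, o_r + i], weights=w_r,
                                          minlength=5)[:4]


def fit_energy_model(rounds: Sequence[SelexReadSet],
                     bg: Optional[MarkovBackground] = None,
                     design=None,
                     L: int = 12,
                     lam: float = 1e-4,
                     seed: int = 0,
                     pool_size: int = 100_000,
                     left_flank: str = "",
                     right_flank: str = "",
                     maxiter: int = 500,
                     tol: float = 1e-6,
                     init: Optional[np.ndarray] = None) -> EnergyModel:
    """Fit the energy matrix by penalised maximum likelihood.

    `rounds` may include round 0; selected rounds (index >= 1) contribute
    likelihood terms, and the partition function Z_r = E_0[W^r] is estimated
    on a fixed pool of `pool_size` sequences subsampled (seeded) from the
    round-0 reads when present, otherwise drawn from `bg`. The quasi-Newton
    optimiser (L-BFGS-B, analytic gradients) stops at relative objective
    change `tol` or `maxiter` iterations; non-convergence returns the best
    iterate with a warning and a metadata flag. Deterministic given the seed.
    """
    selected = [rs for rs in rounds if rs.round_index >= 1]
    round0 = next((rs for rs in rounds if rs.round_index == 0), None)
    if not selected:
        raise ValueError("need at least one selected round (round_index >= 1)")
    rng = np.random.default_rng(seed)

    proto = EnergyModel(np.zeros((4, L)), left_flank, right_flank)
    datasets: list[tuple[int, _Dataset]] = []
    for rs in selected:
        clean = [r for r in rs.reads if "N" not in r]
        codes, counts = _unique_rows(encode_many(clean))
        datasets.append((rs.round_index, _Dataset(codes, counts, proto)))

    if round0 is not None and len(round0) > 0:
        clean0 = [r for r in round0.reads if "N" not in r]
        pool_reads = clean0
        if len(clean0) > pool_size:
            sel = rng.choice(len(clean0), size=pool_size, replace=False)
            pool_reads = [clean0[i] for i in sel]
        pool_codes, pool_counts = _unique_rows(encode_many(pool_reads))
    elif bg is not None:
        read_len = selected[0].read_length()
        pool_codes = bg.sample_codes(pool_size, read_len, rng)
        pool_codes, pool_counts = _unique_rows(pool_codes)
    else:
        raise ValueError("need round-0 reads or a background model for the Z pool")
    pool = _Dataset(pool_codes, pool_counts, proto)

    n_total = sum(ds.n_total for _, ds in datasets)
    log_u = np.log(pool.counts) - np.log(pool.n_total)

    def objective(theta: np.ndarray):
        eps = theta.reshape(4, L)
        grad = np.zeros((4, L))
        loglik = 0.0
        pool_logW, pool_post = pool.logW_and_post(eps)
        for r, ds in datasets:
            logW, post = ds.logW_and_post(eps)
            loglik += r * float(np.dot(ds.counts, logW))
            ds.accumulate(post, r * ds.counts, grad)
            # importance-sampled log Z_r and its gradient
            a = r * pool_logW + log_u
            amax = a.max()
            q = np.exp(a - amax)
            logZ = amax + np.log(q.sum())
            q /= q.sum()
            loglik -= ds.n_total * logZ
            pool.accumulate(pool_post, -r * ds.n_total * q, grad)
        F = -loglik / n_total + lam * float(np.sum(eps**2))
        G = grad / n_total + 2.0 * lam * eps
        return F, G.ravel()

    theta0 = (np.zeros(4 * L) if init is None else np.asarray(init, float).ravel())
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7})
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"energy-model fit did not converge: {res.message}")
    model = EnergyModel(res.x.reshape(4, L), left_flank, right_flank, {
        "rounds": [r for r, _ in datasets],
        "lambda": lam,
        "seed": seed,
        "pool_size": int(pool.n_total),
        "tol": tol,
        "n_iter": int(res.nit),
        "converged": converged,
        "objective": float(res.fun),
    }).gauged()
    return model


def goodness_of_fit(model: EnergyModel, table: KmerAffinityTable,
                    min_obs: int = 10):
    """Predicted-vs-observed enrichment diagnostic.

    Predicted log enrichment of a k-mer is r * log W (the background
    correction is already inside the table's enrichment). When the table's
    k-mers span whole probes the isolated window weight is exact; shorter
    k-mers are scored in a background-averaged context
    (score_kmers_in_context). Observed log enrichment is regressed on the
    prediction by count-weighted least squares (weights = observed counts,
    the inverse variance of a log count), over k-mers with obs >= min_obs.
    Returns (weighted r^2, slope). Fewer than 10 eligible k-mers is an
    error; a flat prediction warns and returns (nan, nan).
    """
    df = table.df[table.df["obs"] >= min_obs]
    if len(df) < 10:
        raise ValueError(f"only {len(df)} k-mers above the count floor; need >= 10")
    kmers = list(df["kmer"])
    if table.read_length is not None and table.k == table.read_length:
        pred = table.round_index * score_sequences(model, kmers, "sum")
    else:
        pred = table.round_index * score_kmers_in_context(model, kmers)
    obs = np.log(df["enrichment"].to_numpy())
    w = df["obs"].to_numpy().astype(float)
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs, w = pred[keep], obs[keep], w[keep]
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("degenerate goodness-of-fit input (zero variance)")
        return float("nan"), float("nan")
    X = np.vstack([np.ones_like(pred), pred]).T
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], obs * sw, rcond=None)
    resid = obs - X @ beta
    centred = obs - np.average(obs, weights=w)
    r2 = 1.0 - float(np.sum(w * resid**2) / np.sum(w * centred**2))
    return r2, float(beta[1])


# ---------------------------------------------------------------------------
# logos and the footprint sweep
# ---------------------------------------------------------------------------

def energy_logo(model: EnergyModel) -> pd.DataFrame:
    """Per-position -ddG values (0 for the consensus base) as a DataFrame."""
    gauged = model.gauged()
    return pd.DataFrame(-gauged.energies.T, columns=list(BASES),
                        index=[f"p{i+1}" for i in range(model.L)])


_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_energy_logo(model: EnergyModel, path) -> None:
    """Render the energy logo as grouped per-base bars (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logo = energy_logo(model)
    fig, ax = plt.subplots(figsize=(0.6 * model.L + 1.5, 3))
    width = 0.2
    xs = np.arange(model.L)
    for j, b in enumerate(BASES):
        ax.bar(xs + (j - 1.5) * width, logo[b], width=width,
               color=_BASE_COLORS[b], label=b)
    ax.set_xticks(xs, [str(i + 1) for i in xs])
    ax.set_xlabel("footprint position")
    ax.set_ylabel(r"$-\Delta\Delta G$ (nat)")
    ax.legend(ncol=4, fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def sweep_footprint(rounds: Sequence[SelexReadSet],
                    bg: Optional[MarkovBackground] = None,
                    Ls: Sequence[int] = range(10, 17),
                    holdout_fraction: float = 0.2,
                    seed: int = 0, **fit_kwargs) -> pd.DataFrame:
    """Refit across footprint lengths, reporting held-out log-likelihood.

    Selected-round reads are split (seeded) into train/held-out fractions;
    the per-read held-out score is r*logW - logZ_r with Z estimated on the
    training pool. Returns a frame with columns L, holdout_loglik, converged.
    """
    rng = np.random.default_rng(seed)
    train_rounds, test_rounds = [], []
    for rs in rounds:
        if rs.round_index == 0:
            train_rounds.append(rs)
            continue
        n = len(rs.reads)
        mask = rng.random(n) < holdout_fraction
        train_rounds.append(SelexReadSet(rs.round_index,
                                         [r for r, m in zip(rs.reads, mask) if not m]))
        test_rounds.append(SelexReadSet(rs.round_index,
                                        [r for r, m in zip(rs.reads, mask) if m]))
    rows = []
    for L in Ls:
        model = fit_energy_model(train_rounds, bg=bg, L=L, seed=seed, **fit_kwargs)
        total, n_obs = 0.0, 0
        round0 = next(rs for rs in train_rounds if rs.round_index == 0)
        pool_scores = score_sequences(model, [r for r in round0.reads if "N" not in r][:20000],
                                      "sum")
        for rs in test_rounds:
            r = rs.round_index
            clean = [x for x in rs.reads if "N" not in x]
            logW = score_sequences(model, clean, "sum")
            a = r * pool_scores
            logZ = float(np.log(np.mean(np.exp(a - a.max()))) + a.max())
            total += float(np.sum(r * logW - logZ))
            n_obs += len(clean)
        rows.append({"L": L, "holdout_loglik": total / max(n_obs, 1),
                     "converged": model.metadata.get("converged", False)})
    return pd.DataFrame(rows)
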