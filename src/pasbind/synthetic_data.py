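"""Ground-truth simulators for every input the pipeline consumes.

The SELEX simulator implements multiplicative Boltzmann selection: each
round keeps a read with probability W(S)/W_max (physical rejection
sampling against the ground-truth energy model), then resamples the
survivors with replacement back to the configured depth, mimicking PCR
amplification of the bound fraction. The peak simulator plants one
Boltzmann-distributed binding site per peak in a random genome and makes
peak intensity an affine function of planted-site score plus Gaussian
noise; the methylation simulator attenuates intensities multiplicatively
with per-peak CpG methylation.

Every generator is a pure function of a SyntheticTruth (config + seed):
identical inputs reproduce outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._seq import BASES, decode, encode_many
from .energy_model import EnergyModel, score_sequences
from .io_formats import GenomicInterval, MethylationCall, SelexReadSet
from .selex_preprocess import FIXED_CORE_8N_CGTG_10N, SelexLibraryDesign

__all__ = ["SyntheticTruth", "PeakParams", "MethylationParams",
           "default_truth_model", "simulate_selex", "simulate_peak_experiment",
           "simulate_methylation", "exact_round1_enrichment", "mini_library_design"]


def default_truth_model(L: int = 12) -> EnergyModel:
    """Planted TACGTG-preferring 12-bp truth matrix.

    Layout: three upstream flank positions, the TACGTG core (c1..c6), three
    downstream flank positions with the family's AT-rich downstream
    preference. Core mismatches cost 2-4 nat; flank preferences are graded
    0-1 nat so they are recoverable but do not dominate selection.
    """
    if L != 12:
        raise ValueError("the packaged truth matrix is defined for L = 12")
    rows = {
        #        f-3   f-2   f-1   c1:T  c2:A  c3:C  c4:G  c5:T  c6:G  f+1   f+2   f+3
        "A": [0.30, 0.00, 0.55, 2.00, 0.00, 3.50, 4.00, 3.50, 4.00, 0.00, 0.10, 0.00],
        "C": [0.60, 0.45, 0.00, 2.50, 2.00, 0.00, 3.50, 3.00, 3.50, 0.55, 0.65, 0.80],
        "G": [0.00, 0.25, 0.80, 2.50, 2.20, 3.00, 0.00, 3.50, 0.00, 0.40, 0.75, 0.60],
        "T": [0.35, 0.60, 0.35, 0.00, 1.80, 3.20, 3.80, 0.00, 3.80, 0.25, 0.00, 0.15],
    }
    eps = np.array([rows[b] for b in BASES])
    return EnergyModel(eps, metadata={"name": "truth_TACGTG_12bp"})


@dataclass(frozen=True)
class PeakParams:
    n_peaks: int = 500
    n_decoys: int = 500
    peak_length: int = 200
    intensity_noise_sd: float = 1.0
    affinity_to_intensity_coefficient: float = 2.0
    # candidate sites planted per called peak: the top n_peaks candidates by
    # intensity are reported, emulating peak calling on bound-site occupancy
    candidate_factor: int = 2


@dataclass(frozen=True)
class MethylationParams:
    site_spacing: int = 30          # mean bp between CpG sites inside a peak
    beta_a: float = 0.3             # per-peak methylation level ~ Beta(a, b)
    beta_b: float = 0.3
    site_concentration: float = 30.0  # per-site jitter around the peak level
    penalty_coefficient: float = 0.8
    mean_coverage: float = 30.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Full configuration of a simulated study, including the seed."""

    truth_model: EnergyModel = field(default_factory=default_truth_model)
    design: SelexLibraryDesign = FIXED_CORE_8N_CGTG_10N
    selection_rounds: int = 2
    reads_per_round: int = 200_000
    gc_bias: float = 0.0
    peak_params: PeakParams = PeakParams()
    methylation_params: MethylationParams = MethylationParams()
    seed: int = 1

    def __post_init__(self) -> None:
        if self.selection_rounds < 0 or self.reads_per_round <= 0:
            raise ValueError("counts must be positive")
        if not -1 < self.gc_bias < 1:
            raise ValueError("gc_bias must lie in (-1, 1)")

    def with_seed(self, seed: int) -> "SyntheticTruth":
        return replace(self, seed=seed)


def _spawn(seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, label]))


def _draw_round0(truth: SyntheticTruth, rng: np.random.Generator) -> np.ndarray:
    """Round-0 variable regions as a code matrix (fixed core inserted)."""
    n, length = truth.reads_per_round, truth.design.variable_length
    p_gc = (1 + truth.gc_bias) / 4
    p_at = (1 - truth.gc_bias) / 4
    probs = np.array([p_at, p_gc, p_gc, p_at])
    codes = rng.choice(4, size=(n, length), p=probs).astype(np.int8)
    if truth.design.fixed_core is not None:
        core, offset = truth.design.fixed_core
        codes[:, offset:offset + len(core)] = encode_many([core])[0]
    return codes


def _codes_to_readset(codes: np.ndarray, round_index: int,
                      design: SelexLibraryDesign) -> SelexReadSet:
    flat = decode(codes.ravel())
    length = codes.shape[1]
    reads = [flat[i * length:(i + 1) * length] for i in range(codes.shape[0])]
    return SelexReadSet(round_index=round_index, reads=reads, design_ref=design.name)


def simulate_selex(truth: SyntheticTruth) -> dict[int, SelexReadSet]:
    """Simulate SELEX rounds 0..selection_rounds under Boltzmann selection.

    Round r+1 is produced by classical rejection sampling against the truth
    model: molecules are drawn with replacement from the round-r pool and
    accepted with probability W(S)/W_max until reads_per_round have been
    accepted. This samples i.i.d. from the selected distribution
    p_{r+1}(S) proportional to p_r(S) * W(S), mirroring physical selection of
    a bound fraction from a library whose molecule count vastly exceeds the
    sequencing depth. If overall acceptance is below 1e-4 the energies are
    rescaled (softer selection) with a warning rather than looping forever.
    """
    import warnings

    rounds: dict[int, SelexReadSet] = {}
    codes = _draw_round0(truth, _spawn(truth.seed, 0))
    rounds[0] = _codes_to_readset(codes, 0, truth.design)
    model = truth.truth_model
    n = truth.reads_per_round
    for r in range(1, truth.selection_rounds + 1):
        rng = _spawn(truth.seed, r)
        logW = score_sequences(model, codes, aggregation="sum")
        accept_logp = logW - logW.max()
        rate = float(np.exp(accept_logp).mean())
        if rate < 1e-4:
            warnings.warn(f"round {r}: acceptance rate {rate:.2e}; "
                          "rescaling energies for tractable selection")
            accept_logp = accept_logp * (np.log(1e-4) / np.log(max(rate, 1e-300)))
        picked: list[np.ndarray] = []
        n_have = 0
        while n_have < n:
            batch = max(int((n - n_have) / max(rate, 1e-4) * 1.2), 1024)
            batch = min(batch, 20_000_000)
            cand = rng.integers(0, codes.shape[0], size=batch)
            keep = np.log(rng.random(batch)) < accept_logp[cand]
            sel = cand[keep]
            picked.append(sel)
            n_have += sel.size
        chosen = np.concatenate(picked)[:n]
        codes = codes[chosen]
        rounds[r] = _codes_to_readset(codes, r, truth.design)
    return rounds


def mini_truth_model() -> EnergyModel:
    """Small 6-bp truth matrix for the enumerable mini-library checks."""
    rows = {
        "A": [0.00, 0.40, 1.20, 0.30, 0.00, 0.50],
        "C": [0.60, 0.00, 0.80, 0.90, 0.70, 0.00],
        "G": [0.20, 0.80, 0.00, 0.00, 1.10, 0.90],
        "T": [0.90, 0.30, 0.50, 0.60, 0.40, 0.20],
    }
    return EnergyModel(np.array([rows[b] for b in BASES]),
                       metadata={"name": "mini_truth_6bp"})


def mini_library_design() -> SelexLibraryDesign:
    """Enumerable mini-library: 8-mer variable region, fixed CGTGAC core.

    Only positions 0 and 1 are free, so the library has 16 distinct
    sequences and round-1 enrichment can be checked sequence by sequence
    against the exact expectation W(S)/E_0[W].
    """
    return SelexLibraryDesign(variable_length=8, fixed_core=("CGTGAC", 2),
                              name="mini_NNCGTGAC")


def exact_round1_enrichment(model: EnergyModel,
                            sequences: list[str]) -> np.ndarray:
    """Exact one-round enrichment W(S)/E_0[W] for a uniform library.

    The expectation is over a uniform round 0 on exactly `sequences`;
    selection multiplies each sequence's frequency by W(S)/E_0[W].
    """
    logW = score_sequences(model, sequences, aggregation="sum")
    W = np.exp(logW - logW.max())
    return W / W.mean()


@dataclass
class PeakExperiment:
    """Simulated ChIP experiment; unpacks as (genome, peaks, decoys).

    planted_scores holds the max-window log-weight of each called peak's
    planted site (aligned with `peaks`), the quantity intensity is an
    affine function of when noise_sd = 0.
    """

    genome: dict[str, str]
    peaks: list[GenomicInterval]
    decoys: list[GenomicInterval]
    planted_scores: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __iter__(self):
        return iter((self.genome, self.peaks, self.decoys))


def simulate_peak_experiment(truth: SyntheticTruth,
                             chrom: str = "chrSim",
                             spacing: int = 3) -> PeakExperiment:
    """Random genome with planted binding sites and intensity-scored peaks.

    Returns (genome dict, peaks, decoys). candidate_factor * n_peaks sites
    are drawn from the truth model's Boltzmann distribution (positions
    independent under the additive model) and inserted one per candidate
    region; candidate intensity is coefficient * best-window log-weight +
    N(0, noise_sd), and the top n_peaks candidates by intensity are reported
    as called peaks (emulating occupancy-thresholded peak calling), with
    intensities shifted to be positive (affine, order-preserving). Decoy
    regions carry no planted site. Deterministic per seed.
    """
    pp = truth.peak_params
    rng = _spawn(truth.seed, 1001)
    n_cand = pp.n_peaks * pp.candidate_factor
    slot = pp.peak_length * spacing
    genome_len = max((n_cand + pp.n_decoys + 2) * slot, slot * 2)
    genome_codes = rng.integers(0, 4, size=genome_len, dtype=np.int8)

    model = truth.truth_model
    boltz = np.exp(-model.energies)
    boltz /= boltz.sum(axis=0, keepdims=True)

    slots = rng.permutation(n_cand + pp.n_decoys)
    sites = np.stack([rng.choice(4, size=n_cand, p=boltz[:, i])
                      for i in range(model.L)], axis=1).astype(np.int8) \
        if n_cand else np.empty((0, model.L), dtype=np.int8)
    cand_spans: list[tuple[int, int]] = []
    for j in range(n_cand):
        start = slots[j] * slot + (slot - pp.peak_length) // 2
        mid = start + (pp.peak_length - model.L) // 2
        genome_codes[mid:mid + model.L] = sites[j]
        cand_spans.append((start, start + pp.peak_length))
    peaks: list[GenomicInterval] = []
    planted = np.empty(0)
    if n_cand:
        raw_scores = score_sequences(model, sites, "max")
        noise = rng.normal(0.0, pp.intensity_noise_sd, size=n_cand)
        raw = pp.affinity_to_intensity_coefficient * raw_scores + noise
        called = np.sort(np.argsort(raw)[-pp.n_peaks:])
        intensities = raw - raw[called].min() + 1.0
        planted = raw_scores[called]
        for rank, j in enumerate(called):
            start, end = cand_spans[j]
            peaks.append(GenomicInterval(chrom, start, end,
                                         score=float(intensities[j]),
                                         name=f"peak{rank}"))
    decoys: list[GenomicInterval] = []
    for j in range(pp.n_decoys):
        start = slots[n_cand + j] * slot + (slot - pp.peak_length) // 2
        decoys.append(GenomicInterval(chrom, start, start + pp.peak_length,
                                      name=f"decoy{j}"))
    genome = {chrom: decode(genome_codes)}
    return PeakExperiment(genome, peaks, decoys, planted)


def simulate_methylation(truth: SyntheticTruth,
                         peaks: list[GenomicInterval]):
    """Per-CpG methylation calls over peaks plus attenuated intensities.

    Each peak gets a latent methylation level m_p ~ Beta(a, b); site-level
    fractions jitter around m_p with the configured concentration; read
    counts are binomial at Poisson coverage. Peak intensity is multiplied by
    (1 - penalty * m_p), embedding the negative methylation-occupancy
    relationship the downstream regression should recover.
    Returns (calls, adjusted peak list).
    """
    mp = truth.methylation_params
    rng = _spawn(truth.seed, 2002)
    calls: list[MethylationCall] = []
    adjusted: list[GenomicInterval] = []
    for peak in peaks:
        level = rng.beta(mp.beta_a, mp.beta_b)
        n_sites = max(1, int(round(len(peak) / mp.site_spacing)))
        positions = np.sort(rng.choice(len(peak), size=n_sites, replace=False))
        a = 1e-3 + level * mp.site_concentration
        b = 1e-3 + (1 - level) * mp.site_concentration
        site_fracs = rng.beta(a, b, size=n_sites)
        for pos, frac in zip(positions, site_fracs):
            cov = max(int(rng.poisson(mp.mean_coverage)), 12)
            m = int(rng.binomial(cov, frac))
            calls.append(MethylationCall(peak.chrom, peak.start + int(pos),
                                         "+", "CpG", m, cov - m))
        new_score = max((peak.score or 0.0) * (1 - mp.penalty_coefficient * level),
                        1e-3)
        adjusted.append(GenomicInterval(peak.chrom, peak.start, peak.end,
                                        score=new_score, name=peak.name))
    return calls, adjusted
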