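# Methods

This note records the models, estimators, defaults and numerical choices
behind `pasbind`, and what the simulation-based tests do and do not
establish.

## Probe geometry and preprocessing

A SELEX probe is barcode + left flank + variable region + right flank.
Two library geometries are built in: a fully random 18-mer and the
fixed-core 22-mer 8N-CGTG-10N (eight random bases, the invariant CGTG
core, ten random bases). `trim_to_variable` matches the constant parts
within a configurable mismatch budget and, for fixed-core designs,
checks the core at its design offset. `filter_single_core` retains reads
with exactly one core occurrence (counting CGTG and, by default, its
reverse complement CACG on the read strand, since a double-stranded
ligand presents both strands to the dimer; overlapping occurrences count
independently). The filter is an optional pipeline stage — affinity
tables are normally built from single-core-filtered reads so that each
read reports one binding event — and is idempotent.

## Background models and k-mer affinity

Relative affinity of a k-mer after r rounds is
(observed/expected)^(1/r), max-normalised to 1, with a pseudocount
(default 0.5) added to numerator and denominator of the enrichment
ratio. The expectation comes from a model of the unselected round-0
library. Two background families are provided:

- **Homogeneous Markov chain** (`fit_markov_background`). Maximum
  likelihood with add-one smoothing (configurable; 0 gives the
  unsmoothed MLE). The model stores m-mer counts for m ≤ order+1 and
  uses the effective order min(order, k−1), which makes k = order+1
  expectations exact when smoothing is 0. By default the order is
  selected by held-out read log-likelihood on an even/odd split of
  round 0, the behaviour of standard SELEX analysis tooling; an explicit
  order can always be forced.
- **Position-aware independent-base model**
  (`fit_positional_background`). Per-position base frequencies; expected
  k-mer counts sum per-offset window probabilities. A homogeneous chain
  cannot represent a library with positional structure: a low order
  misses the fixed core entirely, while a high order develops
  register-mixing artefacts (sequence contexts that straddle the core
  boundary get implausibly small probabilities, inflating the apparent
  enrichment of k-mers that match them). For designed fixed-core
  libraries the positional model is the generative truth of round 0 and
  is the default in the pipeline; the Markov chain remains the right
  choice for random libraries.

Counting is forward-strand by default (reads are a defined sequenced
strand); reverse-complement aggregation is a flag. Reads containing N
are excluded at counting but retained through I/O. `compare_tables`
correlates affinities over all k-mers shared by two tables (count floor
configurable, default none — every observed k-mer is reported).

At desk-scale depth (2×10⁵ reads/round vs tens of millions in a real
run), single-k-mer ranks are affected by lineage "jackpots": one
strongly selected molecule contributes its passenger flanking k-mers
many times. Aggregate statistics (round-to-round correlation, consensus
over the top core-aligned k-mers, heatmap cells) are robust to this;
individual top ranks on short-read-depth fixed-core tables are not, and
tests of top-rank behaviour therefore use a short random library where
every window spans the whole read.

`annotate_kmer` locates the leftmost NNCGTG (CGTG with two upstream
bases), assigns the bHLH taxonomy — E-box (CACGTG), E-box-like (DNCGTG,
D = A/T/G), and the non-CGTG boxes CACC (CACCTG), CAG (CAGCTG), CAT
(CATATG) — and labels flanks outward (f−4…f−1, f+1…f+8).
`derive_consensus` aligns the top-n core-containing k-mers on their core
and emits per-position IUPAC codes covering bases at ≥ 25% frequency.

## Energy model

Mononucleotide-additive matrix ε(b, i) over a footprint of L positions
(default 12, configurable 10–16 via the sweep utility, which refits
across L and reports held-out log-likelihood). Scoring sums Boltzmann
weights over all length-L windows of flank+S+flank on both strands;
"max" mode returns the best single-window log-weight, "sum" mode
log W(S). N-containing windows carry effectively infinite energy and
drop out. The gauge fixes min_b ε(b, i) = 0 per position after fitting.

Fitting maximises Σ r·logW − N_r·logZ_r − λ‖ε‖² with analytic
per-window softmax gradients and L-BFGS-B (relative objective tolerance
1e-6, max 500 iterations; non-convergence returns the best iterate with
a warning flag). Z_r = E₀[W^r] is estimated on a fixed pool of up to
10⁵ sequences subsampled from the round-0 reads when a round 0 is
supplied — the empirical unselected library is the correct importance
distribution for a structured (fixed-core) library, which a low-order
Markov chain cannot represent — with sampling from a background model as
the fallback. Reads are collapsed to unique sequences with counts before
fitting. Identical inputs and seed reproduce the fit exactly.

Regularisation default λ = 1e-4 (per-read-normalised objective). This is
a shrinkage/variance trade-off: stronger penalties visibly shrink the
3–4 nat core penalties (biasing parameter recovery), weaker ones let the
poorly identified cells (bases rarely seen in selected reads, e.g.
core-position mismatches in a fixed-core library) wander.

Two exact degeneracies matter when comparing matrices. W is invariant
under reverse-complement flipping of ε, and nearly invariant under
translating the matrix along the footprint (the window sum only loses
edge windows). `EnergyModel.alignment_correlation` therefore maximises
the Pearson correlation of overlapping columns over both orientations
and small register shifts, the way motif-comparison tools align motifs,
and reports (r, shift, strand).

`goodness_of_fit` regresses observed log k-mer enrichment on the
model-predicted value (r·logW) by count-weighted least squares — the
observed count approximates the inverse variance of a log count — over
k-mers above a count floor (default 10). k-mers that span whole probes
are scored as-is; shorter k-mers are scored in a background-averaged
context (overhanging window positions contribute the position's log-mean
Boltzmann weight), since inside a real probe such windows see real
bases. The slope is attenuated below 1 when the count floor truncates
noisy low-affinity k-mers; the weighting keeps this mild at adequate
depth.

## Genomic validation

`score_bed` extracts interval sequences (dict-of-strings or pyfaidx
FASTA), scores them in batches grouped by length, records the best
window (offset, strand; ties to the smallest offset then forward
strand), and flags all-N intervals as invalid. `sample_random_regions`
draws length-matched regions uniformly (chromosomes weighted by length),
avoiding N runs and previously placed regions for a bounded number of
retries; GC matching within 10 points is available behind a flag but is
off by default. AUROC is rank-based with ties counting one half (equal
to Mann–Whitney U/(n₁n₂)) with the Hanley–McNeil standard error.
`binned_score_regression` min–max rescales model scores to the 0–10
scale (range recorded in the output for reproducibility, and reusable
across runs), cuts integer-width bins, and regresses mean peak intensity
on bin midpoints by OLS. `model_peak_regression` standardises each
model's scores before regression so coefficients compare across models.
Peak intersection partitions each set into shared/unique by ≥ min_overlap
bp, implemented with interval trees and verified against a quadratic
oracle.

## DNA shape

Shape features use the pentamer-query convention: MGW and ProT belong to
the central base of a 5-mer window; HelT and Roll belong to the two
central base steps, and a genomic step averages the (up to two)
pentamers covering it. The packaged table
(`data/synthetic_pentamer_shape.tsv`) is **synthetic**: it is
regenerated deterministically from an additive model (position-weighted
AT content and W|W-step fraction, plus dinucleotide step means of
crystallographic style, with a per-canonical-pentamer deterministic
perturbation) and has exact reverse-complement symmetry. It reproduces
the qualitative behaviour the profile analyses rely on — A/T-rich
sequence narrows the minor groove and drives propeller twist more
negative — but its absolute values are not simulation-derived, so shape
profiles computed with it support method/logic conclusions, not
structural ones.

Affinity-binned profiles use equal-count deciles by default (equal-width
bins behind a flag) to avoid empty high bins on skewed affinity
distributions. Core alignment requires every sequence's leftmost CGTG at
the same offset. The co-dependency heatmap aggregates affinity (mean by
default, max behind a flag) over base identities at two disjoint
position sets relative to the core; empty cells are NaN, never zero, and
the occupancy-weighted cell mean equals the global mean affinity.

## Methylation

Coverage filtering keeps sites with strictly more than 10 reads
(min_cov = 11). Opposite-strand calls of one CpG dinucleotide are merged
(counts summed) before per-peak averaging; a strand-separate mode
exists. The per-peak summary is the unweighted mean of site percentages
(coverage weighting behind a flag), with classes unmethylated (< 10%),
methylated (> 90%), intermediate, and no_data for siteless peaks.
Binned regression cuts % methylation into equal-width bins over 0–100
and regresses mean peak score on midpoints. The two-group comparison is
Mann–Whitney U with ties counting one half; for n₁·n₂ ≤ 10⁴ the
two-sided p-value is exact, computed by convolving the tie-aware rank
distribution over group assignments (scipy's exact method does not
handle ties), otherwise the tie-corrected normal approximation with
continuity correction is used.

## Synthetic data

The generator's defaults are the study conditions: fixed-core
8N-CGTG-10N library, rounds 0–2, 2×10⁵ reads per round, no GC bias, and
a planted 12-bp TACGTG-preferring truth matrix (strong core penalties
2–4 nat, graded flank preferences ≤ 1 nat with an AT-leaning downstream
flank). Selection is classical rejection sampling: molecules are drawn
with replacement from the previous round and accepted with probability
W(S)/W_max until the target depth is reached, which samples i.i.d. from
p_{r+1} ∝ p_r·W — mirroring physical selection of a bound fraction
whose molecule count vastly exceeds sequencing depth — and satisfies the
exact relation E[round-1 enrichment] = W(S)/E₀[W], verified
sequence-by-sequence on an enumerable 16-sequence mini-library (8-bp
variable region with a fixed CGTGAC core; the library is kept this small
so that a 3-standard-error criterion applied to every sequence has a
high joint pass probability). Sequencing error is not simulated
(analyses operate post-quality-filter); an optional uniform substitution
rate could be added without changing interfaces.

The peak simulator plants Boltzmann-distributed sites (positions
independent under the additive model) one per candidate region in a
random genome, sets candidate intensity = 2 × best-window log-weight +
N(0, 1), and reports the top half of candidates by intensity as called
peaks (candidate_factor = 2), emulating occupancy-thresholded peak
calling — without this, the called set would contain weakly bound sites
that no peak caller would report, and model-vs-peak AUROC saturates
around 0.8 rather than reflecting peak-calling practice. Intensities are
shifted to be positive (affine, order-preserving). Decoy regions carry
no planted site. The methylation simulator draws a per-peak level from
Beta(0.3, 0.3) (bimodal, so both extreme classes are populated), jitters
per-site fractions around it (concentration 30), draws binomial counts
at Poisson(30) coverage, and multiplies peak intensity by
(1 − 0.8 × level).

What passing tests show: the estimators recover planted truth under the
generative assumptions they encode (additive energies, independent
per-position site composition, multiplicative selection, multiplicative
methylation penalty). What they do not show: robustness to PCR bias,
duplicate-read structure, chromatin accessibility confounding,
sequence-dependent sequencing error, or real DNA-shape values — none of
which the generator emulates.

## Problem sizes

Defaults used by the test suite and the acceptance script: 2×10⁵
reads/round for study-scale checks (fit ≈ 1 min on one CPU), 2×10⁴ for
unit-level checks, 500 peaks + 500 decoys for validation, 1000 peaks ×
100 seeded replicates for the methylation sign-recovery rate, 10⁵-size
importance pools. These sizes were chosen so each statistic's sampling
noise is small relative to the effect it measures.
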