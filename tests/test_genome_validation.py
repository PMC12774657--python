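import numpy as np
import pytest

from pasbind.energy_model import EnergyModel, score_sequence
from pasbind.genome_validation import (ScoredRegionSet, auroc,
                                       binned_score_regression,
                                       intersect_peaks, model_peak_regression,
                                       sample_random_regions, score_bed)
from pasbind.io_formats import GenomicInterval

from _oracles import auroc_bruteforce, intersect_bruteforce


def _intervals(rng, n, chrom="chr1", max_start=10_000, min_len=20, max_len=120):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_start))
        out.append(GenomicInterval(chrom, start,
                                   start + int(rng.integers(min_len, max_len))))
    return out


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([2, 3], [0, 1])[0] == 1.0

    def test_all_ties(self):
        assert auroc([1.0] * 5, [1.0] * 7)[0] == 0.5

    def test_mixed(self):
        assert auroc([3, 1], [2, 0])[0] == 0.75  # 3/4 winning pairs

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            pos = rng.choice(np.arange(10), size=rng.integers(2, 30)).tolist()
            neg = rng.choice(np.arange(10), size=rng.integers(2, 30)).tolist()
            assert auroc(pos, neg)[0] == pytest.approx(
                auroc_bruteforce(pos, neg))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])


class TestScoreBed:
    def test_consensus_best_site(self, truth_model):
        cons = truth_model.consensus()
        genome = {"chr1": "A" * 40 + cons + "A" * 40}
        ivs = [GenomicInterval("chr1", 20, 80)]
        scored = score_bed(truth_model, genome, ivs)
        assert scored.best_sites[0] == (20, "+")  # consensus at 40 - 20
        assert scored.scores[0] == pytest.approx(0.0)

    def test_all_N_interval_flagged(self, truth_model):
        genome = {"chr1": "N" * 100}
        scored = score_bed(truth_model, genome, [GenomicInterval("chr1", 0, 50)])
        assert not scored.valid_mask()[0]

    def test_consistency_with_score_sequence(self, rng, truth_model):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        ivs = _intervals(rng, 20, max_start=1800, min_len=30, max_len=100)
        scored = score_bed(truth_model, genome, ivs)
        for iv, s in zip(ivs, scored.scores):
            seq = genome["chr1"][iv.start:iv.end]
            assert s == pytest.approx(score_sequence(truth_model, seq, "max"))

    def test_missing_chromosome_error(self, truth_model):
        with pytest.raises(KeyError, match="chrX"):
            score_bed(truth_model, {"chr1": "A" * 100},
                      [GenomicInterval("chrX", 0, 50)])

    def test_planted_affinity_ranking(self):
        from pasbind.synthetic_data import (SyntheticTruth, PeakParams,
                                            simulate_peak_experiment)
        truth = SyntheticTruth(seed=9, peak_params=PeakParams(
            n_peaks=100, n_decoys=0, intensity_noise_sd=0.0))
        exp = simulate_peak_experiment(truth)
        scored = score_bed(truth.truth_model, exp.genome, exp.peaks)
        # max-mode peak scores track planted-site affinity: never below the
        # planted score, and strongly rank-correlated with it
        assert (scored.scores >= exp.planted_scores - 1e-9).all()
        r = np.corrcoef(scored.scores, exp.planted_scores)[0, 1]
        assert r > 0.95


class TestRandomRegions:
    def test_single_template(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        out = sample_random_regions(genome, [GenomicInterval("chrA", 0, 200)],
                                    seed=1)
        assert len(out) == 1 and len(out[0]) == 200

    def test_length_multiset_conserved(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 200_000))}
        template = _intervals(rng, 300, max_start=100)
        out = sample_random_regions(genome, template, seed=2)
        assert sorted(len(t) for t in template) == sorted(len(o) for o in out)

    def test_determinism_and_seed_sensitivity(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}
        template = _intervals(rng, 50, max_start=100)
        a = sample_random_regions(genome, template, seed=5)
        b = sample_random_regions(genome, template, seed=5)
        c = sample_random_regions(genome, template, seed=6)
        assert [(x.start, x.end) for x in a] == [(x.start, x.end) for x in b]
        assert [(x.start, x.end) for x in a] != [(x.start, x.end) for x in c]

    def test_avoids_N_runs(self):
        genome = {"chr1": "N" * 4000 + "ACGT" * 2000}
        out = sample_random_regions(genome, [GenomicInterval("c", 0, 100)] * 20,
                                    seed=0)
        for iv in out:
            assert iv.start >= 4000


class TestBinnedRegression:
    def _scored(self, scores, intensities):
        ivs = [GenomicInterval("chr1", i * 10, i * 10 + 5, score=float(v))
               for i, v in enumerate(intensities)]
        return ScoredRegionSet(ivs, np.asarray(scores, dtype=float))

    def test_planted_linearity(self, rng):
        scores = rng.uniform(0, 10, 500)
        scored = self._scored(scores, 2 * scores)
        reg = binned_score_regression(scored, score_range=(0.0, 10.0))
        assert reg.slope == pytest.approx(2.0, abs=0.1)
        assert reg.pvalue < 1e-6

    def test_independent_intensity_flat(self, rng):
        scores = rng.uniform(0, 10, 2000)
        scored = self._scored(scores, rng.normal(5, 1, 2000))
        reg = binned_score_regression(scored, score_range=(0.0, 10.0))
        assert abs(reg.slope) < 0.15

    def test_too_few_bins_error(self, rng):
        scored = self._scored([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            binned_score_regression(scored)

    def test_bin_occupancy_reported(self, rng):
        scores = rng.uniform(0, 10, 100)
        reg = binned_score_regression(self._scored(scores, scores),
                                      score_range=(0.0, 10.0))
        assert reg.bins["n"].sum() == 100


class TestModelPeakRegression:
    def test_duplicate_model_identical_coefficients(self, rng):
        scores = rng.normal(size=50)
        ivs = [GenomicInterval("chr1", i, i + 5, score=float(abs(s) + 1))
               for i, s in enumerate(scores)]
        srs = ScoredRegionSet(ivs, scores)
        out = model_peak_regression({"m1": srs, "m2": srs}).set_index("model")
        assert out.loc["m1", "coefficient"] == out.loc["m2", "coefficient"]

    def test_truth_beats_decoy_on_simulation(self, truth_model):
        from pasbind.synthetic_data import (SyntheticTruth, PeakParams,
                                            simulate_peak_experiment)
        truth = SyntheticTruth(seed=21,
                               peak_params=PeakParams(n_peaks=200, n_decoys=0))
        genome, peaks, _ = simulate_peak_experiment(truth)
        scored_truth = score_bed(truth.truth_model, genome, peaks, model_id="t")
        decoy = truth.truth_model.shuffled(seed=2)
        scored_decoy = score_bed(decoy, genome, peaks, model_id="d")
        out = model_peak_regression(
            {"t": scored_truth, "d": scored_decoy}).set_index("model")
        assert out.loc["t", "coefficient"] > out.loc["d", "coefficient"]

    def test_mismatched_sets_error(self, rng):
        a = ScoredRegionSet([GenomicInterval("c", 0, 5, score=1.0)], [1.0])
        b = ScoredRegionSet([GenomicInterval("c", 5, 9, score=1.0)], [1.0])
        with pytest.raises(ValueError):
            model_peak_regression({"a": a, "b": b})

    def test_single_interval_error(self):
        a = ScoredRegionSet([GenomicInterval("c", 0, 5, score=1.0)], [1.0])
        with pytest.raises(ValueError):
            model_peak_regression({"a": a})


class TestIntersection:
    def test_identical_sets_all_shared(self, rng):
        ivs = _intervals(rng, 30)
        res = intersect_peaks(ivs, list(ivs))
        assert len(res.shared_a) == 30 and not res.unique_a

    def test_disjoint_chromosomes_all_unique(self, rng):
        a = _intervals(rng, 10, chrom="chr1")
        b = _intervals(rng, 10, chrom="chr2")
        res = intersect_peaks(a, b)
        assert not res.shared_a and len(res.unique_b) == 10

    def test_matches_quadratic_oracle(self, rng):
        a = _intervals(rng, 500)
        b = _intervals(rng, 500)
        res = intersect_peaks(a, b, min_overlap=5)
        sa, ua, sb, ub = intersect_bruteforce(a, b, min_overlap=5)
        assert res.shared_a == sa and res.unique_a == ua
        assert res.shared_b == sb and res.unique_b == ub

    def test_partition_exhaustive_exclusive(self, rng):
        a = _intervals(rng, 100)
        b = _intervals(rng, 100)
        res = intersect_peaks(a, b)
        assert len(res.shared_a) + len(res.unique_a) == len(a)
        assert not set(map(id, res.shared_a)) & set(map(id, res.unique_a))
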