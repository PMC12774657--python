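import numpy as np
import pytest

from pasbind._seq import revcomp
from pasbind.energy_model import (EnergyModel, energy_logo, fit_energy_model,
                                  goodness_of_fit, score_kmer_space,
                                  score_sequence, score_sequences,
                                  window_weight)
from pasbind.io_formats import SelexReadSet
from pasbind.kmer_affinity import build_affinity_table, fit_markov_background
from pasbind.synthetic_data import SyntheticTruth, simulate_selex

from _oracles import window_weight_bruteforce


def _random_model(rng, L=12, flanks=("", "")):
    eps = rng.uniform(0, 3, size=(4, L))
    return EnergyModel(eps, left_flank=flanks[0], right_flank=flanks[1])


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestWindowWeight:
    def test_zero_model_length_L(self):
        m = EnergyModel(np.zeros((4, 12)))
        W, (off, strand) = window_weight(m, "ACGTACGTACGT")
        assert W == pytest.approx(2.0)        # one window x two strands
        assert (off, strand) == (0, "+")      # tie broken to forward

    def test_zero_model_length_L_plus_3(self):
        m = EnergyModel(np.zeros((4, 12)))
        W, _ = window_weight(m, "ACGTACGTACGTAAA")
        assert W == pytest.approx(8.0)        # 4 windows x 2 strands

    @pytest.mark.parametrize("flanks", [("", ""), ("TGG", "CCA")])
    def test_matches_bruteforce_enumeration(self, rng, flanks):
        for _ in range(10):
            m = _random_model(rng, flanks=flanks)
            seq = _random_seq(rng, 30)
            W, _ = window_weight(m, seq)
            W_brute, best_brute = window_weight_bruteforce(
                m.energies, seq, *flanks)
            assert W == pytest.approx(W_brute, rel=1e-10)
            assert score_sequence(m, seq, "max") == pytest.approx(best_brute)
            assert score_sequence(m, seq, "sum") == pytest.approx(np.log(W_brute))

    def test_sum_bounds_max(self, rng):
        m = _random_model(rng)
        for _ in range(20):
            s = _random_seq(rng, 25)
            assert score_sequence(m, s, "sum") >= score_sequence(m, s, "max")

    def test_too_short_error(self):
        m = EnergyModel(np.zeros((4, 12)))
        with pytest.raises(ValueError):
            window_weight(m, "ACGT")

    def test_strand_symmetry_empty_flanks(self, rng):
        m = _random_model(rng)
        for _ in range(20):
            s = _random_seq(rng, 28)
            W1, _ = window_weight(m, s)
            W2, _ = window_weight(m, revcomp(s))
            assert W1 == pytest.approx(W2, rel=1e-12)

    def test_gauge_invariance(self, rng):
        # per-position constants shift log W uniformly; rankings unchanged
        m = _random_model(rng)
        shifts = rng.uniform(-1, 1, size=12)
        m2 = EnergyModel(m.energies + shifts[None, :])
        seqs = [_random_seq(rng, 22) for _ in range(50)]
        s1 = score_sequences(m, seqs, "sum")
        s2 = score_sequences(m2, seqs, "sum")
        rel = (s1 - shifts.sum()) - s2
        assert np.abs(rel).max() < 1e-9

    def test_n_windows_excluded(self):
        m = EnergyModel(np.zeros((4, 4)))
        score = score_sequence(m, "NNNNACGT", "max")
        assert np.isfinite(score)
        assert score_sequence(m, "NNNNNNN", "max") == -np.inf


class TestScoreKmerSpace:
    def test_pattern_counts(self):
        m = EnergyModel(np.zeros((4, 12)))
        out = score_kmer_space(m, "NNNCANNTGNNN")
        assert len(out) == 4 ** 8  # 65,536 12-mers

    def test_fixed_pattern_single_score(self, rng):
        m = _random_model(rng)
        out = score_kmer_space(m, "ACGTACGTACGTA")
        assert len(out) == 1
        assert out["score"].iloc[0] == pytest.approx(
            score_sequence(m, "ACGTACGTACGTA", "max"))

    def test_oversized_pattern_error(self):
        m = EnergyModel(np.zeros((4, 12)))
        with pytest.raises(ValueError, match="chunk"):
            score_kmer_space(m, "N" * 13)


class TestFit:
    def test_null_recovery(self):
        # no selection signal -> fitted energies near zero at study depth
        truth = SyntheticTruth(truth_model=EnergyModel(np.zeros((4, 12))),
                               reads_per_round=200_000, seed=3)
        rounds = simulate_selex(truth)
        model = fit_energy_model(list(rounds.values()), L=12, seed=0)
        assert np.abs(model.energies).max() < 0.1

    def test_regularisation_monotone(self, small_rounds):
        rounds = [small_rounds[0], small_rounds[1]]
        norms = []
        for lam in (1e-4, 2e-4, 4e-4):
            m = fit_energy_model(rounds, L=12, lam=lam, seed=0, pool_size=5000)
            norms.append(np.linalg.norm(m.energies))
        assert norms[0] >= norms[1] >= norms[2]

    def test_fit_determinism(self, small_rounds):
        rounds = [small_rounds[0], small_rounds[1]]
        m1 = fit_energy_model(rounds, L=12, seed=4, pool_size=5000)
        m2 = fit_energy_model(rounds, L=12, seed=4, pool_size=5000)
        assert np.array_equal(m1.energies, m2.energies)

    def test_gauge_applied(self, small_rounds):
        m = fit_energy_model([small_rounds[0], small_rounds[1]], L=12,
                             seed=0, pool_size=5000)
        assert np.allclose(m.energies.min(axis=0), 0)

    def test_small_scale_recovery_with_alignment(self, small_rounds,
                                                 small_truth, truth_model):
        model = fit_energy_model(list(small_rounds.values()), L=12, seed=0,
                                 pool_size=20000)
        r, shift, strand = model.alignment_correlation(truth_model)
        assert r > 0.9

    def test_needs_selected_round(self, small_rounds):
        with pytest.raises(ValueError):
            fit_energy_model([small_rounds[0]], L=12)


class TestGoodnessOfFit:
    def test_self_consistency_and_slope(self, random10_truth, random10_rounds):
        # truth model vs its own simulated table: strong weighted r^2 and a
        # near-unit slope of observed on predicted log enrichment
        bg = fit_markov_background(random10_rounds[0], order=2)
        table = build_affinity_table(random10_rounds[2], bg, k=10, r=2)
        r2, slope = goodness_of_fit(random10_truth.truth_model, table)
        assert r2 >= 0.9
        assert 0.9 <= slope <= 1.1

    def test_too_few_kmers_error(self, truth_model):
        import pandas as pd
        from pasbind.kmer_affinity import KmerAffinityTable
        df = pd.DataFrame({"kmer": ["ACGTACGTACGT"], "obs": [100],
                           "expected": [1.0], "enrichment": [100.0],
                           "affinity": [1.0]})
        with pytest.raises(ValueError):
            goodness_of_fit(truth_model, KmerAffinityTable(12, 1, df))

    def test_degenerate_flat_warns(self, rng):
        import pandas as pd
        from pasbind.kmer_affinity import KmerAffinityTable
        kmers = ["".join(rng.choice(list("ACGT"), 6)) for _ in range(20)]
        df = pd.DataFrame({"kmer": kmers, "obs": [50] * 20,
                           "expected": [50.0] * 20, "enrichment": [1.0] * 20,
                           "affinity": [1.0] * 20})
        zero = EnergyModel(np.zeros((4, 6)))
        with pytest.warns(UserWarning):
            r2, slope = goodness_of_fit(zero, KmerAffinityTable(6, 1, df))
        assert np.isnan(r2)


class TestModelUtilities:
    def test_serialisation_roundtrip(self, rng, tmp_path):
        m = _random_model(rng, flanks=("TGG", "CCA"))
        path = tmp_path / "model.json"
        m.to_json(path)
        back = EnergyModel.from_json(path)
        assert np.array_equal(back.energies, m.energies)
        assert (back.left_flank, back.right_flank) == ("TGG", "CCA")

    def test_revcomp_flip_preserves_W(self, rng):
        m = _random_model(rng)
        flipped = m.revcomp_flipped()
        for _ in range(10):
            s = _random_seq(rng, 20)
            assert window_weight(m, s)[0] == pytest.approx(
                window_weight(flipped, s)[0], rel=1e-12)

    def test_oriented_like_resolves_flip(self, rng):
        m = _random_model(rng)
        assert np.array_equal(
            m.revcomp_flipped().oriented_like(m).energies, m.energies)

    def test_logo_consensus_zero(self, truth_model):
        logo = energy_logo(truth_model)
        assert np.allclose(logo.max(axis=1), 0)

    def test_shuffled_decoy_same_multiset(self, truth_model):
        decoy = truth_model.shuffled(seed=1)
        assert sorted(decoy.energies.ravel()) == \
            sorted(truth_model.energies.ravel())
        assert not np.array_equal(decoy.energies, truth_model.energies)
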