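import numpy as np
import pytest

from pasbind._seq import encode_many
from pasbind.io_formats import SelexReadSet
from pasbind.kmer_affinity import (KmerAffinityTable, annotate_kmer,
                                   build_affinity_table, count_kmers,
                                   derive_consensus, expected_kmer_count,
                                   fit_markov_background, indices_to_kmers,
                                   normalize_zscore, select_markov_order)

from _oracles import kmer_counts_bruteforce


def _random_reads(rng, n, length=18):
    return ["".join(rng.choice(list("ACGT"), length)) for _ in range(n)]


class TestMarkovBackground:
    def test_order0_uniform(self, rng):
        rs = SelexReadSet(0, _random_reads(rng, 3000))
        bg = fit_markov_background(rs, order=0)
        probs = np.exp(bg.log_prob_codes(np.eye(1, 4, k=0, dtype=np.int8).T))
        for b in range(4):
            p = np.exp(bg.log_prob_codes(np.array([[b]], dtype=np.int8)))[0]
            assert p == pytest.approx(0.25, abs=0.02)

    def test_all_A_degenerate(self):
        rs = SelexReadSet(0, ["A" * 18] * 100)
        bg = fit_markov_background(rs, order=0)
        p_a = np.exp(bg.log_prob_codes(np.array([[0]], dtype=np.int8)))[0]
        assert 0.99 < p_a < 1.0  # 1 minus add-one smoothing

    def test_planted_dinucleotide_bias_recovered(self, rng):
        # generate from a known first-order chain, refit, compare transitions
        T = np.array([[0.55, 0.15, 0.15, 0.15],
                      [0.10, 0.40, 0.40, 0.10],
                      [0.25, 0.25, 0.25, 0.25],
                      [0.05, 0.15, 0.30, 0.50]])
        n, length = 20000, 20
        reads = np.empty((n, length), dtype=np.int8)
        reads[:, 0] = rng.integers(0, 4, n)
        for j in range(1, length):
            u = rng.random(n)
            cum = np.cumsum(T, axis=1)
            reads[:, j] = (u[:, None] > cum[reads[:, j - 1]]).sum(1)
        lut = np.array(list("ACGT"))
        rs = SelexReadSet(0, ["".join(lut[row]) for row in reads])
        bg = fit_markov_background(rs, order=1, smoothing=0.0)
        fitted = bg.transition_probabilities.to_numpy()
        assert np.abs(fitted - T).max() < 0.01

    def test_order_ge_read_length_error(self):
        with pytest.raises(ValueError):
            fit_markov_background(SelexReadSet(0, ["ACGT"]), order=4)

    def test_auto_order_detects_fixed_core(self, small_rounds):
        order = select_markov_order(small_rounds[0])
        assert order >= 3  # fixed CGTG core needs a longer context

    def test_sampling_matches_model(self, rng):
        rs = SelexReadSet(0, _random_reads(rng, 2000))
        bg = fit_markov_background(rs, order=1)
        draw = bg.sample_codes(5000, 18, np.random.default_rng(1))
        freqs = np.bincount(draw.ravel(), minlength=4) / draw.size
        assert np.abs(freqs - 0.25).max() < 0.02


class TestExpectedCounts:
    def test_closed_form_uniform(self, rng):
        rs = SelexReadSet(0, _random_reads(rng, 5000))
        bg = fit_markov_background(rs, order=0)
        exp = expected_kmer_count(bg, k=4, n_reads=10, read_length=18)
        assert exp.sum() == pytest.approx(10 * 15, rel=1e-6)
        assert exp.loc["ACGT"] == pytest.approx(10 * 15 / 256, rel=0.1)

    def test_k_equals_read_length_one_window(self, rng):
        rs = SelexReadSet(0, _random_reads(rng, 500, length=6))
        bg = fit_markov_background(rs, order=0)
        exp = expected_kmer_count(bg, k=6, n_reads=100, read_length=6)
        assert exp.sum() == pytest.approx(100, rel=1e-6)

    def test_order1_vs_sampling_oracle(self, rng):
        T_rs = SelexReadSet(0, _random_reads(rng, 4000))
        bg = fit_markov_background(T_rs, order=1)
        # Monte-Carlo oracle: sample reads from the model, count 3-mers
        n_mc, length = 100_000, 12
        draws = bg.sample_codes(n_mc, length, np.random.default_rng(7))
        idx = draws[:, :-2] * 16 + draws[:, 1:-1] * 4 + draws[:, 2:]
        mc = np.bincount(idx.ravel(), minlength=64) / idx.size
        model = expected_kmer_count(bg, 3, n_mc, length) / (n_mc * (length - 2))
        assert np.abs(mc - model.to_numpy()).max() < 4 / np.sqrt(n_mc)

    def test_sum_invariant(self, rng):
        rs = SelexReadSet(0, _random_reads(rng, 2000))
        bg = fit_markov_background(rs, order=2)
        exp = expected_kmer_count(bg, k=5, n_reads=777, read_length=18)
        assert exp.sum() == pytest.approx(777 * 14, rel=1e-6)


class TestAffinityTable:
    def test_counting_matches_bruteforce(self, rng):
        reads = _random_reads(rng, 2000, length=15) + ["ACGTNACGTACGTAC"]
        idx, counts = count_kmers(reads, k=5)
        got = dict(zip(indices_to_kmers(idx, 5), counts))
        assert got == dict(kmer_counts_bruteforce(reads, 5))

    def test_round0_self_enrichment_exact(self, rng):
        # round 0 against itself: exact 1 at k = order+1, no smoothing,
        # no pseudocount
        rs = SelexReadSet(0, _random_reads(rng, 3000))
        bg = fit_markov_background(rs, order=2, smoothing=0.0)
        table = build_affinity_table(rs, bg, k=3, r=1, pseudocount=0.0)
        assert np.allclose(table.df["enrichment"], 1.0)

    def test_affinity_normalisation_and_monotonicity(self, small_rounds):
        bg = fit_markov_background(small_rounds[0], order=2)
        table = build_affinity_table(small_rounds[2], bg, k=8, r=2)
        df = table.df
        assert df["affinity"].max() == pytest.approx(1.0)
        assert (df["affinity"] > 0).all()
        # affinity strictly increasing in enrichment at fixed r
        srt = df.sort_values("enrichment")
        assert (np.diff(srt["affinity"]) >= -1e-12).all()
        assert np.allclose(srt["affinity"],
                           srt["enrichment"] ** 0.5 / df["enrichment"].max() ** 0.5)

    def test_selection_enriches_planted_core(self, random10_rounds):
        # random library selected for TACGTG: top-affinity 10-mer carries it
        bg = fit_markov_background(random10_rounds[0], order=2)
        table = build_affinity_table(random10_rounds[2], bg, k=10, r=2)
        assert "TACGTG" in table.df["kmer"].iloc[0]

    def test_positional_background_exact_for_fixed_core(self, small_rounds):
        # expected counts from the positional model match the design:
        # the core positions are (near-)deterministic in round 0
        from pasbind.kmer_affinity import fit_positional_background
        bg = fit_positional_background(small_rounds[0])
        assert bg.position_frequencies[8].argmax() == 1   # C
        assert bg.position_frequencies[9].argmax() == 2   # G
        assert bg.position_frequencies[8][1] > 0.99
        table = build_affinity_table(small_rounds[2], bg, k=8, r=2)
        assert (table.df["expected"] > 0).all()

    def test_r_lt_1_rejected(self, small_rounds):
        bg = fit_markov_background(small_rounds[0], order=1)
        with pytest.raises(ValueError):
            build_affinity_table(small_rounds[0], bg, k=6)


class TestAnnotation:
    @pytest.mark.parametrize("kmer,offset,c1c2,cls,flanks", [
        ("GGTACGTGAC", 2, "TA", "E-box-like", {"f-1": "G", "f+1": "A"}),
        ("CACGTG", 0, "CA", "E-box", {}),
        ("AACAGCTGAA", 2, "CA", "CAG-box", {}),
    ])
    def test_examples(self, kmer, offset, c1c2, cls, flanks):
        ann = annotate_kmer(kmer)
        assert ann.core_offset == offset
        assert ann.c1c2 == c1c2
        assert ann.core_class == cls
        for label, base in flanks.items():
            assert ann.flank_labels[label] == base

    def test_no_core(self):
        assert annotate_kmer("AAAAAAAA").core_class == "none"

    def test_leftmost_core_wins(self):
        ann = annotate_kmer("AACGTGACGTGA")
        assert ann.core_offset == 0


class TestZscore:
    def test_simple(self):
        assert normalize_zscore([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_warns_zeros(self):
        with pytest.warns(UserWarning):
            out = normalize_zscore([5, 5, 5])
        assert np.allclose(out, 0)

    def test_output_standardised(self, rng):
        out = normalize_zscore(rng.normal(3, 7, size=200))
        assert out.mean() == pytest.approx(0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1)


class TestConsensus:
    def test_single_kmer_verbatim(self):
        import pandas as pd
        df = pd.DataFrame({"kmer": ["GGTACGTGAC"], "obs": [10],
                           "expected": [1.0], "enrichment": [10.0],
                           "affinity": [1.0]})
        table = KmerAffinityTable(k=10, round_index=1, df=df)
        assert derive_consensus(table) == "GGTACGTGAC"

    def test_simulation_truth_consensus(self, small_rounds):
        bg = fit_markov_background(small_rounds[0])
        table = build_affinity_table(small_rounds[2], bg, k=10, r=2)
        assert "TACGTG" in derive_consensus(table, top_n=30)

    def test_npas4_class_truth(self):
        # GTCGTG-preferring truth on a random library recovers its core
        from pasbind.energy_model import EnergyModel
        from pasbind.selex_preprocess import RANDOM_18MER
        from pasbind.synthetic_data import SyntheticTruth, simulate_selex
        eps = np.full((4, 8), 2.0)
        for i, b in enumerate("AGTCGTGA"):
            eps["ACGT".index(b), i] = 0.0
        truth = SyntheticTruth(truth_model=EnergyModel(eps),
                               design=RANDOM_18MER, selection_rounds=2,
                               reads_per_round=15_000, seed=5)
        rounds = simulate_selex(truth)
        bg = fit_markov_background(rounds[0])
        table = build_affinity_table(rounds[2], bg, k=10, r=2)
        assert "GTCGTG" in derive_consensus(table, top_n=30)

    def test_no_core_error(self):
        import pandas as pd
        df = pd.DataFrame({"kmer": ["AAAAAAAA", "TTTTTTTT"], "obs": [5, 4],
                           "expected": [1.0, 1.0], "enrichment": [5.0, 4.0],
                           "affinity": [1.0, 0.8]})
        with pytest.raises(ValueError):
            derive_consensus(KmerAffinityTable(k=8, round_index=1, df=df))
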