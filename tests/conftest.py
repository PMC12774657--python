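import numpy as np
import pytest

from pasbind.synthetic_data import (PeakParams, SyntheticTruth, default_truth_model,
                                    simulate_selex)


@pytest.fixture(scope="session")
def truth_model():
    return default_truth_model().gauged()


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-depth study configuration for unit tests (fast)."""
    return SyntheticTruth(seed=11, reads_per_round=20_000,
                          peak_params=PeakParams(n_peaks=150, n_decoys=150))


@pytest.fixture(scope="session")
def small_rounds(small_truth):
    return simulate_selex(small_truth)


@pytest.fixture(scope="session")
def random10_truth():
    """Random 10-mer library selected by an 8-bp TACGTG-preferring truth.

    Every k=10 window spans the whole read, so k-mer enrichments relate to
    window weights without register or hitchhiker effects - the cleanest
    setting for table-vs-model consistency checks.
    """
    from pasbind.energy_model import EnergyModel
    from pasbind.selex_preprocess import SelexLibraryDesign

    eps = np.zeros((4, 8))
    flank_pen = [0.0, 0.3, 0.15, 0.45]
    for i, b in enumerate("NTACGTGN"):
        for code in range(4):
            if b == "N":
                eps[code, i] = flank_pen[code]
            else:
                eps[code, i] = 0.0 if code == "ACGT".index(b) else 2.0
    truth_model = EnergyModel(eps, metadata={"name": "truth_TACGTG_8bp"})
    design = SelexLibraryDesign(variable_length=10, name="random10")
    return SyntheticTruth(truth_model=truth_model, design=design,
                          reads_per_round=200_000, selection_rounds=2,
                          seed=17)


@pytest.fixture(scope="session")
def random10_rounds(random10_truth):
    return simulate_selex(random10_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
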