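import numpy as np
import pytest

from triald import estimator, simulate, theory


@pytest.fixture
def small_cohort():
    """A small two-reference cohort from a one-pulse history (fixed seed)."""
    rng = np.random.default_rng(20240914)
    sc = simulate.SimScenario(
        history=theory.AdmixtureHistory.one_pulse(0.3, 5, 400),
        n_haplotypes=20,
        n_chromosomes=3,
        n_sites=120,
        fst=0.9,
        n_ref1=60,
        n_ref2=60,
    )
    panel, freqs, truth = simulate.simulate_cohort(sc, rng)
    return panel, freqs, truth


@pytest.fixture
def toy_panel():
    """Tiny hand-sized haplotype panel on two chromosomes."""
    rng = np.random.default_rng(7)
    n, S = 8, 30
    H = rng.integers(0, 2, size=(n, S)).astype(float)
    positions = np.concatenate([np.sort(rng.uniform(0, 0.5, 15)) for _ in range(2)])
    chrom = np.repeat(["1", "2"], 15)
    panel = estimator.GenotypePanel(H, positions, chrom)
    delta = rng.uniform(-1, 1, S)
    f = np.clip(0.5 + delta / 2, 0, 1)
    g = np.clip(0.5 - delta / 2, 0, 1)
    freqs = estimator.FrequencyPanel(f, g)
    return panel, freqs
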