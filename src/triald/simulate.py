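"""Forward simulation of admixed cohorts with known admixture history.

Implements the random-union-of-gametes population model that the analytic
theory describes: a panmictic pool of ``2N`` haploid chromosomes in which
each offspring chromosome is a mosaic copied from the previous generation,
with ancestry junctions arriving as a Poisson process of rate 1 per Morgan
and each junction switching to a freshly drawn uniform parent.  Migrant
pulses replace a fraction of chromosomes with pure second-source material.
Ancestry is tracked at the marker positions where genotypes will later be
drawn, so a haplotype's record is its local-ancestry mosaic sampled at
those markers.

Allele frequencies in the two source populations follow a Balding-Nichols
divergence model around a shared ancestral frequency; the single
divergence parameter controls E[(f - g)^2], the cube of which scales the
weighted-LD surface amplitude.

Also provides :func:`mc_state_oracle`, a Monte-Carlo estimate of the
three-point ancestry covariance obtained by simulating the three-marker
chromosome-arrangement process directly with the same per-generation
transition probabilities the transfer matrices encode - an arithmetic
cross-check on the matrix-product predictions that shares no code with
them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .estimator import FrequencyPanel, GenotypePanel, allele_freq_deltas
from .theory import AdmixtureHistory

__all__ = [
    "SimScenario",
    "simulate_ancestry_tracts",
    "draw_genotypes",
    "simulate_cohort",
    "mc_state_oracle",
]


@dataclass(frozen=True)
class SimScenario:
    """Study design for a synthetic admixed cohort.

    Defaults follow the verification design used throughout the tests:
    50 diploid admixed individuals (100 haplotypes) and 50 diploids per
    reference panel, 20 chromosomes of 1 Morgan, haploid population size
    2N = 1000, and strongly diverged sources (Balding-Nichols F = 0.98,
    emulating two populations separated for several N generations).
    """

    history: AdmixtureHistory = field(
        default_factory=lambda: AdmixtureHistory.one_pulse(0.3, 10, 1000)
    )
    n_haplotypes: int = 100
    n_chromosomes: int = 20
    chrom_length: float = 1.0  # Morgans
    n_sites: int = 300  # per chromosome
    fst: float = 0.98  # Balding-Nichols divergence of the two sources
    n_ref1: int = 100  # reference haplotypes, first source
    n_ref2: int = 100

    def __post_init__(self) -> None:
        if min(self.n_haplotypes, self.n_chromosomes, self.n_sites) < 1:
            raise ValueError("all counts must be positive")
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("divergence parameter must lie in [0, 1)")
        if math.isinf(self.history.N2):
            raise ValueError("forward simulation needs a finite population size")


def _evolve_chromosome(
    history: AdmixtureHistory,
    positions: np.ndarray,
    n_sample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-simulate one chromosome; returns n_sample x S ancestry in {0,1}."""
    N2 = int(history.N2)
    S = positions.size
    q = 1.0 - history.m.get(history.T, 0.0)
    pop = (rng.random(N2) < q).astype(np.uint8)[:, None] * np.ones(S, dtype=np.uint8)
    keep = np.exp(-np.diff(positions))  # P(no junction) per inter-marker interval
    cols = np.arange(S)
    for i in range(history.T - 1, -1, -1):
        switch = np.empty((N2, S), dtype=bool)
        switch[:, 0] = True  # initial parent draw
        switch[:, 1:] = rng.random((N2, S - 1)) >= keep
        draws = rng.integers(0, N2, size=(N2, S))
        last = np.maximum.accumulate(np.where(switch, cols, 0), axis=1)
        parent = np.take_along_axis(draws, last, axis=1)
        pop = pop[parent, cols]
        mi = history.m.get(i, 0.0)
        if mi > 0.0:
            pop[rng.random(N2) < mi, :] = 0
    idx = rng.choice(N2, size=n_sample, replace=False)
    return pop[idx]


def simulate_ancestry_tracts(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Ancestry mosaics for a sample of haplotypes, at random marker positions.

    Returns per-chromosome lists of (n_haplotypes x n_sites) {0,1} ancestry
    matrices (1 = first source) and of sorted marker positions in Morgans.
    Chromosomes evolve independently, as they do in the analytic model.
    """
    if scenario.n_haplotypes > scenario.history.N2:
        raise ValueError("cannot sample more haplotypes than the population holds")
    ancestries, positions = [], []
    for _ in range(scenario.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, scenario.chrom_length, scenario.n_sites))
        anc = _evolve_chromosome(scenario.history, pos, scenario.n_haplotypes, rng)
        ancestries.append(anc)
        positions.append(pos)
    return ancestries, positions


def _source_frequencies(
    n_sites: int, fst: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols draw of (f, g) around a shared ancestral frequency."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    if fst == 0.0:
        return p, p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    f = rng.beta(a, b)
    g = rng.beta(a, b)
    return f, g


def draw_genotypes(
    ancestries: list[np.ndarray],
    positions: list[np.ndarray],
    scenario: SimScenario,
    rng: np.random.Generator,
    diploid: bool = False,
) -> tuple[GenotypePanel, FrequencyPanel, dict]:
    """Drop alleles onto ancestry mosaics and draw reference panels.

    Each sampled allele is Bernoulli(f) or Bernoulli(g) according to its
    local ancestry, independently across sites given the mosaics.  With
    ``diploid=True`` consecutive haplotypes are paired into {0, 1/2, 1}
    genotypes.  Returns the admixed panel, reference-estimated frequencies,
    and a truth dict with the per-site source frequencies and deltas.
    """
    H_parts, F_parts, G_parts, f_true, g_true, chrom_labels = [], [], [], [], [], []
    for ci, (anc, pos) in enumerate(zip(ancestries, positions)):
        S = pos.size
        f, g = _source_frequencies(S, scenario.fst, rng)
        pr = np.where(anc == 1, f, g)
        H_parts.append((rng.random(anc.shape) < pr).astype(float))
        F_parts.append((rng.random((scenario.n_ref1, S)) < f).astype(float))
        G_parts.append((rng.random((scenario.n_ref2, S)) < g).astype(float))
        f_true.append(f)
        g_true.append(g)
        chrom_labels.append(np.full(S, str(ci + 1)))
    H = np.concatenate(H_parts, axis=1)
    if diploid:
        H = 0.5 * (H[0::2] + H[1::2])
    panel = GenotypePanel(
        H,
        np.concatenate(positions),
        np.concatenate(chrom_labels),
        sample_ids=[f"adm{i}" for i in range(H.shape[0])],
    )
    freqs = allele_freq_deltas(np.concatenate(F_parts, axis=1), np.concatenate(G_parts, axis=1))
    truth = {
        "f": np.concatenate(f_true),
        "g": np.concatenate(g_true),
        "delta": np.concatenate(f_true) - np.concatenate(g_true),
        "F": np.concatenate(F_parts, axis=1),
        "G": np.concatenate(G_parts, axis=1),
    }
    return panel, freqs, truth


def simulate_cohort(
    scenario: SimScenario, rng: np.random.Generator, diploid: bool = False
) -> tuple[GenotypePanel, FrequencyPanel, dict]:
    """End-to-end cohort: ancestry mosaics plus genotypes and references."""
    ancestries, positions = simulate_ancestry_tracts(scenario, rng)
    panel, freqs, truth = draw_genotypes(ancestries, positions, scenario, rng, diploid)
    truth["ancestries"] = ancestries
    return panel, freqs, truth


def mc_state_oracle(
    history: AdmixtureHistory,
    d: float,
    dp: float,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Monte-Carlo cov(A_x, A_y, A_z) by simulating the 3-marker process.

    Evolves, in each replicate, a population of 2N chromosomes carrying
    just the three markers.  Each offspring draws two uniform parents; the
    x-y interval recombines with probability 1 - e^{-d} and the y-z
    interval with 1 - e^{-d'}, segments alternating between the two
    parents; migrant replacement zeroes whole chromosomes.

    The estimand is the expected *within-population* covariance - the
    population three-point central moment of a single drift realization,
    averaged over realizations.  That is what the matrix product predicts
    (its drift attenuation lives in the coupled two- and three-chromosome
    moments) and what the sample k-statistic estimates.  Each replicate
    therefore yields one within-population covariance, and the function
    returns their mean and standard error.
    """
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    if math.isinf(history.N2):
        raise ValueError("state oracle needs a finite population size")
    N2 = int(history.N2)
    R = n_reps
    q = 1.0 - history.m.get(history.T, 0.0)
    base = (rng.random((R, N2)) < q).astype(np.uint8)
    pop = np.repeat(base[:, :, None], 3, axis=2)  # chromosomes are pure at founding
    p1j = 1.0 - math.exp(-d)
    p2j = 1.0 - math.exp(-dp)
    for i in range(history.T - 1, -1, -1):
        P1 = rng.integers(0, N2, size=(R, N2))
        P2 = rng.integers(0, N2, size=(R, N2))
        j1 = rng.random((R, N2)) < p1j
        j2 = rng.random((R, N2)) < p2j
        ix = P1
        iy = np.where(j1, P2, P1)
        iz = np.where(j2, P1 + P2 - iy, iy)
        new = np.empty_like(pop)
        new[:, :, 0] = np.take_along_axis(pop[:, :, 0], ix, axis=1)
        new[:, :, 1] = np.take_along_axis(pop[:, :, 1], iy, axis=1)
        new[:, :, 2] = np.take_along_axis(pop[:, :, 2], iz, axis=1)
        pop = new
        mi = history.m.get(i, 0.0)
        if mi > 0.0:
            pop[rng.random((R, N2)) < mi, :] = 0

    A = pop.astype(float)
    mxyz = (A[:, :, 0] * A[:, :, 1] * A[:, :, 2]).mean(axis=1)
    mxy = (A[:, :, 0] * A[:, :, 1]).mean(axis=1)
    mxz = (A[:, :, 0] * A[:, :, 2]).mean(axis=1)
    myz = (A[:, :, 1] * A[:, :, 2]).mean(axis=1)
    mx, my, mz = (A[:, :, k].mean(axis=1) for k in range(3))
    cov_r = mxyz - mxy * mz - mxz * my - myz * mx + 2 * mx * my * mz
    if R == 1:
        return float(cov_r[0]), float("nan")
    return float(cov_r.mean()), float(cov_r.std(ddof=1) / math.sqrt(R))
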