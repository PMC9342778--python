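"""Weighted 3-locus LD estimator: oracle equivalence and invariances."""

import numpy as np
import pytest

from triald import estimator, simulate, theory
from triald.estimator import FrequencyPanel, GenotypePanel


def brute_force_surface(panel, freqs, bin_width, P):
    """Independent triple-loop oracle, written without any shared machinery."""
    n = panel.n
    h = panel.H.mean(axis=0)
    delta = freqs.delta
    num = np.zeros((P + 1, P + 1))
    den = np.zeros((P + 1, P + 1))
    for c in set(panel.chrom.tolist()):
        idx = [i for i in range(panel.S) if panel.chrom[i] == c]
        bins = [int(np.floor(panel.positions[i] / bin_width)) for i in idx]
        for a in range(len(idx)):
            for b in range(len(idx)):
                for cc in range(len(idx)):
                    d = bins[b] - bins[a]
                    dp = bins[cc] - bins[b]
                    if d < 1 or dp < 1 or d > P or dp > P:
                        continue
                    x, y, z = idx[a], idx[b], idx[cc]
                    s = 0.0
                    for i in range(n):
                        s += (
                            (panel.H[i, x] - h[x])
                            * (panel.H[i, y] - h[y])
                            * (panel.H[i, z] - h[z])
                        )
                    num[d, dp] += delta[x] * delta[y] * delta[z] * s
                    den[d, dp] += 1
    with np.errstate(invalid="ignore"):
        vals = n / ((n - 1) * (n - 2)) * num / den
    return vals, den


class TestPanels:
    def test_alphabet_enforced(self):
        with pytest.raises(ValueError):
            GenotypePanel(np.array([[0.3, 1.0]]), [0.1, 0.2], ["1", "1"])

    def test_positions_sorted_within_chromosome(self):
        with pytest.raises(ValueError):
            GenotypePanel(np.zeros((3, 2)), [0.2, 0.1], ["1", "1"])
        # sorted within each chromosome is enough; across chromosomes free
        GenotypePanel(np.zeros((3, 4)), [0.1, 0.2, 0.05, 0.3], ["1", "1", "2", "2"])

    def test_frequency_panel_range(self):
        with pytest.raises(ValueError):
            FrequencyPanel(np.array([1.2]), np.array([0.5]))


class TestFrequencies:
    def test_allele_freq_deltas_extremes(self):
        F = np.ones((4, 3))
        G = np.zeros((5, 3))
        fr = estimator.allele_freq_deltas(F, G)
        np.testing.assert_allclose(fr.delta, 1.0)
        fr = estimator.allele_freq_deltas(G, G)
        np.testing.assert_allclose(fr.delta, 0.0)
        assert fr.n1 == 5 and fr.n2 == 5

    def test_allele_freq_deltas_recovers_truth(self, small_cohort):
        _, freqs, truth = small_cohort
        # binomial sampling error with n_ref haplotypes
        se = np.sqrt(0.5 * 0.5 / 60) * 2 * 4  # generous 4-sigma band
        assert np.max(np.abs(freqs.delta - truth["delta"])) < se

    def test_mismatched_site_sets_rejected(self):
        with pytest.raises(ValueError):
            estimator.allele_freq_deltas(np.ones((2, 3)), np.ones((2, 4)))

    def test_maf_filter_counts(self):
        # admixed frequencies (0.0, 0.04, 0.05, 0.5, 0.96): minor allele
        # frequencies are (0, 0.04, 0.05, 0.5, 0.04), so exactly the sites
        # at h = 0.05 and h = 0.5 survive a 0.05 threshold
        freqs = [0.0, 0.04, 0.05, 0.5, 0.96]
        H = np.array([[0, 0, 0, 0, 1]] * 100, dtype=float)
        for j, f in enumerate(freqs):
            H[: int(round(f * 100)), j] = 1.0
        H[:, 4] = 1.0
        H[: int(round(0.04 * 100)), 4] = 0.0
        panel = GenotypePanel(H, np.linspace(0, 1, 5), ["1"] * 5)
        kept, mask = estimator.maf_filter(panel, 0.05)
        assert kept.S == 2
        assert mask.tolist() == [False, False, True, True, False]
        same, _ = estimator.maf_filter(panel, 0.0)
        assert same.S == 5

    def test_missing_source_one_pulse_relation(self):
        # with M1 = 0 the mixture is h = f (1-M2) + g M2; solving for f
        # recovers it exactly
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 1, 50)
        g = rng.uniform(0, 1, 50)
        M2 = 0.3
        h = f * (1 - M2) + g * M2
        fr, nclip = estimator.missing_source_freqs(h, g, "second", 0.0, M2)
        np.testing.assert_allclose(fr.f, f, atol=1e-12)
        assert nclip == 0

    def test_missing_source_two_pulse_total_proportion(self):
        # two pulses enter only through M = M1(1-M2)+M2
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 1, 30)
        g = rng.uniform(0, 1, 30)
        M1, M2 = 0.3, 0.2
        M = M1 * (1 - M2) + M2
        h = f * (1 - M) + g * M
        fr, _ = estimator.missing_source_freqs(h, f, "first", M1, M2)
        np.testing.assert_allclose(fr.g, g, atol=1e-12)

    def test_missing_source_degenerate_well_mixed(self):
        h = np.array([0.25, 0.7])
        fr, _ = estimator.missing_source_freqs(h, h, "second", 0.1, 0.2)
        np.testing.assert_allclose(fr.f, h, atol=1e-12)

    def test_missing_source_singular_proportion(self):
        with pytest.raises(ValueError):
            estimator.missing_source_freqs(np.array([0.5]), np.array([0.5]), "second", 0.0, 0.0)


class TestSurfaceEstimators:
    def test_direct_matches_brute_force(self, toy_panel):
        panel, freqs = toy_panel
        s = estimator.direct_weighted_ld3(panel, freqs, 0.05, 8)
        vals, den = brute_force_surface(panel, freqs, 0.05, 8)
        m = den > 0
        np.testing.assert_allclose(s.values[m], vals[m], rtol=1e-10)
        np.testing.assert_allclose(s.counts[1:, 1:], den[1:, 1:])

    def test_fft_matches_direct(self, small_cohort):
        panel, freqs, _ = small_cohort
        sf = estimator.fft_weighted_ld3(panel, freqs, 0.01, 20)
        sd = estimator.direct_weighted_ld3(panel, freqs, 0.01, 20)
        scale = np.nanmax(np.abs(sd.values))
        m = np.isfinite(sd.values)
        assert np.allclose(sf.values[m], sd.values[m], atol=1e-10 * scale, rtol=1e-8)
        np.testing.assert_allclose(sf.den[1:, 1:], sd.den[1:, 1:], atol=1e-6)

    def test_zero_weights_give_zero_surface(self, toy_panel):
        panel, _ = toy_panel
        freqs = FrequencyPanel(np.full(panel.S, 0.4), np.full(panel.S, 0.4))
        s = estimator.fft_weighted_ld3(panel, freqs, 0.05, 8)
        m = np.isfinite(s.values)
        np.testing.assert_allclose(s.values[m], 0.0, atol=1e-15)

    def test_monomorphic_chromosome_contributes_zero(self, toy_panel):
        panel, freqs = toy_panel
        H = panel.H.copy()
        H[:, panel.chrom == "2"] = 1.0
        pan2 = GenotypePanel(H, panel.positions, panel.chrom)
        s = estimator.fft_weighted_ld3(pan2, freqs, 0.05, 8)
        np.testing.assert_allclose(s.num_by_chrom["2"], 0.0, atol=1e-12)

    def test_cubic_scaling_in_delta(self, toy_panel):
        panel, freqs = toy_panel
        s1 = estimator.fft_weighted_ld3(panel, freqs, 0.05, 8)
        # halving every delta scales the numerator by (1/2)^3
        kappa = 0.5
        freqs2 = FrequencyPanel(0.5 + kappa * freqs.delta / 2, 0.5 - kappa * freqs.delta / 2)
        np.testing.assert_allclose(freqs2.delta, kappa * freqs.delta, atol=1e-12)
        s2 = estimator.fft_weighted_ld3(panel, freqs2, 0.05, 8)
        np.testing.assert_allclose(s2.num, kappa**3 * s1.num, rtol=1e-9, atol=1e-14)

    def test_sample_permutation_invariance(self, toy_panel):
        panel, freqs = toy_panel
        perm = np.random.default_rng(3).permutation(panel.n)
        s1 = estimator.fft_weighted_ld3(panel, freqs, 0.05, 8)
        s2 = estimator.fft_weighted_ld3(panel.subset_samples(perm), freqs, 0.05, 8)
        np.testing.assert_allclose(s1.num, s2.num, atol=1e-12)

    def test_minimum_sample_size(self, toy_panel):
        panel, freqs = toy_panel
        with pytest.raises(ValueError):
            estimator.fft_weighted_ld3(panel.subset_samples(np.arange(2)), freqs, 0.05, 8)

    def test_bin_occupancy_conserved(self, small_cohort):
        panel, freqs, _ = small_cohort
        seqs = estimator.bin_sequences(panel, freqs, 0.01, 20)
        total = sum(cnt.sum() for _, cnt, _ in seqs.values())
        assert total == panel.S


class TestSplitHalf:
    def test_reproducible_under_seed(self, small_cohort):
        panel, freqs, truth = small_cohort
        args = (panel, truth["g"], "second", 0.0, 0.3, 0.01, 15)
        s1 = estimator.split_half_weighted_ld3(*args, np.random.default_rng(5))
        s2 = estimator.split_half_weighted_ld3(*args, np.random.default_rng(5))
        np.testing.assert_allclose(s1.num, s2.num)

    def test_split_debiasing_matches_independent_weights(self):
        """The split-half surface has the same expectation as an estimate
        whose weights come from samples fully disjoint from the LD panel -
        i.e. the cross-over averaging removes the own-sample coupling.
        (Frequency clipping in the missing-source solve attenuates both
        identically, so it cancels in this comparison.)"""
        rng = np.random.default_rng(99)
        h = theory.AdmixtureHistory.one_pulse(0.3, 4, 4000)
        sc = simulate.SimScenario(
            history=h, n_haplotypes=200, n_chromosomes=2, n_sites=100, fst=0.9,
            n_ref1=200, n_ref2=200,
        )
        diff, scale = [], []
        for _ in range(25):
            panel, freqs, truth = simulate.simulate_cohort(sc, rng)
            ssh = estimator.split_half_weighted_ld3(
                panel.subset_samples(np.arange(100)),
                truth["g"], "second", 0.0, 0.3, 0.02, 8, rng,
            )
            # reference: weights from haplotypes 150:200, LD from 100:150
            h_w = panel.H[150:200].mean(axis=0)
            fr, _ = estimator.missing_source_freqs(h_w, truth["g"], "second", 0.0, 0.3)
            sref = estimator.fft_weighted_ld3(
                panel.subset_samples(np.arange(100, 150)), fr, 0.02, 8
            )
            m = np.isfinite(sref.values) & np.isfinite(ssh.values)
            diff.append(np.nanmean(ssh.values[m] - sref.values[m]))
            scale.append(np.nanmean(np.abs(sref.values[m])))
        bias = abs(np.mean(diff))
        se = np.std(diff, ddof=1) / np.sqrt(len(diff))
        assert bias < max(3 * se, 0.03 * np.mean(scale))


class TestAffineBackground:
    def test_panmictic_background_near_zero(self, small_cohort):
        panel, freqs, _ = small_cohort
        rng = np.random.default_rng(17)
        val, se = estimator.affine_background(panel, freqs, 40_000, rng)
        assert abs(val) < 5 * se + 1e-4

    def test_substructure_inflates_background(self):
        # two unadmixed strata mixed 50/50: every chromosome carries the
        # stratum signal, so cross-chromosome three-way covariance is non-zero
        rng = np.random.default_rng(23)
        n, S = 40, 90
        chrom = np.repeat(["1", "2", "3"], S // 3)
        positions = np.tile(np.sort(rng.uniform(0, 1, S // 3)), 3)
        f = np.full(S, 0.9)
        g = np.full(S, 0.1)
        strata = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        pr = np.where(strata[:, None] == 0, f, g)
        H = (rng.random((n, S)) < pr).astype(float)
        panel = GenotypePanel(H, positions, chrom)
        freqs = FrequencyPanel(f, g)
        val, se = estimator.affine_background(panel, freqs, 40_000, rng)
        assert abs(val) > 5 * se

    def test_requires_three_chromosomes(self, toy_panel):
        panel, freqs = toy_panel
        with pytest.raises(ValueError):
            estimator.affine_background(panel, freqs, 100, np.random.default_rng(0))

    def test_reproducible_under_seed(self, small_cohort):
        panel, freqs, _ = small_cohort
        v1, _ = estimator.affine_background(panel, freqs, 10_000, np.random.default_rng(4))
        v2, _ = estimator.affine_background(panel, freqs, 10_000, np.random.default_rng(4))
        assert v1 == v2
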