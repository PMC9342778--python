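"""Weighted three-locus LD surfaces from genotype or haplotype panels.

The statistic is the three-way covariance of admixed genotype values at
site triples, weighted by the product of between-source allele-frequency
differences delta = f - g, averaged over triples whose two inter-site
genetic distances fall in the same (d, d') bin:

    a_hat[d, d'] = mean over triples of
        delta_x delta_y delta_z * k3(H_x, H_y, H_z)

where ``k3`` is the unbiased three-variate k-statistic
``n * sum_i (H_ix - h_x)(H_iy - h_y)(H_iz - h_z) / ((n-1)(n-2))`` and ``h``
is the empirical admixed allele frequency.  Triples are confined to a
single chromosome.  The surface is proportional to the expected
three-point local-ancestry covariance times E[delta^2]^3, so its shape
carries the admixture-time information.

Two implementations are provided: an exact cubic-time reference
(:func:`direct_weighted_ld3`) and the production estimator
(:func:`fft_weighted_ld3`) which bins sites and evaluates the triple
correlation sums with FFTs, linear in the number of sites.  Both assign a
triple to the bin pair given by the differences of the sites' bin indices,
so they agree to floating-point rounding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "FrequencyPanel",
    "WeightedLDSurface",
    "allele_freq_deltas",
    "maf_filter",
    "missing_source_freqs",
    "direct_weighted_ld3",
    "bin_sequences",
    "fft_weighted_ld3",
    "split_half_weighted_ld3",
    "affine_background",
]


@dataclass
class GenotypePanel:
    """Admixed-sample value matrix with per-site genetic coordinates.

    ``H`` is ``n x S`` with entries in {0, 1} (haplotypes) or {0, 1/2, 1}
    (genotypes); ``positions`` are Morgans, non-decreasing within each
    chromosome; ``chrom`` holds per-site chromosome labels.
    """

    H: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    sample_ids: list[str] | None = None
    bp: np.ndarray | None = None  # original base-pair coordinates, if known

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.chrom = np.asarray(self.chrom)
        if self.H.ndim != 2:
            raise ValueError("H must be a 2-D (samples x sites) matrix")
        if self.H.shape[1] != self.positions.size or self.positions.size != self.chrom.size:
            raise ValueError("H, positions and chrom disagree on the number of sites")
        vals = self.H[np.isfinite(self.H)]
        if vals.size and not np.isin(vals, [0.0, 0.5, 1.0]).all():
            raise ValueError("panel values must come from {0, 1/2, 1}")
        for c in np.unique(self.chrom):
            p = self.positions[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions on chromosome {c!r} are not sorted")

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def S(self) -> int:
        return self.H.shape[1]

    @property
    def chromosomes(self) -> list:
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def admixed_freq(self) -> np.ndarray:
        """Empirical allele frequency ``h_x`` per site."""
        return self.H.mean(axis=0)

    def subset_sites(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.H[:, mask],
            self.positions[mask],
            self.chrom[mask],
            self.sample_ids,
            None if self.bp is None else self.bp[mask],
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypePanel":
        ids = None if self.sample_ids is None else [self.sample_ids[i] for i in idx]
        return GenotypePanel(self.H[idx], self.positions, self.chrom, ids, self.bp)


@dataclass
class FrequencyPanel:
    """Per-site source allele frequencies and their difference delta = f - g."""

    f: np.ndarray
    g: np.ndarray
    n1: int | None = None
    n2: int | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.f.shape != self.g.shape:
            raise ValueError("f and g must have the same length")
        for name, a in (("f", self.f), ("g", self.g)):
            if np.any((a < 0) | (a > 1)):
                raise ValueError(f"{name} contains values outside [0, 1]")

    @property
    def delta(self) -> np.ndarray:
        return self.f - self.g

    def subset(self, mask: np.ndarray) -> "FrequencyPanel":
        return FrequencyPanel(self.f[mask], self.g[mask], self.n1, self.n2)


@dataclass
class WeightedLDSurface:
    """Binned a_hat[d, d'] grid with per-chromosome partial sums.

    ``num``/``den`` are ``(P+1) x (P+1)`` aggregated numerator and
    triple-count grids indexed by bin-lag pairs; lag ``i`` corresponds to a
    genetic distance of ``i * bin_width`` Morgans.  Row and column 0 mix
    same-bin site pairs and are never reported.  ``bias`` is the
    k-statistic factor already applied to ``num`` scaling (kept separate so
    leave-one-chromosome surfaces can be rebuilt by subtraction).
    """

    bin_width: float
    P: int
    n: int
    bias: float
    num: np.ndarray
    den: np.ndarray
    num_by_chrom: dict = field(default_factory=dict)
    den_by_chrom: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        """a_hat grid; NaN where undefined (lag 0 or empty bins)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.bias * self.num / self.den
        v[self.den <= 0] = np.nan
        v[0, :] = np.nan
        v[:, 0] = np.nan
        return v

    @property
    def counts(self) -> np.ndarray:
        return self.den

    @property
    def distances(self) -> np.ndarray:
        """Representative genetic distance (Morgans) for each bin lag."""
        return np.arange(self.P + 1) * self.bin_width

    @property
    def chromosomes(self) -> list:
        return list(self.num_by_chrom)

    def drop_chromosome(self, label) -> "WeightedLDSurface":
        """Leave-one-chromosome surface, rebuilt from cached partial sums."""
        if label not in self.num_by_chrom:
            raise KeyError(f"no partial sums stored for chromosome {label!r}")
        if len(self.num_by_chrom) < 2:
            raise ValueError("cannot drop the only chromosome")
        num = {c: v for c, v in self.num_by_chrom.items() if c != label}
        den = {c: v for c, v in self.den_by_chrom.items() if c != label}
        return WeightedLDSurface(
            self.bin_width,
            self.P,
            self.n,
            self.bias,
            self.num - self.num_by_chrom[label],
            self.den - self.den_by_chrom[label],
            num,
            den,
        )


def allele_freq_deltas(F: np.ndarray, G: np.ndarray) -> FrequencyPanel:
    """Estimate per-site source frequencies from two reference panels.

    ``F`` and ``G`` are samples-by-sites matrices over the same site set;
    missing values may be NaN but a site must be observed in both panels.
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if F.shape[1] != G.shape[1]:
        raise ValueError("reference panels cover different site sets")
    with np.errstate(invalid="ignore"):
        f = np.nanmean(F, axis=0)
        g = np.nanmean(G, axis=0)
    if np.isnan(f).any() or np.isnan(g).any():
        raise ValueError("some sites have no observed alleles in a reference panel")
    return FrequencyPanel(f, g, n1=F.shape[0], n2=G.shape[0])


def maf_filter(
    panel: GenotypePanel, threshold: float
) -> tuple[GenotypePanel, np.ndarray]:
    """Drop sites whose admixed minor allele frequency is below ``threshold``.

    Returns the filtered panel and the boolean site mask, so that frequency
    panels can be subset consistently.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    h = panel.admixed_freq
    mask = np.minimum(h, 1.0 - h) >= threshold
    return panel.subset_sites(mask), mask


def missing_source_freqs(
    h: np.ndarray,
    known: np.ndarray,
    which_known: str,
    M1: float,
    M2: float,
) -> tuple[FrequencyPanel, int]:
    """Reconstruct the unavailable source's allele frequencies.

    The admixed frequency is the ancestry-weighted mixture
    ``h = f (1-M) + g M`` with total second-source proportion
    ``M = M1 (1-M2) + M2`` (for two pulses the per-pulse fractions enter
    only through ``M``).  Solves for whichever source is missing; results
    are clipped to [0, 1] and the number of clipped sites is returned.

    ``which_known`` is ``"first"`` (f available, solve for g) or
    ``"second"`` (g available, solve for f).
    """
    h = np.asarray(h, dtype=float)
    known = np.asarray(known, dtype=float)
    M = M1 * (1.0 - M2) + M2
    if not 0.0 < M < 1.0:
        raise ValueError(f"total admixture proportion M={M} must lie strictly in (0, 1)")
    if which_known == "first":
        f = known
        g = (h - f * (1.0 - M)) / M
    elif which_known == "second":
        g = known
        f = (h - g * M) / (1.0 - M)
    else:
        raise ValueError("which_known must be 'first' or 'second'")
    n_clipped = int(np.sum((f < 0) | (f > 1) | (g < 0) | (g > 1)))
    if n_clipped:
        logger.info("missing-source solve clipped %d site frequencies to [0, 1]", n_clipped)
    return FrequencyPanel(np.clip(f, 0.0, 1.0), np.clip(g, 0.0, 1.0)), n_clipped


def _bias_factor(n: int) -> float:
    if n < 3:
        raise ValueError("three-point estimation needs at least 3 samples")
    return n / ((n - 1.0) * (n - 2.0))


def _bin_indices(positions: np.ndarray, bin_width: float) -> np.ndarray:
    return np.floor(positions / bin_width).astype(np.int64)


def direct_weighted_ld3(
    panel: GenotypePanel,
    freqs: FrequencyPanel,
    bin_width: float,
    P: int,
) -> WeightedLDSurface:
    """Exact cubic-time reference estimator (small panels only).

    Enumerates every within-chromosome site triple with strictly increasing
    bin indices and accumulates it at the bin-lag pair; the FFT estimator
    reproduces these sums exactly.
    """
    bias = _bias_factor(panel.n)
    delta = freqs.delta
    R = panel.H - panel.admixed_freq
    shape = (P + 1, P + 1)
    num_by, den_by = {}, {}
    for c in panel.chromosomes:
        sel = np.flatnonzero(panel.chrom == c)
        bidx = _bin_indices(panel.positions[sel], bin_width)
        Rc, dc = R[:, sel], delta[sel]
        S = sel.size
        num = np.zeros(shape)
        den = np.zeros(shape)
        for ix in range(S):
            # G[y, z] = sum_i R_ix R_iy R_iz
            G = (Rc * Rc[:, [ix]]).T @ Rc
            dlag = bidx - bidx[ix]
            ys = np.flatnonzero(dlag >= 1)
            if ys.size == 0:
                continue
            for iy in ys:
                d = dlag[iy]
                if d > P:
                    continue
                dplag = bidx - bidx[iy]
                zs = np.flatnonzero((dplag >= 1) & (dplag <= P))
                if zs.size == 0:
                    continue
                w = dc[ix] * dc[iy] * dc[zs]
                np.add.at(num[d], dplag[zs], w * G[iy, zs])
                np.add.at(den[d], dplag[zs], 1.0)
        num_by[c] = num
        den_by[c] = den
    num_tot = sum(num_by.values())
    den_tot = sum(den_by.values())
    return WeightedLDSurface(bin_width, P, panel.n, bias, num_tot, den_tot, num_by, den_by)


def bin_sequences(
    panel: GenotypePanel,
    freqs: FrequencyPanel,
    bin_width: float,
    P: int,
) -> dict:
    """Per-chromosome binned weighted-residual sequences and bin counts.

    For each chromosome returns ``(b, c, L)``: ``b[i, w]`` is the sum of
    ``delta_x (H_ix - h_x)`` over sites in bin ``w``, ``c[w]`` the bin
    occupancy, both zero-padded to FFT length ``L`` chosen so that triple
    correlations up to lag ``2 P`` are free of circular wrap-around.
    """
    if P < 1:
        raise ValueError("need at least one bin lag")
    delta = freqs.delta
    W = delta * (panel.H - panel.admixed_freq)
    out = {}
    for c in panel.chromosomes:
        sel = np.flatnonzero(panel.chrom == c)
        bidx = _bin_indices(panel.positions[sel], bin_width)
        bidx = bidx - bidx.min()
        B = int(bidx.max()) + 1
        L = next_fast_len(B + 2 * P)
        b = np.zeros((panel.n, L))
        np.add.at(b.T, bidx, W[:, sel].T)
        cnt = np.zeros(L)
        cnt[:B] = np.bincount(bidx, minlength=B)
        out[c] = (b, cnt, L)
    return out


def _triple_corr(b: np.ndarray, P: int, L: int) -> np.ndarray:
    """sum_w b[., w] b[., w+d] b[., w+d+d'] summed over rows, for lags 0..P.

    Computed as P+1 cross-correlations: with u_d[w] = b[w] b[w+d], the inner
    sum is the correlation of u_d with b at lag d+d'.
    """
    rows, _ = b.shape
    Fb = rfft(b, n=L, axis=-1)
    U = np.zeros((rows, P + 1, L))
    B = b.shape[1]
    for d in range(min(P, B - 1) + 1):
        U[:, d, : B - d] = b[:, : B - d] * b[:, d:]
    acc = (np.conj(rfft(U, n=L, axis=-1)) * Fb[:, None, :]).sum(axis=0)
    corr = irfft(acc, n=L, axis=-1)  # corr[d, t] = sum_w u_d[w] b[w + t]
    lags = np.arange(P + 1)
    cols = lags[:, None] + lags[None, :]  # t = d + d'
    return np.take_along_axis(corr, cols, axis=1)


def fft_weighted_ld3(
    panel: GenotypePanel,
    freqs: FrequencyPanel,
    bin_width: float,
    P: int,
) -> WeightedLDSurface:
    """FFT-accelerated weighted 3-locus LD surface.

    Bins each chromosome, forms the per-sample triple correlation of the
    weighted residual sequence and the triple correlation of the bin-count
    sequence, and divides.  Runtime O(S n + n P L log L) per chromosome with
    L the padded FFT length; per-chromosome numerators and denominators are
    cached for the leave-one-chromosome jackknife.
    """
    bias = _bias_factor(panel.n)
    seqs = bin_sequences(panel, freqs, bin_width, P)
    num_by, den_by = {}, {}
    for c, (b, cnt, L) in seqs.items():
        num_by[c] = _triple_corr(b, P, L)
        den_by[c] = np.round(_triple_corr(cnt[None, :], P, L))
    num_tot = sum(num_by.values())
    den_tot = sum(den_by.values())
    return WeightedLDSurface(bin_width, P, panel.n, bias, num_tot, den_tot, num_by, den_by)


def split_half_weighted_ld3(
    panel: GenotypePanel,
    known: np.ndarray,
    which_known: str,
    M1: float,
    M2: float,
    bin_width: float,
    P: int,
    rng: np.random.Generator,
) -> WeightedLDSurface:
    """Missing-source surface with split-half de-biasing.

    When the admixed samples themselves enter the weight estimate (through
    the missing-source solve), using the same samples for the weights and
    the LD coefficients couples the two and biases the product.  The panel
    is therefore split into random halves: each half's frequencies feed the
    weights applied to the *other* half's LD estimate, and the two unbiased
    surfaces are averaged.
    """
    n = panel.n
    if n < 6:
        raise ValueError("split-half estimation needs at least 6 samples")
    perm = rng.permutation(n)
    half_a, half_b = perm[: n // 2], perm[n // 2 :]
    surfaces = []
    for weights_half, ld_half in ((half_a, half_b), (half_b, half_a)):
        h_w = panel.H[weights_half].mean(axis=0)
        fr, _ = missing_source_freqs(h_w, known, which_known, M1, M2)
        surfaces.append(fft_weighted_ld3(panel.subset_samples(ld_half), fr, bin_width, P))
    s1, s2 = surfaces
    num_by = {
        c: 0.5 * (s1.bias * s1.num_by_chrom[c] + s2.bias * s2.num_by_chrom[c])
        for c in s1.num_by_chrom
    }
    den_by = s1.den_by_chrom  # same sites in both halves
    return WeightedLDSurface(
        bin_width, P, n, 1.0, sum(num_by.values()), sum(den_by.values()), num_by, den_by
    )


def affine_background(
    panel: GenotypePanel,
    freqs: FrequencyPanel,
    n_triples: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Substructure baseline from cross-chromosome site triples.

    Population substructure adds a distance-independent offset to the
    weighted LD; it is estimated as the mean weighted three-way covariance
    over random triples drawn from three distinct chromosomes (which share
    no linkage).  Returns ``(baseline, standard_error)``; the SE treats the
    sampled triples as independent, which overlapping sites make slightly
    optimistic.
    """
    rng = np.random.default_rng() if rng is None else rng
    chroms = panel.chromosomes
    if len(chroms) < 3:
        raise ValueError("affine background needs sites on at least 3 chromosomes")
    bias = _bias_factor(panel.n)
    sites_by_chrom = [np.flatnonzero(panel.chrom == c) for c in chroms]
    R = panel.H - panel.admixed_freq
    delta = freqs.delta
    vals = np.empty(n_triples)
    done = 0
    chunk = 200_000
    while done < n_triples:
        k = min(chunk, n_triples - done)
        # distinct-chromosome trios: sample, then reject collisions
        c3 = rng.integers(0, len(chroms), size=(k, 3))
        bad = (
            (c3[:, 0] == c3[:, 1]) | (c3[:, 0] == c3[:, 2]) | (c3[:, 1] == c3[:, 2])
        )
        while bad.any():
            c3[bad] = rng.integers(0, len(chroms), size=(int(bad.sum()), 3))
            bad = (
                (c3[:, 0] == c3[:, 1]) | (c3[:, 0] == c3[:, 2]) | (c3[:, 1] == c3[:, 2])
            )
        idx = np.empty((k, 3), dtype=np.int64)
        for j in range(3):
            for ci, sites in enumerate(sites_by_chrom):
                sel = np.flatnonzero(c3[:, j] == ci)
                if sel.size:
                    idx[sel, j] = sites[rng.integers(0, sites.size, size=sel.size)]
        prod = (R[:, idx[:, 0]] * R[:, idx[:, 1]] * R[:, idx[:, 2]]).sum(axis=0)
        vals[done : done + k] = (
            delta[idx[:, 0]] * delta[idx[:, 1]] * delta[idx[:, 2]] * bias * prod
        )
        done += k
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_triples))
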