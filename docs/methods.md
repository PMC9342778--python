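# Methods

## Model

`triald` works in a random-union-of-gametes admixture model: a panmictic
pool of `2N` haploid chromosomes is founded `T` generations ago, with a
fraction `1 - m_T` of founders from the first source population and
`m_T` from the second; in each later generation `i` a fraction `m_i` of
chromosomes is replaced by second-source migrants. Local ancestry
`A_x ∈ {0,1}` marks descent from the first source at position `x`.

The quantity the method predicts and estimates is the **expected
within-population covariance** of ancestry at site triples,
`cov(A_x, A_y, A_z)` — the three-point central moment of a single drift
realization, averaged over realizations. This matters for two reasons:
it is what the sample k-statistic on a cohort estimates, and it is the
quantity whose drift attenuation the transfer matrices describe (the
fully marginal covariance of one chromosome would not decay under drift
at zero distance, because marginal ancestry frequencies are martingales;
the coupled two- and three-chromosome state probabilities in the state
vector do decay).

The state vector `v3` tracks the five ways three sites can sit on one,
two, or three chromosomes, ordered (xyz | yz,x | xz,y | xy,z | x,y,z).
Per generation, `v3 ← D_i L U v3` with

- `D_i = diag(q, q², q², q², q³)`, `q = 1 - m_i`: all carriers escape
  migrant replacement;
- `L`: Wright–Fisher coalescence among the distinct carriers (`1/2N` per
  pair);
- `U`: recombination, with per-interval separation probabilities
  `1 - e^{-d}` and `1 - e^{-d'}`; within one meiosis the two flanking
  sites of a doubly-recombined chromosome land back on the same parent,
  which is why `U` has the reunion entry `(1-e^{-d})(1-e^{-d'})`.

`cov(A_x,A_y,A_z) = (1,-1,-1,-1,2) · v3` after `T` applications starting
from the founding vector `(q, q², q², q², q³)`. Because the weight
vector is a left eigenvector of `L` (eigenvalue `(1-1/2N)(1-2/2N)`) and
`U` (eigenvalue `e^{-(d+d')}`), a one-pulse history has the closed form

    cov3 = -M (1-M)(1-2M) [(1-1/2N)(1-2/2N)]^T e^{-T(d+d')}.

The sign convention follows the first-source indicator: at `T = 0` this
is the third central moment of a Bernoulli(1-M) variable, negative for
`M < 1/2`. (Some presentations print the one-pulse amplitude with the
opposite sign; the negative form is the one consistent with the matrix
product, with the two-pulse expression's `M1 → 0` / `M2 → 0` limits, and
with the forward-simulation oracle, so it is used throughout.) The
drift-free two-pulse expression used as the fitting model, and the
two-point analogue (a mixture of two exponentials), are evaluated in
`theory.two_pulse_cov3` / `theory.two_pulse_cov2`; both were verified to
match the matrix product to machine precision.

The matrix product is accumulated in 80-bit extended precision so that
closed-form equivalence holds to better than 1e-12 out to `T = 50`;
histories with no migrants short-circuit to an exact 0.

## Estimator

Weighted three-locus LD:

    â[d,d'] = (1/|S[d,d']|) Σ_{x,y,z} δ̂_x δ̂_y δ̂_z ·
              n Σ_i (H_ix-h_x)(H_iy-h_y)(H_iz-h_z) / ((n-1)(n-2)),

with `h` the admixed sample frequency and `δ̂` the reference-panel
frequency difference (orientation: first source minus second). The
`n/((n-1)(n-2))` factor makes the inner sum the unbiased multivariate
k-statistic, so `E[â] = E[δ²]³ · cov3` for triples of independently
drawn sites. Genotype input {0, ½, 1} scales the expectation by 1/4
(only the haplotype-concordant term of the pairing survives), which the
fitted amplitude absorbs.

Sites are binned by `floor(position / bin_width)` (half-open bins,
default 0.1 cM over 0.5–20 cM; both configurable), and the triple sums
become correlations of the per-sample binned weighted-residual sequence
`b_i` and of the bin-count sequence `c`:

    num[d,d'] = Σ_w b[w] b[w+d] b[w+d+d'] ,

computed per lag `d` as an FFT cross-correlation of `u_d[w] = b[w]b[w+d]`
with `b` (FFT length padded to cover `B + 2P` bins, which provably
excludes circular wrap-around because a non-zero middle factor bounds
`w + d ≤ B-1`). Runtime is `O(S n)` for binning plus
`O(n P L log L)` per chromosome; numerators and denominators are cached
per chromosome for the jackknife. The exact `O(S³)` enumeration
(`direct_weighted_ld3`) uses the same bin-lag assignment and agrees with
the FFT path to floating-point rounding — binning is the only
approximation relative to the raw definition. Triples never span
chromosomes. Lags with `d = 0` or `d' = 0` mix same-bin pairs and are
never reported.

**Missing source.** With one reference panel, the other source's
frequencies solve `h = f(1-M) + gM` where `M = M1(1-M2)+M2` is the total
second-source proportion (for marginal frequencies only the total
matters). Results are clipped to [0,1] with a logged count. Two
consequences are worth knowing:

- clipping shrinks extreme reconstructed frequencies, attenuating the
  surface amplitude by a scalar (about 10% at Balding–Nichols F = 0.98
  divergence); time estimates are unaffected because the attenuation is
  distance-independent and absorbed by the fitted constant `C`;
- using the same samples for the weights and the LD couples the two, so
  `split_half_weighted_ld3` splits the cohort, estimates weights on each
  half, applies them to the other half's LD, and averages the two
  unbiased numerators. A residual `O(1/n_half)` inflation from admixture
  LD *within* the weight products (a percent-level effect) remains; it
  is common to any missing-source weighting scheme.

Sites with admixed MAF below 0.05 (configurable) are removed before
estimation — the missing-source solve is noise-dominated at rare sites.
Sites with >10% missing genotypes are dropped, the rest mean-imputed and
snapped back to the {0, ½, 1} alphabet.

**Affine background.** Population substructure adds a
distance-independent offset to weighted LD. It is estimated as the mean
weighted three-way covariance over random site triples drawn from three
distinct chromosomes (default budget 10⁶ triples, seeded); the reported
SE treats triples as independent and is therefore slightly optimistic.
The sampling scheme (uniform over distinct-chromosome trios, uniform
sites within) is a documented choice; nothing in the statistic's
definition pins it down further.

## Fitting

Non-linear least squares of `C · cov3(T1,T2,M1,M2; d,d') + A` to the
unmasked bins (unweighted loss; a count-weighted option exists behind a
flag). `C` and `A` enter linearly, so every shape trial is scored by a
profiled linear solve; a coarse grid over `T1, T2` (log-spaced 1–50) and
`M1` seeds bounded `scipy.optimize.least_squares` polishing, ties broken
toward smaller `T1`. With an external total-proportion estimate,
`M2 = (M - M1)/(1 - M1)` removes one parameter. Bins with distance below
0.5 cM (short-range LD in the sources) or fewer than 10 supporting
triples are masked. Fits driven to `T1 ≈ 0` or a vanishing pulse
fraction are flagged `one_pulse_boundary` rather than rejected; when the
pulses are close (`T1 < T2`) this happens often and is the expected
identifiability limit — the surface contours are then nearly straight
and carry little information beyond a single pulse.

The affine term can be fixed to the cross-chromosome estimate (the
default analysis path, and what the simulation studies use) or
co-estimated; fixing it removes a parameter that otherwise trades off
against slow decay components.

**Jackknife.** Leave-one-chromosome surfaces are rebuilt by subtracting
the cached per-chromosome partial sums and refitted; the delete-one SE
uses equal chromosome weights (chromosomes of unequal map length make
this an approximation). The reported `±` values are standard errors, not
a fixed-level interval.

## Synthetic data

`simulate` generates the statistical structure the estimator assumes,
forward in time: per chromosome, a pool of `2N` ancestry-labelled
chromosomes; each offspring copies from a uniformly drawn parent,
switching to a fresh uniform parent at ancestry junctions arriving as a
Poisson process (rate 1/Morgan); migrant pulses zero out whole
chromosomes. Ancestry is tracked at the marker positions where alleles
are later dropped. This independent-parent junction model reproduces the
theory's `e^{-d}` two-point decay exactly and is the discrete-generation
analogue of the coalescent-with-recombination; a strict two-parent
meiosis with crossover parity would instead give `((1+e^{-2d})/2)^T`
two-point decay. Neither that model nor this one reproduces the 5-state
theory's within-meiosis reunion entry at separated sites, so simulated
three-point surfaces deviate from the matrix product by `O(d·d')` per
generation — a few percent at 10–20 cM for recent histories, visible as
mild amplitude inflation at the far corner of the surface but immaterial
to the fitted times at the scales tested.

Source allele frequencies follow a Balding–Nichols model around a shared
ancestral frequency `p ~ U(0.05, 0.95)`: `f, g ~ Beta` with mean `p` and
variance `F·p(1-p)`. The default `F = 0.98` emulates sources separated
for several `N` generations (strongly drifted, near-fixed differences at
many sites), the regime in which three-locus dating is realistically
powered; `E[δ²] = 2F·E[p(1-p)] ≈ 0.3`. Alleles are conditionally
independent given local ancestry; reference panels are drawn i.i.d. from
`f` and `g`. Defaults mirror the verification design used throughout the
tests: 50 diploid admixed samples, 50 diploids per reference, 20
chromosomes of 1 Morgan, `2N = 1000`. Site density is a study choice
(600 markers per Morgan in the recovery experiments — marker-array
density; sparser panels inflate the surface variance noticeably).

What the generator does *not* emulate: background LD within the source
populations (so the short-range mask is untested against its real
target), mutation, gene conversion, variable recombination maps,
phasing error, and cross-chromosome assortment correlations (simulated
chromosomes are independent, so the affine background is truly zero in
panmictic scenarios). Passing tests therefore validate the estimator and
fitting machinery under the model's own assumptions, not robustness to
those real-data complications.

`mc_state_oracle` is a separate arithmetic check on the matrices: it
forward-simulates a population of chromosomes carrying just the three
markers, with two parents per meiosis and the printed per-interval
separation probabilities (including the reunion behaviour), and returns
the mean within-population three-point moment with a Monte-Carlo SE. It
shares no code with the matrix product.

## Numerical and design choices

- Distances are Morgans internally; cM only at interfaces. VCF positions
  convert via a genetic map (linear interpolation, terminal-rate
  extrapolation with a warning) or a constant cM/Mb.
- `2N = ∞` is an explicit drift-free mode.
- Genotypes are used unphased by default; a phased haplotype mode
  exists. Allele orientation is taken from the VCF ref/alt as read and
  applied consistently to all panels (δ products of odd order do not
  cancel orientation, so consistency across panels is what matters).
- The drift-free two-pulse expression is the fitting model (fast,
  vectorized); the full matrix product is available for prediction,
  including continuous-migration schedules, but is not used in the loss.
- Optimizer boundaries: `T1, T2 ∈ [0, 200]`, fractions in `[0, 1)`,
  `C ≥ 0`. Non-convergence from all starts yields a flagged result, not
  an exception.
- Surface files are long-format TSV with per-chromosome partial sums and
  a JSON metadata header; round-trip is bit-exact per chromosome
  (`%.17g` + round-trip float parsing).

## Known limitations

- Histories with total proportion near 0.5 have vanishing three-point
  amplitude (`(1-2M) → 0`); estimates there are noise-dominated.
- `T1 < T2` (recent pulse older than the spacing) is weakly identified;
  expect one-pulse boundary fits.
- The method needs hundreds of samples or strongly diverged sources:
  third moments are noisy, with estimator variance constants much larger
  than for two-locus LD.
- Jackknife SEs at ~20 chromosomes are themselves noisy (within a factor
  ~2 of replicate spread in calibration runs).
- Reference panels stand in for the *ancestral* source frequencies;
  post-admixture drift in the sources is ignored.
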