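"""Two-pulse model fits to weighted-LD surfaces, with jackknife intervals.

The drift-free two-pulse three-point ancestry covariance is fitted to the
estimated surface by non-linear least squares

    minimise  sum_bins ( a_hat[d,d'] - C * cov3(T1, T2, M1, M2; d, d') - A )^2

where ``C`` is a proportionality constant absorbing the expected cubed
allele-frequency difference between the sources (E[delta^2]^3, and a
factor 1/4 for diploid genotype input) and ``A`` is an affine background
attributable to population substructure.  When the total admixture
proportion ``M`` is known from an external ancestry estimate, ``M2`` is
tied to ``M1`` through ``M = M1 (1 - M2) + M2``, leaving three free
history parameters.

``C`` and ``A`` enter linearly, so every trial of the shape parameters
(T1, T2, M1[, M2]) is scored by a profiled linear solve; a coarse
multi-start grid seeds bounded least-squares polishing.  Standard errors
come from the delete-one-chromosome jackknife, rebuilding each
leave-one-out surface from the cached per-chromosome partial sums.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.optimize import least_squares

from .estimator import WeightedLDSurface
from .theory import TwoPulseParams, two_pulse_cov3

__all__ = ["FitConfig", "FitResult", "constrain_M2", "fit_two_pulse", "jackknife_ci"]


@dataclass(frozen=True)
class FitConfig:
    """Loss and optimizer settings for surface fits.

    ``min_dist`` masks short-range bins (background LD in the source
    populations contaminates distances below about half a centimorgan);
    ``count_floor`` drops bins supported by too few triples.  ``affine``
    fixes the background term to a pre-estimated value; when None the
    background is co-estimated.  Bounds are generations and fractions.
    """

    min_dist: float = 0.005  # Morgans
    count_floor: float = 10.0
    affine: float | None = None
    weight_by_counts: bool = False
    T_max: float = 200.0
    grid_T: tuple = tuple(float(t) for t in (1, 2, 4, 8, 16, 32, 50))
    grid_M1: tuple = (0.05, 0.1, 0.2, 0.3, 0.4)
    n_polish: int = 3
    rel_tie_tol: float = 1e-8


@dataclass
class FitResult:
    """Point estimates and diagnostics for a two-pulse surface fit."""

    params: TwoPulseParams
    amplitude: float
    affine: float
    residual_norm: float
    converged: bool
    one_pulse_boundary: bool
    M_total: float | None = None
    n_bins: int = 0
    jackknife_se: dict | None = None
    per_chromosome_estimates: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "T1": self.params.T1,
            "T2": self.params.T2,
            "M1": self.params.M1,
            "M2": self.params.M2,
            "M_total": self.params.M_total,
            "amplitude": self.amplitude,
            "affine": self.affine,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "one_pulse_boundary": self.one_pulse_boundary,
            "n_bins": self.n_bins,
        }
        if self.jackknife_se is not None:
            d["jackknife_se"] = self.jackknife_se
        if self.per_chromosome_estimates is not None:
            d["per_chromosome_estimates"] = {
                str(k): v for k, v in self.per_chromosome_estimates.items()
            }
        return d


def constrain_M2(M_total: float, M1: float) -> float:
    """Recent-pulse fraction implied by the total proportion and M1.

    Inverts ``M = M1 (1 - M2) + M2`` to ``M2 = (M - M1) / (1 - M1)``.
    """
    if not 0.0 <= M_total < 1.0:
        raise ValueError(f"M_total={M_total} must lie in [0, 1)")
    if M1 >= 1.0:
        raise ValueError("M1 = 1 makes the constraint singular")
    if not 0.0 <= M1 <= M_total:
        raise ValueError(f"need 0 <= M1 <= M_total, got M1={M1}, M_total={M_total}")
    return (M_total - M1) / (1.0 - M1)


def _surface_data(surface: WeightedLDSurface, config: FitConfig):
    """Unmasked bin values, distances and weights as flat vectors."""
    vals = surface.values
    cnts = surface.counts
    dist = surface.distances
    i0 = int(math.ceil(config.min_dist / surface.bin_width))
    P = surface.P
    ii, jj = np.meshgrid(np.arange(P + 1), np.arange(P + 1), indexing="ij")
    mask = (
        (ii >= max(i0, 1))
        & (jj >= max(i0, 1))
        & np.isfinite(vals)
        & (cnts >= config.count_floor)
    )
    y = vals[mask]
    d = dist[ii[mask]]
    dp = dist[jj[mask]]
    w = np.sqrt(cnts[mask]) if config.weight_by_counts else np.ones_like(y)
    w = w / w.mean() if w.size else w
    return y, d, dp, w


def _shape_to_params(theta: np.ndarray, M_total: float | None) -> TwoPulseParams:
    if M_total is None:
        T1, T2, M1, M2 = theta
    else:
        T1, T2, M1 = theta
        M2 = constrain_M2(M_total, min(M1, M_total))
    return TwoPulseParams(max(T1, 0.0), max(T2, 0.0), float(np.clip(M1, 0, 1)), float(np.clip(M2, 0, 1)))


def _profile_rss(theta, y, d, dp, w, M_total, config):
    """Best (C, A) for the given shape parameters, and the resulting RSS."""
    params = _shape_to_params(np.asarray(theta, dtype=float), M_total)
    m = two_pulse_cov3(params, d, dp)
    if config.affine is None:
        X = np.column_stack([m, np.ones_like(m)])
        coef, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
        C, A = float(coef[0]), float(coef[1])
    else:
        A = config.affine
        mm = float(np.dot(m * w, m * w))
        C = float(np.dot(m * w, (y - A) * w) / mm) if mm > 0 else 0.0
    if C < 0.0:
        C = 0.0
        A = float(np.average(y, weights=w * w)) if config.affine is None else config.affine
    r = (y - C * m - A) * w
    return float(np.dot(r, r)), C, A


def fit_two_pulse(
    surface: WeightedLDSurface,
    M_total: float | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the two-pulse admixture model to a weighted-LD surface.

    With ``M_total`` supplied the free history parameters are
    ``(T1, T2, M1)``; otherwise ``M2`` is free as well.  Multi-start
    profiling over a coarse grid seeds bounded least-squares runs; among
    fits of equal residual the smaller ``T1`` wins, and fits driven to the
    ``T1 ~ 0`` or vanishing-pulse boundary are flagged as effectively
    one-pulse.  A failed optimisation is reported via ``converged=False``
    rather than raised.
    """
    config = config or FitConfig()
    y, d, dp, w = _surface_data(surface, config)
    n_free = 5 if M_total is None else 4
    if config.affine is not None:
        n_free -= 1
    if y.size < n_free:
        raise ValueError(f"only {y.size} usable bins for {n_free} free parameters")

    M_hi = 1.0 - 1e-6 if M_total is None else M_total
    grid_M1 = [m1 for m1 in config.grid_M1 if m1 <= M_hi] or [0.5 * M_hi]
    starts = []
    for t1 in config.grid_T:
        for t2 in config.grid_T:
            for m1 in grid_M1:
                if M_total is None:
                    for m2 in config.grid_M1:
                        starts.append((t1, t2, m1, m2))
                else:
                    starts.append((t1, t2, m1))
    scored = sorted(
        ((_profile_rss(th, y, d, dp, w, M_total, config)[0], th) for th in starts),
        key=lambda t: t[0],
    )

    def residuals(x):
        params = _shape_to_params(x[:-2] if config.affine is None else x[:-1], M_total)
        m = two_pulse_cov3(params, d, dp)
        if config.affine is None:
            C, A = x[-2], x[-1]
        else:
            C, A = x[-1], config.affine
        return (y - C * m - A) * w

    lo_shape = [0.0, 0.0, 0.0] + ([0.0] if M_total is None else [])
    hi_shape = [config.T_max, config.T_max, M_hi] + (
        [1.0 - 1e-6] if M_total is None else []
    )
    best = None
    any_success = False
    for rss0, th in scored[: config.n_polish]:
        _, C0, A0 = _profile_rss(th, y, d, dp, w, M_total, config)
        x0 = list(th) + ([C0, A0] if config.affine is None else [max(C0, 0.0)])
        lo = lo_shape + ([0.0, -np.inf] if config.affine is None else [0.0])
        hi = hi_shape + ([np.inf, np.inf] if config.affine is None else [np.inf])
        try:
            sol = least_squares(
                residuals, np.clip(x0, lo, hi), bounds=(lo, hi), xtol=1e-12, ftol=1e-12
            )
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        any_success = any_success or sol.success
        rss = float(2 * sol.cost)
        t1 = sol.x[0]
        if (
            best is None
            or rss < best[0] * (1 - config.rel_tie_tol)
            or (rss <= best[0] * (1 + config.rel_tie_tol) and t1 < best[1])
        ):
            best = (rss, t1, sol.x)
    if best is None:
        params = _shape_to_params(np.asarray(scored[0][1]), M_total)
        rss0, C0, A0 = _profile_rss(scored[0][1], y, d, dp, w, M_total, config)
        return FitResult(
            params, C0, A0, math.sqrt(rss0), False, False, M_total, y.size
        )
    rss, _, x = best
    shape = x[:-2] if config.affine is None else x[:-1]
    params = _shape_to_params(shape, M_total)
    C = float(x[-2] if config.affine is None else x[-1])
    A = float(x[-1]) if config.affine is None else config.affine
    boundary = (
        params.T1 <= 0.5
        or params.M1 <= 1e-3
        or params.M2 <= 1e-3
        or C <= 0.0
    )
    return FitResult(
        params,
        C,
        A,
        math.sqrt(rss),
        any_success,
        boundary,
        M_total,
        y.size,
    )


_JACK_FIELDS = ("T1", "T2", "M1", "M2", "amplitude", "affine")


def _result_vector(res: FitResult) -> np.ndarray:
    return np.array(
        [res.params.T1, res.params.T2, res.params.M1, res.params.M2, res.amplitude, res.affine]
    )


def jackknife_ci(
    surface: WeightedLDSurface,
    M_total: float | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Full fit plus delete-one-chromosome jackknife standard errors.

    Each leave-one-out surface is rebuilt by subtracting that chromosome's
    cached partial numerator and denominator (no genotype rescan) and
    refitted.  SEs use the standard delete-one formula with equal
    chromosome weights; chromosomes of unequal map length make this an
    approximation.
    """
    chroms = surface.chromosomes
    if len(chroms) < 2:
        raise ValueError("jackknife needs at least 2 chromosomes with partial sums")
    config = config or FitConfig()
    full = fit_two_pulse(surface, M_total, config)
    estimates = {}
    vecs = []
    for c in chroms:
        res_c = fit_two_pulse(surface.drop_chromosome(c), M_total, config)
        estimates[c] = res_c.to_dict()
        vecs.append(_result_vector(res_c))
    V = np.array(vecs)
    G = len(chroms)
    se = np.sqrt((G - 1) / G * ((V - V.mean(axis=0)) ** 2).sum(axis=0))
    full.jackknife_se = dict(zip(_JACK_FIELDS, se.tolist()))
    full.per_chromosome_estimates = estimates
    return full
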