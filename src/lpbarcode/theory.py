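"""Error-rate theory for combinatorial laser-particle (LP) barcoding.

A cell tagged with ``m`` laser particles carries an optical barcode: the
sorted tuple of its emission-line photon energies ``E = (E_1 < ... < E_m)``
in meV.  Two barcodes of equal multiplicity are considered identical when
their Chebyshev distance ``max_i |E_{A,i} - E_{B,i}|`` is at most the
matching half-gap ``delta``.  This module provides the planning mathematics:

* counting unique barcodes for a discrete palette of ``l`` colors,
* the duplicate rate ``eps_dup`` for discrete and continuous spectral
  distributions (closed form for a uniform density, Monte-Carlo otherwise),
* the noise-induced mismatch rate ``eps_noise`` for Gaussian and
  generalized-Gaussian line noise,
* optimization of ``delta`` and of the maximum pool size ``N`` under a
  total-error tolerance ``eps0``,
* Poisson tagging mixtures (stochastic multiplicity) and the resulting
  duplicate-induced sample loss.

Energies are expressed in meV throughout; wavelength conversion lives in
:mod:`lpbarcode.spectra`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "DiscretePalette",
    "SpectralDistribution",
    "NoiseModel",
    "JointBarcodeDistribution",
    "TaggingMixture",
    "ErrorReport",
    "count_unique_barcodes",
    "approx_unique_barcodes",
    "n_distinguishable_colors",
    "duplicate_rate_discrete",
    "min_unique_barcodes",
    "effective_barcodes",
    "duplicate_rate_continuous",
    "noise_error",
    "total_error",
    "optimize_delta",
    "max_pool_size",
    "mixture_error_rates",
    "duplicate_loss",
    "plan_scenario",
]

# Truncation of Gaussian spectral densities, in standard deviations.  Mass
# beyond this point is ~2e-9 and irrelevant at the tolerances used here.
GAUSSIAN_SUPPORT_SIGMAS = 6.0

_SQRT12 = math.sqrt(12.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscretePalette:
    """A discrete palette of ``l`` distinguishable colors and multiplicity ``m``.

    ``gap`` is the bin spacing ``2*delta`` in meV, used only for the
    conversion ``l = Delta / (2*delta)`` between continuous width and color
    count; it does not affect combinatorics.
    """

    l: int
    m: int
    gap: float | None = None

    def __post_init__(self) -> None:
        if self.l < 1 or self.m < 1:
            raise ValueError("palette requires l >= 1 and m >= 1")

    @classmethod
    def from_width(cls, delta_big: float, delta: float, m: int) -> "DiscretePalette":
        """Palette implied by a spectral width ``Delta`` and half-gap ``delta``."""
        if delta <= 0 or delta_big <= 0:
            raise ValueError("widths must be positive")
        return cls(l=int(delta_big / (2.0 * delta)), m=m, gap=2.0 * delta)


@dataclass(frozen=True)
class SpectralDistribution:
    """Single-line emission density ``g(E)`` over photon energy in meV.

    ``delta_big`` is the width parameter Delta: the full support width for a
    uniform density, ``sqrt(12)*sigma`` for a Gaussian (so both share the
    same standard deviation), and the support width for mixtures.
    """

    kind: str  # "uniform" | "gaussian" | "gaussian-mixture"
    delta_big: float
    sigma: float | None = None
    components: tuple[tuple[float, float, float], ...] | None = None
    support: tuple[float, float] = (0.0, 1.0)

    # -- constructors --------------------------------------------------

    @classmethod
    def uniform(cls, delta_big: float, center: float = 950.0) -> "SpectralDistribution":
        if delta_big <= 0:
            raise ValueError("Delta must be positive")
        half = delta_big / 2.0
        return cls(kind="uniform", delta_big=delta_big,
                   support=(center - half, center + half))

    @classmethod
    def gaussian(cls, sigma: float | None = None, delta_big: float | None = None,
                 center: float = 950.0) -> "SpectralDistribution":
        if (sigma is None) == (delta_big is None):
            raise ValueError("give exactly one of sigma or delta_big")
        if sigma is None:
            sigma = delta_big / _SQRT12
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        half = GAUSSIAN_SUPPORT_SIGMAS * sigma
        return cls(kind="gaussian", delta_big=_SQRT12 * sigma, sigma=sigma,
                   support=(center - half, center + half))

    @classmethod
    def gaussian_mixture(
        cls, components: Iterable[tuple[float, float, float]]
    ) -> "SpectralDistribution":
        comps = tuple((float(c), float(s), float(w)) for c, s, w in components)
        if not comps:
            raise ValueError("mixture needs at least one component")
        wsum = sum(w for _, _, w in comps)
        if not math.isclose(wsum, 1.0, abs_tol=1e-6):
            raise ValueError(f"mixture weights sum to {wsum}, expected 1")
        if any(s <= 0 for _, s, _ in comps):
            raise ValueError("component sd must be positive")
        lo = min(c - GAUSSIAN_SUPPORT_SIGMAS * s for c, s, _ in comps)
        hi = max(c + GAUSSIAN_SUPPORT_SIGMAS * s for c, s, _ in comps)
        return cls(kind="gaussian-mixture", delta_big=hi - lo,
                   components=comps, support=(lo, hi))

    # -- density and sampling ------------------------------------------

    @property
    def center(self) -> float:
        return 0.5 * (self.support[0] + self.support[1])

    def pdf(self, energy: np.ndarray | float) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.support
        if self.kind == "uniform":
            out = np.where((e >= lo) & (e <= hi), 1.0 / self.delta_big, 0.0)
        elif self.kind == "gaussian":
            # density renormalized on the +/-6 sigma truncated support
            z = special.erf(GAUSSIAN_SUPPORT_SIGMAS / math.sqrt(2.0))
            out = stats.norm.pdf(e, loc=self.center, scale=self.sigma) / z
            out = np.where((e >= lo) & (e <= hi), out, 0.0)
        elif self.kind == "gaussian-mixture":
            out = np.zeros_like(e, dtype=float)
            for c, s, w in self.components:
                out = out + w * stats.norm.pdf(e, loc=c, scale=s)
            out = np.where((e >= lo) & (e <= hi), out, 0.0)
        else:  # pragma: no cover - constructors prevent this
            raise ValueError(f"unknown kind {self.kind!r}")
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.support
        if self.kind == "uniform":
            return rng.uniform(lo, hi, size=n)
        if self.kind == "gaussian":
            out = rng.normal(self.center, self.sigma, size=n)
            bad = (out < lo) | (out > hi)
            while bad.any():  # resample the ~2e-9 tail mass
                out[bad] = rng.normal(self.center, self.sigma, size=int(bad.sum()))
                bad = (out < lo) | (out > hi)
            return out
        # mixture
        centers = np.array([c for c, _, _ in self.components])
        sds = np.array([s for _, s, _ in self.components])
        ws = np.array([w for _, _, w in self.components])
        idx = rng.choice(len(centers), size=n, p=ws / ws.sum())
        out = rng.normal(centers[idx], sds[idx])
        return np.clip(out, lo, hi)


@dataclass(frozen=True)
class NoiseModel:
    """Per-line measurement fluctuation density ``phi(E')``, symmetric about 0.

    Either a Gaussian with standard deviation ``sigma_phi`` (meV) or a
    generalized Gaussian ``phi(E') = beta/(2 alpha Gamma(1/beta))
    exp(-(|E'|/alpha)^beta)`` with scale ``alpha`` (meV) and exponent
    ``beta``; ``beta = 2`` recovers a Gaussian with ``sigma = alpha/sqrt(2)``.
    """

    family: str  # "gaussian" | "generalized-gaussian"
    sigma_phi: float | None = None
    alpha: float | None = None
    beta: float | None = None

    @classmethod
    def gaussian(cls, sigma_phi: float) -> "NoiseModel":
        if sigma_phi < 0:
            raise ValueError("sigma_phi must be non-negative")
        return cls(family="gaussian", sigma_phi=sigma_phi)

    @classmethod
    def generalized(cls, alpha: float, beta: float) -> "NoiseModel":
        if alpha < 0 or beta <= 0:
            raise ValueError("require alpha >= 0 and beta > 0")
        return cls(family="generalized-gaussian", alpha=alpha, beta=beta)

    @property
    def scale(self) -> float:
        return self.sigma_phi if self.family == "gaussian" else self.alpha

    def interval_mass(self, delta: np.ndarray | float) -> np.ndarray:
        """``P(|E'| <= delta)``, the mass of the noise density inside the gate."""
        d = np.asarray(delta, dtype=float)
        if np.any(d < 0):
            raise ValueError("delta must be non-negative")
        if self.scale == 0.0:
            return np.where(d >= 0, 1.0, 0.0)
        if self.family == "gaussian":
            return special.erf(d / (self.sigma_phi * math.sqrt(2.0)))
        return special.gammainc(1.0 / self.beta, (d / self.alpha) ** self.beta)

    def pdf(self, x: np.ndarray | float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            return stats.norm.pdf(x, scale=self.sigma_phi)
        return stats.gennorm.pdf(x, self.beta, scale=self.alpha)

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0.0:
            return np.zeros(size)
        if self.family == "gaussian":
            return rng.normal(0.0, self.sigma_phi, size=size)
        return stats.gennorm.rvs(self.beta, scale=self.alpha, size=size,
                                 random_state=rng)


@dataclass(frozen=True)
class JointBarcodeDistribution:
    """Joint density ``G_m(E)`` of a sorted m-line barcode.

    With all LPs single-mode (``f_dm = 0``) the sorted-tuple density is
    ``G_m(E) = m! * prod_i g(E_i)``.  A fraction ``f_dm`` of barcodes instead
    contains exactly one dual-mode LP contributing a correlated line pair
    ``(E, E + FSR)`` with the free spectral range FSR drawn uniformly from
    ``[fsr_lo, fsr_hi]`` meV; barcodes with two or more dual-mode LPs are
    neglected (valid for ``f_dm << 1``).
    """

    base: SpectralDistribution
    f_dm: float = 0.0
    fsr_lo: float = 50.0
    fsr_hi: float = 70.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_dm <= 1.0:
            raise ValueError("f_dm must be in [0, 1]")
        if self.fsr_lo <= 0 or self.fsr_hi <= self.fsr_lo:
            raise ValueError("require 0 < fsr_lo < fsr_hi")

    @property
    def is_plain_uniform(self) -> bool:
        return self.base.kind == "uniform" and self.f_dm == 0.0

    def sample_barcodes(self, m: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` sorted barcodes of multiplicity ``m``; shape ``(n, m)``."""
        if m < 1:
            raise ValueError("m must be >= 1")
        x = self.base.sample(n * m, rng).reshape(n, m)
        if self.f_dm > 0.0 and m >= 2:
            dual = rng.random(n) < self.f_dm
            nd = int(dual.sum())
            if nd:
                primary = self.base.sample(nd, rng)
                fsr = rng.uniform(self.fsr_lo, self.fsr_hi, size=nd)
                x[dual, m - 2] = primary
                x[dual, m - 1] = primary + fsr
        x.sort(axis=1)
        return x

    def pdf_sorted(self, barcodes: np.ndarray) -> np.ndarray:
        """Density ``G_m`` evaluated at sorted barcodes, shape ``(n, m)``."""
        x = np.atleast_2d(np.asarray(barcodes, dtype=float))
        n, m = x.shape
        g = self.base.pdf(x)
        g_sm = math.factorial(m) * np.prod(g, axis=1)
        if self.f_dm == 0.0 or m < 2:
            return g_sm
        # One dual-mode pair (E_i, E_j = E_i + FSR): the pair contributes
        # g(E_i) * h(E_j - E_i) with h the FSR density; the remaining m-2
        # single lines contribute (m-2)! * prod g.
        h_norm = 1.0 / (self.fsr_hi - self.fsr_lo)
        g_dm = np.zeros(n)
        cols = np.arange(m)
        for i in range(m):
            for j in range(i + 1, m):
                d = x[:, j] - x[:, i]
                h = np.where((d >= self.fsr_lo) & (d <= self.fsr_hi), h_norm, 0.0)
                keep = cols != j  # second mode's energy is set by E_i + FSR
                g_dm += h * np.prod(g[:, keep], axis=1)
        g_dm *= math.factorial(m - 2)
        return (1.0 - self.f_dm) * g_sm + self.f_dm * g_dm


@dataclass(frozen=True)
class TaggingMixture:
    """Distribution of LP count per cell: fixed ``m`` or Poisson with mean ``lam``.

    Untagged (``m = 0``) cells are unidentifiable; by default they are
    excluded and the multiplicity weights renormalize over ``m >= 1``.
    """

    mode: str  # "fixed" | "poisson"
    m: int | None = None
    lam: float | None = None
    include_untagged: bool = False

    def __post_init__(self) -> None:
        if self.mode == "fixed":
            if self.m is None or self.m < 1:
                raise ValueError("fixed mode requires m >= 1")
        elif self.mode == "poisson":
            if self.lam is None or self.lam <= 0:
                raise ValueError("poisson mode requires lam > 0")
        else:
            raise ValueError(f"unknown tagging mode {self.mode!r}")

    @property
    def untagged_fraction(self) -> float:
        return 0.0 if self.mode == "fixed" else math.exp(-self.lam)

    def weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Multiplicity values ``m >= 1`` and their weights.

        Weights are renormalized over ``m >= 1`` unless ``include_untagged``
        is set, in which case they are raw Poisson masses (summing to
        ``1 - exp(-lam)``).  The support is truncated where the cumulative
        Poisson mass reaches ``1 - 1e-6``.
        """
        if self.mode == "fixed":
            return np.array([self.m]), np.array([1.0])
        m_max = int(stats.poisson.ppf(1.0 - 1e-6, self.lam))
        m_max = max(m_max, 1)
        ms = np.arange(1, m_max + 1)
        w = stats.poisson.pmf(ms, self.lam)
        if not self.include_untagged:
            w = w / (1.0 - self.untagged_fraction)
        return ms, w

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """LP counts per cell, including zeros in poisson mode."""
        if self.mode == "fixed":
            return np.full(n, self.m, dtype=int)
        return rng.poisson(self.lam, size=n)


@dataclass
class ErrorReport:
    """Planning summary for one barcoding scenario (rates in [0, 1], meV units)."""

    N: int
    delta: float | None = None
    eps_dup: float | None = None
    eps_noise: float | None = None
    eps_tot: float | None = None
    delta_opt: float | None = None
    eps_min: float | None = None
    B: int | None = None
    B_eff: float | None = None
    eps0: float | None = None
    mc_stderr: float = 0.0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "extra" and v is not None}
        out.update(self.extra)
        return out


# ---------------------------------------------------------------------------
# Discrete-palette planning
# ---------------------------------------------------------------------------


def count_unique_barcodes(palette: DiscretePalette) -> int:
    """Exact number of unique barcodes, the binomial coefficient C(l, m)."""
    if palette.l < palette.m:
        raise ValueError("need l >= m to choose m distinct colors")
    return math.comb(palette.l, palette.m)


def approx_unique_barcodes(palette: DiscretePalette) -> float:
    """Large-palette approximation ``l^m / m!`` of the barcode count."""
    return palette.l ** palette.m / math.factorial(palette.m)


def n_distinguishable_colors(lambda_lo_nm: float, lambda_hi_nm: float,
                             bin_nm: float = 1.0) -> int:
    """Number of distinct colors for a wavelength range binned at ``bin_nm``."""
    if lambda_hi_nm <= lambda_lo_nm or bin_nm <= 0:
        raise ValueError("require lambda_hi > lambda_lo and bin > 0")
    return int(round((lambda_hi_nm - lambda_lo_nm) / bin_nm))


def duplicate_rate_discrete(B: float, N: int, exact: bool = True) -> float:
    """Probability that a cell's barcode is duplicated in a pool of ``N``.

    Exact form ``1 - (1 - 1/B)^(N-1)``; the approximation ``N/B`` holds for
    ``B >> N``.
    """
    if B < 1 or N < 1:
        raise ValueError("require B >= 1 and N >= 1")
    if N == 1:
        return 0.0
    if exact:
        if B <= 1.0:
            return 1.0
        return -math.expm1((N - 1) * math.log1p(-1.0 / B))
    return min(N / B, 1.0)


def min_unique_barcodes(N: int, eps0: float, exact: bool = False) -> int:
    """Smallest barcode count keeping the duplicate rate at or below ``eps0``.

    The default uses the planning approximation ``eps ~= N/B``; ``exact``
    inverts ``1 - (1 - 1/B)^(N-1) = eps0`` instead.
    """
    if N < 2:
        raise ValueError("require N >= 2")
    if not 0.0 < eps0 < 1.0:
        raise ValueError("require 0 < eps0 < 1")
    if not exact:
        return max(1, math.ceil(N / eps0))
    # 1 - (1 - 1/B)^(N-1) <= eps0  <=>  B >= 1 / (1 - (1-eps0)^(1/(N-1)))
    b = 1.0 / -math.expm1(math.log1p(-eps0) / (N - 1))
    return max(1, math.ceil(b))


# ---------------------------------------------------------------------------
# Continuous-spectrum duplicate and noise rates
# ---------------------------------------------------------------------------


def effective_barcodes(dist: SpectralDistribution, delta: float, m: int) -> float:
    """Effective unique-barcode count ``B_eff = (Delta/2 delta)^m / m!``.

    Defined only for a uniform spectral density (the ratio of total barcode
    space to the Chebyshev cell of one barcode).
    """
    if dist.kind != "uniform":
        raise ValueError("B_eff is defined only for uniform distributions")
    if delta <= 0 or 2.0 * delta >= dist.delta_big:
        raise ValueError("require 0 < 2*delta < Delta")
    if m < 1:
        raise ValueError("m must be >= 1")
    return (dist.delta_big / (2.0 * delta)) ** m / math.factorial(m)


def _survival_power(p: np.ndarray, exponent: float) -> np.ndarray:
    """``(1 - p)^exponent`` with ``p`` clamped to [0, 1], stable for huge N."""
    p = np.clip(p, 0.0, 1.0)
    out = np.zeros_like(p)
    ok = p < 1.0
    out[ok] = np.exp(exponent * np.log1p(-p[ok]))
    if exponent == 0.0:
        out[:] = 1.0
    return out


def duplicate_rate_continuous(
    joint: JointBarcodeDistribution,
    m: int,
    delta: float,
    N: int,
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    force_mc: bool = False,
) -> tuple[float, float]:
    """Duplicate rate ``eps_dup = 1 - int G_m(E) (1 - (2 delta)^m G_m(E))^(N-1) dE``.

    For a plain uniform density this collapses to the closed form
    ``1 - (1 - 1/B_eff)^(N-1)`` (standard error 0).  Otherwise the integral
    is estimated by Monte-Carlo: sample ``E ~ G_m`` and average the clamped
    survival term.  Returns ``(rate, mc_stderr)``.
    """
    if N < 1:
        raise ValueError("require N >= 1")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    if N == 1:
        return 0.0, 0.0
    if joint.is_plain_uniform and not force_mc:
        b_eff = (joint.base.delta_big / (2.0 * delta)) ** m / math.factorial(m)
        p = min(1.0 / b_eff, 1.0)
        return float(-np.expm1((N - 1) * np.log1p(-p))) if p < 1.0 else 1.0, 0.0
    if rng is None:
        if seed is None:
            raise ValueError("Monte-Carlo path requires a seed or rng")
        rng = np.random.default_rng(seed)
    if n_mc < 1_000:
        raise ValueError("n_mc must be at least 1000")
    x = joint.sample_barcodes(m, n_mc, rng)
    gm = joint.pdf_sorted(x)
    surv = _survival_power((2.0 * delta) ** m * gm, N - 1)
    rate = 1.0 - float(surv.mean())
    stderr = float(surv.std(ddof=1) / math.sqrt(n_mc))
    return rate, stderr


def noise_error(noise: NoiseModel, delta: float, m: int) -> float:
    """Mismatch probability ``eps_noise = 1 - (P(|E'| <= delta))^m``."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if m < 1:
        raise ValueError("m must be >= 1")
    inner = float(noise.interval_mass(delta))
    return float(-np.expm1(m * np.log(inner))) if inner > 0.0 else 1.0


def total_error(eps_dup: float, eps_noise: float) -> float:
    """Compounded error ``eps_tot = eps_dup + eps_noise - eps_dup*eps_noise``."""
    for v in (eps_dup, eps_noise):
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    return eps_dup + eps_noise - eps_dup * eps_noise


# ---------------------------------------------------------------------------
# Threshold optimization and pool-size planning
# ---------------------------------------------------------------------------


def _make_dup_rate_fn(joint, m, n_mc, rng):
    """eps_dup(delta, N) with Monte-Carlo samples shared across evaluations."""
    if joint.is_plain_uniform:
        delta_big = joint.base.delta_big
        fact = math.factorial(m)

        def eps_dup(delta: float, N: float) -> float:
            p = min(fact * (2.0 * delta / delta_big) ** m, 1.0)
            if p >= 1.0:
                return 1.0
            return float(-np.expm1((N - 1) * np.log1p(-p)))

        return eps_dup

    x = joint.sample_barcodes(m, n_mc, rng)
    gm = joint.pdf_sorted(x)

    def eps_dup(delta: float, N: float) -> float:
        surv = _survival_power((2.0 * delta) ** m * gm, N - 1)
        return 1.0 - float(surv.mean())

    return eps_dup


def optimize_delta(
    joint: JointBarcodeDistribution,
    noise: NoiseModel,
    m: int,
    N: int,
    n_grid: int = 200,
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    delta_bounds: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Find ``delta_opt`` minimizing ``eps_tot`` and the attained ``eps_min``.

    Searches a log-spaced grid over ``[1e-3 meV, Delta/2]`` (assuming a
    unimodal total error, with the grid guarding against violations), then
    refines with bounded scalar minimization in the best bracket.
    """
    if N < 2:
        raise ValueError("require N >= 2")
    lo, hi = delta_bounds if delta_bounds else (1e-3, joint.base.delta_big / 2.0)
    if noise.scale == 0.0:
        warnings.warn("degenerate zero-scale noise: delta_opt pinned at the "
                      "lower search bound", RuntimeWarning, stacklevel=2)
        if rng is None:
            rng = np.random.default_rng(seed if seed is not None else 0)
        dup = _make_dup_rate_fn(joint, m, n_mc, rng)
        return lo, total_error(dup(lo, N), 0.0)
    if rng is None and not joint.is_plain_uniform:
        if seed is None:
            raise ValueError("non-uniform densities need a seed or rng")
        rng = np.random.default_rng(seed)
    dup = _make_dup_rate_fn(joint, m, n_mc, rng)

    def tot(delta: float) -> float:
        return total_error(dup(delta, N), noise_error(noise, delta, m))

    grid = np.geomspace(lo, hi, n_grid)
    vals = np.array([tot(d) for d in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(tot, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-6})
    if res.fun <= vals[i]:
        return float(res.x), float(res.fun)
    return float(grid[i]), float(vals[i])


def max_pool_size(
    joint: JointBarcodeDistribution,
    noise: NoiseModel,
    m: int,
    eps0: float,
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    n_cap: int = 10**12,
) -> int:
    """Largest pool size ``N`` with minimized total error ``eps_min(N) <= eps0``.

    Uses integer bisection, relying on the monotonicity of ``eps_min`` in
    ``N``.  Returns 0 when even ``N = 2`` exceeds the tolerance, and the cap
    (default ``1e12``) when the tolerance is never exceeded below it.
    """
    if not 0.0 < eps0 < 1.0:
        raise ValueError("require 0 < eps0 < 1")
    if rng is None and not joint.is_plain_uniform:
        if seed is None:
            raise ValueError("non-uniform densities need a seed or rng")
        rng = np.random.default_rng(seed)
    # share one Monte-Carlo sample set across all N evaluations
    shared_rng = rng if rng is not None else np.random.default_rng(0)
    dup = _make_dup_rate_fn(joint, m, n_mc, shared_rng)
    lo_b, hi_b = 1e-3, joint.base.delta_big / 2.0
    grid = np.geomspace(lo_b, hi_b, 200)
    noise_vals = np.array([noise_error(noise, d, m) for d in grid])

    def eps_min(N: int) -> float:
        tots = np.array([total_error(dup(d, N), nv)
                         for d, nv in zip(grid, noise_vals)])
        return float(tots.min())

    if eps_min(2) > eps0:
        return 0
    lo, hi = 2, 2
    while eps_min(hi) <= eps0:
        if hi >= n_cap:
            return n_cap
        lo, hi = hi, min(hi * 8, n_cap)
    # invariant: eps_min(lo) <= eps0 < eps_min(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if eps_min(mid) <= eps0:
            lo = mid
        else:
            hi = mid
    return lo


# ---------------------------------------------------------------------------
# Poisson tagging mixtures
# ---------------------------------------------------------------------------


def mixture_error_rates(
    tagging: TaggingMixture,
    joint: JointBarcodeDistribution,
    noise: NoiseModel,
    delta: float,
    N: int,
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-multiplicity error table and weighted totals for a tagging mixture.

    For each multiplicity ``m`` with weight ``w_m`` (renormalized over
    ``m >= 1`` when untagged cells are excluded) the duplicate rate uses the
    sub-pool size ``N * w_m``, since duplication is only possible between
    barcodes of identical multiplicity.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ms, ws = tagging.weights()
    if rng is None and not joint.is_plain_uniform:
        if seed is None:
            raise ValueError("non-uniform densities need a seed or rng")
        rng = np.random.default_rng(seed)
    rows = []
    for m, w in zip(ms, ws):
        n_sub = N * w
        if joint.is_plain_uniform:
            dup = _make_dup_rate_fn(joint, int(m), n_mc, rng)(delta, max(n_sub, 1.0))
            se = 0.0
        else:
            dup, se = duplicate_rate_continuous(
                joint, int(m), delta, max(int(round(n_sub)), 1),
                n_mc=n_mc, rng=rng)
        rows.append({
            "m": int(m), "weight": float(w), "n_sub": float(n_sub),
            "eps_dup": float(dup), "eps_noise": noise_error(noise, delta, int(m)),
            "mc_stderr": se,
        })
    table = pd.DataFrame(rows)
    totals = {
        "eps_dup": float((table["weight"] * table["eps_dup"]).sum()),
        "eps_noise": float((table["weight"] * table["eps_noise"]).sum()),
        "untagged_fraction": tagging.untagged_fraction,
    }
    totals["eps_tot"] = total_error(min(totals["eps_dup"], 1.0),
                                    min(totals["eps_noise"], 1.0))
    return table, totals


def solve_delta_for_noise(tagging: TaggingMixture, noise: NoiseModel,
                          eps0: float) -> float:
    """The gate ``delta`` at which the weighted noise error equals ``eps0``."""
    ms, ws = tagging.weights()

    def f(delta: float) -> float:
        inner = noise.interval_mass(delta)
        return float(np.sum(ws * -np.expm1(ms * np.log(np.maximum(inner, 1e-300))))) - eps0

    lo = 1e-9
    hi = max(10.0 * noise.scale, 1e-6)
    while f(hi) > 0.0:
        hi *= 4.0
        if hi > 1e6:
            raise RuntimeError("no delta brings the weighted noise error "
                               f"down to eps0={eps0}")
    if f(lo) < 0.0:  # even a vanishing gate meets the tolerance
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def duplicate_loss(
    tagging: TaggingMixture,
    joint: JointBarcodeDistribution,
    noise: NoiseModel,
    N: int,
    eps0: float,
    n_mc: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Duplicate-induced sample loss when the gate is set by the noise budget.

    Chooses ``delta`` so the weighted noise error equals ``eps0`` (duplicates
    are detectable and discarded, so only noise mismatches count as errors),
    then returns the weighted duplicate rate at that gate as the loss
    fraction.  Returns ``(loss, delta)``.
    """
    if not 0.0 < eps0 < 1.0:
        raise ValueError("require 0 < eps0 < 1")
    delta = solve_delta_for_noise(tagging, noise, eps0)
    table, totals = mixture_error_rates(tagging, joint, noise, delta, N,
                                        n_mc=n_mc, seed=seed, rng=rng)
    return totals["eps_dup"], delta


# ---------------------------------------------------------------------------
# One-call planning report
# ---------------------------------------------------------------------------


def plan_scenario(
    joint: JointBarcodeDistribution,
    noise: NoiseModel,
    tagging: TaggingMixture,
    N: int,
    eps0: float,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> ErrorReport:
    """Full planning report for one scenario (used by the ``plan`` command)."""
    rng = np.random.default_rng(seed) if seed is not None else None
    report = ErrorReport(N=N, eps0=eps0)
    if tagging.mode == "fixed":
        m = tagging.m
        d_opt, e_min = optimize_delta(joint, noise, m, N, n_mc=n_mc, rng=rng)
        report.delta_opt = d_opt
        report.eps_min = e_min
        report.delta = d_opt
        dup, se = duplicate_rate_continuous(joint, m, d_opt, N, n_mc=n_mc,
                                            rng=rng) if not joint.is_plain_uniform \
            else duplicate_rate_continuous(joint, m, d_opt, N)
        report.eps_dup = dup
        report.mc_stderr = se
        report.eps_noise = noise_error(noise, d_opt, m)
        report.eps_tot = total_error(min(dup, 1.0), report.eps_noise)
        if joint.is_plain_uniform:
            report.B_eff = effective_barcodes(joint.base, d_opt, m)
        report.extra["m"] = m
    else:
        loss, delta = duplicate_loss(tagging, joint, noise, N, eps0,
                                     n_mc=n_mc, rng=rng)
        table, totals = mixture_error_rates(tagging, joint, noise, delta, N,
                                            n_mc=n_mc, rng=rng)
        report.delta = delta
        report.eps_dup = totals["eps_dup"]
        report.eps_noise = totals["eps_noise"]
        report.eps_tot = totals["eps_tot"]
        report.extra["duplicate_loss"] = loss
        report.extra["untagged_fraction"] = totals["untagged_fraction"]
        report.extra["lambda"] = tagging.lam
        report.extra["per_m"] = table.to_dict(orient="records")
    return report
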