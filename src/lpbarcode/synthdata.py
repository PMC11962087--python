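"""Seeded synthetic-data generators for the full barcoding pipeline.

Everything the other modules consume can be generated here without any
external data: an LP library density (six Gaussian envelopes from six
semiconductor compositions, spanning roughly 800-1100 meV), tagged pools,
two-run measurement experiments with ground truth, emission spectra for
the extraction pipeline, and repeated single-LP measurements for noise
fitting.  Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import BarcodePool, apply_noise, sample_pool
from .spectra import Spectrum
from .theory import JointBarcodeDistribution, NoiseModel, SpectralDistribution, TaggingMixture

__all__ = [
    "LibrarySpec",
    "TwoRunTruth",
    "make_library",
    "default_library",
    "flow_noise",
    "microscope_noise",
    "make_two_run_experiment",
    "make_spectra_dataset",
    "make_repeat_measurements",
]

# Six compositions, emission envelopes centered 825..1075 meV at 50 meV
# spacing; the per-envelope spread reproduces broad but separable modes.
DEFAULT_ENVELOPE_CENTERS = tuple(825.0 + 50.0 * i for i in range(6))
DEFAULT_ENVELOPE_SD = 12.0


@dataclass(frozen=True)
class LibrarySpec:
    """Specification of an LP library's emission-line density."""

    envelopes: tuple[tuple[float, float, float], ...] = tuple(
        (c, DEFAULT_ENVELOPE_SD, 1.0 / 6.0) for c in DEFAULT_ENVELOPE_CENTERS)
    f_dm: float = 0.0
    fsr_lo: float = 50.0
    fsr_hi: float = 70.0

    def __post_init__(self) -> None:
        centers = [c for c, _, _ in self.envelopes]
        if sorted(centers) != centers:
            raise ValueError("envelope centers must be ascending")
        wsum = sum(w for _, _, w in self.envelopes)
        if not math.isclose(wsum, 1.0, abs_tol=1e-6):
            raise ValueError(f"envelope weights sum to {wsum}, expected 1")


@dataclass
class TwoRunTruth:
    """Ground truth of a two-run experiment: a partial bijection of cells.

    ``pairs`` lists the (c1_id, c2_id) rows for cells measured in both
    runs; ``c1_only`` / ``c2_only`` the rest.  ``true_pool`` holds the
    noise-free barcodes keyed by the shared underlying index.
    """

    pairs: pd.DataFrame
    c1_only: list = field(default_factory=list)
    c2_only: list = field(default_factory=list)
    true_pool: BarcodePool | None = None


def make_library(spec: LibrarySpec | None = None) -> JointBarcodeDistribution:
    """Build the joint barcode distribution from a library spec."""
    spec = spec or LibrarySpec()
    if len(spec.envelopes) == 1 and spec.f_dm == 0.0:
        c, s, _ = spec.envelopes[0]
        base = SpectralDistribution.gaussian(sigma=s, center=c)
    else:
        base = SpectralDistribution.gaussian_mixture(spec.envelopes)
    return JointBarcodeDistribution(base=base, f_dm=spec.f_dm,
                                    fsr_lo=spec.fsr_lo, fsr_hi=spec.fsr_hi)


def default_library(f_dm: float = 0.0) -> JointBarcodeDistribution:
    """The six-envelope library with an optional dual-mode fraction."""
    return make_library(LibrarySpec(f_dm=f_dm))


def flow_noise() -> NoiseModel:
    """Flow-cytometry line-noise preset (alpha = 0.25 meV, beta = 1.37)."""
    return NoiseModel.generalized(alpha=0.25, beta=1.37)


def microscope_noise() -> NoiseModel:
    """Confocal-microscope line-noise preset (alpha = 0.047 meV, beta = 1.28)."""
    return NoiseModel.generalized(alpha=0.047, beta=1.28)


# ---------------------------------------------------------------------------
# Two-run matching experiments
# ---------------------------------------------------------------------------


def _measure(pool: BarcodePool, noise: NoiseModel, line_dropout: float,
             rng: np.random.Generator, prefix: str) -> tuple[BarcodePool, list]:
    """One noisy measurement of a pool; returns the run pool and lost ids."""
    noisy = apply_noise(pool, noise, rng=rng)
    ids, energies, kept_idx = [], [], []
    for i in range(len(noisy)):
        e = noisy.energies[i]
        if line_dropout > 0.0:
            e = e[rng.random(e.size) >= line_dropout]
        if e.size == 0:
            continue
        kept_idx.append(i)
        ids.append(f"{prefix}-{noisy.cell_ids[i]}")
        energies.append(e)
    kept = set(kept_idx)
    lost = [noisy.cell_ids[i] for i in range(len(noisy)) if i not in kept]
    run = BarcodePool(ids, energies,
                      provenance={**pool.provenance, "run": prefix},
                      scalars=None if pool.scalars is None
                      else pool.scalars[kept_idx])
    return run, lost


def make_two_run_experiment(
    joint: JointBarcodeDistribution,
    tagging: TaggingMixture,
    noise: NoiseModel,
    N: int,
    cell_dropout: float = 0.10,
    line_dropout: float = 0.0,
    seed: int = 0,
    with_scalars: bool = False,
) -> tuple[BarcodePool, BarcodePool, TwoRunTruth]:
    """Simulate two flow-cytometry measurements of one tagged sample.

    One true pool is drawn; runs C1 and C2 measure it with independent line
    noise.  C2 loses whole cells at ``cell_dropout`` (handling losses
    between runs) and each measurement independently loses lines at
    ``line_dropout``.  ``with_scalars`` attaches a per-cell lognormal
    scalar (a fluorescence-like channel) carried through both runs.
    """
    if not 0.0 <= cell_dropout < 1.0 or not 0.0 <= line_dropout < 1.0:
        raise ValueError("dropout rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_pool = sample_pool(joint, tagging, N, rng=rng)
    if with_scalars:
        true_pool.scalars = rng.lognormal(mean=4.0, sigma=0.6,
                                          size=len(true_pool))
    c1, lost1 = _measure(true_pool, noise, line_dropout, rng, "c1")
    keep = np.flatnonzero(rng.random(len(true_pool)) >= cell_dropout)
    c2_src = true_pool.subset(keep)
    c2, lost2 = _measure(c2_src, noise, line_dropout, rng, "c2")
    ids1 = {cid.removeprefix("c1-"): cid for cid in c1.cell_ids}
    ids2 = {cid.removeprefix("c2-"): cid for cid in c2.cell_ids}
    shared = sorted(set(ids1) & set(ids2))
    pairs = pd.DataFrame({"c1_id": [ids1[s] for s in shared],
                          "c2_id": [ids2[s] for s in shared]})
    truth = TwoRunTruth(
        pairs=pairs,
        c1_only=[ids1[s] for s in set(ids1) - set(ids2)],
        c2_only=[ids2[s] for s in set(ids2) - set(ids1)],
        true_pool=true_pool)
    return c1, c2, truth


# ---------------------------------------------------------------------------
# Instrument emulation for the extraction pipeline
# ---------------------------------------------------------------------------


def make_spectra_dataset(
    pool: BarcodePool,
    e_lo: float = 780.0,
    e_hi: float = 1140.0,
    step: float = 0.2,
    linewidth: float = 0.4,
    snr: float = 50.0,
    seed: int = 0,
    mode: str = "flow",
    patch: int = 3,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Emit synthetic emission spectra for a barcode pool, with ground truth.

    Flow mode yields one spectrum per cell (unit-amplitude Gaussian lines
    plus white noise of standard deviation ``1/snr``).  Imaging mode lays
    each LP line out over a ``patch x patch`` pixel block (pixel blocks of
    one cell are placed side by side on a row per cell) and emits one
    spectrum per pixel.  The truth frame lists every line with its origin
    and whether it fell inside the grid.
    """
    if mode not in ("flow", "imaging"):
        raise ValueError("mode must be 'flow' or 'imaging'")
    rng = np.random.default_rng(seed)
    grid = np.arange(e_lo, e_hi + step / 2, step)
    sigma_noise = 1.0 / snr if np.isfinite(snr) else 0.0
    spectra: list[Spectrum] = []
    truth_rows = []

    def line_profile(energies: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid)
        for e in energies:
            out += np.exp(-0.5 * ((grid - e) / linewidth) ** 2)
        return out

    if mode == "flow":
        for i in range(len(pool)):
            e = pool.energies[i]
            y = line_profile(e)
            if sigma_noise:
                y = y + rng.normal(0.0, sigma_noise, size=grid.size)
            spectra.append(Spectrum(grid.copy(), y, origin=pool.cell_ids[i]))
            for line_idx, en in enumerate(e):
                truth_rows.append({
                    "origin_id": pool.cell_ids[i], "cell_id": pool.cell_ids[i],
                    "line_index": line_idx, "energy_meV": float(en),
                    "in_grid": bool(e_lo <= en <= e_hi)})
    else:
        for i in range(len(pool)):
            e = pool.energies[i]
            for line_idx, en in enumerate(e):
                x0 = line_idx * (patch + 2)
                y0 = i * (patch + 2)
                for dx in range(patch):
                    for dy in range(patch):
                        y = np.exp(-0.5 * ((grid - en) / linewidth) ** 2)
                        if sigma_noise:
                            y = y + rng.normal(0.0, sigma_noise, size=grid.size)
                        spectra.append(Spectrum(grid.copy(), y,
                                                origin=(x0 + dx, y0 + dy)))
                truth_rows.append({
                    "origin_id": pool.cell_ids[i], "cell_id": pool.cell_ids[i],
                    "line_index": line_idx, "energy_meV": float(en),
                    "x0": x0, "y0": y0, "patch": patch,
                    "in_grid": bool(e_lo <= en <= e_hi)})
    return spectra, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Repeated measurements for noise fitting
# ---------------------------------------------------------------------------


def make_repeat_measurements(
    n_lp: int,
    n_repeats: int,
    noise: NoiseModel,
    seed: int = 0,
    library: JointBarcodeDistribution | None = None,
) -> pd.DataFrame:
    """Repeated line measurements of single LPs (for :func:`matching.fit_noise`).

    Each LP's true energy is drawn from the library density; every repeat
    adds an independent noise draw.  Columns: ``lp_id, repeat, energy_meV,
    true_energy_meV``.
    """
    if n_lp < 1 or n_repeats < 2:
        raise ValueError("require n_lp >= 1 and n_repeats >= 2")
    rng = np.random.default_rng(seed)
    lib = library or default_library()
    true_e = lib.base.sample(n_lp, rng)
    draws = noise.sample((n_lp, n_repeats), rng)
    return pd.DataFrame({
        "lp_id": np.repeat([f"lp{i:04d}" for i in range(n_lp)], n_repeats),
        "repeat": np.tile(np.arange(n_repeats), n_lp),
        "energy_meV": (true_e[:, None] + draws).ravel(),
        "true_energy_meV": np.repeat(true_e, n_repeats),
    })
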