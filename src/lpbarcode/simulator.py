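"""Monte-Carlo barcode pools, Chebyshev duplicate counting, division simulation.

Complements :mod:`lpbarcode.theory`: where the theory module integrates the
duplicate-rate model, this module draws explicit pools of barcodes, counts
duplicates empirically with the Chebyshev metric (two barcodes of equal
multiplicity collide when every sorted line pair differs by at most
``delta``), and simulates how barcodes built from multiplet LPs survive
stochastic inheritance across cell divisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .theory import (
    JointBarcodeDistribution,
    NoiseModel,
    TaggingMixture,
)

__all__ = [
    "Barcode",
    "BarcodePool",
    "DivisionConfig",
    "DuplicateReport",
    "sample_pool",
    "apply_noise",
    "count_duplicates",
    "simulate_divisions",
]


@dataclass
class Barcode:
    """One cell's optical barcode: sorted emission-line energies in meV.

    ``plet_ids`` groups lines into physical units (one id per line; lines of
    a dual-mode LP or of a k-plet share an id).  Spectral extraction may
    produce multiplicity-0 records for untagged cells; analysis pools are
    expected to hold ``m >= 1`` barcodes.
    """

    cell_id: str
    energies: np.ndarray
    plet_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 1:
            raise ValueError("energies must be one-dimensional")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("energies must be sorted ascending")
        if self.plet_ids is not None:
            self.plet_ids = np.asarray(self.plet_ids)
            if self.plet_ids.shape != self.energies.shape:
                raise ValueError("plet_ids must parallel energies")

    @property
    def m(self) -> int:
        return int(self.energies.size)

    @property
    def untagged(self) -> bool:
        return self.m == 0


class BarcodePool:
    """A collection of barcodes with generation provenance.

    Stored column-wise (id list + per-cell energy arrays) so that
    per-multiplicity matrices for vectorized neighbor searches are cheap to
    build.
    """

    def __init__(self, cell_ids, energies, plet_ids=None, provenance=None,
                 scalars=None):
        self.cell_ids = list(cell_ids)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        self.energies = [np.asarray(e, dtype=float) for e in energies]
        if len(self.energies) != len(self.cell_ids):
            raise ValueError("one energy array per cell id required")
        self.plet_ids = None if plet_ids is None else [np.asarray(p) for p in plet_ids]
        self.provenance = dict(provenance or {})
        # optional per-cell scalar (e.g. a fluorescence channel)
        self.scalars = None if scalars is None else np.asarray(scalars, dtype=float)
        self._by_m: dict[int, tuple[np.ndarray, np.ndarray]] | None = None

    # -- container protocol -------------------------------------------

    def __len__(self) -> int:
        return len(self.cell_ids)

    def __getitem__(self, i: int) -> Barcode:
        return Barcode(
            self.cell_ids[i], self.energies[i],
            None if self.plet_ids is None else self.plet_ids[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_barcodes(cls, barcodes, provenance=None) -> "BarcodePool":
        bl = list(barcodes)
        return cls([b.cell_id for b in bl], [b.energies for b in bl],
                   plet_ids=None if any(b.plet_ids is None for b in bl)
                   else [b.plet_ids for b in bl],
                   provenance=provenance)

    def multiplicities(self) -> np.ndarray:
        return np.array([e.size for e in self.energies], dtype=int)

    def by_multiplicity(self) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Map ``m -> (cell indices, (n, m) sorted-energy matrix)``."""
        if self._by_m is None:
            ms = self.multiplicities()
            out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for m in np.unique(ms):
                if m == 0:
                    continue
                idx = np.flatnonzero(ms == m)
                mat = np.vstack([self.energies[i] for i in idx])
                out[int(m)] = (idx, mat)
            self._by_m = out
        return self._by_m

    def subset(self, indices, provenance=None) -> "BarcodePool":
        indices = list(indices)
        return BarcodePool(
            [self.cell_ids[i] for i in indices],
            [self.energies[i] for i in indices],
            plet_ids=None if self.plet_ids is None
            else [self.plet_ids[i] for i in indices],
            provenance=provenance or self.provenance,
            scalars=None if self.scalars is None else self.scalars[indices])


@dataclass(frozen=True)
class DivisionConfig:
    """Configuration of a multiplet-inheritance division simulation.

    ``plet_size`` is k, the number of lines per physical tagging unit
    (1 = singlet LP); cells start with a Poisson(``lam / k``) number of
    k-plets so that the mean LP-line count per cell is ``lam`` in all cases.
    """

    plet_size: int = 1
    lam: float = 6.0
    generations: int = 6
    eps0: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plet_size < 1:
            raise ValueError("plet_size must be >= 1")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


# ---------------------------------------------------------------------------
# Pool generation
# ---------------------------------------------------------------------------


def _rng_from(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("a seed or rng is required for stochastic operations")
    return np.random.default_rng(seed)


def sample_pool(
    joint: JointBarcodeDistribution,
    tagging: TaggingMixture,
    N: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "cell",
) -> BarcodePool:
    """Draw a pool of ``N`` cells tagged per ``tagging`` from ``joint``.

    Each LP is independently dual-mode with probability ``joint.f_dm``
    (contributing a correlated line pair spaced by the FSR), otherwise it
    contributes one line drawn from the base density.  Cells left with zero
    LPs are dropped from the pool; their count is recorded in the
    provenance under ``n_untagged``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = _rng_from(seed, rng)
    if tagging.mode == "fixed" and joint.f_dm == 0.0:
        # fixed multiplicity, single-mode LPs: one matrix draw, no assembly
        mat = joint.sample_barcodes(tagging.m, N, rng)
        ids = [f"{id_prefix}{i:06d}" for i in range(N)]
        plet = np.arange(tagging.m)
        prov = {"n_requested": N, "n_untagged": 0, "seed": seed,
                "tagging": "fixed"}
        return BarcodePool(ids, list(mat), plet_ids=[plet] * N, provenance=prov)
    lp_counts = tagging.sample(N, rng)
    tagged = np.flatnonzero(lp_counts > 0)
    n_untagged = int(N - tagged.size)
    counts = lp_counts[tagged]
    total_lps = int(counts.sum())
    dual = (rng.random(total_lps) < joint.f_dm) if joint.f_dm > 0 \
        else np.zeros(total_lps, dtype=bool)
    primary = joint.base.sample(total_lps, rng)
    fsr = rng.uniform(joint.fsr_lo, joint.fsr_hi, size=int(dual.sum()))

    cell_ids, energies, plets = [], [], []
    offsets = np.concatenate([[0], np.cumsum(counts)])
    dual_pos = np.cumsum(dual) - dual  # index into fsr for each dual LP
    for c, cell_idx in enumerate(tagged):
        sl = slice(offsets[c], offsets[c + 1])
        e_primary = primary[sl]
        d = dual[sl]
        lp_index = np.arange(counts[c])
        lines = [e_primary]
        plet = [lp_index]
        if d.any():
            second = e_primary[d] + fsr[dual_pos[sl][d]]
            lines.append(second)
            plet.append(lp_index[d])
        e = np.concatenate(lines)
        p = np.concatenate(plet)
        order = np.argsort(e, kind="stable")
        cell_ids.append(f"{id_prefix}{cell_idx:06d}")
        energies.append(e[order])
        plets.append(p[order])
    if not cell_ids:
        raise ValueError("pool is empty after removing untagged cells")
    prov = {"n_requested": N, "n_untagged": n_untagged,
            "seed": seed, "tagging": tagging.mode}
    return BarcodePool(cell_ids, energies, plet_ids=plets, provenance=prov)


def apply_noise(
    pool: BarcodePool,
    noise: NoiseModel,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BarcodePool:
    """Independently perturb every line by a draw from ``phi`` and re-sort."""
    rng = _rng_from(seed, rng)
    sizes = pool.multiplicities()
    prov = {**pool.provenance, "noise": noise.family}
    if sizes.size and (sizes == sizes[0]).all() and sizes[0] > 0:
        # homogeneous multiplicity: perturb and re-sort as one matrix
        mat = np.vstack(pool.energies) + noise.sample((len(pool), int(sizes[0])), rng)
        order = np.argsort(mat, axis=1, kind="stable")
        sorted_mat = np.take_along_axis(mat, order, axis=1)
        plets = None
        if pool.plet_ids is not None:
            pmat = np.vstack(pool.plet_ids)
            plets = list(np.take_along_axis(pmat, order, axis=1))
        return BarcodePool(pool.cell_ids, list(sorted_mat), plet_ids=plets,
                           provenance=prov, scalars=pool.scalars)
    draws = noise.sample(int(sizes.sum()), rng)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    energies, plets = [], []
    for i in range(len(pool)):
        e = pool.energies[i] + draws[offsets[i]:offsets[i + 1]]
        order = np.argsort(e, kind="stable")
        energies.append(e[order])
        if pool.plet_ids is not None:
            plets.append(pool.plet_ids[i][order])
    return BarcodePool(pool.cell_ids, energies,
                       plet_ids=plets if pool.plet_ids is not None else None,
                       provenance=prov, scalars=pool.scalars)


# ---------------------------------------------------------------------------
# Duplicate counting (Chebyshev metric)
# ---------------------------------------------------------------------------


@dataclass
class DuplicateReport:
    """Per-multiplicity duplicate tallies from empirical counting."""

    delta: float
    per_m: dict[int, dict] = field(default_factory=dict)
    duplicate_ids: frozenset = frozenset()

    @property
    def n_total(self) -> int:
        return sum(v["n"] for v in self.per_m.values())

    @property
    def n_duplicates(self) -> int:
        return sum(v["n_dup"] for v in self.per_m.values())

    @property
    def pooled_fraction(self) -> float:
        n = self.n_total
        return self.n_duplicates / n if n else 0.0


def _duplicate_flags_sweep(mat: np.ndarray, delta: float,
                           max_pairs_chunk: int = 4_000_000) -> np.ndarray:
    """Flags rows of a sorted-energy matrix that have a Chebyshev neighbor.

    Rows are sorted by their first coordinate; any Chebyshev neighbor within
    ``delta`` must then fall inside the first-coordinate window
    ``[E_1 - delta, E_1 + delta]``, which a sliding ``searchsorted`` window
    enumerates exactly.
    """
    n = mat.shape[0]
    flags = np.zeros(n, dtype=bool)
    if n < 2:
        return flags
    order = np.argsort(mat[:, 0], kind="stable")
    x = mat[order]
    col0 = np.ascontiguousarray(x[:, 0])
    lo = np.searchsorted(col0, col0 - delta, side="left")
    hi = np.searchsorted(col0, col0 + delta, side="right")
    counts = hi - lo  # window includes the row itself
    sflags = np.zeros(n, dtype=bool)
    start = 0
    csum = np.concatenate([[0], np.cumsum(counts)])
    while start < n:
        stop = int(np.searchsorted(csum, csum[start] + max_pairs_chunk,
                                   side="left"))
        stop = max(stop, start + 1)
        stop = min(stop, n)
        c = counts[start:stop]
        total = int(c.sum())
        if total:
            rows = np.repeat(np.arange(start, stop), c)
            base = np.repeat(csum[start:stop] - csum[start], c)
            cols = lo[rows] + (np.arange(total) - base)
            keep = cols != rows
            rows, cols = rows[keep], cols[keep]
            if rows.size:
                cheb = np.max(np.abs(x[rows] - x[cols]), axis=1)
                hit = cheb <= delta
                np.logical_or.at(sflags, rows[hit], True)
        start = stop
    flags[order] = sflags
    return flags


def _duplicate_flags_brute(mat: np.ndarray, delta: float) -> np.ndarray:
    """O(n^2) oracle: pairwise Chebyshev distances via ``cdist``."""
    n = mat.shape[0]
    if n < 2:
        return np.zeros(n, dtype=bool)
    d = cdist(mat, mat, metric="chebyshev")
    np.fill_diagonal(d, np.inf)
    return (d <= delta).any(axis=1)


def count_duplicates(pool: BarcodePool, delta: float,
                     method: str = "indexed") -> DuplicateReport:
    """Count barcodes with at least one same-multiplicity Chebyshev neighbor.

    Duplicates are only counted within a multiplicity class: measurements of
    different ``m`` are presumed to originate from distinct barcodes.
    ``method="indexed"`` uses the sorted first-coordinate sweep;
    ``method="brute"`` is the quadratic oracle — both flag exactly the same
    cells.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if method not in ("indexed", "brute"):
        raise ValueError("method must be 'indexed' or 'brute'")
    flag_fn = _duplicate_flags_sweep if method == "indexed" else _duplicate_flags_brute
    report = DuplicateReport(delta=delta)
    dup_ids: set = set()
    for m, (idx, mat) in pool.by_multiplicity().items():
        flags = flag_fn(mat, delta)
        n_dup = int(flags.sum())
        report.per_m[m] = {"n": int(idx.size), "n_dup": n_dup,
                           "fraction": n_dup / idx.size}
        dup_ids.update(pool.cell_ids[i] for i in idx[flags])
    report.duplicate_ids = frozenset(dup_ids)
    return report


# ---------------------------------------------------------------------------
# Cell-division simulation with multiplet inheritance
# ---------------------------------------------------------------------------


def _solve_division_delta(noise: NoiseModel, ms: np.ndarray, ws: np.ndarray,
                          eps0: float) -> float:
    """Gate at which the multiplicity-weighted noise error equals ``eps0``."""

    def f(delta: float) -> float:
        inner = max(float(noise.interval_mass(delta)), 1e-300)
        return float(np.sum(ws * -np.expm1(ms * math.log(inner)))) - eps0

    lo, hi = 1e-9, max(10.0 * noise.scale, 1e-6)
    while f(hi) > 0.0:
        hi *= 4.0
        if hi > 1e6:
            raise RuntimeError("noise too heavy: no delta meets eps0")
    if f(lo) < 0.0:
        return lo
    from scipy.optimize import brentq
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_divisions(
    joint: JointBarcodeDistribution,
    config: DivisionConfig,
    noise: NoiseModel,
    N: int,
    inheritance: str = "bernoulli",
    include_dual_mode: bool = False,
) -> pd.DataFrame:
    """Track identifiable cells across division rounds under k-plet tagging.

    Generation 0 tags ``N`` cells with Poisson(``lam/k``) k-plets whose line
    energies are drawn from the library density.  At each division every
    plet is inherited independently by one of the two daughters (Bernoulli
    1/2 per plet by default; ``inheritance="even"`` splits each cell's plets
    as evenly as possible).  Line energies never change.  Per generation the
    gate ``delta`` is chosen so the multiplicity-weighted noise error equals
    ``eps0``, and a cell counts as identifiable when it holds at least one
    plet and has no same-multiplicity Chebyshev neighbor within ``delta``.

    Returns a frame with columns ``generation, n_cells, n_identifiable,
    delta_meV, n_lines``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if inheritance not in ("bernoulli", "even"):
        raise ValueError("inheritance must be 'bernoulli' or 'even'")
    rng = np.random.default_rng(config.seed)
    k = config.plet_size
    plets_per_cell = rng.poisson(config.lam / k, size=N)
    n_plets = int(plets_per_cell.sum())
    # plet lines: k draws from the library per plet (dual modes off by default)
    lib = joint if include_dual_mode else JointBarcodeDistribution(
        base=joint.base, f_dm=0.0, fsr_lo=joint.fsr_lo, fsr_hi=joint.fsr_hi)
    plet_lines = lib.base.sample(n_plets * k, rng).reshape(n_plets, k)
    plet_cell = np.repeat(np.arange(N, dtype=np.int64), plets_per_cell)

    records = []
    for gen in range(config.generations + 1):
        order = np.argsort(plet_cell, kind="stable")
        pc = plet_cell[order]
        pl = plet_lines[order]
        uniq, starts, counts = np.unique(pc, return_index=True, return_counts=True)
        m_cells = counts * k
        ms, inv = np.unique(m_cells, return_inverse=True)
        ws = np.bincount(inv).astype(float)
        ws /= ws.sum()
        delta = _solve_division_delta(noise, ms.astype(float), ws, config.eps0)
        n_ident = 0
        for mi, m in enumerate(ms):
            rows = np.flatnonzero(inv == mi)
            mat = np.empty((rows.size, int(m)))
            for r, cell_row in enumerate(rows):
                s = starts[cell_row]
                mat[r] = np.sort(pl[s:s + counts[cell_row]].ravel())
            flags = _duplicate_flags_sweep(mat, delta)
            n_ident += int((~flags).sum())
        records.append({"generation": gen, "n_cells": int(uniq.size),
                        "n_identifiable": n_ident, "delta_meV": delta,
                        "n_lines": int(n_plets * k)})
        if gen < config.generations:
            if inheritance == "bernoulli":
                side = rng.integers(0, 2, size=n_plets)
            else:
                # per cell, deal plets alternately after a random shuffle
                side = np.empty(n_plets, dtype=np.int64)
                perm = rng.permutation(n_plets)
                pc_perm = plet_cell[perm]
                o2 = np.argsort(pc_perm, kind="stable")
                ranks = np.empty(n_plets, dtype=np.int64)
                _, cstarts, ccounts = np.unique(pc_perm[o2], return_index=True,
                                                return_counts=True)
                within = np.arange(n_plets) - np.repeat(cstarts, ccounts)
                ranks[perm[o2]] = within % 2
                side = ranks
            plet_cell = plet_cell * 2 + side
    return pd.DataFrame.from_records(records)
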