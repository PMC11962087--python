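"""Cross-run barcode matching and noise-model estimation.

Two flow-cytometry runs of the same tagged sample yield barcode pools C1
and C2.  Candidate pairs are scored by aligning their sorted line lists
(order-preserving, one-to-one, only pairs within an energy gate may match)
and rewarding close lines while penalizing unmatched ones:

    s(a, b) = sum_matched (1 - |dE|/gate) - gap_penalty * (m_a + m_b - 2k)

The distribution of within-run scores (S_self, which contains only
incorrect pairings) calibrates a score threshold; cross-run pairs (S_cross)
above it are resolved one-to-one into accepted matches.  The module also
fits the generalized-Gaussian line-noise model from repeated measurements
of the same LPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .simulator import Barcode, BarcodePool

__all__ = [
    "ScoreParams",
    "MatchSet",
    "NoiseFit",
    "align_lines",
    "score_pair",
    "build_score_sets",
    "select_threshold",
    "match_pools",
    "fit_noise",
]

# DP combines (maximize matched count, then minimize summed |dE|) into one
# scalar: value = k * _BIG - sum|dE|.  Valid while sum|dE| <= m*gate << _BIG.
_BIG = 1.0e4


@dataclass(frozen=True)
class ScoreParams:
    """Scoring configuration; the 1.5 meV gate is the per-line match window."""

    gate: float = 1.5
    gap_penalty: float = 0.25
    min_matched_lines: int = 2

    def __post_init__(self) -> None:
        if self.gate <= 0:
            raise ValueError("gate must be positive")
        if self.gap_penalty < 0:
            raise ValueError("gap_penalty must be non-negative")
        if self.min_matched_lines < 1:
            raise ValueError("min_matched_lines must be >= 1")


@dataclass
class NoiseFit:
    """Maximum-likelihood generalized-Gaussian noise parameters."""

    alpha: float
    beta: float
    n_lines: int
    loglik: float


@dataclass
class MatchSet:
    """Scored candidate pairs between two runs plus the resolved matches."""

    params: ScoreParams
    cross: pd.DataFrame  # columns i, j, score, k_matched, sum_abs_de
    self_scores: np.ndarray
    c1_ids: list = field(default_factory=list)
    c2_ids: list = field(default_factory=list)
    threshold: float | None = None
    matches: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pairwise alignment and scoring
# ---------------------------------------------------------------------------


def _energies(x) -> np.ndarray:
    return x.energies if isinstance(x, Barcode) else np.asarray(x, dtype=float)


def align_lines(a, b, gate: float = 1.5) -> list[tuple[int, int]]:
    """Order-preserving one-to-one line assignment between two sorted barcodes.

    Maximizes the number of matched pairs, breaking ties by the smallest
    summed |dE|; only pairs with |dE| <= gate may match.  Computed by
    dynamic programming (sequence alignment with gaps).
    """
    ea, eb = _energies(a), _energies(b)
    na, nb = ea.size, eb.size
    if na == 0 or nb == 0:
        return []
    val = np.zeros((na + 1, nb + 1))
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0 gap-a, 1 gap-b, 2 match
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = val[i - 1, j]
            mv = 0
            if val[i, j - 1] > best:
                best, mv = val[i, j - 1], 1
            d = abs(ea[i - 1] - eb[j - 1])
            if d <= gate:
                cand = val[i - 1, j - 1] + (_BIG - d)
                if cand > best:
                    best, mv = cand, 2
            val[i, j], move[i, j] = best, mv
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        mv = move[i, j]
        if mv == 2:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif mv == 1:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return pairs


def score_pair(a, b, params: ScoreParams | None = None) -> float:
    """Match score of two barcodes; ``-inf`` marks non-candidates."""
    params = params or ScoreParams()
    ea, eb = _energies(a), _energies(b)
    pairs = align_lines(ea, eb, params.gate)
    k = len(pairs)
    if k < params.min_matched_lines:
        return float("-inf")
    sum_de = sum(abs(ea[i] - eb[j]) for i, j in pairs)
    return k - sum_de / params.gate \
        - params.gap_penalty * (ea.size + eb.size - 2 * k)


def _batch_align(A: np.ndarray, B: np.ndarray, gate: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized alignment over P pairs of equal shape: A (P, ma), B (P, mb).

    Returns matched counts ``k`` and summed |dE| per pair.  Same recurrence
    as :func:`align_lines`, with the lexicographic objective folded into a
    single scalar.
    """
    P, ma = A.shape
    mb = B.shape[1]
    prev = np.zeros((P, mb + 1))
    cur = np.empty((P, mb + 1))
    for i in range(1, ma + 1):
        cur[:, 0] = 0.0
        ai = A[:, i - 1]
        for j in range(1, mb + 1):
            d = np.abs(ai - B[:, j - 1])
            diag = prev[:, j - 1] + (_BIG - d)
            diag[d > gate] = -np.inf
            cur[:, j] = np.maximum(np.maximum(prev[:, j], cur[:, j - 1]), diag)
        prev, cur = cur, prev
    v = prev[:, mb]
    k = np.round(v / _BIG).astype(np.int64)  # sum|dE|/BIG < 0.5 always
    sum_de = k * _BIG - v
    return k, sum_de


def _class_rows(pool: BarcodePool) -> np.ndarray:
    """Row index of each cell within its multiplicity-class matrix."""
    rows = np.zeros(len(pool), dtype=np.int64)
    for _, (idx, _mat) in pool.by_multiplicity().items():
        rows[idx] = np.arange(idx.size)
    return rows


def _score_pairs_bulk(pool_a: BarcodePool, pool_b: BarcodePool,
                      ii: np.ndarray, jj: np.ndarray, params: ScoreParams
                      ) -> pd.DataFrame:
    """Score arbitrary (i, j) index pairs, grouped by multiplicity pattern."""
    ma = pool_a.multiplicities()[ii]
    mb = pool_b.multiplicities()[jj]
    by_m_a = pool_a.by_multiplicity()
    by_m_b = pool_b.by_multiplicity()
    rows_a = _class_rows(pool_a)
    rows_b = _class_rows(pool_b)
    out_score = np.full(ii.size, -np.inf)
    out_k = np.zeros(ii.size, dtype=np.int64)
    out_sum = np.zeros(ii.size)
    combos = np.unique(np.stack([ma, mb], axis=1), axis=0)
    for m1, m2 in combos:
        if m1 == 0 or m2 == 0:
            continue
        sel = np.flatnonzero((ma == m1) & (mb == m2))
        mat_a = by_m_a[int(m1)][1]
        mat_b = by_m_b[int(m2)][1]
        for s in range(0, sel.size, 200_000):
            blk = sel[s:s + 200_000]
            A = mat_a[rows_a[ii[blk]]]
            B = mat_b[rows_b[jj[blk]]]
            k, sum_de = _batch_align(A, B, params.gate)
            score = k - sum_de / params.gate \
                - params.gap_penalty * (m1 + m2 - 2 * k)
            score[k < params.min_matched_lines] = -np.inf
            out_score[blk] = score
            out_k[blk] = k
            out_sum[blk] = sum_de
    keep = np.isfinite(out_score)
    return pd.DataFrame({
        "i": ii[keep], "j": jj[keep], "score": out_score[keep],
        "k_matched": out_k[keep], "sum_abs_de": out_sum[keep],
    })


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------


def _line_bin_keys(pool: BarcodePool, gate: float, pairs: bool
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(key, owner) arrays: binned single lines or binned line pairs per cell."""
    keys, owners = [], []
    shift = 1 << 20
    for m, (idx, mat) in pool.by_multiplicity().items():
        bins = np.floor(mat / gate).astype(np.int64)
        if pairs:
            if m < 2:
                continue
            for i in range(m):
                for j in range(i + 1, m):
                    keys.append(bins[:, i] * shift + bins[:, j])
                    owners.append(idx)
        else:
            for i in range(m):
                keys.append(bins[:, i])
                owners.append(idx)
    if not keys:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(keys), np.concatenate(owners)


def _candidate_pairs(pool_a: BarcodePool, pool_b: BarcodePool,
                     params: ScoreParams) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs that can possibly reach ``min_matched_lines`` aligned lines.

    Single-line inverted index when one matched line suffices; otherwise a
    line-pair index (a pair needs two gated lines, hence a shared binned
    line pair up to +/-1 bin in each coordinate).  Exact: any pair the
    brute-force scorer would keep shares such a key.
    """
    use_pairs = params.min_matched_lines >= 2
    ka, oa = _line_bin_keys(pool_a, params.gate, use_pairs)
    kb, ob = _line_bin_keys(pool_b, params.gate, use_pairs)
    if ka.size == 0 or kb.size == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    order = np.argsort(kb, kind="stable")
    kb_sorted, ob_sorted = kb[order], ob[order]
    shift = 1 << 20
    if use_pairs:
        offsets = [d1 * shift + d2 for d1 in (-1, 0, 1) for d2 in (-1, 0, 1)]
    else:
        offsets = [-1, 0, 1]
    n2 = len(pool_b)
    chunks = []
    block = max(1, 2_000_000 // max(len(offsets), 1))
    for s in range(0, ka.size, block):
        ka_blk, oa_blk = ka[s:s + block], oa[s:s + block]
        codes = []
        for off in offsets:
            q = ka_blk + off
            lo = np.searchsorted(kb_sorted, q, side="left")
            hi = np.searchsorted(kb_sorted, q, side="right")
            c = hi - lo
            if not c.any():
                continue
            rows = np.repeat(np.arange(q.size), c)
            base = np.repeat(np.cumsum(c) - c, c)
            cols = np.repeat(lo, c) + (np.arange(int(c.sum())) - base)
            codes.append(oa_blk[rows] * n2 + ob_sorted[cols])
        if codes:
            chunks.append(np.unique(np.concatenate(codes)))
    if not chunks:
        return (np.empty(0, dtype=np.int64),) * 2
    codes = np.unique(np.concatenate(chunks))
    return codes // n2, codes % n2


def build_score_sets(c1: BarcodePool, c2: BarcodePool,
                     params: ScoreParams | None = None,
                     method: str = "indexed") -> MatchSet:
    """Score cross-run candidates and the within-run self-match distributions.

    ``S_cross`` covers candidate pairs of C1 x C2; ``S_self`` is the union
    of within-run candidate scores (C1-C1 and C2-C2, identities excluded).
    ``method="brute"`` scores every pair and serves as the oracle for the
    indexed candidate generation.
    """
    params = params or ScoreParams()
    if len(c1) == 0 or len(c2) == 0:
        raise ValueError("pools must be non-empty")
    if method not in ("indexed", "brute"):
        raise ValueError("method must be 'indexed' or 'brute'")

    def cross_pairs(pa, pb):
        if method == "brute":
            ii, jj = np.meshgrid(np.arange(len(pa)), np.arange(len(pb)),
                                 indexing="ij")
            return ii.ravel(), jj.ravel()
        return _candidate_pairs(pa, pb, params)

    ii, jj = cross_pairs(c1, c2)
    cross = _score_pairs_bulk(c1, c2, ii, jj, params)

    def self_scores(pool):
        ii, jj = cross_pairs(pool, pool)
        keep = ii < jj
        df = _score_pairs_bulk(pool, pool, ii[keep], jj[keep], params)
        return df["score"].to_numpy()

    s_self = np.concatenate([self_scores(c1), self_scores(c2)])
    return MatchSet(params=params, cross=cross, self_scores=s_self,
                    c1_ids=list(c1.cell_ids), c2_ids=list(c2.cell_ids))


# ---------------------------------------------------------------------------
# Threshold selection and one-to-one resolution
# ---------------------------------------------------------------------------


def select_threshold(ms: MatchSet, q: float = 1e-5) -> float:
    """Score cutoff: the ``(1 - q)`` quantile of the self-match scores.

    Correct matches form a high-score subpopulation present in S_cross but
    absent in S_self, so an extreme upper quantile of S_self separates them.
    When ``q`` is below ``1/|S_self|`` the maximum observed self score is
    used.  The result is stored on ``ms.threshold``.
    """
    if ms.self_scores.size == 0:
        raise ValueError("empty S_self: supply an explicit threshold")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if q < 1.0 / ms.self_scores.size:
        threshold = float(ms.self_scores.max())
    else:
        threshold = float(np.quantile(ms.self_scores, 1.0 - q))
    ms.threshold = threshold
    return threshold


def _resolve_greedy(cand: pd.DataFrame) -> np.ndarray:
    taken1: set = set()
    taken2: set = set()
    rows = []
    for row in cand.itertuples():
        if row.i not in taken1 and row.j not in taken2:
            taken1.add(row.i)
            taken2.add(row.j)
            rows.append(row.Index)
    return np.asarray(rows, dtype=np.int64)


def _resolve_hungarian(cand: pd.DataFrame) -> np.ndarray:
    u1 = {v: k for k, v in enumerate(cand["i"].unique())}
    u2 = {v: k for k, v in enumerate(cand["j"].unique())}
    cost = np.full((len(u1), len(u2)), 1e9)
    for row in cand.itertuples():
        cost[u1[row.i], u2[row.j]] = -row.score
    r, c = linear_sum_assignment(cost)
    ok = cost[r, c] < 1e8
    pairs = {(ri, ci) for ri, ci in zip(r[ok], c[ok])}
    keep = [row.Index for row in cand.itertuples()
            if (u1[row.i], u2[row.j]) in pairs]
    return np.asarray(keep, dtype=np.int64)


def match_pools(c1: BarcodePool, c2: BarcodePool,
                params: ScoreParams | None = None,
                q: float = 1e-5,
                threshold: float | None = None,
                method: str = "indexed",
                assignment: str = "greedy") -> MatchSet:
    """Complete cross-run matching: scores, threshold, one-to-one matches.

    Accepted matches are cross pairs with score above the threshold,
    resolved one-to-one greedily in descending score (ties broken by the
    smaller mean |dE|, then lexicographic cell ids); ``assignment=
    "hungarian"`` solves the optimal assignment instead (small pools).
    Emits the multiplicity confusion table and per-pair diagnostics, and —
    when both pools carry per-cell scalars — the correlation of matched
    scalars as an independent validation channel.
    """
    params = params or ScoreParams()
    ms = build_score_sets(c1, c2, params, method=method)
    if threshold is None:
        threshold = select_threshold(ms, q)
    else:
        ms.threshold = float(threshold)
    cand = ms.cross[ms.cross["score"] > ms.threshold].copy()
    cand["mean_abs_de"] = cand["sum_abs_de"] / cand["k_matched"]
    cand["c1_id"] = [c1.cell_ids[i] for i in cand["i"]]
    cand["c2_id"] = [c2.cell_ids[j] for j in cand["j"]]
    cand = cand.sort_values(
        by=["score", "mean_abs_de", "c1_id", "c2_id"],
        ascending=[False, True, True, True], kind="mergesort")
    if assignment == "greedy":
        keep = _resolve_greedy(cand)
    elif assignment == "hungarian":
        keep = _resolve_hungarian(cand)
    else:
        raise ValueError("assignment must be 'greedy' or 'hungarian'")
    acc = cand.loc[keep]
    m1 = c1.multiplicities()
    m2 = c2.multiplicities()
    matches = pd.DataFrame({
        "c1_id": acc["c1_id"].to_numpy(),
        "c2_id": acc["c2_id"].to_numpy(),
        "score": acc["score"].to_numpy(),
        "k_matched": acc["k_matched"].to_numpy(),
        "mean_abs_dE_meV": acc["mean_abs_de"].to_numpy(),
        "m1": m1[acc["i"].to_numpy()],
        "m2": m2[acc["j"].to_numpy()],
    }).reset_index(drop=True)
    confusion = (matches.groupby(["m1", "m2"]).size().unstack(fill_value=0)
                 if len(matches) else pd.DataFrame())
    ms.matches = matches
    ms.confusion = confusion
    n_ref = min(len(c1), len(c2))
    ms.summary = {
        "n_c1": len(c1), "n_c2": len(c2),
        "n_candidates": int(len(ms.cross)),
        "n_matches": int(len(matches)),
        "match_rate": len(matches) / n_ref if n_ref else 0.0,
        "threshold": ms.threshold, "q": q,
    }
    if c1.scalars is not None and c2.scalars is not None and len(matches) > 1:
        s1 = c1.scalars[acc["i"].to_numpy()]
        s2 = c2.scalars[acc["j"].to_numpy()]
        ms.summary["scalar_correlation"] = float(np.corrcoef(s1, s2)[0, 1])
    return ms


# ---------------------------------------------------------------------------
# Noise-model estimation from repeated measurements
# ---------------------------------------------------------------------------


def fit_noise(repeats: pd.DataFrame, energy_col: str = "energy_meV",
              lp_col: str = "lp_id", min_samples: int = 30) -> NoiseFit:
    """Fit the generalized-Gaussian line-noise model from repeated spectra.

    ``repeats`` holds one row per (LP, repeat) measurement.  Fluctuations
    are each LP's energies minus that LP's mean, pooled across LPs; the
    zero-centered generalized Gaussian ``phi(E') = beta/(2 alpha
    Gamma(1/beta)) exp(-(|E'|/alpha)^beta)`` is fitted by maximum
    likelihood.  LPs with fewer than two repeats carry no fluctuation
    information and are dropped.
    """
    if lp_col not in repeats or energy_col not in repeats:
        raise ValueError(f"need columns {lp_col!r} and {energy_col!r}")
    grp = repeats.groupby(lp_col)[energy_col]
    sizes = grp.transform("size")
    usable = repeats.loc[sizes >= 2]
    if usable.empty:
        raise ValueError("need at least 2 repeats for at least one LP")
    flucts = (usable[energy_col]
              - usable.groupby(lp_col)[energy_col].transform("mean")).to_numpy()
    if flucts.size < min_samples:
        raise ValueError(f"need >= {min_samples} fluctuation samples, "
                         f"got {flucts.size}")
    if np.allclose(flucts, 0.0):
        raise ValueError("degenerate fluctuations: all repeats identical")
    beta, _, alpha = stats.gennorm.fit(flucts, floc=0.0)
    loglik = float(stats.gennorm.logpdf(flucts, beta, scale=alpha).sum())
    return NoiseFit(alpha=float(alpha), beta=float(beta),
                    n_lines=int(flucts.size), loglik=loglik)
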