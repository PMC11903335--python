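"""Pairwise chain-to-chain structural alignment.

Implements a TM-align-style iterative aligner: rigid superpositions are seeded
from gapless fragment threadings and a sequence-identity alignment, then each
seed alternates Kabsch superposition, TM-style rescoring of all residue pairs,
and Needleman-Wunsch realignment until the residue correspondence stabilises.
The best seed by the sum of query- and target-normalized TM scores wins.

This module is the analog of running the complex aligner with its global
TM-align chain mode; a faster structural-alphabet aligner is out of scope, and
externally produced :class:`ChainAlignment` objects are accepted by the
downstream clustering so the pipeline is aligner-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .structures import DegenerateGeometryError, RigidTransform

__all__ = [
    "AlignConfig",
    "ChainAlignment",
    "kabsch_superpose",
    "align_chains",
    "d0_tm",
]


def d0_tm(length: int) -> float:
    """TM-score distance scale d0(L) = 1.24·(L−15)^(1/3) − 1.8 for L > 21, else 0.5."""
    if length > 21:
        return 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    return 0.5


@dataclass
class AlignConfig:
    """Tunables of the iterative chain aligner.

    gap_penalty: linear Needleman-Wunsch gap penalty (no extension penalty).
    max_iters: cap on refine iterations per seed.
    seed_fragment_len: gapless threading fragment length (capped at chain length).
    seed_stride_divisor: threading stride = max(1, min_chain_length // divisor).
    """

    gap_penalty: float = -0.6
    max_iters: int = 30
    seed_fragment_len: int = 20
    seed_stride_divisor: int = 10


@dataclass
class ChainAlignment:
    """Residue-level correspondence between one query and one target chain.

    ``pairs`` is an (n, 2) array of (query_residue_index, target_residue_index),
    strictly increasing in both columns. ``transform`` maps target coordinates
    into the query frame.
    """

    query_chain_index: int
    target_chain_index: int
    pairs: np.ndarray
    transform: RigidTransform
    tm_query_norm: float
    tm_target_norm: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(self.pairs) < 3:
            raise ValueError("an alignment needs at least three residue pairs")
        if not (np.all(np.diff(self.pairs[:, 0]) > 0) and np.all(np.diff(self.pairs[:, 1]) > 0)):
            raise ValueError("alignment pairs must be strictly increasing in both chains")

    def __len__(self) -> int:
        return len(self.pairs)


def kabsch_superpose(q_coords: np.ndarray, t_coords: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rigid superposition of ``t_coords`` onto ``q_coords``.

    Returns the transform minimizing the RMSD between the query points and the
    transformed target points, plus that minimum RMSD (Kabsch/SVD solution,
    reflection-corrected).
    """
    q = np.asarray(q_coords, dtype=float).reshape(-1, 3)
    t = np.asarray(t_coords, dtype=float).reshape(-1, 3)
    if q.shape != t.shape:
        raise ValueError(f"point sets differ in shape: {q.shape} vs {t.shape}")
    n = len(q)
    if n < 3:
        raise ValueError("superposition needs at least three point pairs")
    q_mean = q.mean(axis=0)
    t_mean = t.mean(axis=0)
    qc = q - q_mean
    tc = t - t_mean
    cov = tc.T @ qc
    u, s, vt = np.linalg.svd(cov)
    # rank < 2 (all points collinear or coincident) leaves the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("point set is rank-deficient (collinear points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = q_mean - rot @ t_mean
    transform = RigidTransform(rot, trans)
    diff = q - transform.apply(t)
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return transform, rmsd


@njit(cache=False)
def _nw_trace(score: np.ndarray, gap: float) -> np.ndarray:  # pragma: no cover - numba
    """Needleman-Wunsch with linear gap penalty and free end gaps; returns pairs."""
    n, m = score.shape
    f = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for j in range(1, m + 1):
        ptr[0, j] = 2
    for i in range(1, n + 1):
        ptr[i, 0] = 1
        for j in range(1, m + 1):
            d = f[i - 1, j - 1] + score[i - 1, j - 1]
            u = f[i - 1, j] + gap
            l = f[i, j - 1] + gap
            if d >= u and d >= l:
                f[i, j] = d
                ptr[i, j] = 0
            elif u >= l:
                f[i, j] = u
                ptr[i, j] = 1
            else:
                f[i, j] = l
                ptr[i, j] = 2
    # free trailing gaps: trace back from the best cell on the last row/column
    bi, bj = n, m
    best = f[n, m]
    for j in range(m + 1):
        if f[n, j] > best:
            best = f[n, j]
            bi, bj = n, j
    for i in range(n + 1):
        if f[i, m] > best:
            best = f[i, m]
            bi, bj = i, m
    cap = min(n, m)
    out = np.empty((cap, 2), dtype=np.int64)
    k = cap
    i, j = bi, bj
    while i > 0 and j > 0:
        p = ptr[i, j]
        if p == 0:
            k -= 1
            out[k, 0] = i - 1
            out[k, 1] = j - 1
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return out[k:, :].copy()


def _fixed_transform_tm_sum(
    q: np.ndarray, t: np.ndarray, pairs: np.ndarray, transform: RigidTransform,
    len_q: int, len_t: int,
) -> float:
    """Sum of both TM normalizations under a fixed superposition (seed ranking)."""
    d = np.linalg.norm(q[pairs[:, 0]] - transform.apply(t[pairs[:, 1]]), axis=1)
    tm_q = float(np.sum(1.0 / (1.0 + (d / d0_tm(len_q)) ** 2)) / len_q)
    tm_t = float(np.sum(1.0 / (1.0 + (d / d0_tm(len_t)) ** 2)) / len_t)
    return tm_q + tm_t


def _threading_seeds(len_q: int, len_t: int, cfg: AlignConfig) -> list[np.ndarray]:
    lmin = min(len_q, len_t)
    frag = min(lmin, cfg.seed_fragment_len)
    stride = max(1, lmin // cfg.seed_stride_divisor)
    seeds = []
    for i in range(0, len_q - frag + 1, stride):
        for j in range(0, len_t - frag + 1, stride):
            seeds.append(np.stack([np.arange(i, i + frag), np.arange(j, j + frag)], axis=1))
    return seeds


def _sequence_seed(q_names: list[str], t_names: list[str], cfg: AlignConfig) -> np.ndarray | None:
    qn = np.array(q_names)
    tn = np.array(t_names)
    score = (qn[:, None] == tn[None, :]).astype(np.float64)
    pairs = _nw_trace(score, cfg.gap_penalty)
    return pairs if len(pairs) >= 3 else None


def _refine_seed(
    q: np.ndarray, t: np.ndarray, seed_pairs: np.ndarray, cfg: AlignConfig,
    len_q: int, len_t: int, d0_refine: float,
):
    """Iterate superpose/rescore/realign from one seed.

    Returns (best score, best pairs, best transform, per-iteration trace of the
    running best). Tracking the running best makes the trace non-decreasing.
    """
    try:
        transform, _ = kabsch_superpose(q[seed_pairs[:, 0]], t[seed_pairs[:, 1]])
    except (DegenerateGeometryError, ValueError):
        return -np.inf, None, None, []
    best_score = -np.inf
    best_pairs = None
    best_transform = None
    trace: list[float] = []
    prev: np.ndarray | None = None
    for _ in range(cfg.max_iters):
        dist = cdist(q, transform.apply(t))
        score = 1.0 / (1.0 + (dist / d0_refine) ** 2)
        pairs = _nw_trace(score, cfg.gap_penalty)
        if len(pairs) < 3:
            break
        try:
            transform, _ = kabsch_superpose(q[pairs[:, 0]], t[pairs[:, 1]])
        except DegenerateGeometryError:
            break
        s = _fixed_transform_tm_sum(q, t, pairs, transform, len_q, len_t)
        if s > best_score:
            best_score, best_pairs, best_transform = s, pairs, transform
        trace.append(best_score)
        if prev is not None and pairs.shape == prev.shape and np.array_equal(pairs, prev):
            break
        prev = pairs
    return best_score, best_pairs, best_transform, trace


def align_chains(
    q,
    t,
    config: AlignConfig | None = None,
    query_chain_index: int = 0,
    target_chain_index: int = 0,
    return_trace: bool = False,
):
    """Align two chains; returns a :class:`ChainAlignment` or None if unalignable.

    ``q`` and ``t`` are :class:`~multimeralign.structures.ChainStructure`
    objects of length >= 3. With ``return_trace`` the per-iteration score trace
    of the winning seed is returned as a second value.
    """
    from .complex_score import tm_score  # deferred: complex_score imports kabsch from here

    cfg = config or AlignConfig()
    qc = np.asarray(q.ca_coords, dtype=float)
    tc = np.asarray(t.ca_coords, dtype=float)
    len_q, len_t = len(qc), len(tc)
    if len_q < 3 or len_t < 3:
        raise ValueError("both chains must have at least three residues")
    d0_refine = d0_tm(min(len_q, len_t))

    seeds = _threading_seeds(len_q, len_t, cfg)
    seq_seed = _sequence_seed(q.residue_names, t.residue_names, cfg)
    if seq_seed is not None:
        seeds.append(seq_seed)

    best_score = -np.inf
    best_pairs = None
    best_trace: list[float] = []
    for seed_pairs in seeds:
        score, pairs, _, trace = _refine_seed(qc, tc, seed_pairs, cfg, len_q, len_t, d0_refine)
        if pairs is not None and score > best_score:
            best_score, best_pairs, best_trace = score, pairs, trace
    if best_pairs is None:
        return (None, []) if return_trace else None

    tm_q, transform = tm_score(qc, tc, best_pairs, len_q)
    tm_t, _ = tm_score(qc, tc, best_pairs, len_t)
    alignment = ChainAlignment(
        query_chain_index=query_chain_index,
        target_chain_index=target_chain_index,
        pairs=best_pairs,
        transform=transform,
        tm_query_norm=tm_q,
        tm_target_norm=tm_t,
    )
    return (alignment, best_trace) if return_trace else alignment
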