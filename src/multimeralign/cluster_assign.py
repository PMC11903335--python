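"""Iterative DBSCAN over superposition vectors with validity rescue.

Compatible chain-to-chain alignments — those jointly realizable by one
complex-level superposition — have near-identical superposition vectors, so
they form dense clusters in the normalized supQT space. DBSCAN (minPts = 2) is
run over an increasing radius grid; after every run each cluster is checked
for validity (no query or target chain used twice) and invalid clusters are
rescued by admitting members in order of distance from the initiating core
point until the first chain reuse. The largest valid clusters seen anywhere on
the grid are kept as candidate chain assignments.

In addition, every single row is seeded as a trivially valid size-1 candidate
before the grid starts: a lone chain-to-chain alignment is always a legal
(partial) complex alignment, and minPts = 2 density clustering can never emit
singletons on its own. These seeds are purged as soon as any bigger valid
cluster appears, so they only matter for comparisons such as one chain against
many where no multi-member cluster can exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .chain_align import ChainAlignment
from .superposition_matrix import SuperpositionMatrix

__all__ = [
    "ClusterCandidate",
    "ClusteringState",
    "dbscan_once",
    "rescue_valid_subgroup",
    "iterative_cluster",
]

DELTA = 0.1  # epsilon grid increment, in normalized-space units


@dataclass(frozen=True)
class ClusterCandidate:
    """A valid (one-to-one) set of compatible chain-to-chain alignments."""

    member_rows: tuple[int, ...]
    seed_row: int
    epsilon_found: float

    @property
    def size(self) -> int:
        return len(self.member_rows)

    def chain_pairing(self, alignments: list[ChainAlignment]) -> frozenset[tuple[int, int]]:
        return frozenset(
            (alignments[r].query_chain_index, alignments[r].target_chain_index)
            for r in self.member_rows
        )


@dataclass
class ClusteringState:
    """Bookkeeping of the iterative clustering procedure (exposed for inspection)."""

    epsilon: float
    min_dist: float
    max_dist: float
    c_q: int
    c_t: int
    delta: float = DELTA
    max_cluster_size: int = 0
    candidates: list[ClusterCandidate] = field(default_factory=list)


def is_valid_cluster(rows, alignments: list[ChainAlignment]) -> bool:
    """True iff no query chain and no target chain appears in two members."""
    q_seen: set[int] = set()
    t_seen: set[int] = set()
    for r in rows:
        a = alignments[r]
        if a.query_chain_index in q_seen or a.target_chain_index in t_seen:
            return False
        q_seen.add(a.query_chain_index)
        t_seen.add(a.target_chain_index)
    return True


def dbscan_once(points: np.ndarray, epsilon: float) -> list[tuple[list[int], int]]:
    """One DBSCAN pass (minPts = 2) returning (member rows, seed row) per cluster.

    Neighbors are points at Euclidean distance <= epsilon (inclusive); a core
    point has at least two neighbors including itself. Clusters are grown by
    core-point expansion from the lowest-index unvisited core point (a
    deterministic stand-in for random seeding); non-core neighbors are attached
    without expansion.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("dbscan_once needs at least two rows")
    dist = squareform(pdist(points)) if points.shape[1] > 0 else np.zeros((n, n))
    neighbor = dist <= epsilon + 1e-12
    core = neighbor.sum(axis=1) >= 2
    assigned = np.full(n, False)
    clusters: list[tuple[list[int], int]] = []
    for seed in range(n):
        if not core[seed] or assigned[seed]:
            continue
        members = [seed]
        assigned[seed] = True
        frontier = [seed]
        while frontier:
            cur = frontier.pop(0)
            for nb in np.flatnonzero(neighbor[cur]):
                if core[nb] and not assigned[nb]:
                    assigned[nb] = True
                    members.append(int(nb))
                    frontier.append(int(nb))
        # attach border (non-core) neighbors of cluster members, no expansion
        for cur in list(members):
            for nb in np.flatnonzero(neighbor[cur]):
                if not core[nb] and not assigned[nb]:
                    assigned[nb] = True
                    members.append(int(nb))
        clusters.append((members, seed))
    return clusters


def rescue_valid_subgroup(
    cluster: tuple[list[int], int],
    alignments: list[ChainAlignment],
    points: np.ndarray,
    epsilon: float = float("nan"),
) -> ClusterCandidate:
    """Extract a valid subgroup from a (possibly invalid) raw cluster.

    A valid cluster is returned unchanged. Otherwise members are admitted in
    increasing distance from the initiating core point (the seed itself first,
    at distance 0; ties broken by row index) and admission *stops* — it does
    not skip — at the first member that reuses an already-admitted query or
    target chain.
    """
    members, seed = cluster
    if not members:
        raise ValueError("cannot rescue an empty cluster")
    if is_valid_cluster(members, alignments):
        return ClusterCandidate(tuple(sorted(members)), seed, epsilon)
    points = np.asarray(points, dtype=float)
    if points.shape[1] > 0:
        dist = {r: float(np.linalg.norm(points[r] - points[seed])) for r in members}
    else:
        dist = {r: 0.0 for r in members}
    ordered = sorted(members, key=lambda r: (dist[r], r))
    admitted: list[int] = []
    q_seen: set[int] = set()
    t_seen: set[int] = set()
    for r in ordered:
        a = alignments[r]
        if a.query_chain_index in q_seen or a.target_chain_index in t_seen:
            break
        admitted.append(r)
        q_seen.add(a.query_chain_index)
        t_seen.add(a.target_chain_index)
    return ClusterCandidate(tuple(sorted(admitted)), seed, epsilon)


def _add_candidate(
    state: ClusteringState,
    cand: ClusterCandidate,
    alignments: list[ChainAlignment],
    pairings_seen: set[frozenset[tuple[int, int]]],
) -> None:
    """Record a rescued cluster, purging smaller candidates when it is bigger.

    Candidates are deduplicated by their chain-pairing set; equal-size ties are
    admitted alongside the current best.
    """
    if cand.size < state.max_cluster_size:
        return
    if cand.size > state.max_cluster_size:
        state.max_cluster_size = cand.size
        state.candidates = []
        pairings_seen.clear()
    pairing = cand.chain_pairing(alignments)
    if pairing in pairings_seen:
        return
    pairings_seen.add(pairing)
    state.candidates.append(cand)


def iterative_cluster(
    m: SuperpositionMatrix, c_q: int, c_t: int, delta: float = DELTA
) -> list[ClusterCandidate]:
    """Run DBSCAN over the epsilon grid and return the biggest valid clusters.

    epsilon starts at the minimum pairwise row distance (minDist) and grows by
    ``delta`` up to the maximum pairwise distance (maxDist, inclusive). Early
    stops: (a) the maximum possible valid size min(C_Q, C_T) is reached and the
    candidate list holds max(C_Q, C_T) distinct pairings, so nothing bigger or
    additional can appear; (b) an iteration's rescued clusters are all strictly
    smaller than the current best after a candidate exists (merging past the
    useful radius only degrades clusters).
    """
    if m.normalized is None:
        raise ValueError("matrix must be filtered and normalized before clustering")
    alignments = m.alignment_refs
    n = m.n_rows
    if n == 1:
        return [ClusterCandidate((0,), 0, 0.0)]

    points = m.normalized
    pair_d = pdist(points) if points.shape[1] > 0 else np.zeros(n * (n - 1) // 2)
    min_dist = float(pair_d.min())
    max_dist = float(pair_d.max())
    state = ClusteringState(
        epsilon=min_dist, min_dist=min_dist, max_dist=max_dist, c_q=c_q, c_t=c_t, delta=delta
    )
    pairings_seen: set[frozenset[tuple[int, int]]] = set()

    # singleton seeding: each row alone is a valid partial assignment
    for r in range(n):
        _add_candidate(state, ClusterCandidate((r,), r, 0.0), alignments, pairings_seen)

    max_valid = min(c_q, c_t)
    list_cap = max(c_q, c_t)

    def early_stop() -> bool:
        return state.max_cluster_size == max_valid and len(state.candidates) >= list_cap

    if early_stop():
        return state.candidates

    eps = min_dist
    while eps <= max_dist + 1e-9:
        state.epsilon = eps
        iter_sizes: list[int] = []
        for cluster in dbscan_once(points, eps):
            cand = rescue_valid_subgroup(cluster, alignments, points, eps)
            iter_sizes.append(cand.size)
            _add_candidate(state, cand, alignments, pairings_seen)
        if early_stop():
            break
        if state.candidates and iter_sizes and max(iter_sizes) < state.max_cluster_size:
            break
        eps += delta
    return state.candidates
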