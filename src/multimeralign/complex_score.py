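"""Complex TM-score: scoring candidate chain assignments.

A candidate assignment is scored by concatenating the matched query chains in
query order, concatenating the matched target chains in match order, pooling
the per-chain residue correspondences into the concatenated frame, and
computing a TM-score over the pooled alignment. Both normalizations (by the
full query length L_Q and the full target length L_T, unmatched chains
included) are derived from one unnormalized score sum obtained with a single
pair-level d0 = d0(min(L_Q, L_T)), which makes tm_q·L_Q == tm_t·L_T hold
exactly. No pseudo-bonds are introduced between concatenated chains: distances
are only ever evaluated within aligned residue pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .chain_align import ChainAlignment, d0_tm, kabsch_superpose
from .cluster_assign import ClusterCandidate
from .structures import ComplexStructure, DegenerateGeometryError, RigidTransform

__all__ = [
    "ComplexAlignment",
    "tm_score",
    "score_assignment",
    "best_alignment",
    "exhaustive_best_pairing",
]

REPORT_THRESHOLD = 0.65  # complex-similarity cutoff on the reported TM score


@dataclass
class ComplexAlignment:
    """A validated one-to-one chain pairing with its shared superposition.

    ``transform`` maps target coordinates into the query frame.
    ``tm_query_norm`` and ``tm_target_norm`` share one unnormalized score sum,
    so tm_query_norm·L_Q == tm_target_norm·L_T.
    """

    query_id: str
    target_id: str
    chain_pairs: list[tuple[str, str]]
    per_pair_alignments: list[ChainAlignment]
    transform: RigidTransform
    tm_query_norm: float
    tm_target_norm: float
    aligned_residues: int

    def __post_init__(self) -> None:
        q_ids = [p[0] for p in self.chain_pairs]
        t_ids = [p[1] for p in self.chain_pairs]
        if len(set(q_ids)) != len(q_ids) or len(set(t_ids)) != len(t_ids):
            raise ValueError("chain pairing must be injective on both sides")
        for tm in (self.tm_query_norm, self.tm_target_norm):
            if not 0.0 < tm <= 1.0 + 1e-9:
                raise ValueError(f"TM score out of (0, 1]: {tm}")

    @property
    def assignment(self) -> str:
        return ",".join(f"{q}:{t}" for q, t in self.chain_pairs)

    def score(self, mode: str = "max") -> float:
        if mode == "max":
            return max(self.tm_query_norm, self.tm_target_norm)
        if mode == "query":
            return self.tm_query_norm
        if mode == "target":
            return self.tm_target_norm
        if mode == "avg":
            return 0.5 * (self.tm_query_norm + self.tm_target_norm)
        raise ValueError(f"unknown score mode {mode!r}")


def _search_superposition(
    qa: np.ndarray, ta: np.ndarray, d0: float
) -> tuple[float, RigidTransform]:
    """TM-score superposition search over fragment seeds.

    Seeds are contiguous alignment fragments of lengths L_a, L_a/2, L_a/4 at
    stride max(1, L_a/10); each seed is refined by iterating Kabsch on the
    subset of pairs closer than max(d0, 4.5 Å) until the subset is stable.
    Returns the maximal unnormalized sum Σ 1/(1+(d_i/d0)²) and its transform.
    """
    n = len(qa)
    cutoff = max(d0, 4.5)
    frag_lens = sorted({n, max(3, n // 2), max(3, n // 4)}, reverse=True)
    stride = max(1, n // 10)
    best_sum = -1.0
    best_transform: RigidTransform | None = None
    for frag in frag_lens:
        if frag > n or frag < 3:
            continue
        for start in range(0, n - frag + 1, stride):
            sl = slice(start, start + frag)
            try:
                transform, _ = kabsch_superpose(qa[sl], ta[sl])
            except (DegenerateGeometryError, ValueError):
                continue
            prev_mask: np.ndarray | None = None
            for _ in range(30):
                d = np.linalg.norm(qa - transform.apply(ta), axis=1)
                mask = d < cutoff
                if mask.sum() < 3:
                    break
                if prev_mask is not None and np.array_equal(mask, prev_mask):
                    break
                prev_mask = mask
                try:
                    transform, _ = kabsch_superpose(qa[mask], ta[mask])
                except DegenerateGeometryError:
                    break
            d = np.linalg.norm(qa - transform.apply(ta), axis=1)
            s = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)))
            if s > best_sum:
                best_sum, best_transform = s, transform
    if best_transform is None:
        # every fragment seed degenerate: fall back to centroid matching
        best_transform = RigidTransform(np.eye(3), qa.mean(axis=0) - ta.mean(axis=0))
        d = np.linalg.norm(qa - best_transform.apply(ta), axis=1)
        best_sum = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)))
    return best_sum, best_transform


def tm_score(
    q_coords: np.ndarray,
    t_coords: np.ndarray,
    pairs: np.ndarray,
    L_norm: int,
    d0_override: float | None = None,
) -> tuple[float, RigidTransform]:
    """TM-score of an alignment: max over searched superpositions of
    (1/L_norm)·Σ 1/(1+(d_i/d0)²), with d0 = d0(L_norm) unless overridden."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("tm_score needs a nonempty alignment")
    qa = np.asarray(q_coords, dtype=float)[pairs[:, 0]]
    ta = np.asarray(t_coords, dtype=float)[pairs[:, 1]]
    d0 = d0_tm(L_norm) if d0_override is None else d0_override
    if len(pairs) < 3:
        transform = RigidTransform(np.eye(3), qa.mean(axis=0) - ta.mean(axis=0))
        d = np.linalg.norm(qa - transform.apply(ta), axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm), transform
    s, transform = _search_superposition(qa, ta, d0)
    return s / L_norm, transform


def _concatenate(Q: ComplexStructure, T: ComplexStructure, rows, alignments):
    """Pool per-chain alignments into concatenated coordinate frames."""
    rows = sorted(rows, key=lambda r: alignments[r].query_chain_index)
    q_offsets = np.cumsum([0] + [len(Q.chains[alignments[r].query_chain_index]) for r in rows])
    t_offsets = np.cumsum([0] + [len(T.chains[alignments[r].target_chain_index]) for r in rows])
    q_cat = np.concatenate([Q.chains[alignments[r].query_chain_index].ca_coords for r in rows])
    t_cat = np.concatenate([T.chains[alignments[r].target_chain_index].ca_coords for r in rows])
    pair_blocks = [
        alignments[r].pairs + np.array([q_offsets[k], t_offsets[k]])
        for k, r in enumerate(rows)
    ]
    return rows, q_cat, t_cat, np.concatenate(pair_blocks)


def score_assignment(
    Q: ComplexStructure,
    T: ComplexStructure,
    candidate: ClusterCandidate,
    alignments: list[ChainAlignment],
) -> ComplexAlignment:
    """Score one candidate chain assignment with the complex TM-score.

    Query chains are concatenated in their file order (restricted to matched
    chains) and target chains in match order; both TM normalizations use the
    *total* residue counts of Q and T, unmatched chains included.
    """
    rows, q_cat, t_cat, pairs = _concatenate(Q, T, candidate.member_rows, alignments)
    L_q = Q.total_length
    L_t = T.total_length
    d0_pair = d0_tm(min(L_q, L_t))
    tm_q, transform = tm_score(q_cat, t_cat, pairs, L_q, d0_override=d0_pair)
    tm_t = tm_q * L_q / L_t
    chain_pairs = [
        (
            Q.chains[alignments[r].query_chain_index].chain_id,
            T.chains[alignments[r].target_chain_index].chain_id,
        )
        for r in rows
    ]
    return ComplexAlignment(
        query_id=Q.complex_id,
        target_id=T.complex_id,
        chain_pairs=chain_pairs,
        per_pair_alignments=[alignments[r] for r in rows],
        transform=transform,
        tm_query_norm=tm_q,
        tm_target_norm=tm_t,
        aligned_residues=len(pairs),
    )


def best_alignment(
    Q: ComplexStructure,
    T: ComplexStructure,
    candidates: list[ClusterCandidate],
    alignments: list[ChainAlignment],
) -> ComplexAlignment | None:
    """Score every candidate and return the best by tm_q + tm_t.

    Ties are broken by more aligned residues, then by lexicographically
    smallest chain pairing — fully deterministic.
    """
    if not candidates:
        return None
    scored = [score_assignment(Q, T, c, alignments) for c in candidates]
    return min(
        scored,
        key=lambda a: (
            -(a.tm_query_norm + a.tm_target_norm),
            -a.aligned_residues,
            tuple(a.chain_pairs),
        ),
    )


def exhaustive_best_pairing(
    Q: ComplexStructure,
    T: ComplexStructure,
    alignments: list[ChainAlignment],
) -> ComplexAlignment | None:
    """Exact reference: score every maximal injective chain mapping.

    Enumerates all injective mappings of min(C_Q, C_T) chains and scores each
    with :func:`score_assignment`. Partial mappings are dominated: adding a
    chain pair adds only nonnegative terms to the score sum under any
    superposition, so the maximum over superpositions is monotone in the pair
    set. Factorial cost — a validation/benchmark mode, not the pipeline.
    """
    by_pair = {
        (a.query_chain_index, a.target_chain_index): r for r, a in enumerate(alignments)
    }
    c_q, c_t = len(Q.chains), len(T.chains)
    best: ComplexAlignment | None = None
    best_key = None
    if c_q <= c_t:
        q_idx = list(range(c_q))
        t_choices = itertools.permutations(range(c_t), c_q)
        mappings = (list(zip(q_idx, ts)) for ts in t_choices)
    else:
        t_idx = list(range(c_t))
        q_choices = itertools.permutations(range(c_q), c_t)
        mappings = (list(zip(qs, t_idx)) for qs in q_choices)
    for mapping in mappings:
        rows = tuple(sorted(by_pair[p] for p in mapping if p in by_pair))
        if not rows:
            continue
        cand = ClusterCandidate(rows, rows[0], float("nan"))
        aln = score_assignment(Q, T, cand, alignments)
        key = (
            -(aln.tm_query_norm + aln.tm_target_norm),
            -aln.aligned_residues,
            tuple(aln.chain_pairs),
        )
        if best_key is None or key < best_key:
            best, best_key = aln, key
    return best
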