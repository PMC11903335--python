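"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code: the
quaternion (Horn) closed form instead of SVD Kabsch, a graph-component DBSCAN
instead of seed expansion, and a dense fragment-enumeration TM search instead
of the strided one.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def horn_superpose_rmsd(q: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Closed-form optimal superposition via Horn's quaternion method.

    Returns (rotation mapping centered t onto centered q, minimum RMSD).
    """
    q = np.asarray(q, float)
    t = np.asarray(t, float)
    n = len(q)
    qc = q - q.mean(axis=0)
    tc = t - t.mean(axis=0)
    m = tc.T @ qc  # correlation of target (to be rotated) against query
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    lam = eigvals[-1]
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    sq = (qc * qc).sum() + (tc * tc).sum() - 2.0 * lam
    rmsd = float(np.sqrt(max(sq, 0.0) / n))
    return rot, rmsd


def naive_dbscan(points: np.ndarray, epsilon: float) -> list[set[int]]:
    """O(n²) DBSCAN with minPts = 2 via connected components of the core graph.

    Core points connected when within epsilon form the cluster skeletons;
    border points join the earliest-forming cluster (by minimum core index)
    that reaches them, mirroring deterministic lowest-index seeding.
    """
    points = np.asarray(points, float)
    n = len(points)
    if points.shape[1] == 0:
        dist = np.zeros((n, n))
    else:
        diff = points[:, None, :] - points[None, :, :]
        dist = np.sqrt((diff * diff).sum(axis=2))
    neighbor = dist <= epsilon + 1e-12
    core = neighbor.sum(axis=1) >= 2
    core_idx = np.flatnonzero(core)
    if len(core_idx) == 0:
        return []
    sub = neighbor[np.ix_(core_idx, core_idx)]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    comps = [set(core_idx[labels == c].tolist()) for c in range(n_comp)]
    comps.sort(key=min)
    claimed = set().union(*comps)
    clusters = []
    for comp in comps:
        members = set(comp)
        for p in range(n):
            if core[p] or p in claimed:
                continue
            if neighbor[p, sorted(comp)].any():
                members.add(p)
                claimed.add(p)
        clusters.append(members)
    return clusters


def exhaustive_fragment_tm(
    q_coords: np.ndarray,
    t_coords: np.ndarray,
    pairs: np.ndarray,
    L_norm: int,
    d0: float,
    min_len: int = 5,
) -> float:
    """TM by seeding a superposition from *every* contiguous alignment fragment
    of every length >= min_len, each refined on the close-pair subset."""
    from multimeralign.chain_align import kabsch_superpose
    from multimeralign.structures import DegenerateGeometryError

    pairs = np.asarray(pairs, np.int64)
    qa = np.asarray(q_coords, float)[pairs[:, 0]]
    ta = np.asarray(t_coords, float)[pairs[:, 1]]
    n = len(pairs)
    cutoff = max(d0, 4.5)
    best = -1.0
    for frag in range(min_len, n + 1):
        for start in range(0, n - frag + 1):
            sl = slice(start, start + frag)
            try:
                tr, _ = kabsch_superpose(qa[sl], ta[sl])
            except (DegenerateGeometryError, ValueError):
                continue
            prev = None
            for _ in range(30):
                d = np.linalg.norm(qa - tr.apply(ta), axis=1)
                mask = d < cutoff
                if mask.sum() < 3 or (prev is not None and np.array_equal(mask, prev)):
                    break
                prev = mask
                try:
                    tr, _ = kabsch_superpose(qa[mask], ta[mask])
                except DegenerateGeometryError:
                    break
            d = np.linalg.norm(qa - tr.apply(ta), axis=1)
            best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2))))
    return best / L_norm
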