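"""GDT-TS between Cα traces and the naïve consensus-GDT score.

GDT-TS is the CASP-standard Global Distance Test: the mean over distance
cutoffs {1, 2, 4, 8} Å of the largest fraction of Cα atoms that can be
brought within the cutoff by a rigid-body superposition.  Finding that
largest fraction exactly is combinatorial, so, like the LGA program, we use
an iterative seed-and-extend heuristic: rigid fits seeded from contiguous
backbone fragments are refined by alternating "superpose on current inliers /
recompute inliers" until a fixed point.  The search is deterministic.

The consensus score CGDT of a decoy is its average GDT-TS to all other
members of the decoy set — a reference-free quality estimate that works when
good models form the majority cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import CAStructure, DecoySet, ScoreTable, StructureError

__all__ = [
    "GDT_CUTOFFS",
    "GDTMatrix",
    "kabsch_superpose",
    "gdt_ts",
    "gdt_matrix",
    "consensus_gdt",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


@dataclass
class GDTMatrix:
    """Symmetric matrix of pairwise GDT-TS values with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("GDT matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-6):
            raise ValueError("GDT matrix not symmetric")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of point set P onto Q (Kabsch algorithm).

    Returns ``(R, t, rmsd)`` such that ``P @ R.T + t`` minimizes the RMSD to
    ``Q``.  ``R`` is a proper rotation (det +1); reflections are excluded.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise ValueError("kabsch_superpose needs two equal (N>=3, 3) point sets")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid**2).sum() / len(P)))
    return R, t, rmsd


def _seed_masks(L: int) -> np.ndarray:
    """Boolean seed masks: contiguous fragments of lengths 3/5/7 plus full length.

    Fragment starts are strided for long chains to bound the seed count; short
    chains enumerate every start.
    """
    masks = [np.ones(L, dtype=bool)]
    for frag in (3, 5, 7):
        if frag > L:
            continue
        stride = 1 if L <= 30 else max(1, L // 10)
        starts = list(range(0, L - frag + 1, stride))
        if starts[-1] != L - frag:
            starts.append(L - frag)
        for s in starts:
            m = np.zeros(L, dtype=bool)
            m[s : s + frag] = True
            masks.append(m)
    return np.array(masks)


def _batched_fit_distances(P: np.ndarray, Q: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """For each mask, superpose P[mask] onto Q[mask]; return per-residue distances.

    Vectorized weighted Kabsch over a stack of S masks; returns (S, L) distances
    of the fully transformed P to Q.
    """
    m = masks.astype(float)  # (S, L)
    n = m.sum(axis=1)  # (S,)
    cp = (m @ P) / n[:, None]  # (S, 3)
    cq = (m @ Q) / n[:, None]
    # covariance H_s = sum_i m_si (P_i - cp_s)(Q_i - cq_s)^T, via batched matmul
    H = np.matmul(P.T[None], m[:, :, None] * Q[None]) - n[:, None, None] * cp[:, :, None] * cq[:, None, :]
    U, S, Vt = np.linalg.svd(H)
    V = np.ascontiguousarray(np.transpose(Vt, (0, 2, 1)))
    Ut = np.transpose(U, (0, 2, 1))
    det = np.linalg.det(np.matmul(V, Ut))
    V[:, :, 2] *= np.sign(det)[:, None]  # proper rotations only
    R = np.matmul(V, Ut)
    # transformed P for every seed: R_s (P_i - cp_s) + cq_s
    t = cq - np.matmul(R, cp[:, :, None])[:, :, 0]
    PT = np.matmul(P[None], np.transpose(R, (0, 2, 1))) + t[:, None, :]
    return np.sqrt(((PT - Q[None]) ** 2).sum(axis=2))


_EXACT_MAX_LEN = 12  # up to here the subset search is exhaustive


def _all_subset_masks(L: int) -> np.ndarray:
    """Every residue subset of size >= 3 as a boolean mask (small L only)."""
    idx = np.arange(2**L, dtype=np.uint32)
    bits = (idx[:, None] >> np.arange(L)) & 1
    masks = bits.astype(bool)
    return masks[masks.sum(axis=1) >= 3]


def _prefix_masks(order: np.ndarray) -> np.ndarray:
    """Masks of the first k residues (k >= 3) of a distance ordering."""
    L = len(order)
    masks = np.zeros((L - 2, L), dtype=bool)
    for k in range(3, L + 1):
        masks[k - 3, order[:k]] = True
    return masks


def _gdt_fractions(P: np.ndarray, Q: np.ndarray, cutoffs=GDT_CUTOFFS, max_iter: int = 10) -> np.ndarray:
    L = len(P)
    fracs = np.zeros(len(cutoffs))

    if L <= _EXACT_MAX_LEN:
        dist = _batched_fit_distances(P, Q, _all_subset_masks(L))
        for ci, d in enumerate(cutoffs):
            fracs[ci] = (dist <= d).sum(axis=1).max() / L
        return np.maximum.accumulate(fracs)

    # one joint stack over all cutoffs: rows are (cutoff, seed) refinements
    seeds = _seed_masks(L)
    S = len(seeds)
    nc = len(cutoffs)
    cut = np.repeat(np.asarray(cutoffs, dtype=float), S)[:, None]  # (nc*S, 1)
    masks = np.tile(seeds, (nc, 1))
    row_ci = np.repeat(np.arange(nc), S)
    # final distances and inlier counts per row, filled in as rows converge
    dist = np.full((nc * S, L), np.inf)
    counts = np.zeros(nc * S, dtype=int)
    active = np.arange(nc * S)
    for _ in range(max_iter):
        d_act = _batched_fit_distances(P, Q, masks[active])
        inliers = d_act <= cut[active]
        c_act = inliers.sum(axis=1)
        dist[active] = d_act
        counts[active] = np.maximum(counts[active], c_act)  # refinement may shed inliers
        # freeze rows that converged or would collapse below 3 support points
        ok = c_act >= 3
        new_masks = np.where(ok[:, None], inliers, masks[active])
        changed = np.any(new_masks != masks[active], axis=1)
        masks[active] = new_masks
        active = active[changed]
        if len(active) == 0:
            break
    for ci in range(nc):
        fracs[ci] = max(fracs[ci], counts[row_ci == ci].max() / L)
    # extension pass: refit on distance-ordered prefixes of each cutoff's best seeds
    ext_masks, ext_cut, ext_ci = [], [], []
    for ci in range(nc):
        rows = ci * S + np.argsort(-counts[ci * S : (ci + 1) * S], kind="stable")[: min(3, S)]
        for r in rows:
            pm = _prefix_masks(np.argsort(dist[r], kind="stable"))
            ext_masks.append(pm)
            ext_cut.append(np.full(len(pm), cutoffs[ci]))
            ext_ci.append(np.full(len(pm), ci))
    ext_dist = _batched_fit_distances(P, Q, np.vstack(ext_masks))
    ext_counts = (ext_dist <= np.concatenate(ext_cut)[:, None]).sum(axis=1)
    ext_ci = np.concatenate(ext_ci)
    for ci in range(nc):
        fracs[ci] = max(fracs[ci], ext_counts[ext_ci == ci].max() / L)
    # any superposition achieving fraction f at cutoff d achieves >= f at d' > d
    return np.maximum.accumulate(fracs)


def _common_coords(a: CAStructure, b: CAStructure) -> tuple[np.ndarray, np.ndarray]:
    if np.array_equal(a.resseq, b.resseq):
        return a.coords, b.coords
    common = set(a.resseq.tolist()) & set(b.resseq.tolist())
    if len(common) < 4:
        raise StructureError(
            f"gdt_ts({a.id}, {b.id}): fewer than 4 common residues"
        )
    ra = a.restrict(common)
    rb = b.restrict(common)
    return ra.coords, rb.coords


def gdt_ts(a: CAStructure, b: CAStructure) -> float:
    """GDT-TS between two Cα traces on the common residue set, in [0, 1]."""
    P, Q = _common_coords(a, b)
    if len(P) != len(Q):
        raise StructureError(f"gdt_ts({a.id}, {b.id}): length mismatch")
    if np.allclose(P, Q, atol=1e-9):
        return 1.0
    return float(_gdt_fractions(P, Q).mean())


def gdt_matrix(decoy_set: DecoySet) -> GDTMatrix:
    """All-pairs GDT-TS matrix of a decoy set (each unordered pair once)."""
    decoys = decoy_set.decoys
    n = len(decoys)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                g = gdt_ts(decoys[i], decoys[j])
            except StructureError as e:
                raise StructureError(
                    f"pair ({decoys[i].id}, {decoys[j].id}): {e}"
                ) from e
            M[i, j] = M[j, i] = g
    return GDTMatrix([d.id for d in decoys], M)


def consensus_gdt(M: GDTMatrix) -> ScoreTable:
    """CGDT: each decoy's mean GDT-TS to all other members of the set."""
    n = len(M.ids)
    if n < 2:
        raise ValueError("consensus_gdt needs at least 2 decoys")
    sums = M.values.sum(axis=1) - np.diag(M.values)
    values = {mid: float(s / (n - 1)) for mid, s in zip(M.ids, sums)}
    return ScoreTable("CGDT", values, "higher")
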