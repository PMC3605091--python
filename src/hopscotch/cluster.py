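"""PAM k-medoids on a precomputed dissimilarity matrix, and working-set
assembly.

PAM = BUILD (greedy seeding of k medoids, each pick minimising total cost)
followed by SWAP (steepest-descent exchange of a medoid with a non-medoid
until no exchange lowers the cost).  Operating on medoids rather than means
lets the clustering consume an RMSD matrix directly, with actual snapshots
as cluster representatives.  BUILD is deterministic; exact ties break toward
the lowest snapshot index, so a seed never changes the result and is
accepted only for interface uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import DistanceMatrix

__all__ = ["ClusterResult", "kmedoids", "select_working_set"]


@dataclass
class ClusterResult:
    """Medoid indices, assignment vector and total within-cluster cost (Å)."""

    k: int
    medoids: tuple[int, ...]
    assignment: np.ndarray
    cost: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        for m in self.medoids:
            if self.assignment[m] != m:
                raise ValueError("each medoid must be assigned to itself")

    def members(self, medoid: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == medoid)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "medoids": list(self.medoids),
            "assignment": self.assignment.tolist(),
            "cost_A": self.cost,
        }


def _assign(d: np.ndarray, medoids: np.ndarray) -> tuple[np.ndarray, float]:
    sub = d[medoids]  # (k, n)
    nearest = np.argmin(sub, axis=0)
    cost = float(sub[nearest, np.arange(d.shape[0])].sum())
    return medoids[nearest], cost


def kmedoids(dm: DistanceMatrix | np.ndarray, k: int, seed: int = 0) -> ClusterResult:
    """Partition ``n`` snapshots around ``k`` medoids by PAM.

    The cost Σ_j d(j, medoid(j)) is non-increasing across swap iterations
    and the returned configuration admits no improving single swap.
    """
    d = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    del seed  # ties are index-ordered; kept for interface stability

    # BUILD: greedily add the medoid that most reduces total cost.
    first = int(np.argmin(d.sum(axis=1)))
    medoids = [first]
    nearest_d = d[first].copy()
    for _ in range(1, k):
        # gain of adding candidate c: Σ_j max(nearest_d[j] − d[c, j], 0)
        gain = np.maximum(nearest_d[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest_d = np.minimum(nearest_d, d[c])

    med = np.array(sorted(medoids), dtype=int)
    _, cost = _assign(d, med)

    # SWAP: steepest descent over (medoid out, candidate in) exchanges.
    while True:
        sub = d[med]  # (k, n)
        order = np.argsort(sub, axis=0)
        d1 = sub[order[0], np.arange(n)]
        nearest_idx = order[0]
        d2 = sub[order[1], np.arange(n)] if len(med) > 1 else np.full(n, np.inf)

        best_delta, best_swap = -1e-12, None
        non_medoids = np.setdiff1d(np.arange(n), med, assume_unique=False)
        if non_medoids.size == 0:
            break
        for mi in range(len(med)):
            owned = nearest_idx == mi
            # removal re-routes owned points to min(d[c], d2); others to
            # min(d1, d[c])
            dc = d[non_medoids]  # (n_cand, n)
            delta = np.where(
                owned[None, :],
                np.minimum(dc, d2[None, :]) - d1[None, :],
                np.minimum(dc - d1[None, :], 0.0),
            ).sum(axis=1)
            ci = int(np.argmin(delta))
            if delta[ci] < best_delta:
                best_delta = float(delta[ci])
                best_swap = (mi, int(non_medoids[ci]))
        if best_swap is None:
            break
        mi, c = best_swap
        med[mi] = c
        med = np.sort(med)
        _, cost = _assign(d, med)

    assignment, cost = _assign(d, med)
    return ClusterResult(k=k, medoids=tuple(int(m) for m in med), assignment=assignment, cost=cost)


def select_working_set(
    cr: ClusterResult,
    extra_snapshot_indices=(),
    reference_index: int | None = None,
    n_total: int | None = None,
) -> tuple[int, ...]:
    """Assemble the working set: reference first, then cluster medoids, then
    extra (late-time) snapshots, deduplicated with order preserved.

    ``reference_index`` uses −1 (or any negative sentinel) to denote a
    conformation outside the trajectory, e.g. the crystal structure.
    Duplicate indices are dropped with a warning; out-of-range indices
    raise.
    """
    import warnings

    bound = n_total if n_total is not None else len(cr.assignment)
    extras = [int(i) for i in extra_snapshot_indices]
    for idx in extras:
        if not 0 <= idx < bound:
            raise IndexError(f"snapshot index {idx} out of range [0, {bound})")
    out: list[int] = []
    if reference_index is not None:
        out.append(int(reference_index))
    for idx in list(cr.medoids) + extras:
        if idx in out:
            warnings.warn(f"duplicate snapshot index {idx} dropped", stacklevel=2)
            continue
        out.append(idx)
    return tuple(out)
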