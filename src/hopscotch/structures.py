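"""Structures, conformational ensembles and ET-region RMSD.

Thin coordinate containers over plain numpy arrays, with multi-model PDB
read/write delegated to biotite.  RMSD between snapshots is computed on the
heavy atoms of the electron-transfer region after optimal rigid-body
(Kabsch) superposition on those same atoms, which makes the measure
independent of the simulation frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

__all__ = [
    "Structure",
    "Trajectory",
    "ETRegion",
    "DistanceMatrix",
    "read_structure",
    "write_trajectory",
    "superposed_rmsd",
    "pairwise_rmsd",
]


@dataclass
class Structure:
    """One conformation: per-atom annotations plus an (n_atoms, 3) coordinate
    array in Å.  Residue numbering follows the source file (author numbering,
    1-based); selections are by chain + residue number, never sequence index.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape != (len(self.chain_ids), 3):
            raise ValueError("coordinate/annotation length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)


@dataclass
class Trajectory:
    """An ordered conformational ensemble sharing one atom table.

    ``coords`` has shape (n_models, n_atoms, 3); ``timestamps_ps`` gives the
    extraction time of each snapshot.  ``cluster_labels`` optionally records
    the generating mode of each synthetic snapshot (provenance, unused by
    any estimator).
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    timestamps_ps: np.ndarray | None = None
    cluster_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coords must be (n_models, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.timestamps_ps is None:
            self.timestamps_ps = np.arange(self.coords.shape[0], dtype=float)

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model(self, i: int) -> Structure:
        return Structure(
            chain_ids=self.chain_ids,
            res_ids=self.res_ids,
            res_names=self.res_names,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=self.coords[i],
        )


@dataclass(frozen=True)
class ETRegion:
    """Residue selection spanning the space between donor and acceptor.

    ``residues`` are (chain_id, res_id) pairs in pathway order; donor and
    acceptor selectors are disjoint from the bridge residues.
    """

    residues: tuple[tuple[str, int], ...]
    donor: tuple[tuple[str, int], ...] = ()
    acceptor: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("ET region must contain at least one residue")
        bridge = set(self.residues)
        if (set(self.donor) | set(self.acceptor)) & bridge:
            raise ValueError("donor/acceptor must be disjoint from bridge residues")

    def atom_mask(
        self, traj: Trajectory | Structure, heavy_only: bool = True
    ) -> np.ndarray:
        """Boolean mask over the atom table selecting the region's atoms.

        Raises ``KeyError`` if any selected residue resolves to no atoms.
        """
        mask = np.zeros(len(traj.chain_ids), dtype=bool)
        for chain, res in self.residues:
            hit = (traj.chain_ids == chain) & (traj.res_ids == res)
            if not hit.any():
                raise KeyError(f"residue {chain}:{res} not found in structure")
            mask |= hit
        if heavy_only:
            mask &= traj.elements != "H"
        return mask


# -- PDB I/O ---------------------------------------------------------------


def _to_atom_array(st: Structure | Trajectory, model_coords: np.ndarray):
    arr = struc.AtomArray(len(st.chain_ids))
    arr.chain_id = np.asarray(st.chain_ids, dtype="U4")
    arr.res_id = np.asarray(st.res_ids, dtype=int)
    arr.res_name = np.asarray(st.res_names, dtype="U5")
    arr.atom_name = np.asarray(st.atom_names, dtype="U6")
    arr.element = np.asarray(st.elements, dtype="U2")
    arr.coord = np.asarray(model_coords, dtype=np.float32)
    return arr


def write_trajectory(traj: Trajectory | Structure, path) -> None:
    """Write a structure or multi-model ensemble as PDB."""
    if isinstance(traj, Structure):
        entity = _to_atom_array(traj, traj.coords)
    else:
        arrays = [_to_atom_array(traj, traj.coords[i]) for i in range(traj.n_models)]
        entity = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(entity)
    pdb.write(str(path))


def read_structure(path) -> Structure | Trajectory:
    """Read a PDB file: one MODEL gives a Structure, several a Trajectory.

    Missing ET-region atoms are detected at selection time, not here.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    fields = dict(
        chain_ids=np.asarray(stack.chain_id),
        res_ids=np.asarray(stack.res_id),
        res_names=np.asarray(stack.res_name),
        atom_names=np.asarray(stack.atom_name),
        elements=np.asarray(stack.element),
    )
    coords = np.asarray(stack.coord, dtype=float)
    if stack.stack_depth() == 1:
        return Structure(coords=coords[0], **fields)
    return Trajectory(coords=coords, **fields)


# -- RMSD ------------------------------------------------------------------


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD in Å after optimal proper-rotation superposition.

    Both inputs are (n, 3) with matched atom ordering, n >= 3.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need matched (n>=3, 3) coordinate arrays")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    diff = a - rot.apply(b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise RMSD matrix (Å) with snapshot labels."""

    values: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-9) or np.any(v < -1e-12):
            raise ValueError("distance matrix must have zero diagonal, >= 0")
        self.values = v
        if not self.labels:
            self.labels = tuple(range(v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_text(self, path, sep: str = "\t") -> None:
        header = sep.join(str(lab) for lab in self.labels)
        np.savetxt(str(path), self.values, delimiter=sep, header=header)


def pairwise_rmsd(
    traj: Trajectory, region: ETRegion, heavy_only: bool = True
) -> DistanceMatrix:
    """Full pairwise superposed-RMSD matrix over a trajectory's ET region.

    Vectorised Kabsch: for every snapshot pair the RMSD follows from the
    singular values of the 3×3 cross-covariance of the centred coordinates
    (smallest singular value negated when the optimal orthogonal transform
    would be improper), so no per-pair rotation is materialised.
    """
    mask = region.atom_mask(traj, heavy_only=heavy_only)
    x = traj.coords[:, mask, :]
    m, n_atoms = x.shape[0], x.shape[1]
    if n_atoms < 3:
        raise ValueError("ET region must select at least 3 atoms")
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sum(x**2, axis=(1, 2))  # per-snapshot Σ|r|²

    # All 3×3 cross-covariances H_ij = x_iᵀ x_j at once via one gram matrix
    # of the (3m, n_atoms) component-major coordinate layout.
    flat = x.transpose(0, 2, 1).reshape(3 * m, n_atoms)
    gram = flat @ flat.T
    h = gram.reshape(m, 3, m, 3).transpose(0, 2, 1, 3)
    iu, ju = np.triu_indices(m, k=1)

    vals = np.empty(iu.size)
    block = 200_000  # cap the batched-SVD workspace
    for start in range(0, iu.size, block):
        sl = slice(start, min(start + block, iu.size))
        hb = np.ascontiguousarray(h[iu[sl], ju[sl]])
        s = np.linalg.svd(hb, compute_uv=False)
        sign = np.sign(np.linalg.det(hb))
        sign[sign == 0] = 1.0
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = (norms[iu[sl]] + norms[ju[sl]] - 2.0 * trace) / n_atoms
        vals[sl] = np.sqrt(np.maximum(msd, 0.0))
    out = np.zeros((m, m))
    out[iu, ju] = vals
    out = out + out.T
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(values=out, labels=tuple(range(m)))
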