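"""Tight-binding site model of a protein electron-transfer region.

One site per redox-active moiety (a heme orbital, a bridging residue), with a
hole site energy on the diagonal and distance-decayed electronic couplings off
the diagonal.  Lower site energy means stronger hole acceptor; the occupied
hole state is the lowest eigenstate.  Donor and acceptor fragments group the
(nearly) degenerate frontier states of the cofactors and never belong to the
active bridge set that the pathway search whittles down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Fragment", "SiteModel"]


@dataclass(frozen=True)
class Fragment:
    """A donor or acceptor fragment: member sites plus state degeneracy."""

    sites: tuple[str, ...]
    degeneracy: int = 1

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("fragment needs at least one site")
        if self.degeneracy < 1:
            raise ValueError("degeneracy must be >= 1")


@dataclass
class SiteModel:
    """Sites, energies, couplings and fragments of an ET region.

    Attributes
    ----------
    labels : tuple of str
        Site labels (residue-style, e.g. ``"TRP191"``), unique.
    positions : (n, 3) array
        Site coordinates in Å.
    energies : (n,) array
        Hole site energies in eV (diagonal of the Hamiltonian).
    couplings : (n, n) array
        Symmetric inter-site couplings in eV, zero diagonal.
    donor, acceptor : Fragment
        Disjoint fragments; their sites are never bridge sites.
    active : list of str
        Bridge sites currently in the quantum region of the pathway search.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    energies: np.ndarray
    couplings: np.ndarray
    donor: Fragment
    acceptor: Fragment
    active: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.energies = np.asarray(self.energies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("site labels must be unique")
        if self.positions.shape != (n, 3) or self.energies.shape != (n,):
            raise ValueError("positions/energies shape mismatch with labels")
        if self.couplings.shape != (n, n):
            raise ValueError("coupling table must be n x n")
        if not np.allclose(self.couplings, self.couplings.T):
            raise ValueError("coupling table must be symmetric")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("site energies must be finite")
        frag = set(self.donor.sites) | set(self.acceptor.sites)
        if set(self.donor.sites) & set(self.acceptor.sites):
            raise ValueError("donor and acceptor fragments must be disjoint")
        unknown = frag - set(self.labels)
        if unknown:
            raise ValueError(f"fragment sites not in model: {sorted(unknown)}")
        if not self.active:
            self.active = [s for s in self.labels if s not in frag]
        if frag & set(self.active):
            raise ValueError("fragment sites cannot be in the active bridge set")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- lookups -----------------------------------------------------------

    def index(self, label: str) -> int:
        return self._index[label]

    @property
    def bridge_labels(self) -> tuple[str, ...]:
        """All non-fragment sites, in model order (independent of `active`)."""
        frag = set(self.donor.sites) | set(self.acceptor.sites)
        return tuple(s for s in self.labels if s not in frag)

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    # -- Hamiltonian -------------------------------------------------------

    def hamiltonian(
        self, include: list[str] | tuple[str, ...]
    ) -> tuple[np.ndarray, tuple[str, ...]]:
        """Sub-Hamiltonian over the given sites (model order preserved).

        Diagonal = hole site energies, off-diagonal = couplings.
        """
        order = [s for s in self.labels if s in set(include)]
        missing = set(include) - set(order)
        if missing:
            raise KeyError(f"unknown sites: {sorted(missing)}")
        idx = np.array([self._index[s] for s in order], dtype=int)
        h = self.couplings[np.ix_(idx, idx)].copy()
        np.fill_diagonal(h, self.energies[idx])
        return h, tuple(order)

    def active_hamiltonian(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Hamiltonian over the current active bridge set."""
        return self.hamiltonian(list(self.active))

    def with_active(self, active: list[str]) -> "SiteModel":
        """Copy of the model with a different active bridge set."""
        return SiteModel(
            labels=self.labels,
            positions=self.positions.copy(),
            energies=self.energies.copy(),
            couplings=self.couplings.copy(),
            donor=self.donor,
            acceptor=self.acceptor,
            active=list(active),
        )
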