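"""Donor–acceptor electronic couplings by the fragment charge difference (FCD)
method, over single states and (nearly) degenerate manifolds.

The two-state FCD transformation rotates a pair of adiabatic states (energies
E₁ ≤ E₂, fragment charge differences Δq₁, Δq₂ and transition term Δq₁₂) into
maximally charge-localized diabats, giving the coupling

    |V| = (E₂ − E₁)·|Δq₁₂| / √((Δq₁ − Δq₂)² + 4Δq₁₂²)

which is bounded by half the adiabatic splitting and reduces to it exactly at
resonance.  Applied to state pairs drawn from the eigensystem of a
bridge-including Hamiltonian, the two-state scheme captures both the direct
and the bridge-mediated superexchange interaction.

Manifold handling: with N_D donor-character and N_A acceptor-character states,
couplings form an N_D×N_A matrix summarised by rmsV = √(⟨V²⟩) over its
entries; the effective coupling √N_A·rmsV carries the N_A parallel-channel
multiplicity so that k(V_eff) = N_A·k(rmsV).  Conformational modulation of
the coupling is quantified by the coherence factor C = ⟨|V|⟩²/⟨V²⟩ over a
snapshot ensemble (1 for a fluctuation-free coupling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdiabaticStates",
    "CouplingMatrix",
    "CouplingStats",
    "fragment_charge_terms",
    "fcd_two_state",
    "pairwise_couplings",
    "rms_coupling",
    "effective_coupling",
    "coherence_factor",
]


@dataclass
class AdiabaticStates:
    """Eigen-states of a site Hamiltonian with donor/acceptor fragments.

    Attributes
    ----------
    energies : (n_states,) array
        Adiabatic energies in eV, ascending.
    coefficients : (n_states, n_sites) array
        Orthonormal site-coefficient vectors, one row per state.
    donor_sites, acceptor_sites : tuple of int
        Disjoint site-index sets defining the two fragments.
    site_labels : tuple of str
        Optional labels, parallel to the site axis.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    donor_sites: tuple[int, ...]
    acceptor_sites: tuple[int, ...]
    site_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if set(self.donor_sites) & set(self.acceptor_sites):
            raise ValueError("donor and acceptor fragments must be disjoint")
        gram = self.coefficients @ self.coefficients.T
        if not np.allclose(gram, np.eye(len(self.energies)), atol=1e-8):
            raise ValueError("state coefficient vectors must be orthonormal")

    def fragment_population(self, sites: tuple[int, ...]) -> np.ndarray:
        """Per-state population Σ_{i∈fragment} c_mi² (values in [0, 1])."""
        idx = list(sites)
        return np.sum(self.coefficients[:, idx] ** 2, axis=1)


def fragment_charge_terms(
    states: AdiabaticStates, m: int, n: int
) -> tuple[float, float, float]:
    """Charge-difference matrix elements for states ``m`` and ``n``.

    Returns (Δq_m, Δq_n, Δq_mn) where Δq_m = Σ_D c_mi² − Σ_A c_mi² and
    Δq_mn = Σ_D c_mi·c_ni − Σ_A c_mi·c_ni — expectation and transition
    elements of the donor-minus-acceptor charge operator.
    """
    d = list(states.donor_sites)
    a = list(states.acceptor_sites)
    c = states.coefficients

    def dq(i: int, j: int) -> float:
        return float(np.dot(c[i, d], c[j, d]) - np.dot(c[i, a], c[j, a]))

    return dq(m, m), dq(n, n), dq(m, n)


def fcd_two_state(
    e_1: float, e_2: float, dq_1: float, dq_2: float, dq_12: float
) -> float:
    """Two-state FCD coupling magnitude in eV.

    Requires E₂ ≥ E₁.  Degenerate charge terms (all ≈ 0) leave the diabatic
    rotation undefined and raise ``ValueError``.
    """
    if e_2 < e_1:
        raise ValueError("states must be energy-ordered, E2 >= E1")
    denom_sq = (dq_1 - dq_2) ** 2 + 4.0 * dq_12**2
    if denom_sq < 1e-24:
        raise ValueError(
            "all fragment charge terms vanish; diabatization undefined"
        )
    return (e_2 - e_1) * abs(dq_12) / math.sqrt(denom_sq)


def fcd_from_states(states: AdiabaticStates, m: int, n: int) -> float:
    """FCD coupling between adiabatic states ``m`` and ``n`` (any order)."""
    if states.energies[m] > states.energies[n]:
        m, n = n, m
    dq_m, dq_n, dq_mn = fragment_charge_terms(states, m, n)
    return fcd_two_state(
        float(states.energies[m]), float(states.energies[n]), dq_m, dq_n, dq_mn
    )


@dataclass
class CouplingMatrix:
    """|V_ij| in eV over donor states i ∈ 1..N_D and acceptor states j ∈ 1..N_A.

    ``context`` names the bridge treatment the underlying Hamiltonian used
    (direct / full / a named path).  ``donor_states``/``acceptor_states``
    record which adiabatic states carried the fragment character.
    """

    values: np.ndarray
    context: str
    donor_states: tuple[int, ...] = ()
    acceptor_states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(self.values < 0):
            raise ValueError("coupling magnitudes must be non-negative")

    @property
    def n_d(self) -> int:
        return self.values.shape[0]

    @property
    def n_a(self) -> int:
        return self.values.shape[1]


def pairwise_couplings(
    model,
    context: str,
    path_definitions: dict[str, list[str]] | None = None,
) -> CouplingMatrix:
    """FCD couplings over the donor/acceptor manifolds of a site model.

    The Hamiltonian includes the donor and acceptor fragment sites plus the
    bridge sites selected by ``context``: ``"direct"`` excludes every bridge
    site, ``"full"`` includes them all, any other label selects the residues
    listed under that name in ``path_definitions``.  After diagonalization
    the N_D states of largest donor-fragment population and the N_A states
    of largest acceptor-fragment population are paired; each pair is fed to
    the two-state FCD on that 2-state subspace.

    State assignment is greedy and disjoint: the N_D states of largest
    donor population are claimed first, then the N_A largest acceptor
    populations among the remaining states.  At donor/acceptor resonance,
    where eigenstates are even/odd fragment combinations, this still pairs
    the two resonant states and FCD recovers the coupling from their
    splitting.  A selected acceptor state with more donor than acceptor
    character is reported with a warning (ambiguous fragment character).
    """
    if context == "direct":
        bridge: list[str] = []
    elif context == "full":
        bridge = list(model.bridge_labels)
    else:
        if not path_definitions or context not in path_definitions:
            raise KeyError(f"unknown coupling context {context!r}")
        bridge = [s for s in path_definitions[context] if s in model.bridge_labels]

    include = list(model.donor.sites) + list(model.acceptor.sites) + bridge
    h, labels = model.hamiltonian(include)
    energies, vecs = np.linalg.eigh(h)
    pos = {lab: i for i, lab in enumerate(labels)}
    donor_idx = tuple(pos[s] for s in model.donor.sites)
    acceptor_idx = tuple(pos[s] for s in model.acceptor.sites)
    states = AdiabaticStates(
        energies=energies,
        coefficients=vecs.T,
        donor_sites=donor_idx,
        acceptor_sites=acceptor_idx,
        site_labels=tuple(labels),
    )

    n_d, n_a = model.donor.degeneracy, model.acceptor.degeneracy
    d_pop = states.fragment_population(donor_idx)
    a_pop = states.fragment_population(acceptor_idx)
    # Rank by fragment character; exact ties resolved toward lower energy
    # (stable sort on -population of energy-ascending states).
    d_states = tuple(int(i) for i in np.argsort(-d_pop, kind="stable")[:n_d])
    remaining = [i for i in np.argsort(-a_pop, kind="stable") if i not in d_states]
    a_states = tuple(int(i) for i in remaining[:n_a])
    if len(a_states) < n_a:
        raise ValueError("not enough states for the acceptor manifold")
    for j in a_states:
        # resonance mixes fragments ~evenly; warn only on clear dominance
        if a_pop[j] < 0.5 * d_pop[j]:
            warnings.warn(
                f"state {j} has more donor than acceptor character; "
                "fragment assignment ambiguous",
                stacklevel=2,
            )

    v = np.empty((n_d, n_a))
    for i, ds in enumerate(d_states):
        for j, as_ in enumerate(a_states):
            v[i, j] = fcd_from_states(states, ds, as_)
    return CouplingMatrix(
        values=v, context=context, donor_states=d_states, acceptor_states=a_states
    )


def rms_coupling(cm: CouplingMatrix | np.ndarray) -> float:
    """Root-mean-square coupling √((1/(N_D·N_A)) Σ_ij V_ij²) in eV."""
    values = cm.values if isinstance(cm, CouplingMatrix) else np.asarray(cm, float)
    if values.size == 0:
        raise ValueError("empty coupling matrix")
    return float(np.sqrt(np.mean(values**2)))


def effective_coupling(rms_v: float, n_a: int) -> float:
    """V_eff = √N_A·rmsV; satisfies k(V_eff) = N_A·k(rmsV)."""
    if n_a < 1:
        raise ValueError(f"acceptor multiplicity must be >= 1, got {n_a}")
    return math.sqrt(n_a) * rms_v


def coherence_factor(v_snapshots) -> float:
    """Coherence C = ⟨|V|⟩² / ⟨V²⟩ over a snapshot ensemble, C ∈ (0, 1].

    Uses coupling magnitudes; C = 1 for a constant coupling, small C for a
    strongly fluctuation-dominated one.
    """
    v = np.abs(np.asarray(v_snapshots, dtype=float))
    if v.size < 2:
        raise ValueError("coherence factor needs at least 2 snapshot values")
    mean_sq = float(np.mean(v**2))
    if mean_sq == 0:
        raise ValueError("all-zero coupling ensemble")
    return float(np.mean(v)) ** 2 / mean_sq


@dataclass
class CouplingStats:
    """Ensemble summary of one coupling context."""

    rms_v: float  # eV
    v_eff: float  # eV
    coherence: float
    n_snapshots: int
    context: str = ""
    per_snapshot: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "rms_v_eV": self.rms_v,
            "v_eff_eV": self.v_eff,
            "coherence": self.coherence,
            "n_snapshots": self.n_snapshots,
        }


def ensemble_coupling_stats(
    per_snapshot_rms: np.ndarray, n_a: int, context: str = ""
) -> CouplingStats:
    """Aggregate per-snapshot rmsV values into ensemble statistics.

    The ensemble rmsV is the quadratic mean of the per-snapshot values, so
    V² averages linearly over conformations as the rate does.
    """
    v = np.asarray(per_snapshot_rms, dtype=float)
    rms = float(np.sqrt(np.mean(v**2)))
    return CouplingStats(
        rms_v=rms,
        v_eff=effective_coupling(rms, n_a),
        coherence=coherence_factor(v),
        n_snapshots=int(v.size),
        context=context,
        per_snapshot=v,
    )
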