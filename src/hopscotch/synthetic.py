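"""Synthetic-data generators for every pipeline input.

Three generators emulate the study conditions of a protein–protein
hole-transfer assessment without any external download or simulation:

* :func:`gen_ensemble` — a multi-model conformational ensemble of a ~10
  residue ET region whose snapshots are drawn from a small number of
  Gaussian conformational modes (small, clustered fluctuations around a
  stable complex), standing in for an MD trajectory.
* :func:`gen_site_model` — a tight-binding site model with a planted
  low-energy pathway: a Trp-like trap site (lowest bridge energy) plus a
  geometric chain of bridge residues linking the donor to the acceptor,
  with distance-decayed couplings and detuned off-path residues.
* :func:`gen_gap_series` — Gaussian vertical energy-gap samples for the RO
  and OR redox states with a planted driving force and reorganization
  energy.  The noise is tied to λ through σ² = 2λk_BT, so the generator is
  itself linear-response consistent and λ is recoverable two independent
  ways (mean splitting and gap variance).

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .coupling import AdiabaticStates
from .energetics import GapSeries
from .sitemodel import Fragment, SiteModel
from .structures import Trajectory

__all__ = [
    "EnsembleSpec",
    "PlantedSiteSpec",
    "GapSpec",
    "gen_ensemble",
    "gen_site_model",
    "gen_diabatic_pair",
    "gen_gap_series",
    "ET_REGION_RESIDUES",
]

#: Bridge residues spanning the CcP/Cytc donor–acceptor gap (chain A = CcP,
#: chain B = Cytc), used as the default residue template.
ET_REGION_RESIDUES: tuple[tuple[str, int, str], ...] = (
    ("A", 176, "ALA"),
    ("A", 177, "LEU"),
    ("A", 191, "TRP"),
    ("A", 192, "GLY"),
    ("A", 193, "ALA"),
    ("A", 194, "ALA"),
    ("A", 195, "ASN"),
    ("A", 196, "ASN"),
    ("B", 81, "ALA"),
    ("B", 82, "PHE"),
)

_BACKBONE = (
    ("N", "N", np.array([0.0, 0.0, 0.0])),
    ("CA", "C", np.array([1.46, 0.0, 0.0])),
    ("C", "C", np.array([2.0, 1.4, 0.0])),
    ("O", "O", np.array([1.4, 2.4, 0.3])),
)


# ---------------------------------------------------------------------------
# Conformational ensembles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    """Conditions for a clustered synthetic conformational ensemble.

    ``cluster_spread`` (Å) scales the displacement of whole conformational
    modes; ``within_cluster_sigma`` (Å) the per-snapshot thermal jitter
    around a mode.  Separable clustering requires sigma < spread.
    """

    n_snapshots: int = 2000
    n_clusters: int = 10
    cluster_spread: float = 1.0
    within_cluster_sigma: float = 0.15
    residue_template: tuple[tuple[str, int, str], ...] = ET_REGION_RESIDUES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snapshots < 1 or self.n_clusters < 1:
            raise ValueError("counts must be positive")
        if self.n_snapshots < self.n_clusters:
            raise ValueError("need n_snapshots >= n_clusters")
        if self.cluster_spread <= 0 or self.within_cluster_sigma < 0:
            raise ValueError("spreads must be positive (sigma may be zero)")
        if self.within_cluster_sigma >= self.cluster_spread:
            raise ValueError(
                "within_cluster_sigma must be below cluster_spread "
                "(clusters separable by construction)"
            )
        if not self.residue_template:
            raise ValueError("residue template must be non-empty")


def _base_geometry(template) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Extended-chain base coordinates and atom annotations for the template."""
    chain_ids, res_ids, res_names, atom_names, elements, coords = (
        [], [], [], [], [], [],
    )
    for i, (chain, res_id, res_name) in enumerate(template):
        origin = np.array([3.8 * i, 0.0, 0.5 * (i % 2)])
        for name, element, offset in _BACKBONE:
            chain_ids.append(chain)
            res_ids.append(res_id)
            res_names.append(res_name)
            atom_names.append(name)
            elements.append(element)
            coords.append(origin + offset)
    ann = dict(
        chain_ids=np.array(chain_ids),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
    )
    return np.array(coords), ann


def gen_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Draw a multi-model ensemble from ``n_clusters`` Gaussian modes.

    Each mode displaces every atom of the base geometry by an independent
    Gaussian of scale ``cluster_spread``; snapshots add per-atom jitter of
    scale ``within_cluster_sigma``.  Snapshots are spread evenly over the
    modes and shuffled; the generating mode of each snapshot is kept on
    ``Trajectory.cluster_labels`` as provenance.  Timestamps are 1 ps apart.
    """
    rng = np.random.default_rng(spec.seed)
    base, ann = _base_geometry(spec.residue_template)
    n_atoms = base.shape[0]

    centers = base[None] + rng.normal(
        0.0, spec.cluster_spread, size=(spec.n_clusters, n_atoms, 3)
    )
    reps = int(np.ceil(spec.n_snapshots / spec.n_clusters))
    labels = rng.permutation(
        np.tile(np.arange(spec.n_clusters), reps)[: spec.n_snapshots]
    )
    noise = rng.normal(
        0.0, spec.within_cluster_sigma, size=(spec.n_snapshots, n_atoms, 3)
    ) if spec.within_cluster_sigma > 0 else np.zeros((spec.n_snapshots, n_atoms, 3))
    coords = centers[labels] + noise
    return Trajectory(
        coords=coords,
        timestamps_ps=np.arange(spec.n_snapshots, dtype=float),
        cluster_labels=labels,
        **ann,
    )


# ---------------------------------------------------------------------------
# Planted site models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Conditions for a tight-binding site model with a planted pathway.

    The bridge chain runs donor→acceptor with consecutive sites ~4 Å apart
    (inside a typical 4.5 Å contact cutoff); the trap site — a Trp-like
    strong hole acceptor — carries the strictly lowest bridge energy, the
    remaining chain sites are spaced ``energy_gap_scale`` eV apart, and the
    off-path sites sit above the whole chain and laterally outside contact
    of it.  Couplings decay as V₀·exp(−β·(r−r₀)) with clamping at V₀ below
    the contact distance r₀.
    """

    chain_sites: tuple[str, ...] = ("ALA194", "ALA193", "GLY192", "TRP191")
    trap_site: str = "TRP191"
    off_path_sites: tuple[str, ...] = (
        "ALA176", "LEU177", "ASN195", "ASN196", "ALA81", "PHE82",
    )
    energy_gap_scale: float = 0.3  # eV between successive bridge levels
    coupling_v0: float = 0.05  # eV at contact
    beta: float = 2.0  # Å⁻¹ raw through-space decay; the much slower
    # effective bridge-mediated decay emerges from sequential contact hops
    bridge_offset: float = 1.0  # eV of the lowest bridge level above D/A
    energy_noise: float = 0.01  # eV jitter on bridge levels
    acceptor_offset: float = -0.3  # eV: downhill hole transfer, keeps the
    # donor and acceptor manifolds off-resonance so state assignment is sharp
    chain_spacing: float = 4.0  # Å between consecutive chain sites
    donor_degeneracy: int = 2
    acceptor_degeneracy: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trap_site not in self.chain_sites:
            raise ValueError("trap_site must be a chain site")
        labels = self.chain_sites + self.off_path_sites
        if len(set(labels)) != len(labels):
            raise ValueError("site labels must be unique")
        if self.energy_gap_scale <= 0 or self.coupling_v0 <= 0 or self.beta <= 0:
            raise ValueError("scales must be positive")
        if self.chain_spacing <= 0:
            raise ValueError("chain spacing must be positive")


def gen_site_model(spec: PlantedSiteSpec, contact_r0: float = 3.0) -> SiteModel:
    """Build the planted site model described by ``spec``.

    Donor (heme_Cytc-like) and acceptor (heme_CcP-like) fragments carry two
    nearly degenerate sites each by default; bridge energies are jittered by
    ``energy_noise`` but keep the planted ordering (trap strictly lowest).
    Overlapping site positions are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    n_chain = len(spec.chain_sites)
    a = spec.chain_spacing

    labels: list[str] = []
    positions: list[np.ndarray] = []
    energies: list[float] = []

    # donor fragment at x <= 0, acceptor beyond the chain
    donor_sites = tuple(f"D{i+1}" for i in range(spec.donor_degeneracy))
    acceptor_sites = tuple(f"A{i+1}" for i in range(spec.acceptor_degeneracy))
    for i, lab in enumerate(donor_sites):
        labels.append(lab)
        positions.append(np.array([-0.0, 1.2 * i, 0.0]))
        energies.append(0.005 * i)  # nearly degenerate manifold
    for i, lab in enumerate(acceptor_sites):
        labels.append(lab)
        positions.append(np.array([a * (n_chain + 1), 1.2 * i, 0.0]))
        energies.append(spec.acceptor_offset + 0.005 * i)

    # chain sites between donor and acceptor, consecutive within contact
    chain_energy: dict[str, float] = {}
    rank = 0
    for site in spec.chain_sites:
        if site == spec.trap_site:
            chain_energy[site] = spec.bridge_offset
        else:
            rank += 1
            chain_energy[site] = spec.bridge_offset + rank * spec.energy_gap_scale
    for i, site in enumerate(spec.chain_sites):
        labels.append(site)
        positions.append(np.array([a * (i + 1), 0.0, 0.0]))
        jitter = rng.normal(0.0, spec.energy_noise)
        jitter = float(np.clip(jitter, -0.4 * spec.energy_gap_scale,
                               0.4 * spec.energy_gap_scale))
        energies.append(chain_energy[site] + jitter)

    # off-path sites: above the chain energetically, lateral geometrically
    top = spec.bridge_offset + (n_chain + 1) * spec.energy_gap_scale
    for i, site in enumerate(spec.off_path_sites):
        labels.append(site)
        positions.append(
            np.array([a * (1 + i % max(n_chain, 1)), 8.0 + 2.0 * (i // max(n_chain, 1)), 2.0])
        )
        energies.append(top + (i + 1) * spec.energy_gap_scale
                        + abs(rng.normal(0.0, spec.energy_noise)))

    pos = np.array(positions)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    if np.any(dist[np.triu_indices(len(labels), k=1)] < 1e-6):
        raise ValueError("overlapping site positions")
    couplings = spec.coupling_v0 * np.exp(
        -spec.beta * np.maximum(dist - contact_r0, 0.0)
    )
    np.fill_diagonal(couplings, 0.0)

    return SiteModel(
        labels=tuple(labels),
        positions=pos,
        energies=np.array(energies),
        couplings=couplings,
        donor=Fragment(sites=donor_sites, degeneracy=spec.donor_degeneracy),
        acceptor=Fragment(sites=acceptor_sites, degeneracy=spec.acceptor_degeneracy),
    )


# ---------------------------------------------------------------------------
# Diabatic oracles
# ---------------------------------------------------------------------------


def gen_diabatic_pair(v_true: float, site_offset: float = 0.0) -> AdiabaticStates:
    """Exact eigensystem of the 2×2 diabatic matrix [[0, v], [v, Δ]].

    Site 0 is the donor, site 1 the acceptor; the returned states carry all
    quantities a fragment-charge-difference analysis needs, with the planted
    |v| recoverable exactly.
    """
    if v_true == 0:
        raise ValueError("planted coupling must be nonzero")
    h = np.array([[0.0, v_true], [v_true, site_offset]])
    energies, vecs = np.linalg.eigh(h)
    return AdiabaticStates(
        energies=energies,
        coefficients=vecs.T,
        donor_sites=(0,),
        acceptor_sites=(1,),
        site_labels=("donor", "acceptor"),
    )


# ---------------------------------------------------------------------------
# Gap series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapSpec:
    """Planted driving force and reorganization energy for gap sampling."""

    delta_g_true: float  # eV
    lambda_true: float  # eV, > 0
    n_samples: int = 5
    temperature: float = DEFAULT_CONSTANTS.temperature  # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be positive")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per state")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def gen_gap_series(spec: GapSpec) -> tuple[GapSeries, GapSeries]:
    """Draw (RO, OR) vertical-gap series with planted ΔG° and λ.

    RO samples ~ N(ΔG° + λ, σ) and OR samples ~ N(ΔG° − λ, σ) with
    σ² = 2λk_BT, the variance linear response demands of Gaussian gap
    statistics — so mean splitting and gap variance recover the same λ.
    """
    rng = np.random.default_rng(spec.seed)
    constants = PhysicalConstants(temperature=spec.temperature)
    sigma = float(np.sqrt(2.0 * spec.lambda_true * constants.kbt))
    ro = rng.normal(spec.delta_g_true + spec.lambda_true, sigma, spec.n_samples)
    or_ = rng.normal(spec.delta_g_true - spec.lambda_true, sigma, spec.n_samples)
    return (
        GapSeries(state="RO", samples=ro),
        GapSeries(state="OR", samples=or_),
    )
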