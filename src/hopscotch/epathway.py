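"""Iterative hole-pathway search over a site model.

The procedure mirrors a QM/MM pathway-mapping strategy: localize the hole
(here, the lowest eigenstate of the active-bridge Hamiltonian standing in for
a spin density), record the residue(s) carrying it, exclude them from the
active region so the hole must find its next host, and repeat.  The search
stops when the identified residues form a chain connecting donor to acceptor,
when the active region is exhausted, or after a fixed step cap (default 7).
Ensemble results aggregate into a logo table of identification frequencies
per residue and step, and connected chains are classified against named path
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .sitemodel import SiteModel

__all__ = [
    "SpinDensity",
    "PathwayResult",
    "LogoTable",
    "hole_ground_state",
    "identify_sites",
    "is_connected",
    "epathway_search",
    "classify_path",
    "logo_frequencies",
]

DEFAULT_SHARE_THRESHOLD = 0.8
DEFAULT_CONTACT_CUTOFF = 4.5  # Å, typical heavy-atom contact
MAX_STEPS = 7


@dataclass
class SpinDensity:
    """Hole population per active site, from the occupied (lowest) hole state."""

    populations: dict[str, float]
    energy: float  # eigenvalue of the occupied hole state, eV

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"populations must sum to 1, got {total}")
        if any(p < -1e-12 for p in self.populations.values()):
            raise ValueError("populations must be non-negative")


@dataclass
class PathwayResult:
    """Record of one pathway search on one conformation."""

    steps: list[tuple[int, frozenset[str]]] = field(default_factory=list)
    connected: bool = False
    classified_path: str | None = None

    @property
    def identified(self) -> frozenset[str]:
        """Union of residues identified over all steps."""
        out: set[str] = set()
        for _, sites in self.steps:
            out |= sites
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "steps": [[d, sorted(s)] for d, s in self.steps],
            "connected": self.connected,
            "classified_path": self.classified_path,
        }


def hole_ground_state(model: SiteModel) -> SpinDensity:
    """Diagonalize the active-bridge Hamiltonian; return the lowest state's
    squared coefficients as site populations.

    Raises ``ValueError`` on an empty active set (search exhausted).
    """
    if not model.active:
        raise ValueError("active set is empty: pathway search exhausted")
    h, labels = model.active_hamiltonian()
    energies, vecs = np.linalg.eigh(h)
    ground = vecs[:, 0]
    pops = ground**2
    pops = pops / pops.sum()
    return SpinDensity(
        populations={lab: float(p) for lab, p in zip(labels, pops)},
        energy=float(energies[0]),
    )


def identify_sites(
    sd: SpinDensity, share_threshold: float = DEFAULT_SHARE_THRESHOLD
) -> frozenset[str]:
    """Sites carrying at least ``share_threshold`` of the maximum population.

    Always contains the argmax; several sites when the hole is shared almost
    evenly within a step.
    """
    if not 0 < share_threshold <= 1:
        raise ValueError("share_threshold must be in (0, 1]")
    p_max = max(sd.populations.values())
    return frozenset(
        lab for lab, p in sd.populations.items() if p >= share_threshold * p_max
    )


def is_connected(
    identified: frozenset[str] | set[str],
    model: SiteModel,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> bool:
    """True iff a donor site reaches an acceptor site through identified sites.

    Graph nodes are donor sites, acceptor sites and the identified residues;
    edges join pairs of sites closer than ``contact_cutoff`` (Å, site-point
    distance).
    """
    nodes = list(model.donor.sites) + list(model.acceptor.sites) + sorted(identified)
    coords = np.stack([model.position_of(s) for s in nodes])
    dist = cdist(coords, coords)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= contact_cutoff:
                g.add_edge(nodes[i], nodes[j])
    return any(
        nx.has_path(g, d, a)
        for d in model.donor.sites
        for a in model.acceptor.sites
    )


def epathway_search(
    model: SiteModel,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    max_steps: int = MAX_STEPS,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
) -> PathwayResult:
    """Iterate localize → identify → exclude until donor–acceptor connectivity,
    exhaustion of the active region, or the step cap.

    Works on a copy of the model's active set; every step is recorded, and a
    non-connected outcome is a valid result, not an error.
    """
    work = model.with_active(list(model.active))
    result = PathwayResult()
    identified_total: set[str] = set()
    for step in range(1, max_steps + 1):
        if not work.active:
            break
        sd = hole_ground_state(work)
        found = identify_sites(sd, share_threshold)
        result.steps.append((step, found))
        identified_total |= found
        work.active = [s for s in work.active if s not in found]
        if is_connected(identified_total, model, contact_cutoff):
            result.connected = True
            break
    return result


def classify_path(
    result: PathwayResult, path_definitions: dict[str, list[str] | tuple[str, ...]]
) -> str | None:
    """Label of the first path definition containing every identified residue
    of a connected result; ``None`` for no match or a disconnected result.

    ``path_definitions`` preserves insertion order, so more specific paths
    should be listed first.
    """
    if not result.connected:
        return None
    chain = set(result.identified)
    for label, residues in path_definitions.items():
        if chain <= set(residues):
            return label
    return None


@dataclass
class LogoTable:
    """Identification frequencies per residue and step over an ensemble.

    ``frequency[residue][step] = count / n_conformations``.  Per-residue
    totals may exceed 1 (multi-residue steps) or fall short of it (searches
    stopped early).
    """

    frequency: dict[str, dict[int, float]]
    n_conformations: int

    def residue_step(self, residue: str, step: int) -> float:
        return self.frequency.get(residue, {}).get(step, 0.0)

    def to_dict(self) -> dict:
        return {
            "n_conformations": self.n_conformations,
            "frequency": {
                r: {str(d): f for d, f in steps.items()}
                for r, steps in self.frequency.items()
            },
        }

    def render(self) -> str:
        """Plain-text logo: rows are residues, columns are steps."""
        steps = sorted({d for s in self.frequency.values() for d in s})
        lines = ["residue " + " ".join(f"step{d:>2}" for d in steps)]
        for res in sorted(self.frequency):
            row = " ".join(
                f"{self.frequency[res].get(d, 0.0):6.3f}" for d in steps
            )
            lines.append(f"{res:<8}{row}")
        return "\n".join(lines)


def logo_frequencies(results: list[PathwayResult]) -> LogoTable:
    """Aggregate pathway results into identification frequencies."""
    if not results:
        raise ValueError("no pathway results to aggregate")
    n = len(results)
    counts: dict[str, dict[int, int]] = {}
    for res in results:
        for step, sites in res.steps:
            for site in sites:
                counts.setdefault(site, {}).setdefault(step, 0)
                counts[site][step] += 1
    return LogoTable(
        frequency={
            r: {d: c / n for d, c in steps.items()} for r, steps in counts.items()
        },
        n_conformations=n,
    )
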