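"""Driving forces and linear-response reorganization energies.

The reorganization energy follows from vertical energy gaps ΔE_ET = E_RO −
E_OR sampled on equilibrium trajectories of the two redox states (RO:
reduced donor/oxidized acceptor before transfer; OR: after transfer):

    λ = (⟨ΔE_ET⟩_RO − ⟨ΔE_ET⟩_OR) / 2

In the linear-response (Gaussian fluctuation) regime the same λ is encoded
in the gap variance, λ_var = σ²/(2k_BT), which serves as an internal
consistency diagnostic.  The driving force is taken as the plain energy
change ΔG° ≈ ΔE = E_products − E_reactants, entropy neglected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "GapSeries",
    "StateEnergies",
    "delta_g",
    "lambda_linear_response",
    "gap_diagnostics",
    "read_gap_series",
    "write_gap_series",
]

STATE_LABELS = ("RO", "OR")


@dataclass
class GapSeries:
    """Vertical energy-gap samples ΔE_ET = E_RO − E_OR (eV) from one state's
    equilibrium ensemble.  The ``state`` label records which redox state's
    dynamics generated the snapshots — not the sign of the gap."""

    state: str
    samples: np.ndarray
    snapshot_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.state not in STATE_LABELS:
            raise ValueError(f"state must be one of {STATE_LABELS}")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 2:
            raise ValueError("gap series needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("gap samples must be finite")
        if not self.snapshot_ids:
            self.snapshot_ids = tuple(range(self.samples.size))

    @property
    def n(self) -> int:
        return self.samples.size

    def mean(self) -> float:
        return float(np.mean(self.samples))


@dataclass(frozen=True)
class StateEnergies:
    """Total energies of the reactant and product redox states, eV."""

    e_reactants: float
    e_products: float
    provenance: str = "synthetic"  # gas | solvent | qmmm | synthetic

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e_reactants) and np.isfinite(self.e_products)):
            raise ValueError("state energies must be finite")


def delta_g(se: StateEnergies) -> float:
    """ΔG° ≈ ΔE = E_products − E_reactants in eV (entropy neglected)."""
    return se.e_products - se.e_reactants


def lambda_linear_response(ro: GapSeries, or_: GapSeries) -> float:
    """λ = (⟨ΔE_ET⟩_RO − ⟨ΔE_ET⟩_OR)/2 in eV.

    A negative estimate (sampling noise or swapped labels) is returned
    as-is with a warning, never silently clipped.
    """
    if ro.state != "RO" or or_.state != "OR":
        raise ValueError("pass the RO-ensemble series first, then OR")
    lam = (ro.mean() - or_.mean()) / 2.0
    if lam <= 0:
        warnings.warn(
            f"non-positive reorganization energy estimate {lam:.4f} eV; "
            "check state labels and sampling",
            stacklevel=2,
        )
    return lam


def gap_diagnostics(
    series: GapSeries, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> dict:
    """Mean, variance and the variance-implied λ_var = σ²/(2k_BT) of a series."""
    if series.n < 3:
        raise ValueError("diagnostics need at least 3 samples")
    var = float(np.var(series.samples, ddof=1))
    return {
        "state": series.state,
        "n": series.n,
        "mean_eV": series.mean(),
        "variance_eV2": var,
        "lambda_var_eV": var / (2.0 * constants.kbt),
    }


def write_gap_series(series_list, path, sep: str = "\t") -> None:
    """Write gap series as two-column delimited text (state_label, gap_eV)."""
    frames = [
        pd.DataFrame({"state": s.state, "gap_eV": s.samples}) for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(str(path), sep=sep, index=False)


def read_gap_series(path, sep: str = "\t") -> dict[str, GapSeries]:
    """Read delimited gap text back into {state_label: GapSeries}."""
    df = pd.read_csv(str(path), sep=sep)
    if not {"state", "gap_eV"} <= set(df.columns):
        raise ValueError("gap file needs 'state' and 'gap_eV' columns")
    return {
        state: GapSeries(state=state, samples=group["gap_eV"].to_numpy())
        for state, group in df.groupby("state", sort=False)
    }
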