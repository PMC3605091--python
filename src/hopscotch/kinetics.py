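"""Marcus-theory nonadiabatic electron-transfer kinetics.

Implements the high-temperature nonadiabatic rate

    k = (2π/ħ) · V² · (4πλk_BT)^(−1/2) · exp(−(ΔG° + λ)² / (4λk_BT))

with explicit handling of (nearly) degenerate acceptor manifolds: a hole
leaving the donor can arrive in any of N_A acceptor states, so a rate
computed from the root-mean-square coupling over the manifold must be
multiplied by N_A — equivalently, evaluated with the effective coupling
√N_A·rmsV.  The module also provides the activation-gap diagnostic
λ − (−ΔG°) (zero in the activationless limit) and a one-step versus
two-step (sequential hopping) mechanism comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "marcus_rate",
    "hopping_rate",
    "activation_gap",
    "ETStep",
    "MechanismReport",
    "compare_mechanisms",
]


def marcus_rate(
    v: float,
    delta_g: float,
    lam: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Nonadiabatic Marcus rate constant in s⁻¹.

    Parameters
    ----------
    v : float
        Electronic coupling |V_DA| in eV (enters squared; sign irrelevant).
    delta_g : float
        Driving force ΔG° in eV (negative for exergonic transfer).
    lam : float
        Reorganization energy λ in eV; must be positive.
    constants : PhysicalConstants
        ħ, k_B and temperature.
    """
    if lam <= 0:
        raise ValueError(f"reorganization energy must be positive, got {lam}")
    if v == 0:
        raise ValueError("electronic coupling must be nonzero")
    kbt = constants.kbt
    prefactor = 2.0 * math.pi / constants.hbar
    dos = 1.0 / math.sqrt(4.0 * math.pi * lam * kbt)
    barrier = (delta_g + lam) ** 2 / (4.0 * lam * kbt)
    return prefactor * v * v * dos * math.exp(-barrier)


def hopping_rate(
    rms_v: float,
    n_a: int,
    delta_g: float,
    lam: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Rate into an N_A-fold (nearly) degenerate acceptor manifold.

    N_A parallel channels: k = N_A · marcus_rate(rmsV, ...), identical to
    marcus_rate(√N_A·rmsV, ...) since the rate is quadratic in the coupling.
    """
    if n_a < 1:
        raise ValueError(f"acceptor multiplicity must be >= 1, got {n_a}")
    return n_a * marcus_rate(rms_v, delta_g, lam, constants)


def activation_gap(delta_g: float, lam: float) -> float:
    """λ − (−ΔG°) in eV: distance from the activationless condition λ = −ΔG°."""
    return lam - (-delta_g)


@dataclass
class ETStep:
    """One hole-transfer step: donor→acceptor (DA), donor→bridge (DB) or
    bridge→acceptor (BA).

    `coupling` is the value fed to the rate (typically the highest-context
    rmsV); `n_a` the acceptor-manifold multiplicity applied to the rate.
    """

    label: str
    coupling: float  # eV
    delta_g: float  # eV
    lam: float  # eV
    n_a: int = 1
    distance: float | None = None  # Å, bookkeeping only
    constants: PhysicalConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("reorganization energy must be positive")
        if self.n_a < 1:
            raise ValueError("acceptor multiplicity must be >= 1")

    @property
    def rate(self) -> float:
        """k_ET in s⁻¹ including the acceptor-manifold multiplicity."""
        return hopping_rate(
            self.coupling, self.n_a, self.delta_g, self.lam, self.constants
        )

    @property
    def activation_gap(self) -> float:
        """λ − (−ΔG°) in eV."""
        return activation_gap(self.delta_g, self.lam)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "distance_A": self.distance,
            "coupling_eV": self.coupling,
            "delta_g_eV": self.delta_g,
            "lambda_eV": self.lam,
            "n_a": self.n_a,
            "activation_gap_eV": self.activation_gap,
            "rate_per_s": self.rate,
        }


@dataclass
class MechanismReport:
    """One-step versus two-step (sequential hopping) comparison.

    The effective two-step rate is that of the slowest step; no
    steady-state flux solution is attempted.
    """

    one_step_rate: float
    step_rates: dict  # {"DB": k, "BA": k}
    limiting_step: str
    two_step_rate: float
    rate_ratio: float  # two-step / one-step
    coupling_ratio: float  # limiting-step coupling / one-step coupling
    winner: str  # "one-step" | "two-step"

    def to_dict(self) -> dict:
        return {
            "one_step_rate_per_s": self.one_step_rate,
            "step_rates_per_s": dict(self.step_rates),
            "limiting_step": self.limiting_step,
            "two_step_rate_per_s": self.two_step_rate,
            "rate_ratio_two_over_one": self.rate_ratio,
            "coupling_ratio": self.coupling_ratio,
            "winner": self.winner,
        }


def compare_mechanisms(
    one_step: ETStep, two_step: tuple[ETStep, ETStep]
) -> MechanismReport:
    """Compare a single concerted step against a sequential two-step route.

    The total two-step reaction is limited by its slowest step.  Ties are
    reported deterministically as one-step.
    """
    first, second = two_step
    rates = {first.label: first.rate, second.label: second.rate}
    limiting = first if first.rate <= second.rate else second
    k_two = limiting.rate
    k_one = one_step.rate
    return MechanismReport(
        one_step_rate=k_one,
        step_rates=rates,
        limiting_step=limiting.label,
        two_step_rate=k_two,
        rate_ratio=k_two / k_one,
        coupling_ratio=limiting.coupling / one_step.coupling,
        winner="two-step" if k_two > k_one else "one-step",
    )
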