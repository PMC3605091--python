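# Methods

`hopscotch` assesses long-range electron transfer (ET) between two redox
proteins — concretely, hole transfer (HT) from cytochrome c to cytochrome c
peroxidase (CcP) — as a pipeline of four layers: conformational sampling and
clustering, hole-pathway mapping, electronic-coupling evaluation, and Marcus
kinetics. The quantum-chemical and molecular-dynamics layers that would feed
such an assessment in a production study are replaced here by a
model-Hamiltonian surrogate and by synthetic-data generators, so every stage
is exactly testable; the kinetics layer additionally consumes published
QM/MD-derived parameters for the CcP/Cytc system directly (the "replay"
mode), which is what the headline rate constants rest on.

## Nonadiabatic rate expression

For each HT step the rate is the high-temperature nonadiabatic (Marcus)
expression

    k = (2π/ħ) V² (4πλk_BT)^(−1/2) exp(−(ΔG° + λ)² / (4λk_BT))

with coupling `V`, driving force `ΔG°` and reorganization energy `λ` in eV,
`ħ = 6.582120×10⁻¹⁶ eV·s`, `k_B = 8.617333×10⁻⁵ eV/K`. The temperature is a
parameter, default 298.15 K; the replayed CcP/Cytc rates are insensitive to
the 298.15 K versus 300 K choice at their printed precision.

Heme donor and acceptor manifolds carry two nearly degenerate frontier
states (N_D = N_A = 2, bridge states single). Couplings over the manifold
are summarised by `rmsV = √(⟨V_ij²⟩)` with the 1/(N_D·N_A) normalisation; a
hole can arrive in any of the N_A final states, so the rate computed from
rmsV is multiplied by N_A — equivalently evaluated at the effective coupling
`V_eff = √N_A · rmsV`. The bridge→acceptor step starts from the localized
Trp191⁺ intermediate and targets the single heme_CcP hole state, so it
carries no multiplicity factor; back-calculation against the published rate
constants supports exactly this assignment (a ×2 factor would overshoot by
~80%, no factor agrees within the λ-rounding band).

Mechanism comparison treats the sequential (two-step) route as limited by
its slowest step; no steady-state flux solution is attempted, consistent
with the two step rates differing by more than five orders of magnitude.

## Electronic couplings: two-state FCD

Couplings are extracted from adiabatic state pairs by the fragment charge
difference (FCD) transformation. With energies E₁ ≤ E₂, fragment charge
differences Δq₁, Δq₂ (expectation values of the donor-minus-acceptor charge
operator) and transition term Δq₁₂,

    |V| = (E₂ − E₁) |Δq₁₂| / √((Δq₁ − Δq₂)² + 4 Δq₁₂²).

The expression is exact for any two-state system (verified against 1000
random 2×2 diabatic Hamiltonians to 10⁻¹⁰ relative), reduces to half the
splitting at resonance, and — applied to state pairs of a bridge-including
Hamiltonian — captures both direct and superexchange interactions: on a
D–B–A chain with transfer integral t and bridge detuning ΔE_B it reproduces
the Löwdin/perturbative limit t²/ΔE_B within 1% deep in the tunneling
regime, with the expected V ∝ 1/ΔE_B scaling (log-log slope −1.00 ± 0.02
over a decade).

For manifolds, adiabatic states are assigned greedily: the N_D states of
largest donor-fragment population first, then the N_A largest acceptor
populations among the remainder, ties toward lower energy. At exact
donor/acceptor resonance eigenstates are even/odd fragment combinations and
either assignment yields the same two-state subspace; a state with clearly
dominant wrong-fragment character triggers a warning rather than a silent
result.

Conformational modulation is quantified by the coherence factor
`C = ⟨|V|⟩²/⟨V²⟩` over the snapshot ensemble (1 = fluctuation-free).
Magnitudes are used; a signed convention would only lower C and no published
sign information is available to exploit.

## Hole-pathway search

The pathway mapper mirrors an iterative QM/MM spin-density procedure on a
tight-binding surrogate. A site model assigns each redox-active residue a
hole site energy (diagonal) and distance-decayed couplings
`V₀ exp(−β(r−r₀))`, clamped at V₀ inside the contact distance r₀ = 3 Å.
Lower site energy = stronger hole acceptor. Each iteration diagonalizes the
Hamiltonian over the currently active bridge sites, takes the squared
coefficients of the lowest eigenstate as the "spin density", identifies
every site carrying ≥ 0.8× the maximum population (several per step when
the hole is shared), removes them from the active region, and repeats. The
search stops on donor–acceptor connectivity — a path through identified
sites with inter-site gaps ≤ 4.5 Å — on exhaustion, or after 7 steps.
Ensemble results aggregate into a logo table (frequency of residue r at
step d, denominators = number of conformations; totals may exceed 1 through
multi-site steps or fall short through early stops), and connected chains
are classified against named path definitions by set inclusion, most
specific first.

The share threshold (0.8) and contact cutoff (4.5 Å, a typical heavy-atom
contact) are exposed parameters: no published criterion pins either, so
both are package choices, recorded here rather than hidden.

## Reorganization energies

λ follows from vertical energy gaps ΔE_ET = E_RO − E_OR sampled on the two
redox states' equilibrium ensembles:

    λ = (⟨ΔE_ET⟩_RO − ⟨ΔE_ET⟩_OR) / 2.

ΔG° is taken as the plain energy change E_products − E_reactants (entropy
neglected). In the linear-response regime the gap variance encodes the same
λ via λ_var = σ²/(2k_BT); `gap_diagnostics` reports both so a mismatch
(mislabeled ensembles, zero variance) is visible. Means are uniform and
unweighted.

## Synthetic generators — what they emulate and what they do not

* **Ensembles** (`gen_ensemble`): snapshots of a ten-residue ET region
  (backbone heavy atoms, extended-chain base geometry) drawn from
  `n_clusters` Gaussian conformational modes — whole-mode displacements of
  scale `cluster_spread` = 1.0 Å plus per-snapshot jitter
  `within_cluster_sigma` = 0.15 Å. Defaults are 2000 snapshots (a 2 ns
  window at 1 ps spacing) and 10 modes, matching the study protocol this
  pipeline operationalises; 3 late snapshots and a reference complex extend
  the working set to 14 conformations. Gaussian modes in Cartesian
  coordinates are the simplest model that makes RMSD clustering meaningful;
  they have no backbone connectivity, no anharmonicity, and no kinetic
  ordering, so passing clustering tests demonstrates the estimator chain,
  not MD realism.
* **Site models** (`gen_site_model`): two-site donor and acceptor fragments
  (near-degenerate, 5 meV split, acceptor 0.3 eV below the donor so hole
  transfer is downhill and state assignment is sharp), a four-residue chain
  Ala194–Ala193–Gly192–Trp191 spaced 4 Å with the Trp-like trap strictly
  lowest (bridge offset 1.0 eV above the donor, chain levels spaced
  `energy_gap_scale` = 0.3 eV, jitter 0.01 eV), and six off-path residues
  detuned above the chain and laterally out of contact. β = 2.0 Å⁻¹ governs
  the raw through-space decay; the much slower effective bridge-mediated
  decay emerges from sequential contact hops, which is what makes the
  direct context orders of magnitude weaker than bridge-including contexts,
  as in the real system. The 0.3 eV level spacing is 6× the ~0.05 eV
  contact coupling, inside the regime where the planted chain is recovered
  on every seed. Surrogate couplings are *not* on the eV scale of the real
  QM couplings; only orderings and algebraic relations transfer.
* **Gap series** (`gen_gap_series`): Gaussian samples with means ΔG° ± λ
  and variance σ² = 2λk_BT. No published distributional information exists
  for the real gap fluctuations; the Gaussian linear-response-consistent
  choice is an assumption, made so that the estimator can be validated two
  independent ways. Default 5 samples per state reflects the sparse
  sampling regime of the original protocol; the estimator's sd there is
  σ/√(2n) ≈ 0.03 eV at λ = 0.19 eV, quantified by Monte-Carlo in the tests.

## Clustering

Pairwise RMSD uses the ET region's heavy atoms after optimal rigid-body
(Kabsch) superposition on those same atoms; the matrix is computed from the
singular values of each snapshot pair's 3×3 cross-covariance (smallest
singular value sign-corrected for improper transforms), with all
cross-covariances obtained from one gram matrix. The cancellation in the
trace formula leaves a numerical floor of ~10⁻⁷ Å on exact duplicates —
far below the 10⁻³ Å PDB coordinate precision. Clustering is PAM
(BUILD + steepest-descent SWAP) directly on the RMSD matrix; BUILD is
deterministic and exact ties break toward the lowest snapshot index, so
results are seed-independent. PAM is a local search: it provably matches
exhaustive medoid enumeration on the separable instances tested (and did on
200 randomized balanced instances), but can stop in a local optimum on
ill-separated data.

## Numerical and design choices

* eV/s/K constant set throughout; couplings as magnitudes.
* FCD raises on a degenerate charge denominator (all Δq ≈ 0) instead of
  returning an arbitrary rotation.
* λ estimates that come out non-positive are returned with a warning, never
  clipped.
* Mechanism ties report deterministically as one-step.
* Working-set assembly deduplicates with a warning and keeps the reference
  conformation first.
* Reports contain no wall-clock timestamps, so a rerun with the same config
  and seed is byte-identical.
* Problem sizes in the test suite: the study-scale checks run one
  2003-snapshot ensemble (shared session fixture) with the 2000-snapshot
  window clustered at k = 10; unit-level checks use 20–200 snapshots, which
  is sufficient for every property asserted.

## Known limitations

* The surrogate reproduces the *logic* of spin-density pathway mapping, not
  its physics: populations come from a one-particle tight-binding ground
  state, not an open-shell QM/MM spin density.
* No steady-state or master-equation treatment of multi-step hopping; the
  slowest-step approximation is hard-wired.
* The replay consumes published couplings, driving forces and λ values as
  inputs; the package makes no attempt to recompute them ab initio, and the
  bridge→acceptor multiplicity convention, while numerically supported,
  cannot be pinned beyond the printed precision.
* Trajectory I/O is multi-model PDB only (no XTC/DCD), and no protein
  preparation (protonation, solvation) is provided.
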