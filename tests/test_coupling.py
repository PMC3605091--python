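"""FCD coupling algebra: closed-form 2×2 recovery, superexchange limits,
manifold statistics and the coherence factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopscotch.coupling import (
    AdiabaticStates,
    CouplingMatrix,
    coherence_factor,
    effective_coupling,
    fcd_from_states,
    fcd_two_state,
    fragment_charge_terms,
    pairwise_couplings,
    rms_coupling,
)
from hopscotch.kinetics import marcus_rate
from hopscotch.replay import PATH_DEFINITIONS
from hopscotch.sitemodel import Fragment, SiteModel
from hopscotch.synthetic import PlantedSiteSpec, gen_diabatic_pair, gen_site_model


def three_site_model(t, bridge_energy, acceptor_energy=0.0):
    """D–B–A chain with only nearest-neighbour coupling t."""
    c = np.zeros((3, 3))
    c[0, 1] = c[1, 0] = c[1, 2] = c[2, 1] = t
    return SiteModel(
        labels=("D", "B", "A"),
        positions=np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]]),
        energies=np.array([0.0, bridge_energy, acceptor_energy]),
        couplings=c,
        donor=Fragment(sites=("D",)),
        acceptor=Fragment(sites=("A",)),
    )


class TestFragmentChargeTerms:
    def test_state_fully_on_donor_has_unit_charge_difference(self):
        states = AdiabaticStates(
            energies=np.array([0.0, 1.0]),
            coefficients=np.eye(2),
            donor_sites=(0,),
            acceptor_sites=(1,),
        )
        dq_1, dq_2, dq_12 = fragment_charge_terms(states, 0, 1)
        assert dq_1 == pytest.approx(1.0)
        assert dq_2 == pytest.approx(-1.0)
        assert dq_12 == pytest.approx(0.0)

    def test_resonance_dimer_transition_term_unity(self):
        states = gen_diabatic_pair(0.05, 0.0)
        dq_1, dq_2, dq_12 = fragment_charge_terms(states, 0, 1)
        assert dq_1 == pytest.approx(0.0, abs=1e-12)
        assert dq_2 == pytest.approx(0.0, abs=1e-12)
        assert abs(dq_12) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_charge_operator_expectation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        states = AdiabaticStates(
            energies=np.array([0.0, 0.5, 1.0]),
            coefficients=q,
            donor_sites=(0,),
            acceptor_sites=(2,),
        )
        # brute-force operator: diag(+1 on donor, −1 on acceptor, 0 else)
        op = np.diag([1.0, 0.0, -1.0])
        for m in range(3):
            for n in range(3):
                expected = q[m] @ op @ q[n]
                if m == n:
                    dq_m, _, _ = fragment_charge_terms(states, m, (m + 1) % 3)
                    assert dq_m == pytest.approx(expected, abs=1e-12)
                else:
                    _, _, dq_mn = fragment_charge_terms(states, m, n)
                    assert dq_mn == pytest.approx(expected, abs=1e-12)

    def test_overlapping_fragments_rejected(self):
        with pytest.raises(ValueError):
            AdiabaticStates(
                energies=np.array([0.0, 1.0]),
                coefficients=np.eye(2),
                donor_sites=(0,),
                acceptor_sites=(0,),
            )


class TestFCDTwoState:
    def test_resonance_gives_half_splitting(self):
        assert fcd_two_state(0.0, 0.1, 0.0, 0.0, 1.0) == pytest.approx(0.05)

    def test_bounded_by_half_splitting(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            dq1, dq2 = rng.uniform(-1, 1, 2)
            dq12 = rng.uniform(-1, 1)
            if abs(dq12) < 1e-6:
                continue
            v = fcd_two_state(0.0, 0.3, dq1, dq2, dq12)
            assert v <= 0.15 + 1e-12

    def test_degenerate_charge_terms_rejected(self):
        with pytest.raises(ValueError):
            fcd_two_state(0.0, 1.0, 0.0, 0.0, 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        v=st.floats(1e-4, 0.5),
        delta=st.floats(-1.0, 1.0),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_recovers_planted_two_state_coupling(self, v, delta, sign):
        states = gen_diabatic_pair(sign * v, delta)
        assert fcd_from_states(states, 0, 1) == pytest.approx(v, rel=1e-9)

    def test_invariant_under_global_energy_shift(self):
        states = gen_diabatic_pair(0.03, 0.4)
        shifted = AdiabaticStates(
            energies=states.energies + 7.7,
            coefficients=states.coefficients,
            donor_sites=states.donor_sites,
            acceptor_sites=states.acceptor_sites,
        )
        assert fcd_from_states(shifted, 0, 1) == pytest.approx(
            fcd_from_states(states, 0, 1), rel=1e-12
        )

    def test_invariant_under_fragment_label_swap(self):
        states = gen_diabatic_pair(0.03, 0.4)
        swapped = AdiabaticStates(
            energies=states.energies,
            coefficients=states.coefficients,
            donor_sites=states.acceptor_sites,
            acceptor_sites=states.donor_sites,
        )
        assert fcd_from_states(swapped, 0, 1) == pytest.approx(
            fcd_from_states(states, 0, 1), rel=1e-12
        )


class TestSuperexchange:
    def test_deep_tunneling_matches_perturbative_coupling(self):
        t = 0.01
        de = 50 * t
        cm = pairwise_couplings(three_site_model(t, de), "full")
        assert cm.values[0, 0] == pytest.approx(t * t / de, rel=0.01)

    def test_doubling_bridge_energy_halves_coupling(self):
        t = 0.01
        v1 = pairwise_couplings(three_site_model(t, 1.0), "full").values[0, 0]
        v2 = pairwise_couplings(three_site_model(t, 2.0), "full").values[0, 0]
        assert v1 / v2 == pytest.approx(2.0, rel=0.05)

    def test_inverse_bridge_gap_scaling_over_a_decade(self):
        t = 0.005
        gaps = np.geomspace(0.5, 5.0, 8)
        vs = [
            pairwise_couplings(three_site_model(t, g), "full").values[0, 0]
            for g in gaps
        ]
        slope = np.polyfit(np.log(gaps), np.log(vs), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.02)


class TestPairwiseCouplings:
    def test_single_state_fragments_reduce_to_two_state_fcd(self):
        m = three_site_model(0.01, 1.0)
        direct = pairwise_couplings(m, "direct")
        assert direct.values.shape == (1, 1)
        h, labels = m.hamiltonian(["D", "A"])
        w, vec = np.linalg.eigh(h)
        states = AdiabaticStates(
            energies=w, coefficients=vec.T,
            donor_sites=(labels.index("D"),),
            acceptor_sites=(labels.index("A"),),
        )
        assert direct.values[0, 0] == pytest.approx(
            fcd_from_states(states, 0, 1), rel=1e-12
        )

    def test_direct_far_below_bridge_mediated_contexts(self):
        m = gen_site_model(PlantedSiteSpec(seed=31))
        paths = {k: list(v) for k, v in PATH_DEFINITIONS.items()}
        direct = rms_coupling(pairwise_couplings(m, "direct", paths))
        full = rms_coupling(pairwise_couplings(m, "full", paths))
        path1 = rms_coupling(pairwise_couplings(m, "path1", paths))
        assert full > 100 * direct
        assert path1 > 100 * direct

    def test_manifold_shape_matches_degeneracies(self):
        m = gen_site_model(PlantedSiteSpec(seed=32))
        cm = pairwise_couplings(m, "full")
        assert cm.values.shape == (2, 2)
        assert len(set(cm.donor_states) & set(cm.acceptor_states)) == 0

    def test_unknown_context_rejected(self):
        m = three_site_model(0.01, 1.0)
        with pytest.raises(KeyError):
            pairwise_couplings(m, "pathX")


class TestCouplingStatistics:
    def test_rms_of_equal_entries_is_that_value(self):
        cm = CouplingMatrix(values=np.full((2, 2), 0.007), context="full")
        assert rms_coupling(cm) == pytest.approx(0.007)

    def test_rms_of_three_four(self):
        cm = CouplingMatrix(values=np.array([[3.0, 4.0]]), context="full")
        assert rms_coupling(cm) == pytest.approx(np.sqrt(12.5))

    def test_rms_of_zero_matrix_is_zero(self):
        assert rms_coupling(np.zeros((2, 2))) == 0.0

    def test_rms_between_min_and_max(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.1, 2.0, size=(2, 3))
        r = rms_coupling(v)
        assert v.min() <= r <= v.max()

    def test_effective_coupling_identity_multiplicity(self):
        assert effective_coupling(1e-5, 1) == pytest.approx(1e-5)

    def test_effective_coupling_root_two_multiple(self):
        assert effective_coupling(2.23e-5, 2) == pytest.approx(3.154e-5, rel=1e-3)

    def test_rate_equivalence_of_effective_coupling(self):
        for n_a in range(1, 9):
            k_eff = marcus_rate(effective_coupling(2e-5, n_a), -0.5, 0.9)
            k_rms = n_a * marcus_rate(2e-5, -0.5, 0.9)
            assert k_eff == pytest.approx(k_rms, rel=1e-12)


class TestCoherenceFactor:
    def test_constant_coupling_fully_coherent(self):
        assert coherence_factor([0.01] * 6) == pytest.approx(1.0)

    def test_half_zero_ensemble_gives_half(self):
        assert coherence_factor([1.0, 0.0, 1.0, 0.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 1, 50)
        assert coherence_factor(3.7 * v) == pytest.approx(
            coherence_factor(v), rel=1e-12
        )

    def test_all_zero_ensemble_rejected(self):
        with pytest.raises(ValueError):
            coherence_factor([0.0, 0.0])
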