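"""Hole localization, iterative pathway search, connectivity and logo
aggregation on the tight-binding surrogate."""

import numpy as np
import pytest

from hopscotch.epathway import (
    PathwayResult,
    SpinDensity,
    classify_path,
    epathway_search,
    hole_ground_state,
    identify_sites,
    is_connected,
    logo_frequencies,
)
from hopscotch.replay import PATH_DEFINITIONS
from hopscotch.sitemodel import Fragment, SiteModel
from hopscotch.synthetic import PlantedSiteSpec, gen_site_model


def toy_model(energies, couplings, positions=None, n_bridge=None):
    """Minimal D–bridge–A model with explicit bridge energies/couplings."""
    n = len(energies)
    labels = ["D"] + [f"B{i}" for i in range(1, n - 1)] + ["A"]
    if positions is None:
        positions = np.column_stack([4.0 * np.arange(n), np.zeros(n), np.zeros(n)])
    return SiteModel(
        labels=tuple(labels),
        positions=positions,
        energies=np.asarray(energies, dtype=float),
        couplings=np.asarray(couplings, dtype=float),
        donor=Fragment(sites=("D",)),
        acceptor=Fragment(sites=("A",)),
    )


def chain_couplings(n, t):
    c = np.zeros((n, n))
    for i in range(n - 1):
        c[i, i + 1] = c[i + 1, i] = t
    return c


class TestHoleGroundState:
    def test_single_active_site_carries_full_population(self):
        m = toy_model([0.0, 1.0, -0.2], chain_couplings(3, 0.05))
        sd = hole_ground_state(m)
        assert sd.populations == {"B1": pytest.approx(1.0)}

    def test_two_degenerate_coupled_sites_share_evenly(self):
        m = toy_model([0.0, 1.0, 1.0, -0.2], chain_couplings(4, 0.05))
        sd = hole_ground_state(m)
        assert sd.populations["B1"] == pytest.approx(0.5, abs=1e-12)
        assert sd.populations["B2"] == pytest.approx(0.5, abs=1e-12)

    def test_deep_trap_localizes_population(self):
        m = toy_model([0.0, 1.0, 0.5, 1.0, -0.2], chain_couplings(5, 0.05))
        sd = hole_ground_state(m)
        assert sd.populations["B2"] > 0.9
        # independent eigen-decomposition of the bridge block
        h = np.array([[1.0, 0.05, 0.0], [0.05, 0.5, 0.05], [0.0, 0.05, 1.0]])
        w, v = np.linalg.eigh(h)
        assert sd.energy == pytest.approx(w[0], abs=1e-12)
        assert sd.populations["B2"] == pytest.approx(v[:, 0][1] ** 2, abs=1e-12)

    def test_empty_active_set_signals_exhaustion(self):
        m = toy_model([0.0, 1.0, -0.2], chain_couplings(3, 0.05))
        m.active = []
        with pytest.raises(ValueError, match="exhausted"):
            hole_ground_state(m)

    def test_populations_sum_to_one_every_iteration(self):
        m = gen_site_model(PlantedSiteSpec(seed=17))
        work = m.with_active(list(m.active))
        while work.active:
            sd = hole_ground_state(work)
            assert sum(sd.populations.values()) == pytest.approx(1.0, abs=1e-9)
            found = identify_sites(sd)
            before = len(work.active)
            work.active = [s for s in work.active if s not in found]
            assert len(work.active) < before  # strictly shrinking


class TestIdentifySites:
    def test_dominant_site_alone(self):
        sd = SpinDensity(populations={"a": 0.9, "b": 0.05, "c": 0.05}, energy=0.0)
        assert identify_sites(sd) == {"a"}

    def test_near_tie_identifies_both(self):
        sd = SpinDensity(populations={"a": 0.45, "b": 0.44, "c": 0.11}, energy=0.0)
        assert identify_sites(sd, 0.8) == {"a", "b"}

    def test_uniform_population_identifies_all(self):
        sd = SpinDensity(populations={c: 0.25 for c in "abcd"}, energy=0.0)
        assert identify_sites(sd) == set("abcd")

    def test_threshold_validated(self):
        sd = SpinDensity(populations={"a": 1.0}, energy=0.0)
        with pytest.raises(ValueError):
            identify_sites(sd, 1.5)


def _bfs_reachable(adj, start):
    """Independent breadth-first-search oracle."""
    seen, queue = {start}, [start]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


class TestConnectivity:
    def test_single_bridge_within_cutoff_connects(self):
        m = toy_model([0.0, 1.0, -0.2], chain_couplings(3, 0.05))
        assert is_connected({"B1"}, m, contact_cutoff=4.5)

    def test_gap_beyond_cutoff_disconnects(self):
        pos = np.array([[0.0, 0, 0], [4.0, 0, 0], [10.0, 0, 0]])
        m = toy_model([0.0, 1.0, -0.2], chain_couplings(3, 0.05), positions=pos)
        assert not is_connected({"B1"}, m, contact_cutoff=4.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bfs_oracle_on_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(5, 3))
        m = toy_model([0.0, 1.0, 1.0, 1.0, -0.2],
                      np.zeros((5, 5)), positions=pos)
        cutoff = 5.0
        nodes = ["D", "B1", "B2", "B3", "A"]
        adj = {u: [] for u in nodes}
        for i, u in enumerate(nodes):
            for j, v in enumerate(nodes):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    adj[u].append(v)
        expected = "A" in _bfs_reachable(adj, "D")
        assert is_connected({"B1", "B2", "B3"}, m, cutoff) == expected


class TestPathwaySearch:
    def test_planted_trap_identified_first(self):
        spec = PlantedSiteSpec(seed=23)
        result = epathway_search(gen_site_model(spec))
        assert result.steps[0][1] == {spec.trap_site}

    def test_planted_chain_recovered_and_classified(self):
        spec = PlantedSiteSpec(seed=23)
        result = epathway_search(gen_site_model(spec))
        assert result.connected
        assert result.identified == frozenset(spec.chain_sites)
        assert classify_path(result, PATH_DEFINITIONS) == "path1"

    def test_unbridgeable_geometry_never_connects(self):
        # consecutive chain gaps of 5 Å exceed the 4.5 Å contact cutoff
        spec = PlantedSiteSpec(chain_spacing=5.0, seed=24)
        result = epathway_search(gen_site_model(spec))
        assert not result.connected
        assert len(result.steps) <= 7

    def test_monotone_ladder_identified_in_energy_order(self):
        energies = [0.0, 1.0, 1.3, 1.6, 1.9, -0.2]
        m = toy_model(energies, chain_couplings(6, 0.02))
        # widen geometry so connectivity needs all bridge sites
        result = epathway_search(m, contact_cutoff=4.5)
        order = [next(iter(s)) for _, s in result.steps]
        assert order == ["B1", "B2", "B3", "B4"]

    def test_step_cap_respected(self):
        spec = PlantedSiteSpec(chain_spacing=5.0, seed=25)
        result = epathway_search(gen_site_model(spec), max_steps=7)
        assert len(result.steps) <= 7
        labels = [s for _, ss in result.steps for s in ss]
        assert len(labels) == len(set(labels))  # no residue identified twice


class TestClassifyPath:
    def _connected(self, sites):
        pr = PathwayResult(steps=[(1, frozenset(sites))], connected=True)
        return pr

    def test_path1_residues_classified(self):
        pr = self._connected({"TRP191", "GLY192", "ALA193", "ALA194"})
        assert classify_path(pr, PATH_DEFINITIONS) == "path1"

    def test_path2_residues_classified(self):
        pr = self._connected(
            {"ALA176", "LEU177", "ALA194", "ASN195", "PHE82", "ALA81"}
        )
        assert classify_path(pr, PATH_DEFINITIONS) == "path2"

    def test_disconnected_result_unclassified(self):
        pr = PathwayResult(steps=[(1, frozenset({"TRP191"}))], connected=False)
        assert classify_path(pr, PATH_DEFINITIONS) is None


class TestLogoFrequencies:
    def _result(self, first_site):
        return PathwayResult(steps=[(1, frozenset({first_site}))], connected=True)

    def test_ten_of_fourteen_frequency(self):
        results = [self._result("TRP191")] * 10 + [self._result("ALA176")] * 4
        logo = logo_frequencies(results)
        assert logo.residue_step("TRP191", 1) == pytest.approx(10 / 14)
        assert logo.n_conformations == 14

    def test_single_result_frequencies_are_binary(self):
        logo = logo_frequencies([self._result("TRP191")])
        assert logo.residue_step("TRP191", 1) == 1.0
        assert logo.residue_step("GLY192", 1) == 0.0

    def test_duplicated_ensemble_leaves_frequencies_unchanged(self):
        results = [self._result("TRP191")] * 3 + [self._result("ALA194")]
        once = logo_frequencies(results)
        twice = logo_frequencies(results * 2)
        assert once.residue_step("TRP191", 1) == twice.residue_step("TRP191", 1)

    def test_frequencies_are_rationals_over_n(self):
        results = [self._result("TRP191")] * 5 + [self._result("GLY192")] * 2
        logo = logo_frequencies(results)
        for res_freqs in logo.frequency.values():
            for f in res_freqs.values():
                assert (f * logo.n_conformations) == pytest.approx(
                    round(f * logo.n_conformations), abs=1e-12
                )
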