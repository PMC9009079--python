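"""Hybrid topology construction: MCS search, charge pruning, assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tieskit import (AtomMapping, AtomRecord, LigandGraph, MatchOptions,
                     build_hybrid, enforce_charge_tolerance,
                     find_structural_mcs, region_sizes, select_mapping)
from tieskit.errors import ConfigurationError, StructureError
from tieskit.ligand_topology import STRATEGIES

from conftest import chain, mcs_cardinality_oracle, min_removals_oracle, ring


class TestStructuralMCS:
    def test_identical_molecules_map_identically(self, propane):
        m = find_structural_mcs(propane, propane)
        assert len(m) == 9
        assert m.pairs == [(i, i) for i in range(9)]
        assert m.exact

    def test_toluene_vs_ethylbenzene_matches_exhaustive_oracle(
            self, toluene_heavy, ethylbenzene_heavy):
        m = find_structural_mcs(toluene_heavy, ethylbenzene_heavy)
        assert len(m) == mcs_cardinality_oracle(toluene_heavy, ethylbenzene_heavy) == 7

    def test_ethane_vs_methanol_common_carbon(self):
        ethane = chain(["C", "C"], name="ethane")
        methanol = chain(["C", "O"], name="methanol")
        m = find_structural_mcs(ethane, methanol)
        assert len(m) == mcs_cardinality_oracle(ethane, methanol) == 1
        assert m.pairs[0][1] == 0  # the carbon of methanol

    def test_no_common_atom_gives_empty_mapping(self):
        a = chain(["C"], name="c")
        b = chain(["N"], name="n")
        m = find_structural_mcs(a, b)
        assert len(m) == 0
        assert m.diagnostic is not None

    def test_budget_exhaustion_flags_heuristic_result(self):
        a = ring(8)
        b = ring(8)
        m = find_structural_mcs(a, b, MatchOptions(max_states=5))
        assert not m.exact
        assert len(m) >= 1  # greedy extension still yields a mapping

    def test_strict_bond_order_mode_blocks_order_mismatch(self):
        a = LigandGraph([AtomRecord(0, "C"), AtomRecord(1, "C")], [(0, 1, 2)])
        b = LigandGraph([AtomRecord(0, "C"), AtomRecord(1, "C")], [(0, 1, 1)])
        assert len(find_structural_mcs(a, b)) == 2  # default ignores order
        m = find_structural_mcs(a, b, MatchOptions(strict_bond_order=True))
        assert len(m) == 1

    def test_hydrogens_only_match_with_their_heavy_atoms(self):
        # methane vs lone H-H pair: no common heavy scaffold beyond C,
        # hydrogens may not seed a mapping on their own
        methane = LigandGraph(
            [AtomRecord(0, "C"), *(AtomRecord(i, "H") for i in range(1, 5))],
            [(0, i, 1) for i in range(1, 5)])
        h2 = LigandGraph([AtomRecord(0, "H"), AtomRecord(1, "H")], [(0, 1, 1)])
        assert len(find_structural_mcs(methane, h2)) == 0

    def test_deterministic_across_runs(self, toluene_heavy, ethylbenzene_heavy):
        m1 = find_structural_mcs(toluene_heavy, ethylbenzene_heavy)
        m2 = find_structural_mcs(toluene_heavy, ethylbenzene_heavy)
        assert m1.pairs == m2.pairs


class TestChargeTolerance:
    def _pair_with_charges(self, qa, qb):
        a = chain(["C"] * len(qa), charges=list(qa), name="A")
        b = chain(["C"] * len(qb), charges=list(qb), name="B")
        m = AtomMapping(pairs=[(i, i) for i in range(len(qa))])
        return a, b, m

    def test_zero_differences_returned_unchanged(self):
        a, b, m = self._pair_with_charges([0.1] * 6, [0.1] * 6)
        for strategy in STRATEGIES:
            out = enforce_charge_tolerance(m, a, b, strategy=strategy)
            assert out.pairs == m.pairs

    def test_single_violating_pair_removed(self):
        # one mapped pair at |dq| = 0.15 e against the default 0.1 e tolerance
        qa = [0.0] * 6
        qb = [0.0, 0.0, 0.0, 0.0, 0.0, 0.15]
        a, b, m = self._pair_with_charges(qa, qb)
        out = enforce_charge_tolerance(m, a, b)
        assert (5, 5) not in out.pairs
        assert len(out) == 5
        assert out.removal_trace == [(5, 5, "per-atom tolerance")]

    def test_net_violation_minimal_removals_match_exhaustive_search(self):
        # every pair at dq = +0.04 e: per-atom fine, sum 0.24 e violates net
        qa = [0.04] * 6
        qb = [0.0] * 6
        a, b, m = self._pair_with_charges(qa, qb)
        out = enforce_charge_tolerance(m, a, b, strategy="max_diff")
        k_min = min_removals_oracle(m.pairs, a, b, 0.1, 0.1)
        assert len(m) - len(out) == k_min == 4

    def test_disconnection_moves_smaller_fragment_out(self):
        # removing the middle atom of a 5-chain splits the mapping; the
        # smaller side must be dropped too
        qa = [0.0, 0.0, 0.2, 0.0, 0.0]
        qb = [0.0] * 5
        a, b, m = self._pair_with_charges(qa, qb)
        out = enforce_charge_tolerance(m, a, b)
        kept = [u for u, _ in out.pairs]
        assert kept == [0, 1] or kept == [3, 4]
        reasons = {r for _, _, r in out.removal_trace}
        assert "disconnected from common substructure" in reasons

    def test_unknown_strategy_rejected(self):
        a, b, m = self._pair_with_charges([0.0], [0.0])
        with pytest.raises(ConfigurationError):
            enforce_charge_tolerance(m, a, b, strategy="bogus")

    def test_mapping_emptied_reports_diagnostic(self):
        a, b, m = self._pair_with_charges([0.5, 0.5], [0.0, 0.0])
        out = enforce_charge_tolerance(m, a, b)
        assert len(out) == 0
        assert out.diagnostic is not None

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(-0.3, 0.3), min_size=2, max_size=8),
           st.sampled_from(STRATEGIES))
    def test_postconditions_hold_for_random_charges(self, qa, strategy):
        qb = [0.0] * len(qa)
        a, b, m = self._pair_with_charges(qa, qb)
        out = enforce_charge_tolerance(m, a, b, strategy=strategy)
        dq = [a.charge(u) - b.charge(v) for u, v in out.pairs]
        assert all(abs(d) <= 0.1 + 1e-12 for d in dq)
        assert abs(sum(dq)) <= 0.1 + 1e-12
        if out.pairs:
            import networkx as nx
            assert nx.is_connected(a.to_networkx().subgraph(u for u, _ in out.pairs))


class TestSelectMapping:
    def test_largest_strategy_wins(self):
        # interior violator: max_diff removes it and loses the smaller
        # disconnected half; terminal-first nibbles from the ends instead
        qa = [0.06, 0.06, 0.06, 0.0, 0.0, 0.0]
        qb = [0.0] * 6
        a = chain(["C"] * 6, charges=qa)
        b = chain(["C"] * 6, charges=qb)
        best = select_mapping(a, b)
        individual = [enforce_charge_tolerance(
            find_structural_mcs(a, b), a, b, strategy=s) for s in STRATEGIES]
        assert len(best) == max(len(x) for x in individual)
        assert best.provenance in STRATEGIES

    def test_tie_break_is_deterministic(self):
        a = ring(6)
        b = ring(6)
        results = [select_mapping(a, b) for _ in range(3)]
        assert all(r.pairs == results[0].pairs for r in results)
        assert all(r.provenance == results[0].provenance for r in results)

    def test_zero_charge_differences_keep_structural_mcs(self):
        a = ring(6, charge=-0.1)
        b = ring(6, charge=-0.1)
        structural = find_structural_mcs(a, b)
        best = select_mapping(a, b)
        assert best.pairs == structural.pairs


class TestBuildHybrid:
    def test_identical_ligands_have_empty_regions(self, propane):
        m = find_structural_mcs(propane, propane)
        h = build_hybrid(propane, propane, m)
        assert h.n_dis == h.n_app == 0
        assert sorted((u, v) for (_, u), (_, v), _ in h.merged_bonds) == \
            sorted((i, j) for i, j, _ in propane.bonds)

    def test_benzene_to_toluene_regions(self, toluene_heavy):
        benzene = ring(6, name="benzene")
        m = select_mapping(benzene, toluene_heavy)
        h = build_hybrid(benzene, toluene_heavy, m)
        assert h.n_dis == 0
        assert h.n_app == 1  # the methyl carbon
        assert h.appearing == {6}
        anchors = [bo for u, v, bo in h.merged_bonds
                   if {u[0], v[0]} == {"mcs", "app"}]
        assert len(anchors) == 1

    def test_atom_conservation(self, toluene_heavy, ethylbenzene_heavy):
        m = select_mapping(toluene_heavy, ethylbenzene_heavy)
        h = build_hybrid(toluene_heavy, ethylbenzene_heavy, m)
        assert len(toluene_heavy) + len(ethylbenzene_heavy) == \
            2 * len(h.mcs) + h.n_dis + h.n_app

    def test_disconnected_mapping_rejected(self):
        a = chain(["C", "C", "C"])
        b = chain(["C", "C", "C"])
        m = AtomMapping(pairs=[(0, 0), (2, 2)])  # ends without the middle
        with pytest.raises(StructureError):
            build_hybrid(a, b, m)

    def test_invalid_common_subgraph_rejected(self):
        a = chain(["C", "C", "C"])
        b = ring(3)
        m = AtomMapping(pairs=[(0, 0), (1, 1), (2, 2)])  # chain vs triangle
        with pytest.raises(StructureError):
            build_hybrid(a, b, m)

    def test_multi_bond_anchor_warns(self):
        a = LigandGraph([AtomRecord(0, "C"), AtomRecord(1, "C"),
                         AtomRecord(2, "O")], [(0, 1, 1), (1, 2, 2)])
        b = chain(["C", "C"])
        m = AtomMapping(pairs=[(0, 0), (1, 1)])
        h = build_hybrid(a, b, m)
        assert h.disappearing == {2}
        assert h.warnings  # carbonyl O anchored through a double bond

    def test_charged_region_net_charge_recorded(self):
        from tieskit import toy_ligand_pair
        a, b = toy_ligand_pair("charged_tail")
        m = select_mapping(a, b)
        h = build_hybrid(a, b, m)
        assert h.alchemical_net_charge_app == pytest.approx(1.0)
        assert h.alchemical_net_charge_dis == pytest.approx(0.0)

    def test_serialization_is_byte_identical_across_runs(self, toluene_heavy,
                                                         ethylbenzene_heavy):
        def run():
            m = select_mapping(toluene_heavy, ethylbenzene_heavy)
            return build_hybrid(toluene_heavy, ethylbenzene_heavy, m).to_json()
        assert run() == run()


class TestRegionSizes:
    @pytest.mark.parametrize("n_dis,n_app,alch,tsize,large,flagged", [
        (15, 4, 19, 11, True, False),
        (7, 7, 14, 0, False, False),
        (21, 20, 41, 1, False, True),
    ])
    def test_size_accounting(self, n_dis, n_app, alch, tsize, large, flagged):
        h = _hybrid_with_counts(n_dis, n_app)
        sizes = region_sizes(h)
        assert sizes.alchemical_size == alch
        assert sizes.transformation_size == tsize
        assert sizes.large_transformation is large
        assert sizes.large_alchemical_region is flagged


def _hybrid_with_counts(n_dis, n_app):
    """Synthetic hybrid record with given region sizes (counts only)."""
    from tieskit import HybridTopology
    return HybridTopology(
        mcs=AtomMapping(pairs=[(0, 0)]),
        disappearing=set(range(100, 100 + n_dis)),
        appearing=set(range(200, 200 + n_app)),
        merged_bonds=[], alchemical_net_charge_dis=0.0,
        alchemical_net_charge_app=0.0)
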