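"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use a different route than the package code:
exhaustive enumeration of connected node subsets plus networkx
subgraph-isomorphism for the MCS, and exhaustive subset search for
charge pruning, so they can cross-check the branch-and-bound and the
iterative removal heuristics.
"""

import itertools

import networkx as nx
import pytest
from networkx.algorithms.isomorphism import GraphMatcher

from tieskit import AtomRecord, LigandGraph


def connected_node_subsets(g: nx.Graph):
    """All connected node subsets of g (feasible for ~12 nodes)."""
    seen = set()

    def grow(s):
        fs = frozenset(s)
        if fs in seen:
            return
        seen.add(fs)
        nbrs = set().union(*(set(g[v]) for v in s)) - s
        for v in nbrs:
            grow(s | {v})

    for v in g:
        grow({v})
    return seen


def mcs_cardinality_oracle(a: LigandGraph, b: LigandGraph) -> int:
    """Size of the largest connected common induced subgraph, by exhaustive
    enumeration over connected subsets of A and induced-subgraph
    isomorphism into B (element labels matched, bond order ignored)."""
    ga, gb = a.to_networkx(), b.to_networkx()

    def node_match(x, y):
        return x["element"] == y["element"]

    subsets = sorted(connected_node_subsets(ga), key=len, reverse=True)
    for s in subsets:
        if len(s) > len(gb):
            continue
        if GraphMatcher(gb, ga.subgraph(s), node_match=node_match).subgraph_is_isomorphic():
            return len(s)
    return 0


def min_removals_oracle(pairs, a: LigandGraph, b: LigandGraph,
                        tol_atom: float, tol_net: float) -> int:
    """Smallest number of removals whose remainder satisfies both charge
    criteria and stays connected, by exhaustive search over removal
    subsets (feasible for <= 8 pairs)."""
    ga = a.to_networkx()
    pairs = list(pairs)
    for k in range(len(pairs) + 1):
        for keep in itertools.combinations(pairs, len(pairs) - k):
            if not keep:
                continue
            dq = [a.charge(u) - b.charge(v) for u, v in keep]
            if any(abs(d) > tol_atom for d in dq):
                continue
            if abs(sum(dq)) > tol_net:
                continue
            if not nx.is_connected(ga.subgraph([u for u, _ in keep])):
                continue
            return k
    return len(pairs)


def chain(elements, charges=None, name="chain", start_id=0):
    """Linear molecule builder for test fixtures."""
    charges = charges or [0.0] * len(elements)
    atoms = [AtomRecord(start_id + i, e, f"{e}{i + 1}", q)
             for i, (e, q) in enumerate(zip(elements, charges))]
    bonds = [(start_id + i, start_id + i + 1, 1) for i in range(len(elements) - 1)]
    return LigandGraph(atoms, bonds, name=name)


def ring(n, element="C", charge=0.0, name="ring"):
    atoms = [AtomRecord(i, element, f"{element}{i + 1}", charge) for i in range(n)]
    bonds = [(i, (i + 1) % n, 1) for i in range(n)]
    return LigandGraph(atoms, bonds, name=name)


@pytest.fixture
def propane():
    # 9-atom propane: C3 with explicit hydrogens
    atoms = [AtomRecord(0, "C", "C1", -0.06), AtomRecord(1, "C", "C2", -0.04),
             AtomRecord(2, "C", "C3", -0.06)]
    atoms += [AtomRecord(3 + i, "H", f"H{i + 1}", 0.02) for i in range(6)]
    bonds = [(0, 1, 1), (1, 2, 1),
             (0, 3, 1), (0, 4, 1), (1, 5, 1), (2, 6, 1), (2, 7, 1), (2, 8, 1)]
    return LigandGraph(atoms, bonds, name="propane")


@pytest.fixture
def toluene_heavy():
    g = ring(6, name="toluene")
    atoms = list(g.atoms) + [AtomRecord(6, "C", "C7", 0.0)]
    bonds = list(g.bonds) + [(0, 6, 1)]
    return LigandGraph(atoms, bonds, name="toluene")


@pytest.fixture
def ethylbenzene_heavy():
    g = ring(6, name="ethylbenzene")
    atoms = list(g.atoms) + [AtomRecord(6, "C", "C7", 0.0),
                             AtomRecord(7, "C", "C8", 0.0)]
    bonds = list(g.bonds) + [(0, 6, 1), (6, 7, 1)]
    return LigandGraph(atoms, bonds, name="ethylbenzene")
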