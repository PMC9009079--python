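"""Hybrid dual-topology construction for alchemical ligand transformations.

A relative free-energy calculation morphs ligand A into ligand B. The two
ligands share a maximum common substructure (MCS) that is kept as a single
set of atoms in the simulation-ready hybrid; the remainder of A forms the
"disappearing" alchemical region (fully coupled at λ=0) and the remainder
of B the "appearing" region (fully coupled at λ=1). Both regions anchor to
the unique MCS through the bonds of the parent ligands, so no dummy atoms
or positional restraints are required.

The MCS must be structurally identical (a connected common induced
subgraph, matched element-wise) and chemically near-identical: every
retained atom pair must agree in partial charge to within a per-atom
tolerance, and the summed charge mismatch over the MCS must stay within a
net tolerance (both default 0.1 e). Atoms are removed from the structural
MCS iteratively until the charge criteria hold; four removal strategies
are provided and the builder keeps whichever yields the largest MCS.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import networkx as nx

from .errors import ConfigurationError, StructureError

HYBRID_SCHEMA_VERSION = 1

#: Default per-atom and net partial-charge tolerances (elementary charge).
DEFAULT_TOL_ATOM = 0.1
DEFAULT_TOL_NET = 0.1

#: Transformation sizes above this count are classed "large".
LARGE_TRANSFORMATION_SIZE = 10
#: Alchemical regions with more atoms than this are flagged for slow convergence.
LARGE_ALCHEMICAL_SIZE = 40

#: Charge-tolerance pruning strategies, in canonical order.
STRATEGIES = ("max_diff", "terminal_first", "border_first", "terminal_and_border")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a ligand: identity, partial charge and optional coordinates.

    Parameters
    ----------
    atom_id : int
        Index unique within the ligand.
    element : str
        Chemical symbol (e.g. ``"C"``, ``"N"``, ``"H"``).
    name : str
        Free-text atom label (MOL2 atom name, PDB name, ...).
    partial_charge : float
        Partial charge in elementary-charge units (e).
    coords : tuple of 3 floats, optional
        Cartesian coordinates in Å, if known.
    """

    atom_id: int
    element: str
    name: str = ""
    partial_charge: float = 0.0
    coords: tuple[float, float, float] | None = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class LigandGraph:
    """Molecular graph of one ligand: atoms with charges plus bond topology.

    ``bonds`` are ``(atom_id_i, atom_id_j, order)`` triples with integer bond
    order; the graph must be connected, free of self-bonds, and every bond
    must reference existing atoms.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]]
    net_charge: int = 0
    name: str = ""

    def __post_init__(self):
        ids = [a.atom_id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate atom_ids in ligand {self.name!r}")
        idset = set(ids)
        norm = []
        for i, j, *rest in self.bonds:
            order = rest[0] if rest else 1
            if i == j:
                raise StructureError(f"self-bond on atom {i} in ligand {self.name!r}")
            if i not in idset or j not in idset:
                raise StructureError(
                    f"bond ({i},{j}) references unknown atom in ligand {self.name!r}")
            norm.append((min(i, j), max(i, j), int(order)))
        self.bonds = norm
        if self.atoms and not nx.is_connected(self.to_networkx()):
            raise StructureError(f"ligand graph {self.name!r} is not connected")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.atom_id, element=a.element, charge=a.partial_charge)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    @property
    def atom_ids(self) -> list[int]:
        return [a.atom_id for a in self.atoms]

    def atom(self, atom_id: int) -> AtomRecord:
        try:
            return self._index()[atom_id]
        except KeyError:
            raise StructureError(f"no atom {atom_id} in ligand {self.name!r}") from None

    def _index(self) -> dict[int, AtomRecord]:
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {a.atom_id: a for a in self.atoms}
            object.__setattr__(self, "_idx", idx)
        return idx

    def charge(self, atom_id: int) -> float:
        return self.atom(atom_id).partial_charge

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class AtomMapping:
    """Injective atom correspondence between two ligands.

    ``pairs`` maps atom_ids of ligand A onto atom_ids of ligand B; the induced
    subgraphs on the mapped atoms must be isomorphic under the mapping
    (element-wise and, by edge presence, bond-wise). ``exact`` is False when
    the search budget was exhausted and the result is a flagged heuristic.
    ``removal_trace`` records charge-pruning removals as
    ``(atom_id_A, atom_id_B, reason)`` triples.
    """

    pairs: list[tuple[int, int]]
    provenance: str = "structural"
    exact: bool = True
    removal_trace: list[tuple[int, int, str]] = field(default_factory=list)
    diagnostic: str | None = None

    def __post_init__(self):
        self.pairs = sorted(tuple(p) for p in self.pairs)
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise StructureError("mapping is not injective on both sides")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def mapped_a(self) -> set[int]:
        return {p[0] for p in self.pairs}

    @property
    def mapped_b(self) -> set[int]:
        return {p[1] for p in self.pairs}


@dataclass
class HybridTopology:
    """MCS plus alchemical regions of one ligand pair, ready for serialization.

    Merged-bond endpoints are tagged nodes ``(region, atom_id)`` with region
    one of ``"mcs"`` (A-side atom ids), ``"dis"`` (A ids) or ``"app"`` (B ids).
    """

    mcs: AtomMapping
    disappearing: set[int]
    appearing: set[int]
    merged_bonds: list[tuple[tuple[str, int], tuple[str, int], int]]
    alchemical_net_charge_dis: float
    alchemical_net_charge_app: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n_dis(self) -> int:
        return len(self.disappearing)

    @property
    def n_app(self) -> int:
        return len(self.appearing)

    def to_json(self) -> str:
        """Deterministic JSON serialization (schema-versioned)."""
        doc = {
            "schema_version": HYBRID_SCHEMA_VERSION,
            "mcs_pairs": [list(p) for p in self.mcs.pairs],
            "provenance": self.mcs.provenance,
            "exact": self.mcs.exact,
            "removal_trace": [list(t) for t in self.mcs.removal_trace],
            "disappearing": sorted(self.disappearing),
            "appearing": sorted(self.appearing),
            "n_dis": self.n_dis,
            "n_app": self.n_app,
            "alchemical_net_charge_dis": round(self.alchemical_net_charge_dis, 9),
            "alchemical_net_charge_app": round(self.alchemical_net_charge_app, 9),
            "merged_bonds": [[list(u), list(v), o] for u, v, o in self.merged_bonds],
            "warnings": list(self.warnings),
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))


class RegionSizes(tuple):
    """``(n_dis, n_app, alchemical_size, transformation_size)`` with filters."""

    def __new__(cls, n_dis, n_app, alchemical_size, transformation_size):
        return super().__new__(cls, (n_dis, n_app, alchemical_size, transformation_size))

    n_dis = property(lambda s: s[0])
    n_app = property(lambda s: s[1])
    #: total number of alchemical (appearing + disappearing) atoms
    alchemical_size = property(lambda s: s[2])
    #: absolute imbalance between disappearing and appearing atom counts
    transformation_size = property(lambda s: s[3])

    @property
    def large_transformation(self) -> bool:
        return self.transformation_size > LARGE_TRANSFORMATION_SIZE

    @property
    def large_alchemical_region(self) -> bool:
        return self.alchemical_size > LARGE_ALCHEMICAL_SIZE


@dataclass
class MatchOptions:
    """Structural matching configuration.

    Atoms match iff their elements are identical; bond order is ignored for
    matching (but preserved in output) unless ``strict_bond_order`` is set.
    ``max_states`` bounds the branch-and-bound search; past the budget a
    greedy extension finishes the job and the result is flagged inexact.
    Hydrogens are only matched once their bonded heavy atom is matched
    (they never seed a mapping on their own).
    """

    strict_bond_order: bool = False
    max_states: int = 1_000_000


# ---------------------------------------------------------------------------
# Structural MCS search
# ---------------------------------------------------------------------------

class _BudgetExhausted(Exception):
    pass


def find_structural_mcs(a: LigandGraph, b: LigandGraph,
                        options: MatchOptions | None = None) -> AtomMapping:
    """Maximum-cardinality connected common induced subgraph of two ligands.

    Branch-and-bound over atom pairings: each branch either assigns the
    smallest frontier atom of A to a compatible atom of B or excludes it
    permanently. The mapped subgraphs must be node-induced isomorphic
    (edge presence agrees both ways; element labels agree). Deterministic
    for fixed inputs and options; when two maximum mappings exist the one
    found first in the canonical search order is kept.

    Returns an empty mapping (not an error) when the ligands share no
    common atom under the matching criteria.
    """
    options = options or MatchOptions()
    if len(a) == 0 or len(b) == 0:
        raise StructureError("MCS search requires non-empty ligands")

    ga, gb = a.to_networkx(), b.to_networkx()
    elem_a = nx.get_node_attributes(ga, "element")
    elem_b = nx.get_node_attributes(gb, "element")
    adj_a = {u: set(ga[u]) for u in ga}
    adj_b = {v: set(gb[v]) for v in gb}

    def compatible(u, v):
        return elem_a[u] == elem_b[v]

    def edge_ok(u, x, v, y):
        # induced condition: edge presence must agree; orders too if strict
        ea, eb = ga.has_edge(u, x), gb.has_edge(v, y)
        if ea != eb:
            return False
        if ea and options.strict_bond_order:
            return ga[u][x]["order"] == gb[v][y]["order"]
        return True

    heavy_a = sorted(u for u in ga if elem_a[u].upper() != "H")
    seed_atoms_a = heavy_a or sorted(ga)  # all-H edge case (e.g. H2)

    best: list[tuple[int, int]] = []
    states = 0
    budget = options.max_states
    exact = True

    def extend(mapping: dict[int, int], used_b: set[int],
               excluded: frozenset[int], min_a: int):
        nonlocal best, states
        states += 1
        if states > budget:
            raise _BudgetExhausted
        if len(mapping) > len(best):
            best = sorted(mapping.items())
        # frontier: unmapped A atoms adjacent to the mapped set
        frontier = sorted(
            u for u in set().union(*(adj_a[x] for x in mapping)) - set(mapping)
            if u not in excluded and u >= (min_a if elem_a[u].upper() != "H" else 0))
        if not frontier:
            return
        # bound: even mapping the whole frontier closure cannot beat best
        reachable = _frontier_closure(adj_a, set(mapping), excluded, frontier)
        if len(mapping) + min(len(reachable), len(gb) - len(mapping)) < len(best):
            return
        u = frontier[0]
        cand_b = sorted(
            v for v in set().union(*(adj_b[mapping[x]] for x in mapping)) - used_b
            if compatible(u, v)
            and all(edge_ok(u, x, v, y) for x, y in mapping.items()))
        for v in cand_b:
            mapping[u] = v
            used_b.add(v)
            extend(mapping, used_b, excluded, min_a)
            del mapping[u]
            used_b.discard(v)
        extend(mapping, used_b, excluded | {u}, min_a)

    try:
        for u0 in seed_atoms_a:
            for v0 in sorted(v for v in gb if compatible(u0, v)):
                if 1 > len(best):
                    best = [(u0, v0)]
                # u0 is constrained to be the smallest heavy A-atom mapped
                extend({u0: v0}, {v0}, frozenset(), u0)
    except _BudgetExhausted:
        exact = False
        best = _greedy_extend(best, ga, gb, compatible, edge_ok, elem_a)

    return AtomMapping(pairs=best, provenance="structural", exact=exact,
                       diagnostic=None if best else "no common atom under matching criteria")


def _frontier_closure(adj_a, mapped, excluded, frontier):
    """Unmapped, non-excluded A atoms reachable from the frontier."""
    seen = set(frontier)
    stack = list(frontier)
    while stack:
        u = stack.pop()
        for w in adj_a[u]:
            if w not in seen and w not in mapped and w not in excluded:
                seen.add(w)
                stack.append(w)
    return seen


def _greedy_extend(pairs, ga, gb, compatible, edge_ok, elem_a):
    """Finish an interrupted search by repeatedly adding the canonically
    smallest compatible frontier pair."""
    mapping = dict(pairs)
    used_b = set(mapping.values())
    while True:
        if mapping:
            front_a = sorted(set().union(*(set(ga[x]) for x in mapping)) - set(mapping))
            front_b = set().union(*(set(gb[y]) for y in mapping.values())) - used_b
        else:
            front_a, front_b = sorted(ga), set(gb)
        addition = None
        for u in front_a:
            for v in sorted(front_b):
                if compatible(u, v) and all(edge_ok(u, x, v, y) for x, y in mapping.items()):
                    addition = (u, v)
                    break
            if addition:
                break
        if addition is None:
            return sorted(mapping.items())
        mapping[addition[0]] = addition[1]
        used_b.add(addition[1])


# ---------------------------------------------------------------------------
# Charge-tolerance pruning
# ---------------------------------------------------------------------------

def enforce_charge_tolerance(m: AtomMapping, a: LigandGraph, b: LigandGraph,
                             tol_atom: float = DEFAULT_TOL_ATOM,
                             tol_net: float = DEFAULT_TOL_NET,
                             strategy: str = "max_diff") -> AtomMapping:
    """Iteratively remove atom pairs from a mapping until charge criteria hold.

    The retained mapping satisfies |q_A − q_B| ≤ ``tol_atom`` for every pair
    and |Σ(q_A − q_B)| ≤ ``tol_net`` over all pairs, and remains connected
    (pruning that disconnects the common substructure keeps the largest
    component and moves the rest to the alchemical regions). One atom pair
    is removed per iteration:

    - ``max_diff``: the pair with the largest |Δq|;
    - ``terminal_first``: prefer atoms terminal in the current common
      substructure, then largest |Δq|;
    - ``border_first``: prefer atoms bordering the alchemical region
      (adjacent to an unmapped atom in either parent), then largest |Δq|;
    - ``terminal_and_border``: border membership checked first, then
      terminal, then largest |Δq|.

    When every per-atom difference is within tolerance but the net sum is
    not, candidates are restricted to pairs whose removal shrinks |Σ Δq|.
    Ties break on the smallest ``(atom_id_A, atom_id_B)``.
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(
            f"unknown pruning strategy {strategy!r}; expected one of {STRATEGIES}")
    if tol_atom <= 0 or tol_net <= 0:
        raise ConfigurationError("charge tolerances must be positive")

    ga, gb = a.to_networkx(), b.to_networkx()
    pairs = dict(m.pairs)
    trace = list(m.removal_trace)

    while pairs:
        dq = {u: a.charge(u) - b.charge(v) for u, v in pairs.items()}
        net = sum(dq.values())
        violators = sorted(u for u in pairs if abs(dq[u]) > tol_atom)
        if not violators and abs(net) <= tol_net:
            break
        if violators:
            cands = violators
            reason = "per-atom tolerance"
        else:
            # only the net criterion is violated: removing a pair whose Δq
            # shares the sign of the net sum strictly reduces |net|
            cands = sorted(u for u in pairs if dq[u] * net > 0)
            reason = "net tolerance"

        sub = ga.subgraph(pairs.keys())

        def is_terminal(u):
            return sub.degree(u) <= 1

        def is_border(u):
            v = pairs[u]
            return (any(w not in pairs for w in ga[u])
                    or any(w not in pairs.values() for w in gb[v]))

        if strategy == "max_diff":
            key = lambda u: (-abs(dq[u]), (u, pairs[u]))
        elif strategy == "terminal_first":
            key = lambda u: (not is_terminal(u), -abs(dq[u]), (u, pairs[u]))
        elif strategy == "border_first":
            key = lambda u: (not is_border(u), -abs(dq[u]), (u, pairs[u]))
        else:  # terminal_and_border
            key = lambda u: (not is_border(u), not is_terminal(u),
                             -abs(dq[u]), (u, pairs[u]))

        u = min(cands, key=key)
        trace.append((u, pairs[u], reason))
        del pairs[u]
        pairs, dropped = _keep_largest_component(pairs, ga)
        trace.extend((du, dv, "disconnected from common substructure")
                     for du, dv in dropped)

    diagnostic = None if pairs else "mapping emptied before charge criteria were met"
    return replace(m, pairs=sorted(pairs.items()), provenance=strategy,
                   removal_trace=trace, diagnostic=diagnostic)


def _keep_largest_component(pairs: dict[int, int], ga: nx.Graph):
    """Restrict a mapping to the largest connected component of its A-side
    subgraph. Ties go to the component containing the smallest atom_id."""
    if not pairs:
        return pairs, []
    sub = ga.subgraph(pairs.keys())
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    dropped = sorted((u, pairs[u]) for u in pairs if u not in keep)
    return {u: v for u, v in pairs.items() if u in keep}, dropped


def select_mapping(a: LigandGraph, b: LigandGraph,
                   tol_atom: float = DEFAULT_TOL_ATOM,
                   tol_net: float = DEFAULT_TOL_NET,
                   strategies: tuple[str, ...] = STRATEGIES,
                   options: MatchOptions | None = None) -> AtomMapping:
    """Structural MCS followed by every pruning strategy; keep the largest.

    Each strategy runs independently on the structural MCS; the strategy
    yielding the largest tolerance-satisfying mapping wins. Ties break on
    the lexicographically smallest sorted pair list, then on canonical
    strategy order, so the result is identical across runs.
    """
    if not strategies:
        raise ConfigurationError("at least one pruning strategy is required")
    structural = find_structural_mcs(a, b, options)
    results = [enforce_charge_tolerance(structural, a, b, tol_atom, tol_net, s)
               for s in strategies]
    best = min(results, key=lambda r: (-len(r.pairs), r.pairs,
                                       STRATEGIES.index(r.provenance)))
    if not best.pairs:
        best.diagnostic = "all strategies emptied the mapping"
    return best


# ---------------------------------------------------------------------------
# Hybrid assembly and size accounting
# ---------------------------------------------------------------------------

def build_hybrid(a: LigandGraph, b: LigandGraph, m: AtomMapping) -> HybridTopology:
    """Assemble the hybrid topology from a valid mapping.

    Atoms of A outside the mapping form the disappearing region, atoms of B
    outside it the appearing region. The merged bond list carries the common
    substructure's bonds once (A-side ids) plus each region's internal and
    anchoring bonds. Anchoring through a bond of order > 1 is legal but
    recorded as a warning, since the scheme expects single-bond anchors.
    """
    _validate_mapping(m, a, b)
    amap = m.as_dict()
    bmap = {v: u for u, v in amap.items()}
    dis = set(a.atom_ids) - set(amap)
    app = set(b.atom_ids) - set(bmap)

    def node_a(i):
        return ("mcs", i) if i in amap else ("dis", i)

    def node_b(j):
        return ("mcs", bmap[j]) if j in bmap else ("app", j)

    merged: list[tuple[tuple[str, int], tuple[str, int], int]] = []
    warnings: list[str] = []
    for i, j, order in a.bonds:
        merged.append((node_a(i), node_a(j), order))
    for i, j, order in b.bonds:
        ni, nj = node_b(i), node_b(j)
        if ni[0] == "mcs" and nj[0] == "mcs":
            continue  # already present from the A side
        merged.append((ni, nj, order))
    for u, v, order in merged:
        if order > 1 and {u[0], v[0]} in ({"mcs", "dis"}, {"mcs", "app"}):
            warnings.append(
                f"alchemical region anchored through bond of order {order}: {u}-{v}")
    merged.sort()

    return HybridTopology(
        mcs=m,
        disappearing=dis,
        appearing=app,
        merged_bonds=merged,
        alchemical_net_charge_dis=sum(a.charge(i) for i in dis),
        alchemical_net_charge_app=sum(b.charge(j) for j in app),
        warnings=warnings,
    )


def _validate_mapping(m: AtomMapping, a: LigandGraph, b: LigandGraph) -> None:
    if not m.pairs:
        raise StructureError("cannot build a hybrid from an empty mapping")
    ga, gb = a.to_networkx(), b.to_networkx()
    for u, v in m.pairs:
        if u not in ga or v not in gb:
            raise StructureError(f"mapping pair ({u},{v}) references unknown atoms")
        if ga.nodes[u]["element"] != gb.nodes[v]["element"]:
            raise StructureError(f"mapping pair ({u},{v}) matches different elements")
    amap = m.as_dict()
    for (u, v), (x, y) in itertools.combinations(amap.items(), 2):
        if ga.has_edge(u, x) != gb.has_edge(v, y):
            raise StructureError(
                f"mapping is not a common induced subgraph: bond mismatch ({u},{x})/({v},{y})")
    if not nx.is_connected(ga.subgraph(amap)):
        raise StructureError("mapped common substructure is not connected")


def region_sizes(h: HybridTopology) -> RegionSizes:
    """Alchemical-region accounting for a hybrid.

    ``alchemical_size`` is the total number of appearing plus disappearing
    atoms; ``transformation_size`` the absolute imbalance |n_dis − n_app|.
    Transformations above size 10 are classed large; alchemical regions
    above 40 atoms are flagged as slow to converge.
    """
    return RegionSizes(h.n_dis, h.n_app, h.n_dis + h.n_app, abs(h.n_dis - h.n_app))
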