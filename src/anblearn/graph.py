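"""DAG algebra for Bayesian-network structures.

d-separation, Markov blankets, Markov equivalence (identical skeletons and
v-structures), CPDAG conversion and the structural Hamming distance between
equivalence classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

__all__ = [
    "Structure",
    "PatternGraph",
    "d_separated",
    "markov_blanket",
    "markov_equivalent",
    "v_structures",
    "to_cpdag",
    "shd",
]


@dataclass(frozen=True)
class Structure:
    """A DAG given as one parent set per variable.

    ``parent_sets[i]`` is the set of parents of variable i; ``class_index``
    optionally designates the class variable X0 of a classifier structure.
    Acyclicity is checked at construction.
    """

    parent_sets: tuple[frozenset[int], ...]
    class_index: int | None = None

    def __post_init__(self) -> None:
        n = len(self.parent_sets)
        for i, pa in enumerate(self.parent_sets):
            if i in pa:
                raise ValueError(f"variable {i} is its own parent")
            if any(p < 0 or p >= n for p in pa):
                raise ValueError(f"parent index out of range for variable {i}")
        if self.class_index is not None and not 0 <= self.class_index < n:
            raise ValueError("class_index out of range")
        if self.topological_order() is None:
            raise ValueError("parent sets contain a directed cycle")

    @property
    def n_vars(self) -> int:
        return len(self.parent_sets)

    def edges(self) -> list[tuple[int, int]]:
        return [(p, c) for c in range(self.n_vars) for p in sorted(self.parent_sets[c])]

    def children(self, x: int) -> frozenset[int]:
        return frozenset(c for c in range(self.n_vars) if x in self.parent_sets[c])

    def topological_order(self) -> list[int] | None:
        """Kahn's algorithm; returns None if cyclic.  Lowest index first."""
        remaining = set(range(self.n_vars))
        order: list[int] = []
        while remaining:
            sinks_free = sorted(i for i in remaining
                                if not (self.parent_sets[i] & remaining))
            if not sinks_free:
                return None
            order.extend(sinks_free)
            remaining -= set(sinks_free)
        return order

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_vars))
        g.add_edges_from(self.edges())
        return g

    def is_anb(self, class_index: int | None = None) -> bool:
        """True iff X0 is parentless and a parent of every other variable."""
        c = self.class_index if class_index is None else class_index
        if c is None:
            raise ValueError("no class variable designated")
        if self.parent_sets[c]:
            return False
        return all(c in self.parent_sets[i] for i in range(self.n_vars) if i != c)

    def with_class(self, class_index: int | None) -> "Structure":
        return Structure(self.parent_sets, class_index)


def d_separated(g: Structure, x: int, y: int, z: Iterable[int]) -> bool:
    """Whether x and y are d-separated given z in g.

    Every path between x and y must be blocked: either it passes a
    non-collider that is in z, or a collider whose descendants (itself
    included) are all outside z.
    """
    z = frozenset(z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in z or y in z:
        raise ValueError("x and y must not be in the conditioning set")
    return nx.is_d_separator(g.to_networkx(), {x}, {y}, z)


def markov_blanket(g: Structure, x: int) -> frozenset[int]:
    """Parents, children, and parents-of-children of x (x excluded)."""
    ch = g.children(x)
    mb = set(g.parent_sets[x]) | set(ch)
    for c in ch:
        mb |= g.parent_sets[c]
    mb.discard(x)
    return frozenset(mb)


def _skeleton(g: Structure) -> frozenset[frozenset[int]]:
    return frozenset(frozenset(e) for e in g.edges())


def v_structures(g: Structure) -> frozenset[tuple[int, int, int]]:
    """Convergence connections a -> c <- b with a, b non-adjacent; a < b."""
    skel = _skeleton(g)
    out = set()
    for c in range(g.n_vars):
        for a, b in combinations(sorted(g.parent_sets[c]), 2):
            if frozenset((a, b)) not in skel:
                out.add((a, c, b))
    return frozenset(out)


def markov_equivalent(g1: Structure, g2: Structure) -> bool:
    """Identical links and identical convergence connections."""
    if g1.n_vars != g2.n_vars:
        raise ValueError("structures are over different variable sets")
    return _skeleton(g1) == _skeleton(g2) and v_structures(g1) == v_structures(g2)


@dataclass(frozen=True)
class PatternGraph:
    """CPDAG: compelled edges directed, reversible edges undirected."""

    n_vars: int
    directed: frozenset[tuple[int, int]]
    undirected: frozenset[frozenset[int]]

    def edge_status(self, a: int, b: int) -> str:
        """One of 'none', 'undirected', '->', '<-' for the ordered pair (a, b)."""
        if frozenset((a, b)) in self.undirected:
            return "undirected"
        if (a, b) in self.directed:
            return "->"
        if (b, a) in self.directed:
            return "<-"
        return "none"


def to_cpdag(g: Structure) -> PatternGraph:
    """CPDAG of g's Markov equivalence class.

    Starts from the skeleton with only v-structure edges directed, then
    closes under Meek's orientation rules R1-R3 (R4 cannot fire without
    background knowledge).  Two DAGs map to the same pattern iff they are
    Markov equivalent.
    """
    skel = {tuple(sorted(e)) for e in _skeleton(g)}
    directed: set[tuple[int, int]] = set()
    for a, c, b in v_structures(g):
        directed.add((a, c))
        directed.add((b, c))

    adj: dict[int, set[int]] = {i: set() for i in range(g.n_vars)}
    for a, b in skel:
        adj[a].add(b)
        adj[b].add(a)

    def is_undecided(e: tuple[int, int]) -> bool:
        return e not in directed and (e[1], e[0]) not in directed

    changed = True
    while changed:
        changed = False
        for a, b in sorted(skel):
            if not is_undecided((a, b)):
                continue
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z and y non-adjacent  =>  x -> y
                if any((z, x) in directed and y not in adj[z] and z != y
                       for z in adj[x]):
                    directed.add((x, y))
                    changed = True
                    break
                # R2: directed path x -> z -> y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed
                       for z in adj[x] & adj[y]):
                    directed.add((x, y))
                    changed = True
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1 and z2 non-adjacent => x -> y
                spokes = [z for z in adj[x] & adj[y]
                          if (z, y) in directed
                          and (x, z) not in directed and (z, x) not in directed]
                if any(z2 not in adj[z1] for z1, z2 in combinations(spokes, 2)):
                    directed.add((x, y))
                    changed = True
                    break

    undirected = frozenset(frozenset(e) for e in skel
                           if e not in directed and (e[1], e[0]) not in directed)
    return PatternGraph(g.n_vars, frozenset(directed), undirected)


def shd(g1: Structure, g2: Structure) -> int:
    """Structural Hamming distance between the CPDAGs of g1 and g2.

    Counts node pairs whose edge status (absent / undirected / directed
    either way) differs; a direction mismatch counts 1.
    """
    if g1.n_vars != g2.n_vars:
        raise ValueError("structures are over different variable sets")
    p1, p2 = to_cpdag(g1), to_cpdag(g2)
    return sum(p1.edge_status(a, b) != p2.edge_status(a, b)
               for a, b in combinations(range(g1.n_vars), 2))
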