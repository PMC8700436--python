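"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the algorithms they check: d-separation
is decided by enumerating undirected paths, CPDAGs by enumerating all
orientations of the skeleton, and the exact-search optimum by enumerating
DAGs directly as parent-set assignments filtered for acyclicity.
"""

from __future__ import annotations

from itertools import chain, combinations, product

import numpy as np
import pytest

from anblearn import Dataset, Structure, VariableSpec


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def four_row_dataset() -> Dataset:
    """Rows (X0, X1) = (1,1), (1,2), (2,1), (1,1) over two binary variables."""
    variables = [VariableSpec("X0", ("1", "2")), VariableSpec("X1", ("1", "2"))]
    return Dataset(variables, np.array([[1, 1], [1, 2], [2, 1], [1, 1]]), 0)


def random_dataset(rng: np.random.Generator, n_vars: int, n_rows: int,
                   max_card: int = 3) -> Dataset:
    cards = rng.integers(2, max_card + 1, size=n_vars)
    variables = [VariableSpec(f"X{i}", tuple(str(s) for s in range(c)))
                 for i, c in enumerate(cards)]
    rows = np.column_stack([rng.integers(1, c + 1, size=n_rows) for c in cards])
    return Dataset(variables, rows, class_index=0)


# ------------------------------------------------------------ DAG universe

def all_dags(n: int):
    """Every DAG on n labelled nodes as a Structure (parent-set product
    filtered by acyclicity); 3 -> 25 DAGs, 4 -> 543 DAGs."""
    others = [[frozenset(s) for s in powerset(set(range(n)) - {i})]
              for i in range(n)]
    for assignment in product(*others):
        try:
            yield Structure(tuple(assignment))
        except ValueError:
            continue


def powerset(items):
    items = sorted(items)
    return chain.from_iterable(combinations(items, k)
                               for k in range(len(items) + 1))


def random_dag(rng: np.random.Generator, n: int, p_edge: float = 0.4) -> Structure:
    order = rng.permutation(n)
    parents = [set() for _ in range(n)]
    for t, i in enumerate(order):
        for j in order[:t]:
            if rng.random() < p_edge:
                parents[i].add(int(j))
    return Structure(tuple(frozenset(s) for s in parents))


# -------------------------------------------------------- graph oracles

def d_separated_by_paths(g: Structure, x: int, y: int, z) -> bool:
    """Path-enumeration d-separation oracle.

    Enumerates every undirected simple path between x and y and checks the
    blocking conditions node by node.
    """
    z = frozenset(z)
    n = g.n_vars
    adj = {i: set() for i in range(n)}
    for p, c in g.edges():
        adj[p].add(c)
        adj[c].add(p)

    descendants = {i: _descendants(g, i) for i in range(n)}

    def paths(current, target, visited):
        if current == target:
            yield [current]
            return
        for nxt in sorted(adj[current]):
            if nxt not in visited:
                for rest in paths(nxt, target, visited | {nxt}):
                    yield [current] + rest

    for path in paths(x, y, {x}):
        blocked = False
        for t in range(1, len(path) - 1):
            a, b, c = path[t - 1], path[t], path[t + 1]
            collider = a in g.parent_sets[b] and c in g.parent_sets[b]
            if collider:
                if not (({b} | descendants[b]) & z):
                    blocked = True
                    break
            elif b in z:
                blocked = True
                break
        if not blocked:
            return False
    return True


def _descendants(g: Structure, x: int) -> frozenset[int]:
    out = set()
    frontier = [x]
    while frontier:
        node = frontier.pop()
        for c in g.children(node):
            if c not in out:
                out.add(c)
                frontier.append(c)
    return frozenset(out)


def cpdag_by_enumeration(g: Structure):
    """Exhaustive-orientation CPDAG oracle.

    Re-orients every skeleton edge in all 2^|E| ways, keeps the acyclic
    graphs with the original v-structure set, and calls an edge undirected
    iff both orientations occur among the survivors.  Returns (directed
    edge set, undirected pair set).
    """
    from anblearn.graph import v_structures

    edges = sorted({tuple(sorted((p, c))) for p, c in g.edges()})
    target_v = v_structures(g)
    seen_orientations: dict[tuple[int, int], set[bool]] = {e: set() for e in edges}
    for flips in product((False, True), repeat=len(edges)):
        parents = [set() for _ in range(g.n_vars)]
        for (a, b), flip in zip(edges, flips):
            p, c = (b, a) if flip else (a, b)
            parents[c].add(p)
        try:
            candidate = Structure(tuple(frozenset(s) for s in parents))
        except ValueError:
            continue
        if v_structures(candidate) != target_v:
            continue
        for e, flip in zip(edges, flips):
            seen_orientations[e].add(flip)
    directed = set()
    undirected = set()
    for (a, b), flips_seen in seen_orientations.items():
        if len(flips_seen) == 2:
            undirected.add(frozenset((a, b)))
        elif flips_seen == {False}:
            directed.add((a, b))
        else:
            directed.add((b, a))
    return frozenset(directed), frozenset(undirected)


# -------------------------------------------------------- scoring oracle

def sequential_predictive_log_score(counts: np.ndarray, ess: float) -> float:
    """Dirichlet-multinomial prior-predictive product, one pseudo-observation
    at a time: ln prod_j prod_t (a_jk + seen_jk) / (a_j + seen_j)."""
    counts = np.asarray(counts)
    q, r = counts.shape
    a_j = ess / q
    a_jk = ess / (q * r)
    log_p = 0.0
    for j in range(q):
        seen = 0
        for k in range(r):
            for t in range(int(counts[j, k])):
                log_p += np.log((a_jk + t) / (a_j + seen))
                seen += 1
    return log_p
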