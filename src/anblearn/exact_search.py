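"""Exact structure optimization by dynamic programming over variable subsets.

Finds the globally BDeu-optimal DAG in two search spaces:

* ``gbn`` — all DAGs over the dataset's variables;
* ``anb`` — augmented naive Bayes: the class variable X0 is parentless and
  is a parent of every feature, feature-feature edges free.

The DP has three table-building phases.  Phase 1 scores every admissible
(child, candidate parent set) pair.  Phase 2 propagates best parents
g_i*(S): the admissible subset of S maximizing the local score.  Phase 3
exploits the fact that the optimal network over a variable subset Z has a
sink X_s whose parents are its best parents within Z \\ {X_s}, while the
remaining variables form the optimal network over Z \\ {X_s}; the recursion
bottoms out at the empty set and the optimum over all variables is read off
the full set.  In ANB mode the constant class-marginal score is dropped
during the search and added back for reporting, and the DP runs over
feature subsets only (every candidate parent set implicitly contains X0).

Ties are broken deterministically: equal-scoring parent candidates prefer
the smaller set, then the smaller bit-mask encoding; equal-scoring sinks
prefer the lowest variable index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .data_io import Dataset, VariableSpec
from .graph import Structure
from .scoring import BDeuScorer, ScoreParams

__all__ = [
    "SearchResult",
    "exact_search",
    "exact_search_with_scorer",
    "learn_exact",
    "brute_force_optimum",
    "dp_work_counts",
]

#: maximum total variable count accepted by the exact DP
DEFAULT_VARIABLE_CAP = 25


@dataclass(frozen=True)
class SearchResult:
    """Outcome of an exact search: optimal structure, its full network BDeu
    score, and the instrumented iteration counts of the three DP phases
    (local-score evaluations, best-parent evaluations, sink evaluations)."""

    structure: Structure
    score: float
    work_counts: tuple[int, int, int]


def _bits(mask: int) -> list[int]:
    out = []
    b = 0
    while mask:
        if mask & 1:
            out.append(b)
        mask >>= 1
        b += 1
    return out


def _dp(scorer: BDeuScorer, universe: list[int], fixed_parent: int | None):
    """Core subset DP over the variables in ``universe``.

    ``fixed_parent`` (ANB mode) is a variable outside the universe added to
    every candidate parent set.  Returns (parent set per universe member in
    universe order, dropped-constant score, work counts).
    """
    m = len(universe)
    full = (1 << m) - 1
    extra = () if fixed_parent is None else (fixed_parent,)

    n_local = 0
    n_bp = 0
    # phase 1+2 interleaved per child: local scores then best-parent DP.
    # bp[i][S] = (score, popcount, parent-mask) of the best admissible
    # subset of S; any subset of S is numerically smaller than S, so a
    # plain ascending scan sees completed entries only.
    bp: list[list[tuple[float, int, int] | None]] = []
    for pos in range(m):
        child = universe[pos]
        avail = full & ~(1 << pos)
        table: list[tuple[float, int, int] | None] = [None] * (full + 1)
        for s in range(full + 1):
            if s & ~avail:
                continue
            parents = tuple(universe[b] for b in _bits(s)) + extra
            sc = scorer.local_score(child, parents)
            n_local += 1
            best = (sc, bin(s).count("1"), s)
            for b in _bits(s):
                prev = table[s & ~(1 << b)]
                assert prev is not None
                if (-prev[0], prev[1], prev[2]) < (-best[0], best[1], best[2]):
                    best = prev
            table[s] = best
            n_bp += 1
        bp.append(table)

    # phase 3: best sink per non-empty subset (empty set is the constant 0
    # base case, not an evaluation).
    best_score: list[float] = [0.0] * (full + 1)
    best_sink: list[int] = [-1] * (full + 1)
    n_sink = 0
    for s in range(1, full + 1):
        cand_sink = -1
        cand_score = -np.inf
        for pos in _bits(s):
            rest = s & ~(1 << pos)
            entry = bp[pos][rest]
            assert entry is not None
            total = entry[0] + best_score[rest]
            if total > cand_score:
                cand_score, cand_sink = total, pos
        best_score[s] = cand_score
        best_sink[s] = cand_sink
        n_sink += 1

    parent_sets: dict[int, frozenset[int]] = {}
    s = full
    while s:
        pos = best_sink[s]
        rest = s & ~(1 << pos)
        entry = bp[pos][rest]
        assert entry is not None
        parent_sets[pos] = frozenset(universe[b] for b in _bits(entry[2])) | set(extra)
        s = rest
    return parent_sets, (n_local, n_bp, n_sink)


def exact_search_with_scorer(scorer: BDeuScorer, n_vars: int,
                             class_index: int | None, mode: str,
                             cap: int = DEFAULT_VARIABLE_CAP) -> SearchResult:
    """Run the subset DP against any local-score provider.

    Used with a dataset-backed scorer for learning from data, and with an
    expected-count scorer for population-optimal reference structures.
    """
    if mode not in ("gbn", "anb"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_vars > cap:
        raise ValueError(f"{n_vars} variables exceed the exact-search cap {cap}")
    c = class_index

    if mode == "gbn":
        universe = list(range(n_vars))
        chosen, counts = _dp(scorer, universe, fixed_parent=None)
        parent_sets = tuple(chosen[i] for i in range(n_vars))
    else:
        if c is None:
            raise ValueError("anb mode requires a designated class variable")
        features = [i for i in range(n_vars) if i != c]
        chosen, counts = _dp(scorer, features, fixed_parent=c)
        parent_sets = tuple(
            frozenset() if i == c else chosen[features.index(i)]
            for i in range(n_vars)
        )

    structure = Structure(parent_sets, class_index=c)
    # report the full network score (class marginal included in ANB mode),
    # summed in ascending variable index from the same cached locals.
    score = float(sum(scorer.local_score(i, parent_sets[i])
                      for i in range(n_vars)))
    return SearchResult(structure=structure, score=score, work_counts=counts)


def exact_search(dataset: Dataset, mode: str,
                 params: ScoreParams = ScoreParams(),
                 cap: int = DEFAULT_VARIABLE_CAP) -> SearchResult:
    """Globally score-optimal DAG by the subset DP; see module docstring."""
    scorer = BDeuScorer(dataset, params)
    return exact_search_with_scorer(scorer, dataset.n_vars,
                                    dataset.class_index, mode, cap)


def learn_exact(dataset: Dataset, mode: str,
                params: ScoreParams = ScoreParams(),
                cap: int = DEFAULT_VARIABLE_CAP) -> Structure:
    """Optimal structure only; see :func:`exact_search` for score and counts."""
    return exact_search(dataset, mode, params, cap).structure


def brute_force_optimum(dataset: Dataset, mode: str,
                        params: ScoreParams = ScoreParams()
                        ) -> tuple[Structure, float]:
    """Independent exactness oracle: enumerate every admissible DAG.

    Enumerates all topological orders (permutations) and, for each
    variable, every parent subset drawn from its predecessors; every
    admissible DAG is consistent with at least one order, so the maximum
    over this enumeration is the maximum over all DAGs.  Deliberately free
    of the sink recursion used by the DP.
    """
    if mode not in ("gbn", "anb"):
        raise ValueError(f"unknown mode {mode!r}")
    m = dataset.n_vars
    c = dataset.class_index
    if mode == "gbn":
        if m > 5:
            raise ValueError("gbn brute force capped at 5 variables")
        order_pool = list(range(m))
        extra: tuple[int, ...] = ()
    else:
        if len(dataset.feature_indices) > 5:
            raise ValueError("anb brute force capped at 5 features")
        order_pool = dataset.feature_indices
        extra = (c,)

    scorer = BDeuScorer(dataset, params)
    base = scorer.local_score(c, ()) if mode == "anb" else 0.0

    best_total = -np.inf
    best_assignment: dict[int, frozenset[int]] | None = None
    for perm in permutations(order_pool):
        total = base
        assignment: dict[int, frozenset[int]] = {}
        for t, child in enumerate(perm):
            preds = perm[:t]
            child_best = -np.inf
            child_pa: frozenset[int] = frozenset()
            for mask in range(1 << len(preds)):
                pa = frozenset(preds[b] for b in _bits(mask)) | set(extra)
                sc = scorer.local_score(child, pa)
                if sc > child_best:
                    child_best, child_pa = sc, pa
            total += child_best
            assignment[child] = child_pa
        if total > best_total:
            best_total = total
            best_assignment = assignment
    assert best_assignment is not None

    if mode == "anb":
        best_assignment[c] = frozenset()
    parent_sets = tuple(best_assignment[i] for i in range(m))
    structure = Structure(parent_sets, class_index=c)
    score = float(sum(scorer.local_score(i, parent_sets[i]) for i in range(m)))
    return structure, score


def dp_work_counts(n_features: int, mode: str) -> tuple[int, int, int]:
    """Iteration counts of the three DP phases, measured by instrumented
    table construction on a minimal dataset with ``n_features`` features.

    ANB counts are strictly smaller than GBN counts on the same variable
    set because the class variable never enters the subset lattice.
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    m = n_features + 1
    variables = [VariableSpec(f"X{i}", ("1", "2")) for i in range(m)]
    rng = np.random.default_rng(0)
    rows = rng.integers(1, 3, size=(4, m))
    dataset = Dataset(variables, rows, class_index=0)
    return exact_search(dataset, mode).work_counts
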