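"""BDeu marginal-likelihood scoring and the Bayes-factor statistic.

All scores are natural logarithms.  The local score of a child X_i with
parent set Pa_i (cardinality r, q joint parent configurations, equivalent
sample size N') is

    sum_j [ lnG(N'/q) - lnG(N'/q + N_j) ]
        + sum_j sum_k [ lnG(N'/(r q) + N_jk) - lnG(N'/(r q)) ]

with lnG the log-Gamma function.  The score is 0 for an all-zero table and
is score-equivalent: Markov-equivalent DAGs receive identical network
scores.  The Bayes factor for a zero-or-higher-order conditional
independence test is the difference of two local scores; positive log
values favour independence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.special import gammaln

from .data_io import Dataset, FrequencyTable, build_cft
from .graph import Structure

__all__ = [
    "ScoreParams",
    "bdeu_local_score",
    "BDeuScorer",
    "network_bdeu_score",
    "log_bayes_factor",
]

#: parent sets whose configuration count exceeds this are rejected outright
MAX_PARENT_CONFIGS = 10_000_000


@dataclass(frozen=True)
class ScoreParams:
    """BDeu hyperparameter: the equivalent sample size N' (> 0)."""

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError("equivalent sample size must be positive")


def bdeu_local_score(table: FrequencyTable, params: ScoreParams = ScoreParams()) -> float:
    """Log BDeu local score of a conditional frequency table.

    Accepts fractional (expected) counts; Gamma arguments are real.
    """
    q, r = table.counts.shape
    if q > MAX_PARENT_CONFIGS:
        raise ValueError(f"parent configuration count {q} exceeds {MAX_PARENT_CONFIGS}")
    a_j = params.ess / q
    a_jk = params.ess / (q * r)
    counts = table.counts
    n_j = counts.sum(axis=1)
    term_j = gammaln(a_j) - gammaln(a_j + n_j)
    term_jk = gammaln(a_jk + counts) - gammaln(a_jk)
    return float(term_j.sum() + term_jk.sum())


class BDeuScorer:
    """Local-score provider with a cache keyed by (child, parent set).

    The exact-search DP revisits the same (child, parents) pairs heavily;
    the cache guarantees each table is tallied and scored once.  Counts come
    either from a dataset or from expected counts under a known joint
    distribution (used for population-optimal reference structures).
    """

    def __init__(self, dataset: Dataset, params: ScoreParams = ScoreParams()):
        self.dataset = dataset
        self.params = params
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    @property
    def cardinalities(self) -> np.ndarray:
        return self.dataset.cardinalities

    def table(self, child: int, parents: Iterable[int]) -> FrequencyTable:
        return build_cft(self.dataset, child, tuple(parents))

    def local_score(self, child: int, parents: Iterable[int]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = bdeu_local_score(self.table(child, key[1]), self.params)
        return self._cache[key]


class ExpectedCountScorer(BDeuScorer):
    """BDeu scores from expected counts N_ref * P(child, parents).

    ``joint`` is the exact joint probability array (one axis per variable);
    fractional counts are fine because log-Gamma accepts real arguments.
    """

    def __init__(self, joint: np.ndarray, n_ref: float,
                 params: ScoreParams = ScoreParams()):
        self.joint = np.asarray(joint, dtype=np.float64)
        self.n_ref = float(n_ref)
        self.params = params
        self._cache = {}

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array(self.joint.shape, dtype=np.int64)

    def table(self, child: int, parents: Iterable[int]) -> FrequencyTable:
        parents = tuple(sorted(parents))
        if child in parents:
            raise ValueError("child variable cannot be its own parent")
        keep = parents + (child,)
        drop = tuple(i for i in range(self.joint.ndim) if i not in keep)
        marg = self.joint.sum(axis=drop) if drop else self.joint
        # axes of marg follow ascending variable index; reorder to parents+child
        order = [sorted(keep).index(v) for v in keep]
        marg = np.transpose(marg, order)
        r = self.joint.shape[child]
        counts = (self.n_ref * marg).reshape(-1, r)
        return FrequencyTable(child=child, parents=parents,
                              counts=counts, cardinality=r)


def network_bdeu_score(dataset: Dataset, dag: Structure,
                       params: ScoreParams = ScoreParams(),
                       scorer: BDeuScorer | None = None) -> float:
    """Sum of BDeu local scores over all variables of the DAG.

    Local scores are summed in ascending variable index so the same floats
    always combine in the same order.
    """
    if scorer is None:
        scorer = BDeuScorer(dataset, params)
    if dag.n_vars != scorer.cardinalities.size:
        raise ValueError("structure and dataset have different variable counts")
    return float(sum(scorer.local_score(i, dag.parent_sets[i])
                     for i in range(dag.n_vars)))


def log_bayes_factor(dataset: Dataset, x: int, y: int, z: Iterable[int] = (),
                     params: ScoreParams = ScoreParams()) -> float:
    """log BF(X, Y | Z) = Score(CFT(X, Z)) - Score(CFT(X, Z u {Y})).

    Positive values favour the conditional independence of X and Y given Z;
    the decision rule declares independence when BF exceeds a threshold
    delta, i.e. when the log Bayes factor exceeds ln(delta).
    """
    z = tuple(sorted(z))
    if x == y or x in z or y in z:
        raise ValueError("x, y and z must not overlap")
    s_without = bdeu_local_score(build_cft(dataset, x, z), params)
    s_with = bdeu_local_score(build_cft(dataset, x, tuple(sorted(z + (y,)))), params)
    return s_without - s_with
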