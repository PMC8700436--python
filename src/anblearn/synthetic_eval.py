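"""Generative sampling, random-network fixtures, and evaluation protocols.

Covers the asymptotic-recovery protocol (structural Hamming distance to the
population-optimal augmented-naive-Bayes structure, and Kullback-Leibler
divergence between class posteriors as the sample size grows) and the
k-fold cross-validated accuracy harness, plus everything needed to run the
whole stack without external data: ancestral sampling from a known network
and seeded random discrete networks with known CPTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import (NetworkModel, PriorSpec, accuracy, class_posterior,
                         fit_eap, naive_bayes_structure)
from .data_io import Dataset, VariableSpec
from .exact_search import exact_search_with_scorer, learn_exact
from .feature_selection import SelectionConfig, fit_fsanb
from .graph import Structure, shd
from .scoring import ExpectedCountScorer, ScoreParams

__all__ = [
    "EvalReport",
    "forward_sample",
    "random_discrete_network",
    "class_posterior_kld",
    "reference_optimal_anb",
    "asymptotic_eval",
    "cross_validate_accuracy",
]

#: refuse exact enumeration beyond this many feature configurations
MAX_ENUM_CONFIGS = 1 << 20

#: pseudo sample size behind population-optimal reference structures
REFERENCE_SAMPLE_SIZE = 1e6


@dataclass
class EvalReport:
    """Asymptotic-recovery results: one SHD and one class-posterior KLD per
    sample size."""

    sizes: tuple[int, ...]
    shd: tuple[int, ...]
    kld: tuple[float, ...]
    seed: int


def forward_sample(network: NetworkModel, n: int, seed: int) -> Dataset:
    """Ancestral sampling: n i.i.d. rows in topological order."""
    if n < 0:
        raise ValueError("sample size must be non-negative")
    network.validate(atol=1e-6)
    order = network.structure.topological_order()
    assert order is not None
    rng = np.random.default_rng(seed)
    m = network.n_vars
    rows = np.zeros((n, m), dtype=np.int64)
    for i in order:
        pa = sorted(network.structure.parent_sets[i])
        j = np.zeros(n, dtype=np.int64)
        for p in pa:
            j = j * network.variables[p].cardinality + (rows[:, p] - 1)
        probs = network.cpts[i][j]            # (n, r_i)
        u = rng.random(n)
        rows[:, i] = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1) + 1
        np.clip(rows[:, i], 1, network.variables[i].cardinality, out=rows[:, i])
    ci = network.class_index if network.class_index is not None else 0
    return Dataset(list(network.variables), rows, class_index=ci)


def _separated_cpt(rng: np.random.Generator, q: int, r: int, pa_cards: list[int],
                   min_parent_effect: float, alpha: float) -> np.ndarray:
    """Dirichlet CPT rows, resampled until every parent has a visible effect.

    For each parent and each configuration of the remaining parents, the
    conditional rows across that parent's states must differ by at least
    ``min_parent_effect`` in total variation.  Keeps fixtures strictly
    faithful so that population-optimal structures are identifiable.
    """
    for _ in range(1000):
        cpt = rng.dirichlet(np.full(r, alpha), size=q)
        if not pa_cards or min_parent_effect <= 0:
            return cpt
        shaped = cpt.reshape(pa_cards + [r])
        ok = True
        for axis in range(len(pa_cards)):
            moved = np.moveaxis(shaped, axis, 0).reshape(pa_cards[axis], -1, r)
            for a in range(pa_cards[axis]):
                for b in range(a + 1, pa_cards[axis]):
                    tv = 0.5 * np.abs(moved[a] - moved[b]).sum(axis=1)
                    if tv.min() < min_parent_effect:
                        ok = False
            if not ok:
                break
        if ok:
            return cpt
    raise RuntimeError("could not sample a CPT with the requested parent effect")


def random_discrete_network(n_vars: int, max_parents: int,
                            cardinalities: Sequence[int] | int = 2,
                            seed: int = 0, anb_like: bool = False,
                            min_parent_effect: float = 0.1,
                            alpha: float = 1.0) -> NetworkModel:
    """Seeded random DAG with Dirichlet CPT rows.

    With ``anb_like`` the variable X0 is a parentless class adjacent to
    every feature and ``max_parents`` bounds the extra feature-feature
    parents, producing networks whose Markov blanket of X0 contains all
    features with each adjacent to X0 (the regime in which exact ANB
    learning is asymptotically classification-equivalent to the truth).
    """
    if n_vars < 2:
        raise ValueError("need at least two variables")
    if max_parents < 0:
        raise ValueError("max_parents must be non-negative")
    cards = ([int(cardinalities)] * n_vars if np.isscalar(cardinalities)
             else [int(c) for c in cardinalities])
    if len(cards) != n_vars:
        raise ValueError("cardinality list length mismatch")
    rng = np.random.default_rng(seed)

    if anb_like:
        feature_order = list(rng.permutation(np.arange(1, n_vars)))
        parent_sets: list[frozenset[int]] = [frozenset()] * n_vars
        for t, i in enumerate(feature_order):
            pool = feature_order[:t]
            k = int(rng.integers(0, min(max_parents, len(pool)) + 1))
            extra = rng.choice(pool, size=k, replace=False) if k else []
            parent_sets[i] = frozenset({0} | {int(p) for p in extra})
        class_index = 0
    else:
        order = list(rng.permutation(n_vars))
        parent_sets = [frozenset()] * n_vars
        for t, i in enumerate(order):
            pool = order[:t]
            k = int(rng.integers(0, min(max_parents, len(pool)) + 1))
            extra = rng.choice(pool, size=k, replace=False) if k else []
            parent_sets[i] = frozenset(int(p) for p in extra)
        class_index = None

    variables = [VariableSpec(f"X{i}", tuple(str(s + 1) for s in range(cards[i])))
                 for i in range(n_vars)]
    cpts = []
    for i in range(n_vars):
        pa = sorted(parent_sets[i])
        pa_cards = [cards[p] for p in pa]
        q = int(np.prod(pa_cards)) if pa_cards else 1
        cpts.append(_separated_cpt(rng, q, cards[i], pa_cards,
                                   min_parent_effect, alpha))
    structure = Structure(tuple(parent_sets), class_index=class_index)
    model = NetworkModel(structure=structure, variables=variables, cpts=cpts)
    model.validate(atol=1e-9)
    return model


def _feature_configs(network: NetworkModel, class_index: int):
    cards = network.cardinalities
    features = [i for i in range(network.n_vars) if i != class_index]
    total = int(np.prod([cards[f] for f in features])) if features else 1
    if total > MAX_ENUM_CONFIGS:
        raise ValueError(f"{total} feature configurations exceed the "
                         f"enumeration cap {MAX_ENUM_CONFIGS}")
    dims = [int(cards[f]) for f in features]
    for flat in range(total):
        digits = np.unravel_index(flat, dims) if dims else ()
        x = np.zeros(network.n_vars, dtype=np.int64)
        for f, d in zip(features, digits):
            x[f] = d + 1
        yield x


def class_posterior_kld(model_a: NetworkModel, model_b: NetworkModel,
                        reference: NetworkModel) -> float:
    """Expected KL divergence of class posteriors, sum_x P_ref(x) KL(b || a).

    ``model_b`` plays the role of the true-structure model, ``model_a`` the
    learned one; ``x`` runs over every feature configuration, weighted by
    the reference network's exact feature marginal.
    """
    names = [v.name for v in reference.variables]
    for m in (model_a, model_b):
        if [v.name for v in m.variables] != names:
            raise ValueError("models and reference are over different variables")
        if m.class_index != model_a.class_index:
            raise ValueError("models disagree on the class variable")
    c = model_a.class_index
    if c is None:
        raise ValueError("models have no designated class variable")

    feature_axes = tuple(i for i in range(reference.n_vars) if i != c)
    feature_marginal = reference.joint_table().sum(axis=c)
    kld = 0.0
    for x in _feature_configs(reference, c):
        idx = tuple(int(x[i]) - 1 for i in feature_axes)
        w = float(feature_marginal[idx])
        if w == 0.0:
            continue
        p_a = class_posterior(model_a, x)
        p_b = class_posterior(model_b, x)
        kld += w * float(np.sum(p_b * (np.log(p_b) - np.log(p_a))))
    # identical posteriors can round to a tiny negative total
    return 0.0 if -1e-12 < kld < 0.0 else kld


def reference_optimal_anb(network: NetworkModel, class_index: int | None = None,
                          params: ScoreParams = ScoreParams(),
                          n_ref: float = REFERENCE_SAMPLE_SIZE) -> Structure:
    """Population-optimal ANB structure of a known network.

    Runs the exact ANB search on expected counts n_ref * P(config) under
    the network's exact joint (log-Gamma accepts fractional counts), which
    removes sampling noise: the result is the I-map with the fewest
    parameters among all ANB structures whenever the distribution is
    faithful to its DAG.
    """
    ci = network.class_index if class_index is None else class_index
    if ci is None:
        raise ValueError("a class variable is required")
    if network.n_vars > 12:
        raise ValueError("reference search capped at 12 variables")
    scorer = ExpectedCountScorer(network.joint_table(), n_ref, params)
    return exact_search_with_scorer(scorer, network.n_vars, ci, "anb").structure


def asymptotic_eval(network: NetworkModel, sizes: Sequence[int], seed: int,
                    class_index: int | None = None,
                    params: ScoreParams = ScoreParams()) -> EvalReport:
    """Sample, exact-ANB learn, and score SHD/KLD at each sample size.

    SHD is taken against the population-optimal ANB of the generating
    network; KLD compares the learned model's class posterior with that of
    the true structure EAP-fitted on the same sample.
    """
    ci = network.class_index if class_index is None else class_index
    if ci is None:
        raise ValueError("a class variable is required")
    sizes = tuple(int(s) for s in sizes)
    if not sizes:
        return EvalReport(sizes=(), shd=(), kld=(), seed=seed)
    reference = reference_optimal_anb(network, ci, params)
    true_structure = network.structure.with_class(ci)
    rng = np.random.default_rng(seed)
    shds, klds = [], []
    for n in sizes:
        sample = forward_sample(network, n, int(rng.integers(0, 2**31 - 1)))
        sample.class_index = ci
        learned = learn_exact(sample, "anb", params)
        shds.append(shd(learned, reference))
        model_a = fit_eap(sample, learned, PriorSpec())
        model_b = fit_eap(sample, true_structure, PriorSpec())
        klds.append(class_posterior_kld(model_a, model_b, network))
    return EvalReport(sizes=sizes, shd=tuple(shds), kld=tuple(klds), seed=seed)


def cross_validate_accuracy(dataset: Dataset, method: str, folds: int,
                            seed: int, params: ScoreParams = ScoreParams(),
                            config: SelectionConfig | None = None) -> float:
    """Mean held-out accuracy over a seeded k-fold split.

    ``method`` is one of nb (naive Bayes), gbn, anb (exact searches), or
    fsanb (feature selection + exact ANB, tuning nested inside each
    training fold).  Fold sizes differ by at most one row.
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    if dataset.n_rows < folds:
        raise ValueError("more folds than rows")
    if method not in ("nb", "gbn", "anb", "fsanb"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.n_rows)
    parts = np.array_split(order, folds)
    accs = []
    for k in range(folds):
        train = dataset.subset_rows(np.concatenate(
            [parts[j] for j in range(folds) if j != k]))
        test = dataset.subset_rows(parts[k])
        if method == "fsanb":
            cfg = config if config is not None else SelectionConfig(seed=seed)
            model, selection = fit_fsanb(train, cfg)
            columns = sorted((train.class_index,) + selection.kept)
            accs.append(accuracy(model, test.select_variables(columns)))
            continue
        if method == "nb":
            structure = naive_bayes_structure(train)
        else:
            structure = learn_exact(train, method, params)
        model = fit_eap(train, structure, PriorSpec())
        accs.append(accuracy(model, test))
    return float(np.mean(accs))
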