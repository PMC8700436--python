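"""Bayes-factor feature selection and the fsANB-BDeu pipeline.

The PC (parent-child) search tests each feature against the class with a
zero-order Bayes factor only — n tests, no conditioning sets — and removes
a feature when the factor favours independence beyond a threshold delta.
Under Assumption that every Markov-blanket member is adjacent to the class,
the surviving features are a redundant superset of the class's Markov
blanket, which is the safe side: missing variables hurt classification more
than extra ones.

The equivalent sample size N' (shared between the Bayes factor and the
structure score) and delta are tuned on a grid (default N' in {1, 2, 5},
delta in {3, 20, 150}) by two-fold cross-validated accuracy of the whole
pipeline: select, exact-ANB learn, EAP fit, classify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classifier import NetworkModel, PriorSpec, accuracy, fit_eap
from .data_io import Dataset
from .exact_search import DEFAULT_VARIABLE_CAP, learn_exact
from .graph import Structure
from .scoring import ScoreParams, log_bayes_factor

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "bf_pc_select",
    "tune_hyperparameters",
    "fit_fsanb",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning grid and fold seed for the fsANB pipeline."""

    ess_grid: tuple[float, ...] = (1.0, 2.0, 5.0)
    delta_grid: tuple[float, ...] = (3.0, 20.0, 150.0)
    cv_folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ess_grid or not self.delta_grid:
            raise ValueError("tuning grids must be non-empty")
        if any(d <= 0 for d in self.delta_grid):
            raise ValueError("Bayes-factor thresholds must be positive")


@dataclass
class SelectionResult:
    """Outcome of the PC search: kept/removed features (dataset variable
    indices) and the per-feature log Bayes factor against the class."""

    kept: tuple[int, ...]
    removed: tuple[int, ...]
    log_bf: dict[int, float]
    ess: float
    delta: float


def bf_pc_select(dataset: Dataset, params: ScoreParams = ScoreParams(),
                 delta: float = 20.0) -> SelectionResult:
    """Zero-order Bayes-factor PC search around the class variable.

    Feature X_i is removed iff log BF(X0, X_i | {}) > ln(delta), i.e. the
    marginal likelihood favours independence by more than the threshold.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    c = dataset.class_index
    log_delta = math.log(delta)
    kept, removed, log_bf = [], [], {}
    for i in dataset.feature_indices:
        lbf = log_bayes_factor(dataset, c, i, (), params)
        log_bf[i] = lbf
        (removed if lbf > log_delta else kept).append(i)
    return SelectionResult(kept=tuple(kept), removed=tuple(removed),
                           log_bf=log_bf, ess=params.ess, delta=delta)


def _class_only_structure(dataset: Dataset) -> Structure:
    c = dataset.class_index
    return Structure(tuple(frozenset() for _ in range(dataset.n_vars)),
                     class_index=c)


def _pipeline_model(train: Dataset, ess: float, delta: float,
                    cap: int = DEFAULT_VARIABLE_CAP
                    ) -> tuple[NetworkModel, SelectionResult, list[int]]:
    """Select features, exact-learn the ANB on the kept set, fit EAP.

    Returns the fitted model, the selection, and the column subset (class
    included, ascending) the model is defined over.  With every feature
    removed, the model degenerates to the class-marginal classifier.
    """
    params = ScoreParams(ess)
    selection = bf_pc_select(train, params, delta)
    columns = sorted((train.class_index,) + selection.kept)
    sub = train.select_variables(columns)
    if selection.kept:
        structure = learn_exact(sub, "anb", params, cap=cap)
    else:
        structure = _class_only_structure(sub)
    model = fit_eap(sub, structure, PriorSpec())
    return model, selection, columns


def tune_hyperparameters(dataset: Dataset, config: SelectionConfig = SelectionConfig()
                         ) -> tuple[float, float]:
    """Grid-search (N', delta) by cross-validated pipeline accuracy.

    Folds come from a seeded unstratified shuffle.  Ties prefer the smaller
    N', then the smaller delta (weaker prior, more inclusive selection).
    """
    n = dataset.n_rows
    if n < config.cv_folds:
        raise ValueError("fewer rows than folds")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, config.cv_folds)

    best: tuple[float, float] | None = None
    best_acc = -np.inf
    for ess in sorted(config.ess_grid):
        for delta in sorted(config.delta_grid):
            accs = []
            for k in range(config.cv_folds):
                test_idx = folds[k]
                train_idx = np.concatenate([folds[j] for j in range(config.cv_folds)
                                            if j != k])
                model, _, columns = _pipeline_model(
                    dataset.subset_rows(train_idx), ess, delta)
                test = dataset.subset_rows(test_idx).select_variables(columns)
                accs.append(accuracy(model, test))
            mean_acc = float(np.mean(accs))
            if mean_acc > best_acc:
                best_acc, best = mean_acc, (ess, delta)
    assert best is not None
    return best


def fit_fsanb(dataset: Dataset, config: SelectionConfig = SelectionConfig()
              ) -> tuple[NetworkModel, SelectionResult]:
    """The fsANB-BDeu pipeline: tune (N', delta), select, exact ANB, EAP.

    The returned model is defined over the class plus the kept features
    (other columns dropped); with an empty kept set it is the prior-only
    class-marginal classifier.
    """
    ess, delta = tune_hyperparameters(dataset, config)
    model, selection, _ = _pipeline_model(dataset, ess, delta)
    return model, selection
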