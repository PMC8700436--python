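"""EAP parameterization of a fixed structure and class-posterior inference.

The expected-a-posteriori estimate of a conditional probability parameter
under a Dirichlet prior with pseudo-counts N'_ijk is

    theta_ijk = (N'_ijk + N_ijk) / (N'_ij + N_j),       N'_ij = sum_k N'_ijk.

The default prior is the BDeu-consistent choice N'_ijk = N'/(r_i q_Pai)
with N' = 1, under which Markov-equivalent structures fitted on the same
data define identical predictive joints, hence identical class posteriors
(classification equivalence).

Classification multiplies, for a candidate class value c, the class factor
and the factors of every child of the class given its parent configuration,
then normalizes; variables outside the Markov blanket of X0 cancel and
never affect the result.  Accumulation is in log space with log-sum-exp
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_io import Dataset, build_cft
from .graph import Structure, markov_blanket

__all__ = [
    "PriorSpec",
    "NetworkModel",
    "fit_eap",
    "class_posterior",
    "predict",
    "predict_dataset",
    "accuracy",
    "naive_bayes_structure",
]


@dataclass(frozen=True)
class PriorSpec:
    """EAP prior: pseudo-counts N'_ijk = ess / (r_i * q_Pai), ess > 0.

    ess = 1 is the uniform-joint prior 1/(r_i q_Pai); it coincides with the
    BDeu score's hyperparameters, which is what makes EAP-fitted
    Markov-equivalent structures classification-equivalent.
    """

    ess: float = 1.0

    def __post_init__(self) -> None:
        if not self.ess > 0:
            raise ValueError("prior equivalent sample size must be positive")


@dataclass
class NetworkModel:
    """A Bayesian network: DAG plus one CPT per variable.

    ``cpts[i]`` has shape (q_Pai, r_i) with parent configurations in the
    package's mixed-radix order (ascending parent index, last fastest).
    Doubles as a generative ground truth and as a fitted classifier.
    """

    structure: Structure
    variables: list
    cpts: list[np.ndarray]
    prior_spec: PriorSpec | None = None

    def __post_init__(self) -> None:
        self.cpts = [np.asarray(c, dtype=np.float64) for c in self.cpts]

    @property
    def n_vars(self) -> int:
        return self.structure.n_vars

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([v.cardinality for v in self.variables], dtype=np.int64)

    @property
    def class_index(self) -> int | None:
        return self.structure.class_index

    def validate(self, atol: float = 1e-9) -> None:
        cards = self.cardinalities
        for i in range(self.n_vars):
            q = int(np.prod([cards[p] for p in sorted(self.structure.parent_sets[i])],
                            dtype=np.int64)) if self.structure.parent_sets[i] else 1
            if self.cpts[i].shape != (q, cards[i]):
                raise ValueError(
                    f"CPT of {self.variables[i].name} has shape "
                    f"{self.cpts[i].shape}, expected {(q, int(cards[i]))}")
            rows = self.cpts[i].sum(axis=1)
            if np.abs(rows - 1.0).max() > atol:
                raise ValueError(
                    f"CPT rows of {self.variables[i].name} do not sum to 1")

    def parent_config(self, i: int, assignment: np.ndarray) -> int:
        """Mixed-radix row index of variable i's parents in a full (or
        partial, 0 = missing) 1-based assignment vector."""
        j = 0
        for p in sorted(self.structure.parent_sets[i]):
            state = int(assignment[p])
            if state < 1:
                raise ValueError(
                    f"missing value for {self.variables[p].name}, required "
                    f"as a parent of {self.variables[i].name}")
            j = j * self.variables[p].cardinality + (state - 1)
        return j

    def joint_table(self) -> np.ndarray:
        """Exact joint probability array, one axis per variable.

        Feasible for small networks only (product of cardinalities).
        """
        cards = self.cardinalities
        joint = np.ones(tuple(int(r) for r in cards), dtype=np.float64)
        for i in range(self.n_vars):
            pa = sorted(self.structure.parent_sets[i])
            dims = [int(cards[p]) for p in pa] + [int(cards[i])]
            factor = self.cpts[i].reshape(dims)
            # move axes into full-array positions pa + (i,)
            order = pa + [i]
            expand = [slice(None) if v in order else np.newaxis
                      for v in range(self.n_vars)]
            perm = np.argsort(order)  # ascending variable index
            joint = joint * np.transpose(factor, perm)[tuple(expand)]
        return joint


def fit_eap(dataset: Dataset, structure: Structure,
            prior: PriorSpec = PriorSpec()) -> NetworkModel:
    """EAP-fit every CPT of ``structure`` on ``dataset``.

    Rows sum to 1 by construction; unseen parent configurations fall back
    to the prior-only (uniform) estimate, which is exactly what the EAP
    formula yields at zero counts.
    """
    if structure.n_vars != dataset.n_vars:
        raise ValueError("structure and dataset have different variable counts")
    cpts = []
    for i in range(dataset.n_vars):
        table = build_cft(dataset, i, tuple(structure.parent_sets[i]))
        q, r = table.counts.shape
        a_jk = prior.ess / (q * r)
        a_j = prior.ess / q
        theta = (a_jk + table.counts) / (a_j + table.marginals)[:, None]
        cpts.append(theta)
    model = NetworkModel(structure=structure, variables=list(dataset.variables),
                         cpts=cpts, prior_spec=prior)
    model.validate(atol=1e-9)
    return model


def class_posterior(model: NetworkModel, x) -> np.ndarray:
    """Posterior probability vector over class values given features.

    ``x`` is a 1-based assignment over all variables (the class entry is
    ignored; 0 marks a missing value, allowed only outside the Markov
    blanket of the class variable).
    """
    c = model.class_index
    if c is None:
        raise ValueError("model has no designated class variable")
    x = np.asarray(x, dtype=np.int64).copy()
    mb = markov_blanket(model.structure, c)
    for v in sorted(mb):
        if x[v] < 1:
            raise ValueError(
                f"missing value for Markov-blanket variable {model.variables[v].name}")
    r0 = model.variables[c].cardinality
    children = sorted(model.structure.children(c))
    log_post = np.empty(r0, dtype=np.float64)
    for k in range(r0):
        x[c] = k + 1
        lp = np.log(model.cpts[c][model.parent_config(c, x), k])
        for ch in children:
            j = model.parent_config(ch, x)
            lp += np.log(model.cpts[ch][j, int(x[ch]) - 1])
        log_post[k] = lp
    return np.exp(log_post - logsumexp(log_post))


def predict(model: NetworkModel, x) -> int:
    """Most probable class (1-based); ties go to the lowest class index."""
    return int(np.argmax(class_posterior(model, x))) + 1


def predict_dataset(model: NetworkModel, dataset: Dataset) -> np.ndarray:
    """Predicted 1-based class codes for every row of ``dataset``."""
    if [v.name for v in model.variables] != [v.name for v in dataset.variables]:
        raise ValueError("model and dataset variables differ")
    return np.array([predict(model, row) for row in dataset.rows], dtype=np.int64)


def accuracy(model: NetworkModel, dataset: Dataset) -> float:
    """Fraction of rows whose class is predicted correctly."""
    if dataset.n_rows == 0:
        raise ValueError("cannot score an empty dataset")
    pred = predict_dataset(model, dataset)
    return float(np.mean(pred == dataset.rows[:, dataset.class_index]))


def naive_bayes_structure(dataset: Dataset) -> Structure:
    """X0 -> X_i for every feature and nothing else."""
    c = dataset.class_index
    return Structure(
        tuple(frozenset() if i == c else frozenset({c})
              for i in range(dataset.n_vars)),
        class_index=c,
    )
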