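"""Dataset ingestion, preprocessing, frequency tables, and network file formats.

Discrete datasets are held as integer state matrices with 1-based state codes
(state ``k`` of variable ``X_i`` ranges over ``1..r_i``, following the usual
Bayesian-network notation).  Continuous columns are binarized at the sample
median; rows containing the missing marker ``"?"`` (or an empty cell) are
dropped before anything else.

Parent configurations of a conditional frequency table are enumerated in a
fixed mixed-radix order with the *last* parent (highest variable index)
varying fastest, i.e. C-order over the parents sorted by variable index.
Every score table, CPT row ordering and file format in the package uses this
same enumeration.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_MARKER = "?"

__all__ = [
    "MISSING_MARKER",
    "VariableSpec",
    "Dataset",
    "FrequencyTable",
    "load_dataset",
    "discretize_median",
    "build_cft",
    "parent_config_index",
    "read_network",
    "write_network",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class VariableSpec:
    """A discrete variable: name plus its ordered state labels.

    States are externally indexed 1..r_i in the order given here.
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(
                f"variable {self.name!r} has cardinality {len(self.states)} < 2"
            )
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)


@dataclass
class Dataset:
    """A complete discrete dataset of N i.i.d. rows with a designated class.

    ``rows`` is an ``(N, n_vars)`` integer matrix of 1-based state codes;
    column ``class_index`` is the class variable X0.
    """

    variables: list[VariableSpec]
    rows: np.ndarray
    class_index: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64).reshape(-1, len(self.variables))
        if not 0 <= self.class_index < len(self.variables):
            raise ValueError(f"class_index {self.class_index} out of range")
        for i, v in enumerate(self.variables):
            col = self.rows[:, i]
            if col.size and (col.min() < 1 or col.max() > v.cardinality):
                raise ValueError(f"state codes of {v.name!r} outside 1..{v.cardinality}")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def feature_indices(self) -> list[int]:
        return [i for i in range(self.n_vars) if i != self.class_index]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([v.cardinality for v in self.variables], dtype=np.int64)

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "Dataset":
        return Dataset(self.variables, self.rows[np.asarray(index, dtype=np.int64)],
                       self.class_index)

    def select_variables(self, keep: Sequence[int]) -> "Dataset":
        """Column subset; ``keep`` must contain the class variable."""
        keep = list(keep)
        if self.class_index not in keep:
            raise ValueError("selected variable set must contain the class variable")
        return Dataset([self.variables[i] for i in keep], self.rows[:, keep],
                       keep.index(self.class_index))


@dataclass
class FrequencyTable:
    """Counts N_ijk of a child given a parent set (a CFT), or a joint table.

    ``counts[j, k]`` is the number of rows with the child in state k+1 while
    the parents are in joint configuration j (mixed-radix, last parent
    fastest); ``marginals[j]`` is N_j.  An empty parent set gives q = 1.
    Counts may be fractional (expected counts under a known distribution).
    """

    child: int
    parents: tuple[int, ...]
    counts: np.ndarray
    cardinality: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.cardinality:
            raise ValueError("counts must be a q x r matrix")

    @property
    def q(self) -> int:
        return self.counts.shape[0]

    @property
    def marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> float:
        return float(self.counts.sum())


def discretize_median(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Binarize a numeric vector at its sample median.

    Values ≤ median go to state 1, the rest to state 2.  The cutoff uses the
    whole column (before any train/test split).  A constant column is
    rejected since it would produce a single-state variable.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if np.isnan(arr).any():
        raise ValueError("missing values must be removed before discretization")
    cutoff = float(np.median(arr))
    out = np.where(arr <= cutoff, 1, 2).astype(np.int64)
    if (out == 1).all() or (out == 2).all():
        raise ValueError("constant column: median binarization yields cardinality 1")
    return out


def load_dataset(
    path: str | Path,
    class_name: str,
    continuous_columns: Sequence[str] = (),
) -> Dataset:
    """Read a CSV (header row) into a :class:`Dataset`.

    Rows containing the missing marker are dropped first; the listed
    continuous columns are then median-binarized; all remaining columns are
    treated as categorical with states sorted lexicographically.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    if class_name not in df.columns:
        raise ValueError(f"unknown class column {class_name!r}")
    unknown = set(continuous_columns) - set(df.columns)
    if unknown:
        raise ValueError(f"unknown continuous columns {sorted(unknown)}")
    if len(df) == 0:
        raise ValueError("empty dataset")
    missing = (df == MISSING_MARKER) | (df == "")
    df = df.loc[~missing.any(axis=1)]
    if len(df) == 0:
        raise ValueError("empty dataset after removing rows with missing values")

    variables: list[VariableSpec] = []
    columns = []
    for name in df.columns:
        col = df[name]
        if name in continuous_columns:
            codes = discretize_median(col.astype(float).to_numpy())
            states = ("low", "high")
        else:
            states = tuple(sorted(col.unique()))
            if len(states) < 2:
                raise ValueError(
                    f"column {name!r} has a single observed state; cardinality < 2"
                )
            lookup = {s: k + 1 for k, s in enumerate(states)}
            codes = col.map(lookup).to_numpy(dtype=np.int64)
        variables.append(VariableSpec(name, states))
        columns.append(codes)
    rows = np.column_stack(columns)
    return Dataset(variables, rows, class_index=list(df.columns).index(class_name))


def parent_config_index(rows: np.ndarray, parents: Sequence[int],
                        cards: np.ndarray) -> tuple[np.ndarray, int]:
    """Mixed-radix joint configuration index of each row's parent values.

    Parents are taken in ascending variable index; the last one varies
    fastest.  Returns (0-based config index per row, q).
    """
    parents = sorted(parents)
    if not parents:
        return np.zeros(rows.shape[0], dtype=np.int64), 1
    dims = [int(cards[p]) for p in parents]
    idx = np.zeros(rows.shape[0], dtype=np.int64)
    for p, r in zip(parents, dims):
        idx = idx * r + (rows[:, p] - 1)
    q = int(np.prod(dims))
    return idx, q


def build_cft(dataset: Dataset, child: int, parents: Sequence[int]) -> FrequencyTable:
    """Tally the conditional frequency table CFT(X_child, parents)."""
    parents = tuple(sorted(parents))
    if child in parents:
        raise ValueError("child variable cannot be its own parent")
    cards = dataset.cardinalities
    r = int(cards[child])
    j, q = parent_config_index(dataset.rows, parents, cards)
    flat = j * r + (dataset.rows[:, child] - 1)
    counts = np.bincount(flat, minlength=q * r).reshape(q, r).astype(np.float64)
    return FrequencyTable(child=child, parents=parents, counts=counts, cardinality=r)


# --------------------------------------------------------------------------
# Network file formats: BIF (bnlearn-compatible subset), JSON dialect,
# edge-list text.  NetworkModel lives in the classifier module; imported
# lazily to keep module layering acyclic.
# --------------------------------------------------------------------------

_BIF_VARIABLE = re.compile(
    r"variable\s+(\S+)\s*\{[^}]*?type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}",
    re.S,
)
_BIF_PROBABILITY = re.compile(r"probability\s*\(([^)]*)\)\s*\{(.*?)\}", re.S)


def _parse_bif(text: str):
    variables: dict[str, tuple[str, ...]] = {}
    for m in _BIF_VARIABLE.finditer(text):
        name, card, states = m.group(1), int(m.group(2)), m.group(3)
        labels = tuple(s.strip() for s in states.split(",") if s.strip())
        if len(labels) != card:
            raise ValueError(f"variable {name}: {len(labels)} states, declared {card}")
        variables[name] = labels

    tables: dict[str, tuple[list[str], dict[tuple[str, ...], list[float]]]] = {}
    for m in _BIF_PROBABILITY.finditer(text):
        head, body = m.group(1), m.group(2)
        if "|" in head:
            child_part, parent_part = head.split("|")
            parents = [p.strip() for p in parent_part.split(",")]
        else:
            child_part, parents = head, []
        child = child_part.strip()
        rows: dict[tuple[str, ...], list[float]] = {}
        for line in body.split(";"):
            line = line.strip()
            if not line:
                continue
            if line.startswith("table"):
                rows[()] = [float(v) for v in line[len("table"):].split(",")]
            else:
                cm = re.match(r"\(([^)]*)\)\s*(.*)", line)
                if cm is None:
                    raise ValueError(f"unparseable probability row: {line!r}")
                config = tuple(s.strip() for s in cm.group(1).split(","))
                rows[config] = [float(v) for v in cm.group(2).split(",")]
        tables[child] = (parents, rows)
    return variables, tables


def read_network(path: str | Path):
    """Read a network (structure + CPTs) from BIF or the JSON dialect.

    Returns a :class:`anblearn.classifier.NetworkModel`.  CPT rows must each
    sum to 1 within 1e-6 and the structure must be acyclic.
    """
    from .classifier import NetworkModel
    from .graph import Structure

    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json" or text.lstrip().startswith("{"):
        return _network_from_json(json.loads(text))

    var_states, tables = _parse_bif(text)
    names = list(var_states)
    index = {n: i for i, n in enumerate(names)}
    variables = [VariableSpec(n, var_states[n]) for n in names]

    parent_sets: list[frozenset[int]] = []
    cpts: list[np.ndarray] = []
    for name in names:
        if name not in tables:
            raise ValueError(f"no probability block for variable {name}")
        parent_names, rows = tables[name]
        pa = frozenset(index[p] for p in parent_names)
        # rows keyed by parent state labels in the order listed in the block;
        # re-enumerate in ascending-variable-index, last-fastest order.
        pa_sorted = sorted(pa)
        dims = [variables[p].cardinality for p in pa_sorted]
        q = int(np.prod(dims)) if dims else 1
        r = variables[index[name]].cardinality
        cpt = np.empty((q, r), dtype=np.float64)
        listed_order = [index[p] for p in parent_names]
        for config, values in rows.items():
            if len(values) != r:
                raise ValueError(f"CPT row for {name} has {len(values)} entries, need {r}")
            j = 0
            states_by_var = dict(zip(listed_order, config))
            for p in pa_sorted:
                label = states_by_var[p]
                if label not in variables[p].states:
                    raise ValueError(f"unknown state {label!r} of parent of {name}")
                j = j * variables[p].cardinality + variables[p].states.index(label)
            cpt[j] = values
        if len(rows) != q:
            raise ValueError(f"CPT for {name}: {len(rows)} rows, expected {q}")
        parent_sets.append(pa)
        cpts.append(cpt)

    structure = Structure(tuple(parent_sets))
    model = NetworkModel(structure=structure, variables=variables, cpts=cpts)
    model.validate(atol=1e-6)
    return model


def _network_from_json(obj: dict):
    from .classifier import NetworkModel
    from .graph import Structure

    nodes = obj["nodes"]
    names = [n["name"] for n in nodes]
    index = {n: i for i, n in enumerate(names)}
    variables = [VariableSpec(n["name"], tuple(n["states"])) for n in nodes]
    parent_sets = tuple(frozenset(index[p] for p in n["parents"]) for n in nodes)
    cpts = [np.asarray(n["cpt"], dtype=np.float64) for n in nodes]
    class_index = index[obj["class"]] if obj.get("class") is not None else None
    structure = Structure(parent_sets, class_index=class_index)
    model = NetworkModel(structure=structure, variables=variables, cpts=cpts)
    model.validate(atol=1e-6)
    return model


def write_network(model, path: str | Path) -> None:
    """Write a NetworkModel as BIF (``.bif``) or the JSON dialect (``.json``).

    The JSON dialect exists because BIF has no canonical slot for a class
    marker; ``"class"`` is stored as metadata there.  ``read_network`` after
    ``write_network`` is the identity up to float formatting.
    """
    path = Path(path)
    if path.suffix == ".json":
        obj = {
            "class": (model.variables[model.structure.class_index].name
                      if model.structure.class_index is not None else None),
            "nodes": [
                {
                    "name": v.name,
                    "states": list(v.states),
                    "parents": [model.variables[p].name
                                for p in sorted(model.structure.parent_sets[i])],
                    "cpt": np.asarray(model.cpts[i]).tolist(),
                }
                for i, v in enumerate(model.variables)
            ],
        }
        path.write_text(json.dumps(obj, indent=1))
        return

    lines = ["network unknown {", "}"]
    for v in model.variables:
        lines.append(f"variable {v.name} {{")
        lines.append(f"  type discrete [ {v.cardinality} ] {{ {', '.join(v.states)} }};")
        lines.append("}")
    for i, v in enumerate(model.variables):
        pa = sorted(model.structure.parent_sets[i])
        cpt = np.asarray(model.cpts[i])
        if not pa:
            lines.append(f"probability ( {v.name} ) {{")
            lines.append("  table " + ", ".join(repr(float(x)) for x in cpt[0]) + ";")
        else:
            pa_names = ", ".join(model.variables[p].name for p in pa)
            lines.append(f"probability ( {v.name} | {pa_names} ) {{")
            dims = [model.variables[p].cardinality for p in pa]
            for j in range(cpt.shape[0]):
                digits = np.unravel_index(j, dims)
                labels = ", ".join(model.variables[p].states[d]
                                   for p, d in zip(pa, digits))
                lines.append(f"  ({labels}) "
                             + ", ".join(repr(float(x)) for x in cpt[j]) + ";")
        lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def write_edge_list(structure, path: str | Path, names: Sequence[str] | None = None) -> None:
    """One ``parent child`` pair per line; names default to X0, X1, ..."""
    names = list(names) if names is not None else [f"X{i}" for i in range(structure.n_vars)]
    lines = [f"{names[p]} {names[c]}"
             for c in range(structure.n_vars)
             for p in sorted(structure.parent_sets[c])]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_edge_list(path: str | Path, names: Sequence[str]):
    """Read a ``parent child`` edge list over the given variable names."""
    from .graph import Structure

    index = {n: i for i, n in enumerate(names)}
    parents: list[set[int]] = [set() for _ in names]
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        p, c = line.split()
        parents[index[c]].add(index[p])
    return Structure(tuple(frozenset(s) for s in parents))
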