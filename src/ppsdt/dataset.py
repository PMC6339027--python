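"""Clinical dataset model, CSV I/O, partitioning, and frequency counting.

A dataset is a table of categorical symptom attributes plus one categorical
diagnosis class column.  The per-attribute *frequency matrix* — a k×l table
counting co-occurrences of attribute value (row) and class (column) within a
partition — is the sufficient statistic the whole training protocol exchanges:
row sums give attribute-value frequencies, column sums give class frequencies,
and the grand total is the partition size.

All hospitals must produce structurally aligned matrices, so values and
classes are always indexed by their position in the shared
:class:`AttributeSchema`; tokens are arbitrary strings, order is schema order.

The synthetic generator emulates the evaluation setting of acute urinary
inflammation diagnosis: five binary symptom attributes — Nausea (N), Lumbar
pain (LP), Urine pushing (UP), Micturition pains (MP), Burning of urethra
(BU) — and four diagnosis classes (0 = no disease, 1 = nephritis,
2 = bladder inflammation, 3 = both), split horizontally across hospitals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "AttributeSchema",
    "ClinicalDataset",
    "SplitPath",
    "FrequencyMatrix",
    "default_schema",
    "default_rule",
    "read_csv",
    "write_csv",
    "filter_partition",
    "count_frequencies",
    "generate_synthetic",
    "nausea_fixture",
]


class DatasetError(ValueError):
    """Schema violation or malformed input."""


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered attribute names, per-attribute value domains, and class labels."""

    attribute_names: Tuple[str, ...]
    value_domains: Mapping[str, Tuple[str, ...]]
    class_labels: Tuple[str, ...]
    class_column: str = "class"

    def __post_init__(self) -> None:
        names = self.attribute_names
        if len(set(names)) != len(names):
            raise DatasetError("attribute names must be unique")
        if set(self.value_domains) != set(names):
            raise DatasetError("value_domains must cover exactly the attribute names")
        for a, dom in self.value_domains.items():
            if not dom:
                raise DatasetError(f"attribute {a!r} has an empty value domain")
        if not self.class_labels:
            raise DatasetError("class_labels must be non-empty")
        if self.class_column in names or set(self.class_labels) & set(names):
            raise DatasetError("class labels/column must be disjoint from attribute names")

    def drop(self, attribute: str) -> "AttributeSchema":
        """Schema without one attribute (used when recursing into a partition)."""
        return AttributeSchema(
            attribute_names=tuple(a for a in self.attribute_names if a != attribute),
            value_domains={a: d for a, d in self.value_domains.items() if a != attribute},
            class_labels=self.class_labels,
            class_column=self.class_column,
        )

    def to_dict(self) -> dict:
        return {
            "attributes": {a: list(self.value_domains[a]) for a in self.attribute_names},
            "classes": list(self.class_labels),
            "class_column": self.class_column,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AttributeSchema":
        return cls(
            attribute_names=tuple(d["attributes"]),
            value_domains={a: tuple(v) for a, v in d["attributes"].items()},
            class_labels=tuple(d["classes"]),
            class_column=d.get("class_column", "class"),
        )


@dataclass(frozen=True)
class SplitPath:
    """(attribute, value) constraints fixed so far along a root-to-node path."""

    constraints: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        attrs = [a for a, _ in self.constraints]
        if len(set(attrs)) != len(attrs):
            raise DatasetError("an attribute may appear at most once on a path")

    @property
    def attributes(self) -> Tuple[str, ...]:
        return tuple(a for a, _ in self.constraints)

    def extend(self, attribute: str, value: str) -> "SplitPath":
        return SplitPath(self.constraints + ((attribute, value),))


@dataclass
class ClinicalDataset:
    """Records over a shared schema; one row per patient, tokens all categorical."""

    schema: AttributeSchema
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = list(self.schema.attribute_names) + [self.schema.class_column]
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        self.frame = self.frame[cols].astype(str).reset_index(drop=True)
        if self.frame.isna().any().any():
            raise DatasetError("missing values are not supported")
        for a in self.schema.attribute_names:
            bad = ~self.frame[a].isin(self.schema.value_domains[a])
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DatasetError(
                    f"row {row}, column {a!r}: value {self.frame[a].iloc[row]!r} "
                    f"outside domain {self.schema.value_domains[a]}"
                )
        bad = ~self.frame[self.schema.class_column].isin(self.schema.class_labels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DatasetError(
                f"row {row}, column {self.schema.class_column!r}: class "
                f"{self.frame[self.schema.class_column].iloc[row]!r} outside {self.schema.class_labels}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> List[Tuple[Dict[str, str], str]]:
        cc = self.schema.class_column
        return [
            ({a: row[a] for a in self.schema.attribute_names}, row[cc])
            for row in self.frame.to_dict("records")
        ]

    def class_counts(self) -> np.ndarray:
        """Counts per class label, in schema order."""
        vc = self.frame[self.schema.class_column].value_counts()
        return np.array([int(vc.get(c, 0)) for c in self.schema.class_labels], dtype=np.int64)


@dataclass(frozen=True)
class FrequencyMatrix:
    """k×l co-occurrence counts of one attribute's values (rows) vs classes (columns)."""

    attribute: str
    values: Tuple[str, ...]
    classes: Tuple[str, ...]
    cells: np.ndarray  # shape (k, l), non-negative ints

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.shape != (len(self.values), len(self.classes)):
            raise DatasetError("cell shape does not match value/class counts")
        if (cells < 0).any():
            raise DatasetError("counts must be non-negative")
        object.__setattr__(self, "cells", cells)

    @property
    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def column_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.cells.sum())


# --------------------------------------------------------------------------
# CSV I/O — RFC-4180, UTF-8, header row; optional JSON schema sidecar


def _sidecar(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".schema.json")


def write_csv(dataset: ClinicalDataset, path: Union[str, Path], sidecar: bool = True) -> None:
    dataset.frame.to_csv(path, index=False)
    if sidecar:
        _sidecar(path).write_text(json.dumps(dataset.schema.to_dict(), indent=1))


def read_csv(path: Union[str, Path], schema: Optional[AttributeSchema] = None) -> ClinicalDataset:
    """Load a dataset; schema from argument, sidecar JSON, or inferred.

    Inference takes the last column as the class and sorts observed tokens to
    fix a deterministic domain order.  Validation errors name the offending
    row and column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema is None and _sidecar(path).exists():
        schema = AttributeSchema.from_dict(json.loads(_sidecar(path).read_text()))
    if schema is None:
        *attrs, cc = frame.columns
        schema = AttributeSchema(
            attribute_names=tuple(attrs),
            value_domains={a: tuple(sorted(frame[a].unique())) for a in attrs},
            class_labels=tuple(sorted(frame[cc].unique())) if len(frame) else ("0",),
            class_column=cc,
        )
    return ClinicalDataset(schema=schema, frame=frame)


# --------------------------------------------------------------------------
# partitioning and counting


def filter_partition(dataset: ClinicalDataset, path: SplitPath) -> ClinicalDataset:
    """Records satisfying every (attribute = value) constraint on ``path``.

    The returned schema drops the constrained attributes so downstream
    counting only sees candidates still available for splitting.
    """
    schema = dataset.schema
    for a, _ in path.constraints:
        if a not in schema.attribute_names:
            raise DatasetError(f"unknown attribute {a!r} in split path")
    mask = pd.Series(True, index=dataset.frame.index)
    for a, v in path.constraints:
        mask &= dataset.frame[a] == v
    narrowed = schema
    for a, _ in path.constraints:
        narrowed = narrowed.drop(a)
    keep = list(narrowed.attribute_names) + [schema.class_column]
    return ClinicalDataset(schema=narrowed, frame=dataset.frame.loc[mask, keep])


def count_frequencies(
    dataset: ClinicalDataset, attribute: str, path: SplitPath = SplitPath()
) -> FrequencyMatrix:
    """Tally the k×l (attribute value, class) co-occurrence matrix of a partition."""
    if attribute in path.attributes:
        raise DatasetError(f"attribute {attribute!r} is already fixed by the split path")
    part = filter_partition(dataset, path) if path.constraints else dataset
    if attribute not in part.schema.attribute_names:
        raise DatasetError(f"unknown attribute {attribute!r}")
    values = part.schema.value_domains[attribute]
    classes = part.schema.class_labels
    vi = {v: i for i, v in enumerate(values)}
    ci = {c: i for i, c in enumerate(classes)}
    cells = np.zeros((len(values), len(classes)), dtype=np.int64)
    av = part.frame[attribute].to_numpy()
    cl = part.frame[part.schema.class_column].to_numpy()
    for v, c in zip(av, cl):
        cells[vi[v], ci[c]] += 1
    return FrequencyMatrix(attribute=attribute, values=values, classes=classes, cells=cells)


# --------------------------------------------------------------------------
# synthetic data


def default_schema() -> AttributeSchema:
    """Five binary symptom attributes, four diagnosis classes."""
    attrs = ("N", "LP", "UP", "MP", "BU")
    return AttributeSchema(
        attribute_names=attrs,
        value_domains={a: ("0", "1") for a in attrs},
        class_labels=("0", "1", "2", "3"),
    )


def default_rule(record: Mapping[str, str]) -> str:
    """Deterministic diagnosis rule mirroring the acute-inflammation setting.

    Bladder inflammation when urine pushing and micturition pains co-occur;
    nephritis when lumbar pain and nausea co-occur; class encodes the two
    findings as 0/1/2/3 (none / nephritis / bladder / both).
    """
    bladder = record["UP"] == "1" and record["MP"] == "1"
    nephritis = record["LP"] == "1" and record["N"] == "1"
    return str((2 if bladder else 0) + (1 if nephritis else 0))


ClassRule = Union[Callable[[Mapping[str, str]], str], Mapping[Tuple[str, ...], str]]


def generate_synthetic(
    n_hospitals: int,
    records_per_hospital: int,
    schema: Optional[AttributeSchema] = None,
    class_rule: Optional[ClassRule] = None,
    class_conditional: Optional[Mapping[str, Mapping[str, float]]] = None,
    class_prior: Optional[Sequence[float]] = None,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> List[ClinicalDataset]:
    """Simulate horizontally partitioned hospital datasets.

    Two generating modes:

    * **rule mode** (default): attribute values drawn uniformly from their
      domains, class assigned by ``class_rule`` (default
      :func:`default_rule`), then flipped to a different uniform class with
      probability ``noise_rate``.
    * **class-conditional mode**: when ``class_conditional`` is given, a class
      is drawn from ``class_prior`` (uniform if omitted) and each binary
      attribute takes its second domain value with the class-conditional
      probability ``class_conditional[class][attribute]``.

    Deterministic under ``seed``; hospitals receive consecutive blocks so the
    pooled dataset is independent of ``n_hospitals``.
    """
    if schema is None:
        schema = default_schema()
    if not 0.0 <= noise_rate <= 1.0:
        raise DatasetError("noise_rate must lie in [0, 1]")
    if len(schema.class_labels) == 1:
        import warnings

        warnings.warn("degenerate schema: a single class makes every tree a stump")
    rng = Random(seed)
    rule: Optional[Callable[[Mapping[str, str]], str]] = None
    if class_conditional is None:
        if callable(class_rule):
            rule = class_rule
        elif class_rule is not None:
            table = dict(class_rule)
            rule = lambda rec: table[tuple(rec[a] for a in schema.attribute_names)]
        else:
            rule = default_rule

    rows = []
    for _ in range(n_hospitals * records_per_hospital):
        if class_conditional is not None:
            labels = schema.class_labels
            if class_prior is not None:
                c = rng.choices(labels, weights=list(class_prior))[0]
            else:
                c = rng.choice(labels)
            rec = {}
            for a in schema.attribute_names:
                dom = schema.value_domains[a]
                p = class_conditional[c][a]
                if not 0.0 <= p <= 1.0:
                    raise DatasetError("class-conditional probabilities must lie in [0, 1]")
                rec[a] = dom[-1] if rng.random() < p else dom[0]
        else:
            rec = {a: rng.choice(schema.value_domains[a]) for a in schema.attribute_names}
            c = rule(rec)
            if noise_rate and rng.random() < noise_rate:
                c = rng.choice([x for x in schema.class_labels if x != c])
        rec[schema.class_column] = c
        rows.append(rec)

    frame = pd.DataFrame(rows)
    out = []
    for h in range(n_hospitals):
        chunk = frame.iloc[h * records_per_hospital : (h + 1) * records_per_hospital]
        out.append(ClinicalDataset(schema=schema, frame=chunk.copy()))
    return out


def nausea_fixture() -> Tuple[FrequencyMatrix, Tuple[int, ...]]:
    """The aggregated Nausea frequency matrix of the three-hospital worked example.

    22 pooled records; row Nausea=0 holds classes (8, 3, 5, 0), row Nausea=1
    holds (0, 2, 0, 4); class totals (8, 5, 5, 4).
    """
    m = FrequencyMatrix(
        attribute="N",
        values=("0", "1"),
        classes=("0", "1", "2", "3"),
        cells=np.array([[8, 3, 5, 0], [0, 2, 0, 4]], dtype=np.int64),
    )
    return m, (8, 5, 5, 4)
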