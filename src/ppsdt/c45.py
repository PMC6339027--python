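"""Information-gain decision trees over categorical clinical data.

The split criterion is plain information gain on class frequencies:

    Entropy(D)      = Σ_i −(freq(c_i, D)/|D|) · log₂(freq(c_i, D)/|D|)
    Entropy_T(D)    = Σ_j (|t_j|/|D|) · Entropy(t_j)        (rows of the frequency matrix)
    IG(T)           = Entropy(D) − Entropy_T(D)

Everything a split decision needs is contained in one k×l frequency matrix
per candidate attribute, which is what makes the encrypted-aggregation
protocol possible: parties exchange matrices, never records.

Although the method is conventionally labelled C4.5, it uses information gain
rather than gain ratio, categorical attributes only, and no pruning; the
builder here is the plaintext reference against which the multi-party
protocol's trees are checked node-for-node.

Determinism rules (all parties must agree bit-for-bit):

* equal-IG ties go to the attribute earliest in schema order;
* a pure partition becomes a leaf of its class;
* with no attributes left, the majority class wins, ties to the lowest
  class index;
* an empty child partition becomes a leaf of the parent's majority class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

import numpy as np

from .dataset import (
    AttributeSchema,
    ClinicalDataset,
    DatasetError,
    FrequencyMatrix,
    SplitPath,
    count_frequencies,
)

__all__ = [
    "EntropyError",
    "DecisionNode",
    "DecisionTree",
    "entropy",
    "attribute_entropy",
    "information_gain",
    "select_split",
    "majority_class",
    "build_tree_plaintext",
    "classify",
    "tree_to_json",
    "tree_from_json",
]

IG_EPSILON = 1e-9  # floating-point guard: IG is non-negative up to rounding


class EntropyError(ValueError):
    """Entropy requested of an empty partition."""


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count vector; 0·log₂0 ≡ 0."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise EntropyError("entropy undefined for an empty partition")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def attribute_entropy(m: FrequencyMatrix) -> float:
    """Weighted class entropy after splitting on the matrix's attribute.

    Each row (one attribute value) contributes its entropy weighted by the
    fraction of records it holds; empty rows contribute nothing.
    """
    total = m.total
    if total == 0:
        raise EntropyError("attribute entropy undefined for an empty partition")
    acc = 0.0
    for row in m.cells:
        rs = int(row.sum())
        if rs:
            acc += (rs / total) * entropy(row)
    return acc


def information_gain(m: FrequencyMatrix) -> float:
    """Reduction in class entropy from splitting on the matrix's attribute."""
    ig = entropy(m.column_sums) - attribute_entropy(m)
    if ig < -IG_EPSILON:
        raise ValueError(f"information gain {ig} below the floating-point guard")
    return ig


def select_split(matrices: Mapping[str, FrequencyMatrix]) -> str:
    """Attribute of maximal information gain; ties go to the earliest entry.

    All matrices must describe the same partition (equal totals and class
    column sums), otherwise the inputs are inconsistent and selection aborts.
    """
    if not matrices:
        raise ValueError("no candidate attributes")
    items = list(matrices.items())
    ref = items[0][1]
    for _, m in items[1:]:
        if m.total != ref.total or not np.array_equal(m.column_sums, ref.column_sums):
            raise ValueError("matrices describe different partitions")
    best_attr, best_ig = items[0][0], information_gain(items[0][1])
    for attr, m in items[1:]:
        ig = information_gain(m)
        if ig > best_ig:
            best_attr, best_ig = attr, ig
    return best_attr


def majority_class(class_counts, class_labels: Tuple[str, ...]) -> str:
    """Most frequent class; ties resolved to the lowest class index."""
    counts = np.asarray(class_counts)
    return class_labels[int(np.argmax(counts))]


# --------------------------------------------------------------------------
# tree structure


@dataclass
class DecisionNode:
    """Internal node (attribute + one child per domain value) or leaf (class)."""

    attribute: Optional[str] = None
    children: Optional[Dict[str, "DecisionNode"]] = None
    class_label: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.class_label is not None

    def __eq__(self, other) -> bool:
        if not isinstance(other, DecisionNode):
            return NotImplemented
        if self.is_leaf or other.is_leaf:
            return self.class_label == other.class_label
        return self.attribute == other.attribute and self.children == other.children


@dataclass
class DecisionTree:
    """The shared classification model every hospital holds after training."""

    root: DecisionNode
    schema: AttributeSchema
    metadata: Dict[str, object] = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DecisionTree):
            return NotImplemented
        return self.root == other.root


def build_tree_plaintext(dataset: ClinicalDataset) -> DecisionTree:
    """Recursive information-gain tree on pooled plaintext records.

    This is the single-site reference algorithm: the federated protocol must
    produce the identical tree from the same records however they are
    distributed.
    """
    if len(dataset) == 0:
        raise DatasetError("cannot train on an empty dataset")
    schema = dataset.schema

    def grow(path: SplitPath, parent_majority: Optional[str]) -> DecisionNode:
        from .dataset import filter_partition

        part = filter_partition(dataset, path)
        counts = part.class_counts()
        if counts.sum() == 0:
            return DecisionNode(class_label=parent_majority)
        nonzero = np.flatnonzero(counts)
        if len(nonzero) == 1:
            return DecisionNode(class_label=schema.class_labels[int(nonzero[0])])
        avail = [a for a in schema.attribute_names if a not in path.attributes]
        maj = majority_class(counts, schema.class_labels)
        if not avail:
            return DecisionNode(class_label=maj)
        matrices = {a: count_frequencies(dataset, a, path) for a in avail}
        split = select_split(matrices)
        children = {
            v: grow(path.extend(split, v), maj) for v in schema.value_domains[split]
        }
        return DecisionNode(attribute=split, children=children)

    root = grow(SplitPath(), None)
    return DecisionTree(root=root, schema=schema, metadata={"algorithm": "plaintext-ig"})


def classify(tree: DecisionTree, symptoms: Mapping[str, str]) -> str:
    """Follow the unique root-to-leaf path for a full symptom vector."""
    node = tree.root
    while not node.is_leaf:
        attr = node.attribute
        if attr not in symptoms:
            raise KeyError(f"symptom vector missing attribute {attr!r}")
        value = symptoms[attr]
        if value not in node.children:
            raise ValueError(
                f"value {value!r} for attribute {attr!r} outside the trained domain"
            )
        node = node.children[value]
    return node.class_label


# --------------------------------------------------------------------------
# JSON serialization — stable key order for diffability


def _node_to_obj(node: DecisionNode) -> dict:
    if node.is_leaf:
        return {"leaf": node.class_label}
    return {
        "attribute": node.attribute,
        "children": {v: _node_to_obj(c) for v, c in sorted(node.children.items())},
    }


def _node_from_obj(obj: Mapping) -> DecisionNode:
    if "leaf" in obj:
        return DecisionNode(class_label=obj["leaf"])
    return DecisionNode(
        attribute=obj["attribute"],
        children={v: _node_from_obj(c) for v, c in obj["children"].items()},
    )


def tree_to_json(tree: DecisionTree) -> str:
    payload = {
        "schema": tree.schema.to_dict(),
        "node": _node_to_obj(tree.root),
        "metadata": tree.metadata,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def tree_from_json(text: str) -> DecisionTree:
    obj = json.loads(text)
    return DecisionTree(
        root=_node_from_obj(obj["node"]),
        schema=AttributeSchema.from_dict(obj["schema"]),
        metadata=dict(obj.get("metadata", {})),
    )
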