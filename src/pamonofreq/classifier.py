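"""Depth-limited decision trees and random forests over feature vectors.

Training delegates split search to scikit-learn's CART implementation, but
the fitted tree is immediately converted into an explicit node list owned
by this module: prediction, JSON round-tripping and if-else code export all
operate on that structure, so a deployed tree is exactly the serialized
one.  Conventions fixed here:

* a sample goes LEFT iff feature <= threshold (matching the exported code);
* forest prediction is a majority vote over trees, ties resolved to class 0
  ("no virus") — in a screening pipeline an undecided patch is reported
  negative rather than positive;
* thresholds are serialized and exported at full precision (17 significant
  digits, the float64 round-trip length): platform-dependent floating-point
  noise in extracted features can flip comparisons, so the exporter must
  never round.

The default depth cap is 12: deep enough for the patch-classification task
while keeping the exported if-else tree small and its execution time
negligible next to feature extraction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

MODEL_FORMAT_VERSION = "pamonofreq-tree-1"


class ModelError(Exception):
    """Invalid, incompatible or corrupt model data."""


class FeatureDimensionError(ModelError):
    """Feature vector length does not match the model's training layout."""


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration; defaults give a single depth-12 Gini tree."""

    max_depth: int = 12
    n_trees: int = 1
    seed: int = 0
    criterion: str = "gini"

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class TreeNode:
    """Internal node (left/right >= 0) or leaf (klass >= 0)."""

    feature_index: int = -1
    threshold: float = 0.0
    left: int = -1
    right: int = -1
    klass: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.klass >= 0


@dataclass(frozen=True)
class DecisionTreeModel:
    """Binary decision tree as a flat node list rooted at index 0."""

    nodes: tuple[TreeNode, ...]
    n_features: int

    @property
    def depth(self) -> int:
        """Length of the longest root-to-leaf path (a lone leaf has depth 0)."""
        def walk(i: int) -> int:
            node = self.nodes[i]
            if node.is_leaf:
                return 0
            return 1 + max(walk(node.left), walk(node.right))

        return walk(0)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def predict(self, features: Sequence[float]) -> int:
        x = np.asarray(features, dtype=np.float64)
        if x.shape != (self.n_features,):
            raise FeatureDimensionError(
                f"expected {self.n_features} features, got shape {x.shape}"
            )
        i = 0
        while True:
            node = self.nodes[i]
            if node.is_leaf:
                return node.klass
            i = node.left if x[node.feature_index] <= node.threshold else node.right


@dataclass(frozen=True)
class ForestModel:
    """Bagged ensemble of decision trees with majority voting (ties -> 0)."""

    trees: tuple[DecisionTreeModel, ...]

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return self.trees[0].n_features

    def predict(self, features: Sequence[float]) -> int:
        votes = sum(t.predict(features) for t in self.trees)
        return 1 if 2 * votes > self.n_trees else 0


def _validate_table(values: np.ndarray, labels: np.ndarray) -> None:
    if values.size == 0:
        raise ValueError("cannot train on an empty feature table")
    if labels is None:
        raise ValueError("training requires labels")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")


def _from_sklearn(clf: DecisionTreeClassifier, n_features: int) -> DecisionTreeModel:
    """Flatten a fitted sklearn tree into our node-list structure."""
    t = clf.tree_
    classes = clf.classes_.astype(int)
    nodes = []
    for i in range(t.node_count):
        if t.children_left[i] == -1:  # leaf
            klass = int(classes[int(np.argmax(t.value[i][0]))])
            nodes.append(TreeNode(klass=klass))
        else:
            nodes.append(
                TreeNode(
                    feature_index=int(t.feature[i]),
                    threshold=float(t.threshold[i]),
                    left=int(t.children_left[i]),
                    right=int(t.children_right[i]),
                )
            )
    return DecisionTreeModel(tuple(nodes), n_features)


def train_tree(table, config: TrainConfig = TrainConfig()) -> DecisionTreeModel:
    """Fit a depth-capped binary decision tree on a labeled feature table.

    Deterministic for a fixed (table, config) pair.
    """
    values = np.asarray(table.values, dtype=np.float64)
    _validate_table(values, table.labels)
    clf = DecisionTreeClassifier(
        max_depth=config.max_depth,
        criterion=config.criterion,
        random_state=config.seed,
    )
    clf.fit(values, table.labels)
    return _from_sklearn(clf, values.shape[1])


def train_forest(table, config: TrainConfig = TrainConfig(n_trees=10)) -> ForestModel:
    """Fit n_trees depth-capped trees on seeded bootstrap resamples."""
    values = np.asarray(table.values, dtype=np.float64)
    _validate_table(values, table.labels)
    rng = np.random.default_rng(config.seed)
    n = values.shape[0]
    trees = []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        clf = DecisionTreeClassifier(
            max_depth=config.max_depth,
            criterion=config.criterion,
            random_state=tree_seed,
        )
        clf.fit(values[idx], table.labels[idx])
        trees.append(_from_sklearn(clf, values.shape[1]))
    return ForestModel(tuple(trees))


def predict(model: DecisionTreeModel | ForestModel, features: Sequence[float]) -> int:
    """Binary decision for one feature vector."""
    return model.predict(features)


# ---------------------------------------------------------------------------
# if-else code export


def export_if_else(
    model: DecisionTreeModel, function_name: str = "classify_patch"
) -> tuple[str, Callable[[Sequence[float]], int]]:
    """Unroll a tree into a self-contained C function of nested if-else.

    Returns the source text together with a structural interpreter obtained
    by parsing the emitted text back — parity between the interpreter and
    ``model.predict`` certifies the generated code, threshold literals
    included.
    """
    lines = [f"int {function_name}(const double features[{model.n_features}]) {{"]

    def emit(i: int, indent: int) -> None:
        pad = "    " * indent
        node = model.nodes[i]
        if node.is_leaf:
            lines.append(f"{pad}return {node.klass};")
            return
        lines.append(
            f"{pad}if (features[{node.feature_index}] <= {node.threshold!r}) {{"
        )
        emit(node.left, indent + 1)
        lines.append(f"{pad}}} else {{")
        emit(node.right, indent + 1)
        lines.append(f"{pad}}}")

    emit(0, 1)
    lines.append("}")
    source = "\n".join(lines) + "\n"
    return source, parse_if_else(source)


_IF_RE = re.compile(r"^if \(features\[(\d+)\] <= ([-+0-9.eE]+)\) \{$")
_RETURN_RE = re.compile(r"^return ([01]);$")


def parse_if_else(source: str) -> Callable[[Sequence[float]], int]:
    """Parse exported if-else source into an evaluating interpreter."""
    body = [ln.strip() for ln in source.strip().splitlines()[1:-1] if ln.strip()]
    pos = 0

    def parse_block():
        nonlocal pos
        line = body[pos]
        m = _RETURN_RE.match(line)
        if m:
            pos += 1
            klass = int(m.group(1))
            return lambda x: klass
        m = _IF_RE.match(line)
        if m is None:
            raise ModelError(f"unparseable exported line: {line!r}")
        feat, thr = int(m.group(1)), float(m.group(2))
        pos += 1
        left = parse_block()
        if body[pos] != "} else {":
            raise ModelError("malformed exported tree: missing else branch")
        pos += 1
        right = parse_block()
        if body[pos] != "}":
            raise ModelError("malformed exported tree: missing closing brace")
        pos += 1
        return lambda x, f=feat, t=thr, l=left, r=right: l(x) if x[f] <= t else r(x)

    fn = parse_block()
    if pos != len(body):
        raise ModelError("trailing content in exported tree source")
    return fn


# ---------------------------------------------------------------------------
# JSON serialization


def _tree_to_dict(model: DecisionTreeModel) -> dict:
    return {
        "n_features": model.n_features,
        "nodes": [
            {"klass": n.klass}
            if n.is_leaf
            else {
                "feature_index": n.feature_index,
                "threshold": n.threshold,
                "left": n.left,
                "right": n.right,
            }
            for n in model.nodes
        ],
    }


def _tree_from_dict(data: dict) -> DecisionTreeModel:
    try:
        nodes = tuple(
            TreeNode(klass=int(nd["klass"]))
            if "klass" in nd
            else TreeNode(
                feature_index=int(nd["feature_index"]),
                threshold=float(nd["threshold"]),
                left=int(nd["left"]),
                right=int(nd["right"]),
            )
            for nd in data["nodes"]
        )
        return DecisionTreeModel(nodes, int(data["n_features"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelError(f"malformed tree data: {exc}") from exc


def save_model(model: DecisionTreeModel | ForestModel, path: str | Path) -> None:
    """Write a model as JSON; float thresholds survive bit-exactly
    (Python's shortest-repr float serialization round-trips float64)."""
    if isinstance(model, ForestModel):
        payload = {
            "version": MODEL_FORMAT_VERSION,
            "kind": "forest",
            "trees": [_tree_to_dict(t) for t in model.trees],
        }
    else:
        payload = {
            "version": MODEL_FORMAT_VERSION,
            "kind": "tree",
            **_tree_to_dict(model),
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> DecisionTreeModel | ForestModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"unsupported model version {payload.get('version')!r} in {path}"
        )
    if payload.get("kind") == "forest":
        return ForestModel(tuple(_tree_from_dict(t) for t in payload["trees"]))
    if payload.get("kind") == "tree":
        return _tree_from_dict(payload)
    raise ModelError(f"unknown model kind {payload.get('kind')!r}")
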