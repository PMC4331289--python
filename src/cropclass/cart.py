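"""CART classification trees with Gini splitting, written from scratch.

The tree is grown by exhaustive binary splitting: at each node every
(variable, threshold) pair is scored, thresholds being midpoints of
consecutive distinct sorted values, and the split maximizing the Gini
improvement

    improvement = gini(parent) - (n_L/n) gini(L) - (n_R/n) gini(R)

is taken, subject to minimum node sizes. Candidate comparisons are done in
exact integer arithmetic (class counts are integers), so the documented
tie-breaks — earlier variable in column order, then smaller threshold —
can never be flipped by floating-point round-off.

Growth stops at a configurable depth limit and minimum parent/child sizes
(defaults 5 / 8 / 4). Model quality is summarized by the risk estimate
(misclassification proportion with binomial standard error), either by
resubstitution or by seeded stratified k-fold cross-validation. Variable
importance sums size-weighted improvements over primary splits and is
normalized so the top variable scores 100%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from cropclass.features import MatrixData


@dataclass
class TreeParams:
    """Growth and validation parameters.

    ``max_depth`` counts splits along a root-to-leaf path (root at depth
    0); ``min_parent`` / ``min_child`` are absolute case counts.
    """

    max_depth: int = 5
    min_parent: int = 8
    min_child: int = 4
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 0 or self.min_child < 1 or self.min_parent < 2:
            raise ValueError("invalid tree parameters")


@dataclass
class Split:
    variable: str
    threshold: float
    improvement: float


@dataclass
class TreeNode:
    node_id: int
    depth: int
    class_counts: dict[str, int]
    gini: float
    terminal_class: str
    terminal_probability: float
    split: Split | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def size(self) -> int:
        return sum(self.class_counts.values())

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class Tree:
    """A grown CART model."""

    root: TreeNode
    classes: list[str]
    feature_names: list[str]
    params: TreeParams

    def nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.split is not None:
                stack.extend([node.right, node.left])

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        return max(n.depth for n in self.nodes())

    # -- JSON audit serialization ------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(n: TreeNode) -> dict:
            d = {
                "node_id": n.node_id,
                "depth": n.depth,
                "class_counts": n.class_counts,
                "gini": n.gini,
                "terminal_class": n.terminal_class,
                "terminal_probability": n.terminal_probability,
            }
            if n.split is not None:
                d["split"] = {
                    "variable": n.split.variable,
                    "threshold": n.split.threshold,
                    "improvement": n.split.improvement,
                }
                d["left"] = node_dict(n.left)
                d["right"] = node_dict(n.right)
            return d

        return {
            "classes": self.classes,
            "feature_names": self.feature_names,
            "params": {
                "max_depth": self.params.max_depth,
                "min_parent": self.params.min_parent,
                "min_child": self.params.min_child,
                "cv_folds": self.params.cv_folds,
                "seed": self.params.seed,
            },
            "root": node_dict(self.root),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, data: dict) -> "Tree":
        def build(d: dict) -> TreeNode:
            node = TreeNode(
                node_id=d["node_id"],
                depth=d["depth"],
                class_counts={k: int(v) for k, v in d["class_counts"].items()},
                gini=d["gini"],
                terminal_class=d["terminal_class"],
                terminal_probability=d["terminal_probability"],
            )
            if "split" in d:
                s = d["split"]
                node.split = Split(s["variable"], s["threshold"], s["improvement"])
                node.left = build(d["left"])
                node.right = build(d["right"])
            return node

        return cls(
            root=build(data["root"]),
            classes=list(data["classes"]),
            feature_names=list(data["feature_names"]),
            params=TreeParams(**data["params"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Tree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RiskEstimate:
    """Misclassification proportion with its binomial standard error."""

    risk: float
    se: float
    method: str  # "resubstitution" | "cross_validation"
    n: int


def gini(class_counts) -> float:
    """Gini impurity sum_i p_i (1 - p_i) of a node's class counts."""
    if isinstance(class_counts, Mapping):
        counts = np.asarray(list(class_counts.values()), dtype=float)
    else:
        counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0 or np.any(counts < 0):
        raise ValueError("class counts must be non-negative and non-empty")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero class counts")
    p = counts / total
    return float(np.sum(p * (1.0 - p)))


# ---------------------------------------------------------------------------
# Split search (exact integer scoring)


def _best_split_arrays(
    X: np.ndarray, y: np.ndarray, n_classes: int, feature_names: Sequence[str],
    min_child: int,
) -> Split | None:
    """Best admissible split, or None.

    Candidates are scored by sum_children sum_i c_i^2 / n_child, which is a
    monotone transform of the Gini improvement at fixed parent; scores are
    compared by integer cross-multiplication. A strictly-greater test keeps
    the earliest variable and smallest threshold among exact ties.
    """
    n = len(y)
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), y] = 1
    parent_counts = onehot.sum(axis=0)
    sum_parent_sq = int(np.sum(parent_counts.astype(object) ** 2))

    best: tuple[int, int] | None = None  # (numerator, denominator)
    best_var = -1
    best_thr = 0.0
    sizes_l = np.arange(1, n, dtype=np.int64)
    sizes_r = n - sizes_l
    for j, name in enumerate(feature_names):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        # split after position i (left size i+1); valid where value changes
        valid = (xs[:-1] < xs[1:]) & (sizes_l >= min_child) & (sizes_r >= min_child)
        if not valid.any():
            continue
        cum = np.cumsum(onehot[order], axis=0)[:-1]  # counts in left child
        sl = np.einsum("ij,ij->i", cum, cum)
        right = parent_counts[None, :] - cum
        sr = np.einsum("ij,ij->i", right, right)
        nums = sl * sizes_r + sr * sizes_l
        dens = sizes_l * sizes_r
        for i in np.nonzero(valid)[0]:
            num, den = int(nums[i]), int(dens[i])
            if best is None or num * best[1] > best[0] * den:
                best = (num, den)
                best_var = j
                best_thr = float((xs[i] + xs[i + 1]) / 2.0)
    if best is None:
        return None
    num, den = best
    # zero improvement iff num * n == sum_parent_sq * den (exact)
    if num * n == sum_parent_sq * den:
        return None
    improvement = num / (den * n) - sum_parent_sq / (n * n)
    return Split(feature_names[best_var], best_thr, float(improvement))


def best_split(
    rows, candidate_variables: Sequence[str], params: TreeParams
) -> Split | None:
    """Best split of a node's rows over the candidate variables.

    ``rows`` is a mapping/DataFrame-like with the candidate variables as
    numeric columns and a ``label`` column.
    """
    import pandas as pd

    frame = pd.DataFrame(rows)
    y_labels = frame["label"].to_numpy()
    classes = sorted(set(y_labels))
    y = np.searchsorted(np.array(classes), y_labels)
    X = frame[list(candidate_variables)].to_numpy(dtype=float)
    if len(frame) < params.min_parent:
        raise ValueError(
            f"node of size {len(frame)} is below min_parent={params.min_parent}"
        )
    return _best_split_arrays(X, y, len(classes), list(candidate_variables),
                              params.min_child)


# ---------------------------------------------------------------------------
# Tree growth


def _majority(counts: np.ndarray, classes: Sequence[str]) -> tuple[str, float]:
    # ties go to the first class in sorted order (argmax convention)
    k = int(np.argmax(counts))
    total = counts.sum()
    return classes[k], float(counts[k] / total)


def _grow(
    X: np.ndarray, y: np.ndarray, classes: Sequence[str],
    feature_names: Sequence[str], params: TreeParams,
) -> TreeNode:
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = y[idx]
        counts = np.bincount(sub_y, minlength=len(classes))
        term_class, term_prob = _majority(counts, classes)
        node = TreeNode(
            node_id=counter[0],
            depth=depth,
            class_counts={c: int(counts[i]) for i, c in enumerate(classes)},
            gini=gini(counts) if counts.sum() else 0.0,
            terminal_class=term_class,
            terminal_probability=term_prob,
        )
        counter[0] += 1
        n = len(idx)
        pure = np.max(counts) == n
        if pure or n < params.min_parent or depth >= params.max_depth:
            return node
        split = _best_split_arrays(
            X[idx], sub_y, len(classes), feature_names, params.min_child
        )
        if split is None:
            return node
        j = list(feature_names).index(split.variable)
        go_left = X[idx, j] <= split.threshold
        node.split = split
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    return build(np.arange(len(y)), 0)


def grow_tree(matrix: MatrixData, params: TreeParams | None = None) -> Tree:
    """Grow a CART tree on the labeled rows of a feature matrix."""
    params = params or TreeParams()
    labeled = matrix.labeled()
    if len(labeled) < 2:
        raise ValueError("need at least 2 labeled rows to grow a tree")
    feature_names = labeled.feature_columns
    if not feature_names:
        raise ValueError("matrix has no feature columns")
    classes = sorted(labeled.labels.unique())
    X = labeled.features().to_numpy(dtype=float)
    y = np.searchsorted(np.array(classes), labeled.labels.to_numpy())
    root = _grow(X, y, classes, feature_names, params)
    return Tree(root=root, classes=classes, feature_names=feature_names,
                params=params)


# ---------------------------------------------------------------------------
# Prediction and validation


def predict(tree: Tree, record: Mapping[str, float]) -> tuple[str, float]:
    """Descend root-to-leaf; values equal to a threshold go left (<=)."""
    node = tree.root
    while node.split is not None:
        var = node.split.variable
        if var not in record:
            raise KeyError(f"record lacks variable {var!r} tested by the tree")
        node = node.left if record[var] <= node.split.threshold else node.right
    return node.terminal_class, node.terminal_probability


def _predict_codes(root: TreeNode, X: np.ndarray, feat_index: dict[str, int],
                   classes: Sequence[str]) -> np.ndarray:
    out = np.empty(len(X), dtype=object)
    for i, x in enumerate(X):
        node = root
        while node.split is not None:
            node = (node.left if x[feat_index[node.split.variable]] <= node.split.threshold
                    else node.right)
        out[i] = node.terminal_class
    return out


def predict_matrix(tree: Tree, matrix: MatrixData) -> "np.ndarray":
    """Predicted class per row of a matrix (array of labels, row order)."""
    missing = [v for v in tree.feature_names if v not in matrix.feature_columns]
    if missing:
        raise KeyError(f"matrix lacks variables tested by the tree: {missing}")
    X = matrix.frame[tree.feature_names].to_numpy(dtype=float)
    feat_index = {v: i for i, v in enumerate(tree.feature_names)}
    return _predict_codes(tree.root, X, feat_index, tree.classes)


def resubstitution_risk(tree: Tree, matrix: MatrixData) -> RiskEstimate:
    """Misclassification proportion of the training data on its own tree."""
    labeled = matrix.labeled()
    pred = predict_matrix(tree, labeled)
    obs = labeled.labels.to_numpy()
    n = len(obs)
    risk = float(np.mean(pred != obs))
    return RiskEstimate(risk, float(np.sqrt(risk * (1 - risk) / n)),
                        "resubstitution", n)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per row, stratified by class, seeded."""
    fold = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        # stagger fold numbering across classes to balance fold sizes
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)
    return fold


def cross_validate(matrix: MatrixData, params: TreeParams | None = None) -> RiskEstimate:
    """Stratified k-fold cross-validated misclassification risk.

    If some class has fewer members than the requested fold count, the
    fold count is reduced (with a warning) to the smallest class size.
    """
    params = params or TreeParams()
    labeled = matrix.labeled()
    n = len(labeled)
    if n < 2:
        raise ValueError("need at least 2 labeled rows for cross-validation")
    feature_names = labeled.feature_columns
    classes = sorted(labeled.labels.unique())
    X = labeled.features().to_numpy(dtype=float)
    y = np.searchsorted(np.array(classes), labeled.labels.to_numpy())
    min_class = int(np.bincount(y).min())
    k = min(params.cv_folds, max(2, min_class), n)
    if k < params.cv_folds:
        warnings.warn(
            f"reducing folds from {params.cv_folds} to {k} (smallest class "
            f"has {min_class} members)", stacklevel=2)
    rng = np.random.default_rng(params.seed)
    fold = _stratified_folds(y, k, rng)
    feat_index = {v: i for i, v in enumerate(feature_names)}
    errors = 0
    for f in range(k):
        train = fold != f
        test = ~train
        if not test.any():
            continue
        root = _grow(X[train], y[train], classes, feature_names, params)
        pred = _predict_codes(root, X[test], feat_index, classes)
        obs = np.array(classes, dtype=object)[y[test]]
        errors += int(np.sum(pred != obs))
    risk = errors / n
    return RiskEstimate(float(risk), float(np.sqrt(risk * (1 - risk) / n)),
                        "cross_validation", n)


def variable_importance(tree: Tree) -> list[tuple[str, float]]:
    """Normalized variable importance from primary splits.

    raw(v) = sum over internal nodes splitting on v of
    (node_size / root_size) * improvement; scaled so the maximum is 100%.
    Returns (variable, percent) pairs sorted by decreasing importance,
    ties in feature-column order. Empty for a splitless tree.
    """
    root_size = tree.root.size
    raw: dict[str, float] = {}
    for node in tree.nodes():
        if node.split is not None:
            raw[node.split.variable] = raw.get(node.split.variable, 0.0) + (
                node.size / root_size
            ) * node.split.improvement
    if not raw:
        return []
    top = max(raw.values())
    order = {v: i for i, v in enumerate(tree.feature_names)}
    ranked = sorted(raw.items(), key=lambda kv: (-kv[1], order[kv[0]]))
    return [(v, 100.0 * val / top) for v, val in ranked]
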