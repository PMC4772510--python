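"""Random-forest training with non-recursive hybrid tree construction.

Decision trees are grown iteratively from an explicit frontier of unexpanded
nodes rather than by recursion.  Construction starts depth-first (the
frontier is popped last-in-first-out) and, once the number of created nodes
reaches a crossover threshold, switches to breadth-first (first-in-first-out).
The crossover value is either user-supplied or resolved from the regression

    threshold(n, f) = 3705 + 0.0577 * n + 21.84 * f

where ``n`` is the training-sample count and ``f`` the number of candidate
features per node split.  The construction order is an efficiency knob only:
each node's candidate-feature subset is keyed by the root-to-node path, so
the finished tree — and therefore every prediction — is identical for any
crossover value.  Splits maximize GINI-impurity gain; a frontier node is
finalized as a leaf once it is sufficiently pure, too small, too deep, or
admits no gainful split.  Leaf-label ties resolve to *active*, matching the
screening goal of not losing active molecules.

The ensemble is standard bagging: each tree trains on an n-with-replacement
bootstrap resample, out-of-bag row indices are recorded per tree, and
prediction is by majority vote (see :mod:`rfscreen.screening`).
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .descriptors import ACTIVE, INACTIVE, FeatureTable

__all__ = [
    "ForestParams",
    "TreeNode",
    "DecisionTree",
    "ForestModel",
    "gini_impurity",
    "best_split",
    "crossover_threshold",
    "bootstrap_sample",
    "node_feature_subset",
    "build_tree_hybrid",
    "train_forest",
]

MODEL_FORMAT_VERSION = 1

# Crossover regression coefficients (node-count threshold for the
# depth-first -> breadth-first switch), taken as given.
_CROSSOVER_INTERCEPT = 3705.0
_CROSSOVER_PER_SAMPLE = 0.0577
_CROSSOVER_PER_FEATURE = 21.84


def _derive_seed(*parts) -> int:
    """Stable 64-bit stream key from hashed parts (platform-independent)."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:8], "little")


def _rng(*parts) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(_derive_seed(*parts)))


# ---------------------------------------------------------------------------
# Parameters and tree structures
# ---------------------------------------------------------------------------

@dataclass
class ForestParams:
    """Hyper-parameters of forest construction.

    ``bfs_threshold="auto"`` resolves the depth/breadth crossover from the
    regression above at training time.  The defaults grow 50 fully developed
    trees with sqrt-of-179 = 14 candidate features per split.
    """

    n_trees: int = 50
    max_features: int = 14
    bfs_threshold: Union[str, float] = "auto"
    gini_leaf_threshold: float = 0.0
    min_gain: float = 1e-7
    min_samples_leaf: int = 1
    max_depth: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if not (0.0 <= self.gini_leaf_threshold <= 0.5):
            raise ValueError("gini_leaf_threshold must be in [0, 0.5]")
        if self.min_gain < 0:
            raise ValueError("min_gain must be >= 0")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if isinstance(self.bfs_threshold, str):
            if self.bfs_threshold != "auto":
                raise ValueError("bfs_threshold must be 'auto' or a non-negative number")
        elif self.bfs_threshold < 0:
            raise ValueError("bfs_threshold must be 'auto' or a non-negative number")

    def resolve_bfs_threshold(self, n_samples: int) -> float:
        if self.bfs_threshold == "auto":
            return crossover_threshold(n_samples, self.max_features)
        return float(self.bfs_threshold)


@dataclass
class TreeNode:
    node_id: int
    kind: str  # "internal" | "leaf"
    impurity: float
    n_samples: int
    depth: int
    feature_index: Optional[int] = None
    threshold: Optional[float] = None
    left_child: Optional[int] = None
    right_child: Optional[int] = None
    label: Optional[int] = None


@dataclass
class DecisionTree:
    """Flat node store built iteratively; root is ``nodes[root_id]``."""

    nodes: list[TreeNode]
    root_id: int
    feature_count: int
    tree_seed: int

    def as_arrays(self) -> dict[str, np.ndarray]:
        """Columnar view for vectorized traversal."""
        m = len(self.nodes)
        arr = {
            "is_leaf": np.zeros(m, dtype=bool),
            "feature": np.zeros(m, dtype=np.int64),
            "threshold": np.zeros(m, dtype=float),
            "left": np.zeros(m, dtype=np.int64),
            "right": np.zeros(m, dtype=np.int64),
            "label": np.zeros(m, dtype=np.int64),
        }
        for node in self.nodes:
            i = node.node_id
            if node.kind == "leaf":
                arr["is_leaf"][i] = True
                arr["label"][i] = node.label
            else:
                arr["feature"][i] = node.feature_index
                arr["threshold"][i] = node.threshold
                arr["left"][i] = node.left_child
                arr["right"][i] = node.right_child
        return arr


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    params: ForestParams
    feature_count: int
    class_labels: dict = field(default_factory=lambda: {"inactive": INACTIVE, "active": ACTIVE})
    training_summary: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # -- JSON schema (used by screening.save_model / load_model) -----------
    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "params": {
                "n_trees": self.params.n_trees,
                "max_features": self.params.max_features,
                "bfs_threshold": self.params.bfs_threshold,
                "gini_leaf_threshold": self.params.gini_leaf_threshold,
                "min_gain": self.params.min_gain,
                "min_samples_leaf": self.params.min_samples_leaf,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
            },
            "feature_count": self.feature_count,
            "class_labels": self.class_labels,
            "training_summary": self.training_summary,
            "trees": [
                {
                    "root_id": t.root_id,
                    "tree_seed": t.tree_seed,
                    "nodes": [
                        {
                            "node_id": n.node_id,
                            "kind": n.kind,
                            "impurity": n.impurity,
                            "n_samples": n.n_samples,
                            "depth": n.depth,
                            "feature_index": n.feature_index,
                            "threshold": n.threshold,
                            "left_child": n.left_child,
                            "right_child": n.right_child,
                            "label": n.label,
                        }
                        for n in t.nodes
                    ],
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ForestModel":
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {version!r}, expected {MODEL_FORMAT_VERSION}"
            )
        params = ForestParams(**payload["params"])
        trees = [
            DecisionTree(
                nodes=[TreeNode(**n) for n in t["nodes"]],
                root_id=t["root_id"],
                feature_count=payload["feature_count"],
                tree_seed=t["tree_seed"],
            )
            for t in payload["trees"]
        ]
        return cls(
            trees=trees,
            params=params,
            feature_count=payload["feature_count"],
            class_labels=payload.get("class_labels", {"inactive": INACTIVE, "active": ACTIVE}),
            training_summary=payload.get("training_summary", {}),
        )


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def gini_impurity(class_counts: Sequence[int]) -> float:
    """GINI impurity 1 - sum(p_i^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one sample required")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def crossover_threshold(n: float, f: float) -> float:
    """Node-count threshold for the depth-first -> breadth-first switch."""
    if n < 0 or f < 0:
        raise ValueError("n and f must be non-negative")
    return _CROSSOVER_INTERCEPT + _CROSSOVER_PER_SAMPLE * n + _CROSSOVER_PER_FEATURE * f


def bootstrap_sample(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform draws with replacement from [0, n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.integers(0, n, size=n)


def node_feature_subset(tree_seed: int, node_path_key: int, f: int, total_features: int) -> np.ndarray:
    """f distinct candidate features for one node, keyed by (tree, path).

    ``node_path_key`` is the node's index in the implicit complete binary
    tree (root 1, children 2k and 2k+1), so the subset depends only on the
    node's position — never on the order in which the frontier was consumed.
    """
    if f > total_features:
        raise ValueError("f cannot exceed the number of features")
    rng = _rng(tree_seed, "features", node_path_key)
    return np.sort(rng.choice(total_features, size=f, replace=False))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    candidate_features: Sequence[int],
    min_gain: float = 0.0,
) -> Optional[tuple[int, float, float]]:
    """Exhaustive GINI-gain maximization over candidate features.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values of each feature (for 0/1 fingerprint columns this reduces
    to the single threshold 0.5).  Returns ``(feature, threshold, gain)`` or
    ``None`` when no threshold separates the rows or the best gain is
    ``<= min_gain``.  Ties break to the lowest feature index, then the lowest
    threshold.
    """
    rows = np.asarray(rows)
    if rows.size < 2:
        raise ValueError("need at least 2 rows to split")
    if len(candidate_features) == 0:
        raise ValueError("candidate_features must be non-empty")
    yr = y[rows].astype(np.int64)
    n_tot = rows.size
    act_tot = int(yr.sum())
    parent = gini_impurity([n_tot - act_tot, act_tot])

    best: Optional[tuple[int, float, float]] = None
    for feat in sorted(int(c) for c in candidate_features):
        vals = X[rows, feat]
        order = np.argsort(vals, kind="stable")
        v = vals[order]
        lab = yr[order]
        boundary = np.nonzero(v[1:] > v[:-1])[0]
        if boundary.size == 0:
            continue
        cum_act = np.cumsum(lab)
        left_n = (boundary + 1).astype(float)
        left_act = cum_act[boundary].astype(float)
        right_n = n_tot - left_n
        right_act = act_tot - left_act
        g_left = 1.0 - ((left_act / left_n) ** 2 + ((left_n - left_act) / left_n) ** 2)
        g_right = 1.0 - ((right_act / right_n) ** 2 + ((right_n - right_act) / right_n) ** 2)
        gains = parent - (left_n * g_left + right_n * g_right) / n_tot
        k = int(np.argmax(gains))  # first max -> lowest threshold
        gain = float(gains[k])
        if best is None or gain > best[2]:
            threshold = float((v[boundary[k]] + v[boundary[k] + 1]) / 2.0)
            best = (feat, threshold, gain)
    if best is None or best[2] <= min_gain:
        return None
    return best


# ---------------------------------------------------------------------------
# Hybrid tree construction (non-recursive)
# ---------------------------------------------------------------------------

def build_tree_hybrid(
    table: FeatureTable,
    rows: np.ndarray,
    params: ForestParams,
    tree_seed: int,
) -> DecisionTree:
    """Grow one decision tree iteratively from an explicit frontier.

    The frontier (a deque of unexpanded nodes) is popped LIFO while the
    created-node count is below the crossover threshold and FIFO afterwards.
    A node becomes a leaf when its impurity is at or below
    ``gini_leaf_threshold``, it holds fewer than ``2 * min_samples_leaf``
    rows, it sits at ``max_depth``, or no split clears ``min_gain``; leaf
    labels are the majority class with ties going to *active*.
    """
    if table.labels is None:
        raise ValueError("training requires a labelled feature table")
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("bootstrap row set is empty")
    X = table.matrix
    y = table.labels
    n_features = X.shape[1]
    if params.max_features > n_features:
        raise ValueError("max_features exceeds the table's feature count")
    crossover = params.resolve_bfs_threshold(rows.size)

    nodes: list[TreeNode] = []

    def create_node(row_idx: np.ndarray, depth: int) -> int:
        counts = np.bincount(y[row_idx], minlength=2)
        node = TreeNode(
            node_id=len(nodes),
            kind="pending",
            impurity=gini_impurity(counts),
            n_samples=int(row_idx.size),
            depth=depth,
        )
        nodes.append(node)
        return node.node_id

    root_id = create_node(rows, 0)
    # frontier entries: (node_id, row indices, heap path key)
    frontier: deque[tuple[int, np.ndarray, int]] = deque([(root_id, rows, 1)])

    while frontier:
        depth_first = len(nodes) < crossover
        node_id, row_idx, path = frontier.pop() if depth_first else frontier.popleft()
        node = nodes[node_id]
        counts = np.bincount(y[row_idx], minlength=2)

        split = None
        is_leaf = (
            node.impurity <= params.gini_leaf_threshold
            or row_idx.size < 2 * params.min_samples_leaf
            or (params.max_depth is not None and node.depth >= params.max_depth)
        )
        if not is_leaf:
            feats = node_feature_subset(tree_seed, path, params.max_features, n_features)
            split = best_split(X, y, row_idx, feats, params.min_gain)
            is_leaf = split is None

        if is_leaf:
            node.kind = "leaf"
            node.label = ACTIVE if counts[ACTIVE] >= counts[INACTIVE] else INACTIVE
        else:
            feat, threshold, _gain = split
            go_left = X[row_idx, feat] <= threshold
            left_rows = row_idx[go_left]
            right_rows = row_idx[~go_left]
            node.kind = "internal"
            node.feature_index = feat
            node.threshold = threshold
            left_id = create_node(left_rows, node.depth + 1)
            right_id = create_node(right_rows, node.depth + 1)
            node.left_child = left_id
            node.right_child = right_id
            frontier.append((left_id, left_rows, 2 * path))
            frontier.append((right_id, right_rows, 2 * path + 1))

    return DecisionTree(nodes=nodes, root_id=root_id, feature_count=n_features, tree_seed=tree_seed)


def train_forest(table: FeatureTable, params: ForestParams) -> ForestModel:
    """Bagging: one bootstrap resample and one hybrid-built tree per seed.

    Tree seeds are derived from ``(params.seed, tree_index)``, so trees are
    independent and the model is a pure function of (table, params) whatever
    the execution order.  Out-of-bag row indices are recorded per tree.
    """
    if table.labels is None:
        raise ValueError("training requires a labelled feature table")
    class_counts = np.bincount(table.labels, minlength=2)
    if np.any(class_counts == 0):
        raise ValueError("training set must contain both active and inactive compounds")

    n = table.n
    trees: list[DecisionTree] = []
    oob_indices: list[list[int]] = []
    for t in range(1, params.n_trees + 1):
        tree_seed = _derive_seed(params.seed, "tree", t)
        boot = bootstrap_sample(n, _rng(params.seed, "bootstrap", t))
        trees.append(build_tree_hybrid(table, boot, params, tree_seed))
        oob_indices.append(sorted(set(range(n)) - set(boot.tolist())))

    summary = {
        "n": int(n),
        "class_counts": {"inactive": int(class_counts[INACTIVE]), "active": int(class_counts[ACTIVE])},
        "bfs_threshold_resolved": params.resolve_bfs_threshold(n),
        "oob_indices": oob_indices,
    }
    return ForestModel(trees=trees, params=params, feature_count=table.matrix.shape[1], training_summary=summary)
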