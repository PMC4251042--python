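"""From-scratch random forest for binary classification with probability output.

Trees are grown by greedy information gain (entropy in bits); each tree of a
forest is trained on a bootstrap replicate of the data, with random feature
subsets drawn either afresh at every split (``per_split``, the classic
random-forest rule and the default) or once per tree (``per_tree``).  The
forest's class probability is the plain arithmetic mean of the per-tree leaf
probabilities, and the predicted class is the argmax, with an exact 0.5 tie
going to class 0 (the majority/negative class in fold recognition, where
negatives outnumber positives by two orders of magnitude).

Models serialise to a self-describing JSON document; save -> load -> predict
is bit-exact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._kernels import grow_tree
from .io import atomic_write_text

__all__ = [
    "entropy",
    "information_gain",
    "ForestParams",
    "DecisionTree",
    "Forest",
    "train_tree",
    "predict_tree",
    "train_forest",
    "predict_forest",
]

FORMAT_NAME = "foldrec-forest"
FORMAT_VERSION = 1


def entropy(class_counts) -> float:
    """Shannon entropy in bits of a class-count vector.

    For two classes the result lies in [0, 1].  Raises if every count is
    zero or any count is negative.
    """
    c = np.asarray(class_counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative class count")
    n = c.sum()
    if n == 0:
        raise ValueError("entropy undefined for all-zero counts")
    p = c[c > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_counts, left_counts, right_counts) -> float:
    """entropy(parent) minus the size-weighted mean child entropy (>= 0)."""
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.array_equal(left + right, parent):
        raise ValueError("left + right counts must equal parent counts")
    n = parent.sum()
    gain = entropy(parent)
    for child in (left, right):
        if child.sum() > 0:
            gain -= child.sum() / n * entropy(child)
    return float(gain)


@dataclass
class ForestParams:
    """Training hyper-parameters.

    ``n_features_sampled=None`` means ceil(sqrt(p)), the standard
    classification default.  ``max_depth=None`` grows trees to purity.
    """

    n_trees: int = 500
    feature_sampling: str = "per_split"  # or "per_tree"
    n_features_sampled: int | None = None
    bootstrap: bool = True
    min_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0

    def validate(self, n_features: int | None = None) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.feature_sampling not in ("per_split", "per_tree"):
            raise ValueError(
                f"unknown feature_sampling mode {self.feature_sampling!r}"
            )
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")
        if self.n_features_sampled is not None:
            if self.n_features_sampled < 1:
                raise ValueError("n_features_sampled must be >= 1")
            if n_features is not None and self.n_features_sampled > n_features:
                raise ValueError(
                    "n_features_sampled exceeds the feature dimension"
                )

    def resolved_k(self, n_features: int) -> int:
        if self.n_features_sampled is not None:
            return min(self.n_features_sampled, n_features)
        return math.ceil(math.sqrt(n_features))


class DecisionTree:
    """A trained tree stored as flat node arrays.

    ``feature[i] == -1`` marks a leaf; internal node ``i`` routes samples
    with ``x[feature[i]] <= threshold[i]`` to ``left[i]`` (boundary values
    inclusive) and the rest to ``right[i]``.  ``probs[i]`` holds the
    training-sample class fractions of the node.
    """

    def __init__(self, feature, threshold, left, right, probs,
                 n_features: int, trained_feature_indices=None):
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.probs = np.asarray(probs, dtype=np.float64)
        self.n_features = int(n_features)
        if trained_feature_indices is None:
            trained_feature_indices = np.arange(n_features)
        self.trained_feature_indices = np.asarray(
            trained_feature_indices, dtype=np.int64
        )
        internal = self.feature >= 0
        if np.any(self.feature[internal] >= self.n_features):
            raise ValueError("node references a feature outside the training dimension")

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Leaf class-probability vectors for a (n, p) matrix of inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input has {X.shape[1]} features, tree was trained on {self.n_features}"
            )
        node = np.zeros(len(X), dtype=np.int64)
        rows = np.arange(len(X))
        while True:
            f = self.feature[node]
            active = f >= 0
            if not active.any():
                break
            r = rows[active]
            go_left = X[r, f[active]] <= self.threshold[node[active]]
            node[active] = np.where(
                go_left, self.left[node[active]], self.right[node[active]]
            )
        return self.probs[node]

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "probs": self.probs.tolist(),
            "n_features": self.n_features,
            "trained_feature_indices": self.trained_feature_indices.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(
            d["feature"], d["threshold"], d["left"], d["right"], d["probs"],
            d["n_features"], d["trained_feature_indices"],
        )


def _prepare_xy(X, y):
    X = np.ascontiguousarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature matrix")
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(X) == 0:
        raise ValueError("cannot train on zero samples")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return X, np.ascontiguousarray(y, dtype=np.int8)


def train_tree(
    X,
    y,
    params: ForestParams | None = None,
    seed: int | None = None,
    feature_subset=None,
) -> DecisionTree:
    """Train one tree on the given samples (no bootstrap at this level).

    In ``per_tree`` mode the tree's fixed feature subset is either supplied
    via ``feature_subset`` or drawn here from ``seed``.  ``seed`` defaults
    to ``params.seed``.
    """
    params = params or ForestParams(n_trees=1)
    X, y = _prepare_xy(X, y)
    p = X.shape[1]
    params.validate(p)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    k = params.resolved_k(p)
    per_split = params.feature_sampling == "per_split"
    if per_split:
        candidates = np.arange(p, dtype=np.int64)
        trained = np.arange(p, dtype=np.int64)
    else:
        if feature_subset is None:
            feature_subset = np.sort(rng.choice(p, size=k, replace=False))
        candidates = np.asarray(feature_subset, dtype=np.int64)
        trained = candidates
    kernel_seed = int(rng.integers(2**32))
    max_depth = -1 if params.max_depth is None else params.max_depth
    feat, thr, left, right, probs = grow_tree(
        X, y, candidates, per_split, k, params.min_leaf, max_depth, kernel_seed
    )
    return DecisionTree(feat, thr, left, right, probs, p, trained)


def predict_tree(tree: DecisionTree, v) -> np.ndarray:
    """Class-probability vector of the leaf reached by a single input."""
    return tree.predict_proba(np.asarray(v, dtype=float).reshape(1, -1))[0]


class Forest:
    """An ensemble of decision trees with averaged probability output."""

    def __init__(self, trees: list[DecisionTree], params: ForestParams,
                 feature_names: list[str] | None = None):
        self.trees = trees
        self.params = params
        self.feature_names = list(feature_names) if feature_names else None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the per-tree class-probability vectors, shape (n, 2)."""
        if not self.trees:
            raise ValueError("empty forest")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        acc = np.zeros((len(X), 2))
        for tree in self.trees:
            acc += tree.predict_proba(X)
        return acc / len(self.trees)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(P(class 1 | v), predicted class); ties at 0.5 go to class 0."""
        p1 = self.predict_proba(X)[:, 1]
        return p1, (p1 > 0.5).astype(np.int64)

    def save(self, path) -> None:
        doc = {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "params": {
                "n_trees": self.params.n_trees,
                "feature_sampling": self.params.feature_sampling,
                "n_features_sampled": self.params.n_features_sampled,
                "bootstrap": self.params.bootstrap,
                "min_leaf": self.params.min_leaf,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
            },
            "feature_names": self.feature_names,
            "trees": [t.to_dict() for t in self.trees],
        }
        atomic_write_text(path, json.dumps(doc))

    @classmethod
    def load(cls, path) -> "Forest":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != FORMAT_NAME:
            raise ValueError(f"{path}: not a {FORMAT_NAME} model file")
        params = ForestParams(**doc["params"])
        trees = [DecisionTree.from_dict(d) for d in doc["trees"]]
        return cls(trees, params, doc.get("feature_names"))


def train_forest(
    X, y, params: ForestParams | None = None, feature_names: list[str] | None = None
) -> Forest:
    """Train ``params.n_trees`` trees on bootstrap replicates of (X, y).

    Each tree draws its bootstrap sample, its feature subset (per-tree mode)
    and its split-sampling stream from an independent RNG stream derived
    from ``(params.seed, tree_index)``, so training is reproducible and
    independent of execution order.
    """
    params = params or ForestParams()
    X, y = _prepare_xy(X, y)
    if len(X) < 2:
        raise ValueError("need at least 2 samples to train a forest")
    p = X.shape[1]
    params.validate(p)
    if len(np.unique(y)) < 2:
        warnings.warn("training data contains a single class", stacklevel=2)
    n = len(X)
    trees: list[DecisionTree] = []
    children = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    for child in children:
        rng = np.random.default_rng(child)
        if params.bootstrap:
            boot = rng.integers(0, n, size=n)
            Xb, yb = np.ascontiguousarray(X[boot]), np.ascontiguousarray(y[boot])
        else:
            Xb, yb = X, y
        tree_seed = int(rng.integers(2**31))
        trees.append(train_tree(Xb, yb, params, seed=tree_seed))
    return Forest(trees, params, feature_names)


def predict_forest(forest: Forest, v) -> tuple[float, int]:
    """(P(class 1 | v), predicted class) for a single feature vector."""
    p1, cls = forest.predict(np.asarray(v, dtype=float).reshape(1, -1))
    return float(p1[0]), int(cls[0])
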