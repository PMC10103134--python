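"""From-scratch random forest with entropy (information gain) splitting.

Binary CART trees are grown on bootstrap resamples; at every node
``max(1, floor(sqrt(k)))`` candidate features are drawn without replacement,
where ``k`` is the total number of features in the training matrix.  The
ensemble predicts by majority vote; the *confidence* of a prediction is the
fraction of trees voting for the returned class, and generalisation is
estimated by the out-of-bag (OOB) error.

Classes are handled in sorted order and an exact vote tie resolves to the
first class — for boolean motif labels that is ``False`` (motif absent).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from ._cart import LEAF, _grow_forest, _predict_votes, _scan_split

__all__ = [
    "ForestConfig",
    "DecisionNode",
    "ForestModel",
    "Prediction",
    "entropy",
    "best_split",
    "grow_tree",
    "train_forest",
    "predict",
    "oob_error",
]


@dataclass
class ForestConfig:
    """Hyperparameters of the forest.

    ``features_per_node_rule`` currently supports only ``"sqrt"``:
    max(1, floor(√k)) candidate features per node.  ``max_depth`` of ``None``
    grows trees until purity or ``min_samples_split``.
    """

    n_trees: int = 100
    features_per_node_rule: str = "sqrt"
    max_depth: int | None = None
    min_samples_split: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.features_per_node_rule != "sqrt":
            raise ValueError("only the 'sqrt' features-per-node rule is supported")

    def candidates_for(self, k: int) -> int:
        return max(1, int(math.floor(math.sqrt(k))))


@dataclass
class DecisionNode:
    """Nested view of one tree node (internal split or leaf)."""

    feature_index: int | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None
    class_counts: dict | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature_index is None


@dataclass(frozen=True)
class Prediction:
    label: object
    confidence: float


class UndefinedOOBError(ValueError):
    """No sample is out-of-bag for any tree."""


def entropy(class_counts: Mapping[object, float] | Sequence[float]) -> float:
    """Shannon entropy in bits, −Σ pᵢ log₂ pᵢ over nonzero classes."""
    if isinstance(class_counts, Mapping):
        counts = np.array(list(class_counts.values()), dtype=float)
    else:
        counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy undefined for empty count set")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def best_split(
    X: np.ndarray, y: np.ndarray, candidate_features: Sequence[int]
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, information gain) over the candidates.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties break toward the lower feature index, then the lower threshold.
    Returns ``None`` when no split has positive gain.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y01 = np.ascontiguousarray(y, dtype=np.int8)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to split")
    cand = np.sort(np.asarray(candidate_features, dtype=np.int64))
    if cand.size == 0:
        raise ValueError("need at least one candidate feature")
    samples = np.arange(X.shape[0], dtype=np.int64)
    f, t, g = _scan_split(X, y01, samples, 0, X.shape[0], cand, cand.size)
    if f == LEAF:
        return None
    return int(f), float(t), float(g)


@dataclass
class ForestModel:
    """A trained forest: flat per-tree node arrays plus bootstrap bookkeeping."""

    config: ForestConfig
    classes_: list
    n_features: int
    feat: np.ndarray  # (n_trees, max_nodes) int32, LEAF for leaves
    thr: np.ndarray
    left: np.ndarray
    right: np.ndarray
    cnt0: np.ndarray
    cnt1: np.ndarray
    node_counts: np.ndarray
    bootstrap_indices: np.ndarray  # (n_trees, m)
    n_train: int

    FORMAT_VERSION = 1

    # -- structure -----------------------------------------------------
    @property
    def n_trees(self) -> int:
        return self.feat.shape[0]

    def oob_indices(self, tree: int) -> np.ndarray:
        """Training-row indices not drawn into ``tree``'s bootstrap sample."""
        mask = np.ones(self.n_train, dtype=bool)
        mask[self.bootstrap_indices[tree]] = False
        return np.flatnonzero(mask)

    def tree_root(self, tree: int) -> DecisionNode:
        """Nested :class:`DecisionNode` view of one tree."""

        def build(node: int) -> DecisionNode:
            counts = {self.classes_[0]: int(self.cnt0[tree, node])}
            if len(self.classes_) > 1:
                counts[self.classes_[1]] = int(self.cnt1[tree, node])
            if self.feat[tree, node] == LEAF:
                return DecisionNode(class_counts=counts)
            return DecisionNode(
                feature_index=int(self.feat[tree, node]),
                threshold=float(self.thr[tree, node]),
                left=build(int(self.left[tree, node])),
                right=build(int(self.right[tree, node])),
                class_counts=counts,
            )

        return build(0)

    # -- inference -----------------------------------------------------
    def votes(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature vector length {X.shape[1]} != model feature count "
                f"{self.n_features}"
            )
        return _predict_votes(self.feat, self.thr, self.left, self.right, self.cnt0, self.cnt1, X)

    def predict_one(self, features: np.ndarray) -> Prediction:
        votes = self.votes(np.asarray(features, dtype=float).reshape(1, -1))[0]
        n1 = int(votes.sum())
        n0 = votes.size - n1
        winner = 0 if n0 >= n1 else 1  # tie -> first (negative) class
        conf = (n0 if winner == 0 else n1) / votes.size
        label = self.classes_[winner] if winner < len(self.classes_) else self.classes_[0]
        return Prediction(label=label, confidence=float(conf))

    def predict_many(self, X: np.ndarray) -> list[Prediction]:
        return [self.predict_one(row) for row in np.atleast_2d(X)]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        nt = self.n_trees
        trees = []
        for t in range(nt):
            nn = int(self.node_counts[t])
            trees.append(
                {
                    "feature": self.feat[t, :nn].tolist(),
                    "threshold": [float(v) for v in self.thr[t, :nn]],
                    "left": self.left[t, :nn].tolist(),
                    "right": self.right[t, :nn].tolist(),
                    "count0": self.cnt0[t, :nn].tolist(),
                    "count1": self.cnt1[t, :nn].tolist(),
                }
            )
        return {
            "format_version": self.FORMAT_VERSION,
            "config": asdict(self.config),
            "classes": [_json_label(c) for c in self.classes_],
            "n_features": self.n_features,
            "n_train": self.n_train,
            "bootstrap_indices": self.bootstrap_indices.tolist(),
            "trees": trees,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    def digest(self) -> str:
        """SHA-256 of the canonical JSON serialization."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "ForestModel":
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {d.get('format_version')}")
        trees = d["trees"]
        nt = len(trees)
        max_nodes = max(len(t["feature"]) for t in trees)
        feat = np.full((nt, max_nodes), LEAF, dtype=np.int32)
        thr = np.zeros((nt, max_nodes))
        left = np.full((nt, max_nodes), LEAF, dtype=np.int32)
        right = np.full((nt, max_nodes), LEAF, dtype=np.int32)
        cnt0 = np.zeros((nt, max_nodes), dtype=np.int32)
        cnt1 = np.zeros((nt, max_nodes), dtype=np.int32)
        node_counts = np.zeros(nt, dtype=np.int64)
        for t, tree in enumerate(trees):
            nn = len(tree["feature"])
            node_counts[t] = nn
            feat[t, :nn] = tree["feature"]
            thr[t, :nn] = tree["threshold"]
            left[t, :nn] = tree["left"]
            right[t, :nn] = tree["right"]
            cnt0[t, :nn] = tree["count0"]
            cnt1[t, :nn] = tree["count1"]
        return cls(
            config=ForestConfig(**d["config"]),
            classes_=[_unjson_label(c) for c in d["classes"]],
            n_features=int(d["n_features"]),
            feat=feat,
            thr=thr,
            left=left,
            right=right,
            cnt0=cnt0,
            cnt1=cnt1,
            node_counts=node_counts,
            bootstrap_indices=np.asarray(d["bootstrap_indices"], dtype=np.int64),
            n_train=int(d["n_train"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "ForestModel":
        return cls.from_dict(json.loads(s))


def _json_label(c: object) -> object:
    if isinstance(c, (bool, np.bool_)):
        return bool(c)
    if isinstance(c, (int, np.integer)):
        return int(c)
    return str(c)


def _unjson_label(c: object) -> object:
    return c


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: ForestConfig | None = None,
    seed: int | None = None,
) -> ForestModel:
    """Grow a single CART tree on all rows (no bootstrap).

    Returned as a one-tree :class:`ForestModel` so the usual prediction and
    serialization machinery applies; inspect the structure via
    :meth:`ForestModel.tree_root`.
    """
    config = config or ForestConfig(n_trees=1)
    cfg = ForestConfig(
        n_trees=1,
        features_per_node_rule=config.features_per_node_rule,
        max_depth=config.max_depth,
        min_samples_split=config.min_samples_split,
        seed=config.seed if seed is None else seed,
    )
    return _fit(X, y, cfg, bootstrap=False)


def train_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig | None = None) -> ForestModel:
    """Train a forest with bootstrap aggregation (seeded, reproducible)."""
    return _fit(X, y, config or ForestConfig(), bootstrap=True)


def _fit(X: np.ndarray, y: np.ndarray, config: ForestConfig, bootstrap: bool) -> ForestModel:
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.asarray(y)
    n, k = X.shape
    if n < 1 or y.shape[0] != n:
        raise ValueError("X and y must have matching, non-empty first dimensions")
    classes = sorted(set(_json_label(v) for v in y.tolist()))
    if len(classes) > 2:
        raise ValueError("only binary classification is supported")
    if len(classes) == 1:
        warnings.warn(
            "training labels contain a single class; forest degenerates to "
            "one-leaf trees",
            stacklevel=2,
        )
    index = {c: i for i, c in enumerate(classes)}
    y01 = np.array([index[_json_label(v)] for v in y.tolist()], dtype=np.int8)

    rng = np.random.default_rng(config.seed)
    nt = config.n_trees
    if bootstrap:
        boot = rng.integers(0, n, size=(nt, n), dtype=np.int64)
    else:
        boot = np.tile(np.arange(n, dtype=np.int64), (nt, 1))
    seeds = rng.integers(0, 2**63, size=nt, dtype=np.uint64)

    max_nodes = 2 * n + 1
    feat = np.full((nt, max_nodes), LEAF, dtype=np.int32)
    thr = np.zeros((nt, max_nodes))
    left = np.full((nt, max_nodes), LEAF, dtype=np.int32)
    right = np.full((nt, max_nodes), LEAF, dtype=np.int32)
    cnt0 = np.zeros((nt, max_nodes), dtype=np.int32)
    cnt1 = np.zeros((nt, max_nodes), dtype=np.int32)
    node_counts = np.zeros(nt, dtype=np.int64)

    max_depth = -1 if config.max_depth is None else int(config.max_depth)
    _grow_forest(
        X,
        y01,
        boot,
        seeds,
        config.candidates_for(k),
        max_depth,
        config.min_samples_split,
        feat,
        thr,
        left,
        right,
        cnt0,
        cnt1,
        node_counts,
    )
    return ForestModel(
        config=config,
        classes_=classes,
        n_features=k,
        feat=feat,
        thr=thr,
        left=left,
        right=right,
        cnt0=cnt0,
        cnt1=cnt1,
        node_counts=node_counts,
        bootstrap_indices=boot,
        n_train=n,
    )


def predict(model: ForestModel, features: np.ndarray) -> Prediction:
    """Majority-vote prediction with vote-fraction confidence."""
    return model.predict_one(features)


def oob_error(model: ForestModel, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag misclassification rate.

    Each training sample is predicted by majority vote of the trees whose
    bootstrap sample omitted it; samples in-bag for every tree are excluded
    from the rate.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.asarray(y)
    votes = model.votes(X)  # (n, n_trees) in {0,1}
    index = {c: i for i, c in enumerate(model.classes_)}
    y01 = np.array([index[_json_label(v)] for v in y.tolist()])

    inbag = np.zeros((model.n_trees, X.shape[0]), dtype=bool)
    for t in range(model.n_trees):
        drawn = model.bootstrap_indices[t]
        inbag[t, drawn[drawn < X.shape[0]]] = True

    wrong = 0
    evaluable = 0
    for i in range(X.shape[0]):
        oob_trees = np.flatnonzero(~inbag[:, i])
        if oob_trees.size == 0:
            continue
        v = votes[i, oob_trees]
        n1 = int(v.sum())
        n0 = v.size - n1
        pred = 0 if n0 >= n1 else 1
        evaluable += 1
        wrong += int(pred != y01[i])
    if evaluable == 0:
        raise UndefinedOOBError("no sample is out-of-bag for any tree")
    return wrong / evaluable
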