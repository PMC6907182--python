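"""Neutral boosted-tree-ensemble representation.

The interpretation layer never touches the training library directly; it
consumes this representation: a base score in margin (log-odds) units plus a
list of binary trees whose nodes carry a split feature, a threshold, a cover
(training samples reaching the node) and, at the leaves, an additive value.
The routing rule is fixed: a sample goes left iff ``x[feature] < threshold``.
The ensemble margin is ``base_score + sum of leaf values along each tree's
path``; the predicted class is *increase* iff the margin is positive.

Feature matrices here are complete by construction, so the representation
deliberately has no missing-value default direction; importing a serialised
ensemble that carries one is rejected.

Numerical note: thresholds and leaf values originating from gradient-boosting
libraries are float32.  Routing therefore casts inputs to float32.  Margins
accumulate in float64 by default (the reference for attribution
conservation); ``dtype=np.float32`` accumulates exactly like the backing
booster and is used for export-fidelity checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Tree", "TreeEnsemble", "random_ensemble"]

_FORBIDDEN_NODE_KEYS = {"default_left", "default_child", "missing"}


@dataclass
class Tree:
    """One binary tree in flat-array form; ``feature[i] == -1`` marks a leaf."""

    feature: np.ndarray      # int, -1 at leaves
    threshold: np.ndarray    # float64 (float32-exact values)
    left: np.ndarray         # int, -1 at leaves
    right: np.ndarray
    cover: np.ndarray        # float64, >= 0
    leaf_value: np.ndarray   # float64, 0 at internal nodes

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def is_leaf(self, node: int) -> bool:
        return self.feature[node] == -1

    def validate(self, n_features: int) -> None:
        internal = self.feature >= 0
        if np.any((self.feature >= n_features) & internal):
            raise ValueError("tree references a feature outside the ensemble's space")
        if np.any((self.left[internal] < 0) | (self.right[internal] < 0)):
            raise ValueError("internal node lacking two children")
        nodes = np.flatnonzero(internal)
        if np.any(self.left[nodes] <= nodes) or np.any(self.right[nodes] <= nodes):
            raise ValueError("children must have larger node ids than their parent")
        if np.any(self.cover < 0):
            raise ValueError("negative cover")
        kids = self.cover[self.left[internal]] + self.cover[self.right[internal]]
        parent = self.cover[internal]
        bad = np.abs(kids - parent) > 1e-6 * np.maximum(parent, 1.0)
        if bad.any():
            raise ValueError("cover not additive: cover(node) != cover(left)+cover(right)")

    def expected_values(self) -> np.ndarray:
        """Cover-weighted expected leaf value below each node (bottom-up)."""
        ev = np.array(self.leaf_value, dtype=np.float64)
        # children always have larger ids than parents in our construction and
        # in xgboost dumps; a reversed sweep is a valid bottom-up order.
        for node in range(self.n_nodes - 1, -1, -1):
            if self.feature[node] >= 0:
                l, r = self.left[node], self.right[node]
                cl, cr = self.cover[l], self.cover[r]
                total = cl + cr
                ev[node] = (cl * ev[l] + cr * ev[r]) / total if total > 0 else 0.5 * (ev[l] + ev[r])
        return ev

    def leaf_of(self, X32: np.ndarray) -> np.ndarray:
        """Leaf index for each row of a float32 matrix (vectorised routing)."""
        node = np.zeros(len(X32), dtype=np.int64)
        thr32 = self.threshold.astype(np.float32)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X32[idx, self.feature[cur]] < thr32[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
            active[idx] = self.feature[node[idx]] >= 0
        return node


@dataclass
class TreeEnsemble:
    base_score: float
    feature_names: list[str]
    trees: list[Tree] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._name_to_idx = {n: i for i, n in enumerate(self.feature_names)}
        for tree in self.trees:
            tree.validate(len(self.feature_names))

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _as_float32(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"sample lacks feature {missing[0]!r} referenced by the ensemble")
            X = X[self.feature_names].to_numpy()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError("sample width does not match the ensemble's feature space")
        return X

    def margin(self, X: pd.DataFrame | np.ndarray, dtype=np.float64) -> np.ndarray:
        """Raw additive score; predicted class is increase iff margin > 0."""
        X32 = self._as_float32(X)
        out = np.full(len(X32), self.base_score, dtype=dtype)
        for tree in self.trees:
            out += tree.leaf_value[tree.leaf_of(X32)].astype(dtype)
        return out.astype(np.float64)

    def predict_increase(self, X) -> np.ndarray:
        return (self.margin(X) > 0).astype(int)

    # -- decision paths ----------------------------------------------------

    def paths(self) -> Iterator[list[tuple[int, str, float]]]:
        """Yield every root-to-leaf path of every tree.

        Each path is a list of ``(feature_index, side, threshold)`` with side
        ``"<"`` (went left) or ``">="`` (went right).
        """
        for tree in self.trees:
            stack: list[tuple[int, list]] = [(0, [])]
            while stack:
                node, constraints = stack.pop()
                if tree.is_leaf(node):
                    yield constraints
                    continue
                f, t = int(tree.feature[node]), float(tree.threshold[node])
                stack.append((int(tree.right[node]), constraints + [(f, ">=", t)]))
                stack.append((int(tree.left[node]), constraints + [(f, "<", t)]))

    # -- serialisation -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        def tree_dict(tree: Tree) -> dict:
            return {
                "feature": [self.feature_names[f] if f >= 0 else None for f in tree.feature],
                "threshold": [float(x) for x in tree.threshold],
                "left": tree.left.tolist(),
                "right": tree.right.tolist(),
                "cover": [float(x) for x in tree.cover],
                "leaf_value": [float(x) for x in tree.leaf_value],
            }

        text = json.dumps(
            {
                "base_score": float(self.base_score),
                "feature_names": self.feature_names,
                "routing": "left iff value < threshold",
                "trees": [tree_dict(t) for t in self.trees],
            }
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TreeEnsemble":
        text = Path(source).read_text() if isinstance(source, Path) else source
        obj = json.loads(text)
        names = obj["feature_names"]
        idx = {n: i for i, n in enumerate(names)}
        trees = []
        for t in obj["trees"]:
            bad = _FORBIDDEN_NODE_KEYS & set(t)
            if bad:
                raise ValueError(
                    f"ensemble JSON carries missing-value routing field {sorted(bad)[0]!r}; "
                    "this representation requires complete feature matrices"
                )
            trees.append(
                Tree(
                    feature=np.array([idx[f] if f is not None else -1 for f in t["feature"]]),
                    threshold=np.array(t["threshold"], dtype=np.float64),
                    left=np.array(t["left"], dtype=np.int64),
                    right=np.array(t["right"], dtype=np.int64),
                    cover=np.array(t["cover"], dtype=np.float64),
                    leaf_value=np.array(t["leaf_value"], dtype=np.float64),
                )
            )
        return cls(base_score=float(obj["base_score"]), feature_names=list(names), trees=trees)

    # -- import from xgboost ------------------------------------------------

    @classmethod
    def from_xgboost(cls, booster, feature_names: Sequence[str]) -> "TreeEnsemble":
        """Build from an ``xgboost.Booster`` trained with ``binary:logistic``.

        Uses the native JSON model dump, whose thresholds and leaf values are
        exact float32.  The stored ``base_score`` is a probability and enters
        the margin through its logit.
        """
        raw = json.loads(bytearray(booster.save_raw(raw_format="json")))
        learner = raw["learner"]
        base_prob = float(learner["learner_model_param"]["base_score"])
        base_margin = math.log(base_prob / (1.0 - base_prob))
        trees = []
        for t in learner["gradient_booster"]["model"]["trees"]:
            lc = np.array(t["left_children"], dtype=np.int64)
            rc = np.array(t["right_children"], dtype=np.int64)
            sc = np.array(t["split_conditions"], dtype=np.float32).astype(np.float64)
            si = np.array(t["split_indices"], dtype=np.int64)
            leaf = lc == -1
            trees.append(
                Tree(
                    feature=np.where(leaf, -1, si),
                    threshold=np.where(leaf, 0.0, sc),
                    left=lc,
                    right=rc,
                    cover=np.array(t["sum_hessian"], dtype=np.float64),
                    leaf_value=np.where(leaf, sc, 0.0),
                )
            )
        return cls(base_score=base_margin, feature_names=list(feature_names), trees=trees)


def random_ensemble(
    n_trees: int,
    depth: int,
    feature_names: Sequence[str],
    seed: int,
    base_score: float = 0.0,
    root_cover: float = 1000.0,
) -> TreeEnsemble:
    """Random full-binary-tree ensemble for tests and calibration checks.

    Thresholds are float32-exact; covers split each node's cover by a random
    fraction so cover additivity holds exactly.
    """
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        feature, threshold, left, right, cover, leaf_value = [], [], [], [], [], []

        def grow(level: int, node_cover: float) -> int:
            node = len(feature)
            if level == depth:
                feature.append(-1)
                threshold.append(0.0)
                left.append(-1)
                right.append(-1)
                cover.append(node_cover)
                leaf_value.append(float(np.float32(rng.normal(scale=0.5))))
                return node
            feature.append(int(rng.integers(len(feature_names))))
            threshold.append(float(np.float32(rng.normal())))
            left.append(-1)
            right.append(-1)
            cover.append(node_cover)
            leaf_value.append(0.0)
            frac = rng.uniform(0.2, 0.8)
            left[node] = grow(level + 1, node_cover * frac)
            right[node] = grow(level + 1, node_cover * (1 - frac))
            return node

        grow(0, root_cover)
        trees.append(
            Tree(
                feature=np.array(feature),
                threshold=np.array(threshold),
                left=np.array(left),
                right=np.array(right),
                cover=np.array(cover),
                leaf_value=np.array(leaf_value),
            )
        )
    return TreeEnsemble(base_score=base_score, feature_names=list(feature_names), trees=trees)
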