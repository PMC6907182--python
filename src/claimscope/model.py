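"""Cost-change classifiers: logistic regression, boosted trees, a small
feedforward network -- organised as a Model / Results pair.

:class:`CostChangeModel` wraps a :class:`~claimscope.cohort.LabeledSplit`
and a :class:`TrainConfig`; ``fit()`` returns a :class:`CostChangeResults`
that carries the fitted classifier, per-partition accuracy/AUC reports, a
``summary()`` table, and (for the boosted model) ``export_ensemble()`` into
the neutral :class:`~claimscope.ensemble.TreeEnsemble` the interpretation
layer consumes.

Accuracy is the fraction of samples whose thresholded probability (> 0.5)
matches the label, reported in percent.  AUC is the rank-based (Mann-Whitney)
probability that a random increase-patient scores above a random
decrease-patient, ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import LabeledSplit, build_labeled_split
from .ensemble import TreeEnsemble
from .synthetic import ClaimsBundle

__all__ = [
    "TrainConfig",
    "ModelReport",
    "CostChangeModel",
    "CostChangeResults",
    "accuracy_pct",
    "rank_auc",
    "stepwise_experiment",
    "DEFAULT_PLAN",
]


def accuracy_pct(y: np.ndarray, prob: np.ndarray) -> float:
    """Percent of samples with (prob > 0.5) equal to the binary label."""
    return 100.0 * float(np.mean((prob > 0.5).astype(int) == y))


def rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = scipy.stats.rankdata(score)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; all explicit because the method is seed-reproducible.

    ``kind`` is one of ``"lr"`` (L2 logistic regression), ``"bdt"``
    (gradient-boosted trees) or ``"fnn"`` (one-hidden-layer network; used for
    model comparison only, never for interpretation).
    """

    kind: str = "bdt"
    n_trees: int = 300
    max_depth: int = 5
    learning_rate: float = 0.1
    min_child_weight: float = 30.0    # hessian mass per leaf; curbs overfitting
    colsample_bytree: float = 0.8     # feature subsampling; decorrelates trees so
                                      # correlated markers all get used somewhere
    l2_strength: float = 1.0          # LR inverse-regularisation C
    hidden_width: int = 64
    max_iter: int = 200               # FNN epochs / LR solver iterations
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lr", "bdt", "fnn"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @classmethod
    def bdt(cls, n_trees: int = 300, max_depth: int = 5, learning_rate: float = 0.1,
            min_child_weight: float = 30.0, colsample_bytree: float = 0.8,
            train_seed: int = 0):
        return cls(kind="bdt", n_trees=n_trees, max_depth=max_depth,
                   learning_rate=learning_rate, min_child_weight=min_child_weight,
                   colsample_bytree=colsample_bytree, train_seed=train_seed)

    @classmethod
    def lr(cls, l2_strength: float = 1.0, train_seed: int = 0):
        return cls(kind="lr", l2_strength=l2_strength, train_seed=train_seed, max_iter=2000)

    @classmethod
    def fnn(cls, hidden_width: int = 64, max_iter: int = 200, train_seed: int = 0):
        return cls(kind="fnn", hidden_width=hidden_width, max_iter=max_iter, train_seed=train_seed)


@dataclass
class ModelReport:
    model_kind: str
    feature_sets: tuple[str, ...]
    n_features: int
    partition: str
    accuracy: float   # percent
    auc: float


class CostChangeModel:
    """Binary increase/decrease classifier over a labelled, partitioned cohort."""

    def __init__(self, split: LabeledSplit, config: TrainConfig | None = None):
        self.split = split
        self.config = config or TrainConfig()

    @classmethod
    def from_bundle(
        cls,
        bundle: ClaimsBundle,
        sets: Sequence[str],
        split_seed: int = 0,
        config: TrainConfig | None = None,
        **kwargs,
    ) -> "CostChangeModel":
        return cls(build_labeled_split(bundle, sets, split_seed, **kwargs), config)

    def fit(self) -> "CostChangeResults":
        X, y = self.split.Xy("train")
        if len(X) == 0:
            raise ValueError("training partition is empty")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        cfg = self.config
        if cfg.kind == "bdt":
            dtrain = xgb.DMatrix(X.to_numpy(np.float32), label=y,
                                 feature_names=list(X.columns))
            booster = xgb.train(
                {
                    "objective": "binary:logistic",
                    "max_depth": cfg.max_depth,
                    "eta": cfg.learning_rate,
                    "min_child_weight": cfg.min_child_weight,
                    "colsample_bytree": cfg.colsample_bytree,
                    "base_score": 0.5,
                    "tree_method": "hist",
                    "nthread": 1,
                    "seed": cfg.train_seed,
                },
                dtrain,
                num_boost_round=cfg.n_trees,
            )
            return CostChangeResults(self, booster)
        if cfg.kind == "lr":
            clf = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("lr", LogisticRegression(C=cfg.l2_strength, max_iter=cfg.max_iter,
                                              random_state=cfg.train_seed)),
                ]
            )
        else:  # fnn
            clf = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("mlp", MLPClassifier(hidden_layer_sizes=(cfg.hidden_width,),
                                          max_iter=cfg.max_iter, random_state=cfg.train_seed,
                                          early_stopping=False)),
                ]
            )
        clf.fit(X.to_numpy(np.float64), y)
        return CostChangeResults(self, clf)


class CostChangeResults:
    """Fitted classifier plus evaluation and interpretation entry points."""

    def __init__(self, model: CostChangeModel, fitted):
        self.model = model
        self.split = model.split
        self.config = model.config
        self._fitted = fitted

    # -- prediction --------------------------------------------------------

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(increase) per row."""
        if self.config.kind == "bdt":
            dm = xgb.DMatrix(X.to_numpy(np.float32), feature_names=list(X.columns))
            return self._fitted.predict(dm)
        return self._fitted.predict_proba(X.to_numpy(np.float64))[:, 1]

    def predict_margin(self, X: pd.DataFrame) -> np.ndarray:
        """Raw margin (log-odds) of the boosted model."""
        if self.config.kind != "bdt":
            raise TypeError("raw margins are only defined for the boosted model")
        dm = xgb.DMatrix(X.to_numpy(np.float32), feature_names=list(X.columns))
        return self._fitted.predict(dm, output_margin=True)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, partition: str = "validation") -> ModelReport:
        Xp, yp = self.split.Xy(partition)
        prob = self.predict_proba(Xp)
        sets = tuple(sorted(set(self.split.X.set_membership.values())))
        return ModelReport(
            model_kind=self.config.kind,
            feature_sets=sets,
            n_features=self.split.X.width,
            partition=partition,
            accuracy=accuracy_pct(yp, prob),
            auc=rank_auc(yp, prob),
        )

    def summary(self) -> str:
        lines = [
            "Cost-change classification results",
            "==================================",
            f"model kind        : {self.config.kind.upper()}",
            f"features          : {self.split.X.width} "
            f"({', '.join(sorted(set(self.split.X.set_membership.values())))})",
            f"train/val/test n  : {self.split.part_sizes()}",
        ]
        for part in ("validation", "test"):
            rep = self.evaluate(part)
            lines.append(f"{part:<18}: accuracy {rep.accuracy:5.1f} %   AUC {rep.auc:.3f}")
        return "\n".join(lines)

    # -- export ------------------------------------------------------------

    def export_ensemble(self) -> TreeEnsemble:
        """Neutral tree representation; boosted model only."""
        if self.config.kind != "bdt":
            raise TypeError(f"cannot export a {self.config.kind!r} model as a tree ensemble")
        return TreeEnsemble.from_xgboost(self._fitted, self.split.X.feature_names)

    # -- interpretation entry points (delegating) ---------------------------

    def attribute(self, X: pd.DataFrame):
        from .interpret import attribute

        return attribute(self.export_ensemble(), X)

    def weight_analysis(self, **kwargs):
        from .interpret import weight_analysis

        return weight_analysis(self.export_ensemble(), self.split, **kwargs)

    def mine_subgroups(self, atc4: str, **kwargs):
        from .interpret import mine_subgroups

        return mine_subgroups(self.export_ensemble(), self.split, atc4=atc4, **kwargs)


#: Stepwise feature-set plan: nested rows from demographics to the complete model.
DEFAULT_PLAN: list[tuple[str, ...]] = [
    ("demographic",),
    ("demographic", "counts"),
    ("demographic", "counts", "chronic"),
    ("demographic", "counts", "chronic", "additional"),
    ("demographic", "counts", "chronic", "additional", "pharmacotherapy"),
    ("demographic", "counts", "chronic", "additional", "pharmacotherapy", "costs"),
]


def stepwise_experiment(
    bundle: ClaimsBundle,
    plan: Sequence[Sequence[str]] | None = None,
    configs: Sequence[TrainConfig] | None = None,
    split_seed: int = 0,
    chronic_map=None,
) -> list[ModelReport]:
    """Train every model kind on every feature-set row of ``plan``.

    Every row is evaluated on the validation partition; the final (complete)
    row is additionally evaluated on the test partition.  The patient
    partition is identical across rows (same split seed on the same cohort).
    """
    if plan is None:
        plan = DEFAULT_PLAN
    if configs is None:
        configs = [TrainConfig.lr(), TrainConfig.bdt(), TrainConfig.fnn()]
    reports: list[ModelReport] = []
    for i, sets in enumerate(plan):
        split = build_labeled_split(bundle, list(sets), split_seed, chronic_map=chronic_map)
        for cfg in configs:
            res = CostChangeModel(split, cfg).fit()
            rep = res.evaluate("validation")
            rep.feature_sets = tuple(sets)
            reports.append(rep)
            if i == len(plan) - 1:
                rep_test = res.evaluate("test")
                rep_test.feature_sets = tuple(sets)
                reports.append(rep_test)
    return reports


def reports_frame(reports: Sequence[ModelReport]) -> pd.DataFrame:
    """Stepwise reports as a table: one row per feature bundle x partition."""
    rows = {}
    for rep in reports:
        key = ("+".join(rep.feature_sets), rep.partition, rep.n_features)
        row = rows.setdefault(key, {})
        row[f"{rep.model_kind}_acc"] = round(rep.accuracy, 1)
        row[f"{rep.model_kind}_auc"] = round(rep.auc, 2)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["features", "partition", "size"])
    return frame.reset_index()
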