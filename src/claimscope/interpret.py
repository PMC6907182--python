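"""Interpretation of the boosted cost-change model.

Four analyses, all consuming the neutral
:class:`~claimscope.ensemble.TreeEnsemble` representation:

* :func:`attribute` -- per-sample additive decomposition of the margin into
  per-feature scores (cover-weighted path attribution).  At each internal
  node of each tree the split feature receives the change in cover-weighted
  expected leaf value between the child taken and the node itself; the
  intercept is the base score plus every tree's root expectation.  The
  decomposition is conservative: intercept + sum of scores = margin.
* :func:`weight_analysis` -- which drug classes contribute at least a given
  fraction (default 5%) of a sample's total positive or negative score, how
  often, and how accurately the contribution direction matches the observed
  label; decrease rows are stratified by hospitalisation.
* :func:`drug_probability_table` -- empirical probability of increase (or
  decrease), conditioned on having at least one prescription of each drug
  class and stratified by hospitalisation.  The overall probability is the
  patient-count-weighted mixture of the stratum probabilities by
  construction.
* :func:`mine_subgroups` -- decision-path subgroup mining: root-to-leaf
  paths in which the *prescribed* side of a drug-class feature participates
  are merged into per-feature interval rules, and each rule's *gain* is the
  absolute change in conditional increase probability when the drug-class
  constraint is removed.
* :func:`backward_deletion` -- greedy backward feature elimination guided by
  validation accuracy, with a cheap retrain inside each round and a full
  refit for the reported trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import LabeledSplit
from .ensemble import Tree, TreeEnsemble
from .model import CostChangeModel, TrainConfig, accuracy_pct

logger = logging.getLogger(__name__)

__all__ = [
    "attribute",
    "weight_analysis",
    "drug_probability_table",
    "pooled_probability",
    "SubgroupRule",
    "mine_subgroups",
    "DeletionTrace",
    "backward_deletion",
]


# ---------------------------------------------------------------------------
# per-sample additive attribution

def attribute(ensemble: TreeEnsemble, X: pd.DataFrame | np.ndarray):
    """Cover-weighted path attribution for every row of ``X``.

    Returns ``(scores, intercept)`` where ``scores`` is an (n_samples,
    n_features) DataFrame (columns = ensemble feature names) and
    ``intercept`` a scalar; ``intercept + scores.sum(axis=1)`` equals
    ``ensemble.margin(X)`` up to float64 round-off.
    """
    X32 = ensemble._as_float32(X)
    n, f = len(X32), len(ensemble.feature_names)
    scores = np.zeros((n, f), dtype=np.float64)
    intercept = ensemble.base_score
    for tree in ensemble.trees:
        ev = tree.expected_values()
        intercept += ev[0]
        node = np.zeros(n, dtype=np.int64)
        thr32 = tree.threshold.astype(np.float32)
        active = tree.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            feat = tree.feature[cur]
            go_left = X32[idx, feat] < thr32[cur]
            child = np.where(go_left, tree.left[cur], tree.right[cur])
            scores[idx, feat] += ev[child] - ev[cur]
            node[idx] = child
            active[idx] = tree.feature[child] >= 0
    columns = list(ensemble.feature_names)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return pd.DataFrame(scores, index=index, columns=columns), float(intercept)


# ---------------------------------------------------------------------------
# weight analysis

def weight_analysis(
    ensemble: TreeEnsemble,
    split: LabeledSplit,
    partition: str = "test",
    threshold: float = 0.05,
    n_min_increase: int = 40,
    n_min_decrease: int = 20,
    drug_features: Sequence[str] | None = None,
    hosp_feature: str = "n_hospitalisations",
) -> pd.DataFrame:
    """Drug classes contributing >= ``threshold`` of a sample's total score.

    For each sample let S+ be the sum of its positive attributions and S-
    the magnitude of the sum of its negative ones.  A drug-class feature
    *contributes to increase* on that sample if its score is at least
    ``threshold * S+`` (and to decrease if at most ``-threshold * S-``).
    Rows aggregate per class and direction; decrease rows are additionally
    stratified by hospitalisation.  ``acc`` is the percentage of
    contributing samples whose observed label matches the direction.
    Increase rows with n < ``n_min_increase`` are dropped, decrease rows are
    dropped when the non-hospitalised stratum has n < ``n_min_decrease``.
    Rows are sorted by descending accuracy.
    """
    if drug_features is None:
        drug_features = split.X.features_in_set("pharmacotherapy")
    drug_features = [f for f in drug_features if f in ensemble.feature_names]
    Xp, yp = split.Xy(partition)
    scores, _ = attribute(ensemble, Xp)
    pos = scores.to_numpy().clip(min=0).sum(axis=1)
    neg = -scores.to_numpy().clip(max=0).sum(axis=1)
    if (pos == 0).any():
        logger.info("%d samples have zero positive score and contribute no increase rows",
                    int((pos == 0).sum()))
    if hosp_feature in Xp.columns:
        hospitalised = Xp[hosp_feature].to_numpy() >= 1
    else:
        hospitalised = np.zeros(len(Xp), dtype=bool)

    rows = []
    for cls in drug_features:
        s = scores[cls].to_numpy()
        inc = (pos > 0) & (s >= threshold * pos) & (s > 0)
        n_inc = int(inc.sum())
        if n_inc >= n_min_increase:
            rows.append(
                {
                    "atc4": cls,
                    "direction": "increase",
                    "stratum": "all",
                    "n": n_inc,
                    "acc": 100.0 * float(np.mean(yp[inc] == 1)),
                }
            )
        dec = (neg > 0) & (s <= -threshold * neg) & (s < 0)
        n_nohosp = int((dec & ~hospitalised).sum())
        if n_nohosp >= n_min_decrease:
            for stratum, mask in (
                ("not_hospitalised", dec & ~hospitalised),
                ("hospitalised", dec & hospitalised),
            ):
                if mask.any():
                    rows.append(
                        {
                            "atc4": cls,
                            "direction": "decrease",
                            "stratum": stratum,
                            "n": int(mask.sum()),
                            "acc": 100.0 * float(np.mean(yp[mask] == 0)),
                        }
                    )
    frame = pd.DataFrame(rows, columns=["atc4", "direction", "stratum", "n", "acc"])
    return frame.sort_values("acc", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# conditional drug probabilities

def pooled_probability(ns: Sequence[float], ps: Sequence[float]) -> float:
    """Count-weighted mixture of stratum probabilities (same units as ``ps``)."""
    ns = np.asarray(ns, dtype=float)
    ps = np.asarray(ps, dtype=float)
    if ns.sum() <= 0:
        raise ValueError("total count must be positive")
    return float((ns * ps).sum() / ns.sum())


def drug_probability_table(
    split: LabeledSplit,
    direction: str = "increase",
    partition: str | None = None,
    min_n_nohosp: int = 1500,
    drug_features: Sequence[str] | None = None,
    hosp_feature: str = "n_hospitalisations",
) -> pd.DataFrame:
    """Per-class probability of the direction label, conditioned on >= 1
    prescription of the class, overall and per hospitalisation stratum.

    Classes prescribed to fewer than ``min_n_nohosp`` non-hospitalised
    patients are filtered out; rows are sorted by descending probability in
    the non-hospitalised stratum (the convention used for reporting).  The
    ``p_all`` column is exactly the count-weighted mixture of the stratum
    probabilities.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    if drug_features is None:
        drug_features = split.X.features_in_set("pharmacotherapy")
    Xp, yp = split.Xy(partition)
    hit = yp == (1 if direction == "increase" else 0)
    hosp = Xp[hosp_feature].to_numpy() >= 1 if hosp_feature in Xp.columns else np.zeros(len(Xp), bool)
    rows = []
    for cls in drug_features:
        has = Xp[cls].to_numpy() >= 1
        n_all = int(has.sum())
        n_hosp = int((has & hosp).sum())
        n_nohosp = n_all - n_hosp
        if n_all == 0 or n_nohosp < min_n_nohosp:
            continue
        p_hosp = 100.0 * float(hit[has & hosp].mean()) if n_hosp else 0.0
        p_nohosp = 100.0 * float(hit[has & ~hosp].mean()) if n_nohosp else 0.0
        rows.append(
            {
                "atc4": cls,
                "n_all": n_all,
                "p_all": pooled_probability([n_hosp, n_nohosp], [p_hosp, p_nohosp]),
                "n_hosp": n_hosp,
                "p_hosp": p_hosp,
                "n_nohosp": n_nohosp,
                "p_nohosp": p_nohosp,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["atc4", "n_all", "p_all", "n_hosp", "p_hosp", "n_nohosp", "p_nohosp"]
    )
    return frame.sort_values("p_nohosp", ascending=False, kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# decision-path subgroup mining

@dataclass
class SubgroupRule:
    """Conjunction of per-feature half-open interval cuts [lo, hi).

    ``cuts`` maps feature name -> (lo, hi); lo is inclusive (came from
    right branches, x >= threshold), hi exclusive (left branches,
    x < threshold).  ``gain = |p_increase - p_without|`` where ``p_without``
    drops every cut on the drug-class feature the rule was mined for.
    """

    cuts: dict[str, tuple[float, float]]
    drug_feature: str
    n: int = 0
    p_increase: float = 0.0
    p_without: float = 0.0

    @property
    def gain(self) -> float:
        return abs(self.p_increase - self.p_without)

    def mask(self, X: pd.DataFrame, drop_drug: bool = False) -> np.ndarray:
        m = np.ones(len(X), dtype=bool)
        for feat, (lo, hi) in self.cuts.items():
            if drop_drug and feat == self.drug_feature:
                continue
            v = X[feat].to_numpy(dtype=np.float32)
            if lo > -np.inf:
                m &= v >= np.float32(lo)
            if hi < np.inf:
                m &= v < np.float32(hi)
        return m

    def describe(self) -> str:
        parts = []
        for feat, (lo, hi) in sorted(self.cuts.items()):
            if lo > -np.inf and hi < np.inf:
                parts.append(f"{lo:g} <= {feat} < {hi:g}")
            elif lo > -np.inf:
                parts.append(f"{feat} >= {lo:g}")
            else:
                parts.append(f"{feat} < {hi:g}")
        cond = " AND ".join(parts)
        return (
            f"{cond}  [n={self.n}, P(increase|cut)={self.p_increase:.2f}, "
            f"without {self.drug_feature}: {self.p_without:.2f}, gain={self.gain:.2f}]"
        )


def _merge_path(path) -> dict[int, tuple[float, float]]:
    """Merge a path's (feature, side, threshold) constraints into intervals."""
    cuts: dict[int, tuple[float, float]] = {}
    for feat, side, thr in path:
        lo, hi = cuts.get(feat, (-np.inf, np.inf))
        if side == ">=":
            lo = max(lo, thr)
        else:
            hi = min(hi, thr)
        cuts[feat] = (lo, hi)
    return cuts


def mine_subgroups(
    ensemble: TreeEnsemble,
    split: LabeledSplit,
    partition: str = "train",
    atc4: str | None = None,
    max_cuts: int = 5,
    min_support: int = 100,
) -> list[SubgroupRule]:
    """Mine decision-path subgroups around a drug-class feature.

    Enumerates every root-to-leaf path of every tree, keeps those whose
    constraints on ``atc4`` pin the *prescribed* side (feasible region
    requires a count >= 1, i.e. the merged lower bound is positive), merges
    the path's constraints into per-feature intervals, and evaluates each
    distinct rule on the requested partition.  Rules touching more than
    ``max_cuts`` distinct features are discarded rather than truncated
    (truncation would change the conditional), as are rules with support
    below ``min_support``.  Returned sorted by descending gain.
    """
    if atc4 is None:
        raise ValueError("atc4 drug-class feature is required")
    if atc4 not in ensemble.feature_names:
        raise KeyError(f"{atc4!r} is not a feature of the ensemble")
    feat_idx = {n: i for i, n in enumerate(ensemble.feature_names)}
    drug_idx = feat_idx[atc4]
    names = ensemble.feature_names

    seen: set[tuple] = set()
    candidates: list[SubgroupRule] = []
    for path in ensemble.paths():
        feats = {f for f, _, _ in path}
        if drug_idx not in feats:
            continue
        cuts = _merge_path(path)
        lo, hi = cuts[drug_idx]
        if not (lo > 0):          # must require >= 1 prescription (counts are integer)
            continue
        if lo >= hi:              # infeasible interval
            continue
        if len(cuts) > max_cuts:
            continue
        named = {names[f]: iv for f, iv in cuts.items()}
        key = tuple(sorted((f, iv) for f, iv in named.items()))
        if key in seen:
            continue
        seen.add(key)
        candidates.append(SubgroupRule(cuts=named, drug_feature=atc4))

    if not candidates:
        logger.info("drug class %s is not used on any prescribed-side path", atc4)
        return []

    Xp, yp = split.Xy(partition)
    rules = []
    for rule in candidates:
        m = rule.mask(Xp)
        n = int(m.sum())
        if n < min_support or n == 0:
            continue
        m_without = rule.mask(Xp, drop_drug=True)
        rule.n = n
        rule.p_increase = float(yp[m].mean())
        rule.p_without = float(yp[m_without].mean()) if m_without.any() else 0.0
        rules.append(rule)
    rules.sort(key=lambda r: (-r.gain, r.describe()))
    return rules


def subgroup_frame(rules: Sequence[SubgroupRule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rule": r.describe().split("  [")[0],
                "drug_feature": r.drug_feature,
                "n": r.n,
                "p_increase": r.p_increase,
                "p_without": r.p_without,
                "gain": r.gain,
            }
            for r in rules
        ],
        columns=["rule", "drug_feature", "n", "p_increase", "p_without", "gain"],
    )


# ---------------------------------------------------------------------------
# backward deletion

@dataclass
class DeletionTrace:
    """Greedy backward-elimination trace.

    ``steps`` holds (deleted_feature, validation accuracy in percent after a
    full refit without it); ``retained_features`` is the final feature list.
    """

    steps: list[tuple[str, float]] = field(default_factory=list)
    retained_features: list[str] = field(default_factory=list)
    tolerance: float = 0.5
    start_accuracy: float = 0.0

    def deleted_features(self) -> list[str]:
        return [f for f, _ in self.steps]


def backward_deletion(
    split: LabeledSplit,
    cfg: TrainConfig,
    tolerance: float = 0.5,
    cheap_cfg: TrainConfig | None = None,
    min_features: int = 1,
) -> DeletionTrace:
    """Greedy backward feature elimination on validation accuracy.

    Each round retrains once per candidate feature with that feature removed
    (using ``cheap_cfg``, a reduced-size booster, to keep the O(F^2) retrain
    loop affordable) and deletes the feature whose removal maximises
    validation accuracy (ties broken by lexicographic feature name).  The
    accepted deletion is re-measured with a full ``cfg`` refit; the loop
    stops when that accuracy falls more than ``tolerance`` accuracy points
    below the running best.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive (accuracy points)")
    if split.X.width < 2:
        raise ValueError("backward deletion needs at least 2 features")
    cheap_cfg = cheap_cfg or TrainConfig.bdt(n_trees=25, max_depth=3,
                                             learning_rate=0.3, train_seed=cfg.train_seed)

    def val_accuracy(features: list[str], config: TrainConfig) -> float:
        res = CostChangeModel(split.subset_features(features), config).fit()
        Xv, yv = res.split.Xy("validation")
        return accuracy_pct(yv, res.predict_proba(Xv))

    features = list(split.X.feature_names)
    best = val_accuracy(features, cfg)
    trace = DeletionTrace(tolerance=tolerance, start_accuracy=best)
    while len(features) > min_features:
        candidates = []
        for f in sorted(features):
            rest = [g for g in features if g != f]
            candidates.append((val_accuracy(rest, cheap_cfg), f))
        top = max(acc for acc, _ in candidates)
        delete = min(f for acc, f in candidates if acc == top)  # ties -> lexicographic
        rest = [g for g in features if g != delete]
        full_acc = val_accuracy(rest, cfg)
        if full_acc < best - tolerance:
            break
        features = rest
        trace.steps.append((delete, full_acc))
        best = max(best, full_acc)
        logger.info("deleted %s (validation accuracy %.2f%%, %d features left)",
                    delete, full_acc, len(features))
    trace.retained_features = features
    return trace
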