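"""Interpretation layer: attribution conservation, weight analysis,
conditional drug probabilities, subgroup mining vs a brute-force oracle,
and backward deletion."""

import numpy as np
import pandas as pd
import pytest

import claimscope as cs
from claimscope.ensemble import Tree, TreeEnsemble, random_ensemble
from claimscope.interpret import (
    attribute,
    backward_deletion,
    drug_probability_table,
    mine_subgroups,
    pooled_probability,
    weight_analysis,
)
from conftest import make_split


def leaf_tree(value: float, cover: float = 10.0) -> Tree:
    return Tree(
        feature=np.array([-1]), threshold=np.array([0.0]), left=np.array([-1]),
        right=np.array([-1]), cover=np.array([cover]), leaf_value=np.array([value]),
    )


def stump(feature: int, threshold: float, left_value: float, right_value: float,
          cover=(10.0, 5.0, 5.0)) -> Tree:
    return Tree(
        feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        cover=np.array(cover),
        leaf_value=np.array([0.0, left_value, right_value]),
    )


def test_attribution_leaf_only_tree():
    ens = TreeEnsemble(base_score=0.3, feature_names=["f"], trees=[leaf_tree(0.5)])
    scores, icpt = attribute(ens, pd.DataFrame({"f": [1.0, 2.0]}))
    assert np.allclose(scores.to_numpy(), 0.0)
    assert icpt == pytest.approx(0.8)


def test_attribution_symmetric_stump():
    # equal-cover leaves -1/+1: expected root value 0, so the routed side
    # receives the full leaf value
    ens = TreeEnsemble(base_score=0.0, feature_names=["f"],
                       trees=[stump(0, 0.5, -1.0, +1.0)])
    X = pd.DataFrame({"f": [0.0, 1.0]})
    scores, icpt = attribute(ens, X)
    assert icpt == pytest.approx(0.0)
    assert scores["f"].tolist() == pytest.approx([-1.0, +1.0])


def test_attribution_conservation_random_ensembles():
    """intercept + sum(scores) equals the float64 margin everywhere."""
    rng = np.random.default_rng(6)
    names = [f"f{i}" for i in range(8)]
    for seed in range(5):
        ens = random_ensemble(n_trees=5, depth=3, feature_names=names, seed=seed,
                              base_score=float(rng.normal()))
        X = pd.DataFrame(rng.normal(size=(200, 8)), columns=names)
        scores, icpt = attribute(ens, X)
        recon = icpt + scores.sum(axis=1).to_numpy()
        assert np.abs(recon - ens.margin(X)).max() < 1e-9


def test_attribution_missing_feature_rejected():
    ens = TreeEnsemble(base_score=0.0, feature_names=["f"], trees=[stump(0, 0.5, -1, 1)])
    with pytest.raises(KeyError, match="f"):
        attribute(ens, pd.DataFrame({"g": [1.0]}))


def _drug_split(n=400, seed=0, p_with=0.8, p_without=0.5):
    """Tiny cohort: one drug-class count feature drives the label."""
    rng = np.random.default_rng(seed)
    drug = (rng.random(n) < 0.3).astype(float) * rng.integers(1, 4, n)
    hosp = (rng.random(n) < 0.2).astype(float)
    p = np.where(drug >= 1, p_with, p_without)
    y = (rng.random(n) < p).astype(int)
    X = np.column_stack([drug, hosp, rng.normal(size=n)])
    split = make_split(X, y, seed=seed, names=["D01AA", "n_hospitalisations", "noise"])
    split.X.set_membership["D01AA"] = "pharmacotherapy"
    split.X.set_membership["n_hospitalisations"] = "counts"
    return split


def test_weight_analysis_single_drug_stump():
    split = _drug_split()
    ens = TreeEnsemble(base_score=0.0,
                       feature_names=split.X.feature_names,
                       trees=[stump(0, 1.0, -0.4, +0.9, cover=(10, 7, 3))])
    rows = weight_analysis(ens, split, partition="train", n_min_increase=1, n_min_decrease=1)
    inc = rows[(rows.direction == "increase")]
    assert list(inc.atc4) == ["D01AA"]  # the only split feature gets 100% of the score
    Xt, yt = split.Xy("train")
    assert inc.n.iloc[0] == int((Xt["D01AA"] >= 1).sum())


def test_weight_analysis_vacuous_threshold():
    split = _drug_split()
    ens = TreeEnsemble(base_score=0.0, feature_names=split.X.feature_names,
                       trees=[stump(0, 1.0, -0.4, +0.9)])
    rows = weight_analysis(ens, split, partition="train", threshold=1.01,
                           n_min_increase=1, n_min_decrease=1)
    assert rows.empty  # nothing can contribute 101% of the total score


def test_weight_analysis_recovers_planted_class(ensemble20k, split20k):
    """The chronic-progressive class shows up among increase contributors
    with accuracy reflecting its planted conditional probability."""
    rows = weight_analysis(ensemble20k, split20k)
    hit = rows[(rows.atc4 == "N06DA") & (rows.direction == "increase")]
    assert len(hit) == 1
    assert hit.n.iloc[0] >= 40
    assert 70 <= hit.acc.iloc[0] <= 90


def test_drug_probability_mixture_identity(split20k):
    table = drug_probability_table(split20k, min_n_nohosp=50)
    assert len(table) > 5
    mix = (table.n_hosp * table.p_hosp + table.n_nohosp * table.p_nohosp) / table.n_all
    assert np.allclose(mix, table.p_all, atol=1e-9)
    assert (table.n_all == table.n_hosp + table.n_nohosp).all()
    # sorted by non-hospitalised probability
    assert (table.p_nohosp.diff().dropna() <= 1e-9).all()


def test_drug_probability_rare_class_filtered():
    split = _drug_split(n=200)
    # D01AA reaches ~60 patients; a huge min_n filters everything
    table = drug_probability_table(split, min_n_nohosp=10_000)
    assert table.empty
    table = drug_probability_table(split, min_n_nohosp=1)
    assert "D01AA" in set(table.atc4)


def test_drug_probability_null_labels_near_half():
    rng = np.random.default_rng(9)
    n = 4000
    drug = (rng.random(n) < 0.5).astype(float)
    y = (rng.random(n) < 0.5).astype(int)  # labels independent of the drug
    split = make_split(np.column_stack([drug, np.zeros(n)]), y,
                       names=["D01AA", "n_hospitalisations"], seed=9)
    split.X.set_membership["D01AA"] = "pharmacotherapy"
    table = drug_probability_table(split, min_n_nohosp=1)
    p = table.loc[table.atc4 == "D01AA", "p_all"].iloc[0]
    assert abs(p - 50.0) < 4.0  # binomial noise at n ~ 2000


def test_pooled_probability_printed_strata():
    """Count-weighted pooling reproduces the published overall percentages."""
    assert pooled_probability([3177, 7290], [28.4, 63.1]) == pytest.approx(52.6, abs=0.05)
    assert pooled_probability([1964, 5887], [82.1, 70.5]) == pytest.approx(73.4, abs=0.05)
    with pytest.raises(ValueError):
        pooled_probability([0, 0], [10.0, 20.0])


def test_mine_single_stump_gain_is_marginal_contrast():
    split = _drug_split(n=2000, seed=1)
    ens = TreeEnsemble(base_score=0.0, feature_names=split.X.feature_names,
                       trees=[stump(0, 0.5, -0.4, +0.9)])
    rules = mine_subgroups(ens, split, partition="train", atc4="D01AA", min_support=10)
    assert len(rules) == 1
    rule = rules[0]
    Xt, yt = split.Xy("train")
    has = Xt["D01AA"].to_numpy() >= 1
    assert rule.n == int(has.sum())
    assert rule.p_increase == pytest.approx(float(yt[has].mean()))
    assert rule.p_without == pytest.approx(float(yt.mean()))  # whole population
    assert rule.gain == pytest.approx(abs(rule.p_increase - rule.p_without))


def test_mine_unused_class_returns_empty():
    split = _drug_split()
    ens = TreeEnsemble(base_score=0.0, feature_names=split.X.feature_names,
                       trees=[stump(2, 0.0, -0.1, 0.1)])  # splits only on noise
    assert mine_subgroups(ens, split, partition="train", atc4="D01AA") == []
    with pytest.raises(KeyError):
        mine_subgroups(ens, split, partition="train", atc4="Z99ZZ")


def brute_force_rules(ens, split, partition, atc4, max_cuts, min_support):
    """Independent rule evaluator: every sample tested against every path."""
    names = ens.feature_names
    drug_idx = names.index(atc4)
    Xp, yp = split.Xy(partition)
    V = Xp[names].to_numpy(dtype=np.float32)
    results = {}
    for path in ens.paths():
        if drug_idx not in {f for f, _, _ in path}:
            continue
        cuts = {}
        for f, side, thr in path:
            lo, hi = cuts.get(f, (-np.inf, np.inf))
            cuts[f] = (max(lo, thr), hi) if side == ">=" else (lo, min(hi, thr))
        lo, hi = cuts[drug_idx]
        if not (lo > 0) or lo >= hi or len(cuts) > max_cuts:
            continue
        key = tuple(sorted(cuts.items()))
        if key in results:
            continue
        keep = np.ones(len(V), dtype=bool)
        keep_wo = np.ones(len(V), dtype=bool)
        for f, (flo, fhi) in cuts.items():
            m = np.ones(len(V), dtype=bool)
            if flo > -np.inf:
                m &= V[:, f] >= np.float32(flo)
            if fhi < np.inf:
                m &= V[:, f] < np.float32(fhi)
            keep &= m
            if f != drug_idx:
                keep_wo &= m
        n = int(keep.sum())
        if n < min_support or n == 0:
            continue
        results[key] = (
            n,
            float(yp[keep].mean()),
            float(yp[keep_wo].mean()) if keep_wo.any() else 0.0,
        )
    return results


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_mine_subgroups_matches_bruteforce(seed):
    """Support, conditional probabilities and gain agree with exhaustive
    per-sample rule evaluation on small random ensembles."""
    rng = np.random.default_rng(seed)
    n = 800
    names = ["D01AA", "n_hospitalisations", "a", "b"]
    X = np.column_stack([
        (rng.random(n) < 0.4) * rng.integers(1, 5, n),
        (rng.random(n) < 0.2).astype(float),
        rng.normal(size=n),
        rng.normal(size=n),
    ])
    y = (rng.random(n) < 0.5).astype(int)
    split = make_split(X, y, seed=seed, names=names)
    # random trees with drug-count thresholds in a realistic range
    ens = random_ensemble(n_trees=5, depth=3, feature_names=names, seed=seed + 50)
    for tree in ens.trees:  # rescale thresholds for the count features
        for i in range(tree.n_nodes):
            if tree.feature[i] in (0, 1):
                tree.threshold[i] = float(np.float32(abs(tree.threshold[i]) * 2))
    mined = mine_subgroups(ens, split, partition="train", atc4="D01AA",
                           max_cuts=5, min_support=5)
    expected = brute_force_rules(ens, split, "train", "D01AA", 5, 5)
    assert len(mined) == len(expected)
    for rule in mined:
        key = tuple(sorted(
            (ens.feature_names.index(f), iv) for f, iv in rule.cuts.items()
        ))
        n, p, p_wo = expected[key]
        assert rule.n == n
        assert rule.p_increase == pytest.approx(p)
        assert rule.p_without == pytest.approx(p_wo)
        assert rule.gain == pytest.approx(abs(p - p_wo))


def test_mine_recovers_pregnancy_subgroup(ensemble20k, split20k):
    """The planted pregnancy-like subgroup surfaces as a high-probability,
    high-gain rule on the folic-acid analogue."""
    rules = mine_subgroups(ensemble20k, split20k, partition="train", atc4="B03BB")
    assert rules, "no rules mined for B03BB"
    good = [r for r in rules if r.p_increase >= 0.75 and r.gain >= 0.10]
    assert good
    assert all(len(r.cuts) <= 5 and r.n >= 100 for r in rules)
    # gains sorted descending
    gains = [r.gain for r in rules]
    assert gains == sorted(gains, reverse=True)


def test_backward_deletion_drops_noise_first():
    rng = np.random.default_rng(7)
    n = 1500
    x_good = rng.normal(size=n)
    y = (x_good + 0.3 * rng.normal(size=n) > 0).astype(int)
    X = np.column_stack([x_good, rng.normal(size=n)])
    split = make_split(X, y, seed=7, names=["signal", "noise"])
    cfg = cs.TrainConfig.bdt(n_trees=40, max_depth=3)
    trace = backward_deletion(split, cfg, tolerance=2.0, min_features=1)
    assert trace.deleted_features()[0] == "noise"
    assert "signal" in trace.retained_features


def test_backward_deletion_validates_inputs(planted_noise_split):
    with pytest.raises(ValueError, match="tolerance"):
        backward_deletion(planted_noise_split, cs.TrainConfig.bdt(), tolerance=0.0)


def test_backward_deletion_trace_monotone(planted_noise_split):
    """Accuracy along the trace never drops more than the tolerance below
    the running best, and planted informative features survive."""
    cfg = cs.TrainConfig.bdt(n_trees=150, max_depth=4)
    cheap = cs.TrainConfig.bdt(n_trees=25, max_depth=3, learning_rate=0.3)
    trace = backward_deletion(planted_noise_split, cfg, tolerance=0.5, cheap_cfg=cheap)
    best = trace.start_accuracy
    for _, acc in trace.steps:
        assert acc >= best - trace.tolerance
        best = max(best, acc)
    kept_informative = [f for f in trace.retained_features if f.startswith("inf_")]
    assert len(kept_informative) >= 4
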