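"""Cohort construction: inclusion rules, the increase label, the 80/10/10 split.

Inclusion mirrors the study design the package emulates: adults with at
least five prescriptions in each of the two years, complete demographics and
both annual cost totals.  The label is *increase* iff year-2 costs strictly
exceed year-1 costs (a tie counts as decrease).  The partition is a uniform
random permutation cut at floor(0.8 n) / floor(0.1 n) / remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix, assemble
from .synthetic import ClaimsBundle

__all__ = ["LabeledSplit", "include", "label_increase", "split_partition", "build_labeled_split"]

PARTS = ("train", "validation", "test")


def include(bundle: ClaimsBundle, min_prescriptions: int = 5) -> ClaimsBundle:
    """Filter the bundle down to patients meeting the inclusion rules."""
    pat = bundle.patients
    rx_counts = (
        bundle.prescriptions.groupby("patient_id").size()
        if len(bundle.prescriptions)
        else pd.Series(dtype=int)
    )
    rx_y1 = rx_counts.reindex(pat["patient_id"], fill_value=0).to_numpy()
    have_costs = pat["patient_id"].isin(set(bundle.costs["patient_id"])).to_numpy()
    complete = pat.notna().all(axis=1).to_numpy()
    keep = (
        (pat["age_years"].to_numpy() >= 18)
        & (rx_y1 >= min_prescriptions)
        & (pat["rx_count_y2"].to_numpy() >= min_prescriptions)
        & complete
        & have_costs
    )
    return bundle.filter_patients(pat.loc[keep, "patient_id"])


def label_increase(costs: pd.DataFrame) -> pd.Series:
    """Binary label per patient: 1 iff total_costs_y2 - total_costs_y1 > 0."""
    diff = costs["total_costs_y2"].to_numpy() - costs["total_costs_y1"].to_numpy()
    return pd.Series((diff > 0).astype(int), index=pd.Index(costs["patient_id"]), name="increase")


def split_partition(patient_ids: Sequence, seed: int) -> pd.Series:
    """Random 80/10/10 partition: floor(0.8n) train, floor(0.1n) validation, rest test."""
    ids = pd.Index(patient_ids)
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 patients to split 80/10/10, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(0.8 * n))
    n_val = int(np.floor(0.1 * n))
    part = np.empty(n, dtype=object)
    part[order[:n_train]] = "train"
    part[order[n_train : n_train + n_val]] = "validation"
    part[order[n_train + n_val :]] = "test"
    return pd.Series(part, index=ids, name="partition")


@dataclass
class LabeledSplit:
    """Feature matrix + binary increase label + train/validation/test partition."""

    X: FeatureMatrix
    y: pd.Series
    partition: pd.Series
    split_seed: int

    def __post_init__(self) -> None:
        ids = pd.Index(self.X.patient_ids)
        if not (self.y.index.equals(ids) and self.partition.index.equals(ids)):
            raise ValueError("labels/partition must be indexed like the feature matrix")
        if self.y.isna().any():
            raise ValueError("labels must be defined for every included patient")

    def mask(self, part: str) -> np.ndarray:
        if part not in PARTS:
            raise ValueError(f"unknown partition {part!r}")
        return (self.partition == part).to_numpy()

    def Xy(self, part: str | None = None) -> tuple[pd.DataFrame, np.ndarray]:
        if part is None:
            return self.X.frame, self.y.to_numpy()
        m = self.mask(part)
        return self.X.frame.loc[m], self.y.to_numpy()[m]

    def part_sizes(self) -> dict[str, int]:
        return {p: int(self.mask(p).sum()) for p in PARTS}

    def subset_features(self, features) -> "LabeledSplit":
        return LabeledSplit(self.X.subset(features), self.y, self.partition, self.split_seed)


def build_labeled_split(
    bundle: ClaimsBundle,
    sets: Sequence[str],
    seed: int,
    chronic_map: Mapping[str, Sequence[str]] | None = None,
    vocabulary_from_train: bool = True,
) -> LabeledSplit:
    """Apply inclusion, split, then featurise (pharmacotherapy vocabulary
    restricted to classes observed in the training partition to avoid
    evaluation-time vocabulary leakage)."""
    cohort = include(bundle)
    ids = cohort.patients["patient_id"]
    partition = split_partition(ids, seed)
    vocab = None
    if vocabulary_from_train and "pharmacotherapy" in sets:
        train_ids = set(partition.index[partition == "train"])
        rx = cohort.prescriptions
        train_rx = rx[rx["patient_id"].isin(train_ids)]
        vocab = sorted(train_rx["atc5"].str[:5].unique()) if len(train_rx) else []
    X = assemble(cohort, sets, chronic_map=chronic_map, pharma_vocabulary=vocab)
    y = label_increase(cohort.costs).reindex(pd.Index(X.patient_ids))
    return LabeledSplit(X, y, partition.reindex(pd.Index(X.patient_ids)), seed)
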