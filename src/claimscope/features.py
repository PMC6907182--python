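"""Claims feature engineering.

Turns a :class:`~claimscope.synthetic.ClaimsBundle` into a dense
patients x features matrix organised into six named feature sets:

``demographic``
    18 five-year age bands (18-22 upwards, top band collapsed), gender,
    language area, deductible bands for both years plus a changed-deductible
    flag, insurance model -- categoricals expanded to indicators.
``counts``
    Simple utilisation counts: hospitalisations, office visits, distinct
    drugs (5th-level ATC) and prescription events.
``chronic``
    Per-condition counts of distinct ATC codes matching the prefixes of a
    configurable chronic-condition map (a reduced stand-in for the published
    22-condition ATC mapping).
``pharmacotherapy``
    Prescription counts per observed 4th-level ATC class.
``additional``
    Temporal visit/prescription histograms (monthly and quarterly), weekend
    visits, hospital-stay descriptors, administration modes, dispensers,
    specialties, care events, and interval regularity statistics.
``costs``
    Year-1 total costs only (used to assess complementarity of the medical
    features).

All features are defined from year-1 data alone.  Absent events encode as 0;
interval statistics for patients with fewer than two events are 0 with a
companion ``*_has_intervals`` indicator so that 0 is unambiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import (
    ATC5_PATTERN,
    CARE_KINDS,
    ClaimsBundle,
    DEDUCTIBLE_BANDS,
    DISPENSERS,
    HARM_TYPES,
    HOSPITAL_TYPES,
    INSURANCE_MODELS,
    MODES,
)

__all__ = [
    "DEFAULT_CHRONIC_MAP",
    "FEATURE_SETS",
    "FeatureMatrix",
    "IntervalStats",
    "assemble",
    "atc4_of",
    "chronic_features",
    "count_features",
    "hospitalisation_features",
    "interval_stats",
    "mode_and_care_features",
    "pharmacotherapy_features",
    "temporal_features",
    "demographic_features",
    "cost_features",
]

FEATURE_SETS = ("demographic", "counts", "chronic", "pharmacotherapy", "additional", "costs")

#: Reduced chronic-condition stand-in: condition -> ATC prefixes.
DEFAULT_CHRONIC_MAP: dict[str, list[str]] = {
    "diabetes": ["A10"],
    "cardiovascular": ["C01", "C03", "C07", "C09"],
    "anticoagulation": ["B01"],
    "dementia": ["N06D"],
    "pain": ["N02"],
    "ophthalmic": ["S01"],
}

N_AGE_BANDS = 18
AGE_BAND_WIDTH = 5
AGE_MIN = 18


class IntervalStats(NamedTuple):
    median: float
    mean: float
    sd: float
    min: float
    max: float


def atc4_of(atc5: str) -> str:
    """4th-level (5-character) class of a 7-character 5th-level ATC code."""
    if not isinstance(atc5, str) or not ATC5_PATTERN.match(atc5):
        raise ValueError(f"malformed 5th-level ATC code: {atc5!r}")
    return atc5[:5]


def interval_stats(dates: Sequence) -> IntervalStats:
    """Descriptive statistics of gaps (days) between successive dated events.

    ``dates`` must be sorted ascending (dates, datetimes or day numbers).
    With fewer than two dates every statistic is the 0 sentinel; callers
    pair the block with a ``has_intervals`` indicator.  ``sd`` is the
    sample standard deviation (n-1 denominator; 0 for a single gap).
    """
    arr = pd.to_datetime(pd.Series(list(dates))) if len(dates) and isinstance(
        next(iter(dates)), str
    ) else pd.Series(list(dates))
    if arr.is_monotonic_increasing is False:
        raise ValueError("dates must be sorted ascending")
    if len(arr) < 2:
        return IntervalStats(0.0, 0.0, 0.0, 0.0, 0.0)
    values = arr.to_numpy()
    if np.issubdtype(values.dtype, np.datetime64):
        gaps = np.diff(values).astype("timedelta64[D]").astype(float)
    else:
        gaps = np.diff(values.astype(float))
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else 0.0
    return IntervalStats(
        float(np.median(gaps)), float(np.mean(gaps)), sd, float(gaps.min()), float(gaps.max())
    )


class FeatureMatrix:
    """Dense numeric patients x features matrix with feature-set labels."""

    def __init__(self, frame: pd.DataFrame, set_membership: Mapping[str, str]):
        if frame.columns.duplicated().any():
            dup = frame.columns[frame.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")
        unknown = set(set_membership.values()) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature-set label(s): {sorted(unknown)}")
        missing = [c for c in frame.columns if c not in set_membership]
        if missing:
            raise ValueError(f"feature {missing[0]!r} has no set label")
        if frame.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        self.frame = frame.astype(np.float64)
        self.set_membership = {c: set_membership[c] for c in frame.columns}

    @property
    def patient_ids(self) -> list:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def width(self) -> int:
        return self.frame.shape[1]

    def features_in_set(self, label: str) -> list[str]:
        return [f for f, s in self.set_membership.items() if s == label]

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        overlap = set(self.feature_names) & set(other.feature_names)
        if overlap:
            raise ValueError(f"feature blocks overlap on {sorted(overlap)[0]!r}")
        if list(self.frame.index) != list(other.frame.index):
            raise ValueError("feature blocks have different patient order")
        return FeatureMatrix(
            pd.concat([self.frame, other.frame], axis=1),
            {**self.set_membership, **other.set_membership},
        )

    def subset(self, features: Iterable[str]) -> "FeatureMatrix":
        features = list(features)
        return FeatureMatrix(
            self.frame[features], {f: self.set_membership[f] for f in features}
        )

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        path = Path(path)
        self.frame.rename_axis("patient_id").to_csv(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".sets.json")
        sidecar.write_text(json.dumps(self.set_membership, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "FeatureMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col="patient_id")
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".sets.json")
        return cls(frame, json.loads(sidecar.read_text()))

    def equals(self, other: "FeatureMatrix") -> bool:
        return self.frame.equals(other.frame) and self.set_membership == other.set_membership


# ---------------------------------------------------------------------------
# helpers

def _patient_index(bundle: ClaimsBundle) -> pd.Index:
    return pd.Index(bundle.patients["patient_id"], name="patient_id")


def _block(frame: pd.DataFrame, label: str) -> FeatureMatrix:
    return FeatureMatrix(frame, {c: label for c in frame.columns})


def _counts_by_patient(events: pd.DataFrame, index: pd.Index, name: str) -> pd.Series:
    counts = events.groupby("patient_id").size() if len(events) else pd.Series(dtype=float)
    return counts.reindex(index, fill_value=0).rename(name).astype(float)


def _category_counts(
    events: pd.DataFrame, col: str, categories: Sequence, index: pd.Index, prefix: str
) -> pd.DataFrame:
    out = {}
    for cat in categories:
        sub = events[events[col] == cat]
        out[f"{prefix}{cat}"] = _counts_by_patient(sub, index, f"{prefix}{cat}")
    return pd.DataFrame(out, index=index)


def _grouped_interval_block(
    events: pd.DataFrame, index: pd.Index, prefix: str
) -> pd.DataFrame:
    """Vectorised per-patient interval statistics over the ``date`` column."""
    cols = [f"{prefix}_gap_{s}" for s in ("median", "mean", "sd", "min", "max")]
    out = pd.DataFrame(0.0, index=index, columns=cols + [f"{prefix}_gap_has_intervals"])
    if not len(events):
        return out
    ev = events[["patient_id", "date"]].copy()
    ev["day"] = pd.to_datetime(ev["date"]).dt.dayofyear.astype(float)
    ev = ev.sort_values(["patient_id", "day"], kind="mergesort")
    same = ev["patient_id"].to_numpy()[1:] == ev["patient_id"].to_numpy()[:-1]
    gaps = pd.DataFrame(
        {
            "patient_id": ev["patient_id"].to_numpy()[1:][same],
            "gap": np.diff(ev["day"].to_numpy())[same],
        }
    )
    if len(gaps):
        agg = gaps.groupby("patient_id")["gap"].agg(
            median="median", mean="mean", sd=lambda g: g.std(ddof=1), min="min", max="max"
        )
        agg["sd"] = agg["sd"].fillna(0.0)  # single gap -> sd 0
        agg.columns = cols
        out.loc[agg.index, cols] = agg
        out.loc[agg.index, f"{prefix}_gap_has_intervals"] = 1.0
    return out


# ---------------------------------------------------------------------------
# feature blocks

def demographic_features(bundle: ClaimsBundle) -> FeatureMatrix:
    idx = _patient_index(bundle)
    pat = bundle.patients.set_index("patient_id").loc[idx]
    band = np.clip((pat["age_years"] - AGE_MIN) // AGE_BAND_WIDTH, 0, N_AGE_BANDS - 1)
    frame = pd.DataFrame(index=idx)
    for b in range(N_AGE_BANDS):
        lo = AGE_MIN + b * AGE_BAND_WIDTH
        name = f"age_{lo}_{lo + AGE_BAND_WIDTH - 1}" if b < N_AGE_BANDS - 1 else f"age_{lo}_plus"
        frame[name] = (band == b).astype(float)
    frame["gender_female"] = (pat["gender"] == "female").astype(float)
    for lang in ("German", "French", "Italian"):
        frame[f"language_{lang}"] = (pat["language_area"] == lang).astype(float)
    for yr, col in (("y1", "deductible_y1"), ("y2", "deductible_y2")):
        for band_name in DEDUCTIBLE_BANDS:
            safe = band_name.replace(">", "gt").replace("-", "_")
            frame[f"deductible_{yr}_{safe}"] = (pat[col] == band_name).astype(float)
    frame["deductible_changed"] = (pat["deductible_y1"] != pat["deductible_y2"]).astype(float)
    for model in INSURANCE_MODELS:
        frame[f"insurance_{model}"] = (pat["insurance_model"] == model).astype(float)
    return _block(frame, "demographic")


def count_features(bundle: ClaimsBundle) -> FeatureMatrix:
    idx = _patient_index(bundle)
    rx = bundle.prescriptions
    office = bundle.visits[bundle.visits["setting"] == "office"]
    distinct = (
        rx.groupby("patient_id")["atc5"].nunique() if len(rx) else pd.Series(dtype=float)
    )
    frame = pd.DataFrame(
        {
            "n_hospitalisations": _counts_by_patient(bundle.hospitalisations, idx, "x"),
            "n_office_visits": _counts_by_patient(office, idx, "x"),
            "n_different_drugs": distinct.reindex(idx, fill_value=0).astype(float),
            "n_prescriptions": _counts_by_patient(rx, idx, "x"),
        },
        index=idx,
    )
    return _block(frame, "counts")


def chronic_features(
    bundle: ClaimsBundle, chronic_map: Mapping[str, Sequence[str]] | None = None
) -> FeatureMatrix:
    if chronic_map is None:
        chronic_map = DEFAULT_CHRONIC_MAP
    if not chronic_map:
        warnings.warn("empty chronic-condition map: chronic block has no features")
        return _block(pd.DataFrame(index=_patient_index(bundle)), "chronic")
    for condition, prefixes in chronic_map.items():
        for p in prefixes:
            if not _valid_prefix(p):
                raise ValueError(f"invalid ATC prefix {p!r} for condition {condition!r}")
    idx = _patient_index(bundle)
    rx = bundle.prescriptions[["patient_id", "atc5"]].drop_duplicates()
    frame = pd.DataFrame(index=idx)
    for condition, prefixes in chronic_map.items():
        if len(rx):
            hit = rx["atc5"].str.startswith(tuple(prefixes))
            counts = rx[hit].groupby("patient_id").size()
        else:
            counts = pd.Series(dtype=float)
        frame[f"chronic_{condition}"] = counts.reindex(idx, fill_value=0).astype(float)
    return _block(frame, "chronic")


def _valid_prefix(prefix: str) -> bool:
    if not 1 <= len(prefix) <= 5:
        return False
    template = [str.isalpha, str.isdigit, str.isdigit, str.isalpha, str.isalpha]
    return all(check(ch) for ch, check in zip(prefix, template))


def pharmacotherapy_features(
    bundle: ClaimsBundle, vocabulary: Sequence[str] | None = None
) -> FeatureMatrix:
    """Prescription-event counts per 4th-level ATC class.

    ``vocabulary`` fixes the class list (e.g. classes observed in the
    training partition, to avoid leaking evaluation-time vocabulary); by
    default the classes observed anywhere in the bundle are used.  A class
    never prescribed in the vocabulary source gets no column.
    """
    idx = _patient_index(bundle)
    rx = bundle.prescriptions
    atc4 = rx["atc5"].str[:5] if len(rx) else pd.Series(dtype=str)
    if vocabulary is None:
        vocabulary = sorted(atc4.unique())
    counts = (
        pd.DataFrame({"patient_id": rx["patient_id"], "atc4": atc4})
        .groupby(["patient_id", "atc4"])
        .size()
        .unstack(fill_value=0)
        if len(rx)
        else pd.DataFrame(index=idx)
    )
    frame = pd.DataFrame(index=idx)
    for cls in vocabulary:
        col = counts[cls] if cls in counts.columns else pd.Series(0.0, index=idx)
        frame[cls] = col.reindex(idx, fill_value=0).astype(float)
    return _block(frame, "pharmacotherapy")


def temporal_features(bundle: ClaimsBundle) -> FeatureMatrix:
    idx = _patient_index(bundle)
    frame = pd.DataFrame(index=idx)

    def add_histograms(events: pd.DataFrame, prefix: str) -> None:
        ev = events.copy()
        if len(ev):
            dt = pd.to_datetime(ev["date"])
            ev["month"] = dt.dt.month
            ev["quarter"] = dt.dt.quarter
        for m in range(1, 13):
            sub = ev[ev["month"] == m] if len(ev) else ev
            frame[f"{prefix}_month_{m}"] = _counts_by_patient(sub, idx, "x")
        for q in range(1, 5):
            sub = ev[ev["quarter"] == q] if len(ev) else ev
            frame[f"{prefix}_q{q}"] = _counts_by_patient(sub, idx, "x")

    office = bundle.visits[bundle.visits["setting"] == "office"]
    bedside = bundle.visits[bundle.visits["setting"] == "bedside"]
    add_histograms(office, "office")
    add_histograms(bedside, "bedside")
    add_histograms(bundle.prescriptions, "rx")
    weekend = bundle.visits[bundle.visits["weekend"] == 1]
    frame["weekend_visits"] = _counts_by_patient(weekend, idx, "x")
    return _block(frame, "additional")


def hospitalisation_features(bundle: ClaimsBundle, mdc_range: int = 25) -> FeatureMatrix:
    idx = _patient_index(bundle)
    hosp = bundle.hospitalisations
    frame = pd.DataFrame(index=idx)
    if len(hosp):
        los = (
            pd.to_datetime(hosp["discharge_date"]) - pd.to_datetime(hosp["admit_date"])
        ).dt.days.astype(float)
        total = pd.DataFrame({"patient_id": hosp["patient_id"], "los": los}).groupby(
            "patient_id"
        )["los"].sum()
    else:
        total = pd.Series(dtype=float)
    frame["los_total_days"] = total.reindex(idx, fill_value=0).astype(float)
    for m in range(1, mdc_range + 1):
        sub = hosp[hosp["mdc"] == m] if len(hosp) else hosp
        frame[f"mdc_{m:02d}"] = _counts_by_patient(sub, idx, "x")
    frame = pd.concat(
        [
            frame,
            _category_counts(hosp, "hospital_type", HOSPITAL_TYPES, idx, "hosp_type_"),
            _category_counts(hosp, "harm_type", HARM_TYPES, idx, "harm_"),
        ],
        axis=1,
    )
    return _block(frame, "additional")


def mode_and_care_features(bundle: ClaimsBundle) -> FeatureMatrix:
    idx = _patient_index(bundle)
    rx, visits, care = bundle.prescriptions, bundle.visits, bundle.care
    specialties = sorted(visits["specialty"].unique()) if len(visits) else []
    frame = pd.concat(
        [
            _category_counts(rx, "mode", MODES, idx, "mode_"),
            _category_counts(rx, "dispenser", DISPENSERS, idx, "dispenser_"),
            _category_counts(visits, "specialty", specialties, idx, "specialty_"),
            _category_counts(care, "kind", CARE_KINDS, idx, "care_"),
        ],
        axis=1,
    )
    # near-duplicate count conventions kept deliberately distinct
    atc4 = rx["atc5"].str[:5] if len(rx) else pd.Series(dtype=str)
    frame["n_distinct_atc4"] = (
        pd.DataFrame({"patient_id": rx["patient_id"], "atc4": atc4})
        .groupby("patient_id")["atc4"]
        .nunique()
        .reindex(idx, fill_value=0)
        .astype(float)
        if len(rx)
        else 0.0
    )
    frame["n_purchase_dates"] = (
        rx.groupby("patient_id")["date"].nunique().reindex(idx, fill_value=0).astype(float)
        if len(rx)
        else 0.0
    )
    home_care = care[care["kind"] == "home_care"]
    frame = pd.concat(
        [
            frame,
            _grouped_interval_block(rx, idx, "rx"),
            _grouped_interval_block(visits, idx, "visit"),
            _grouped_interval_block(home_care, idx, "homecare"),
        ],
        axis=1,
    )
    return _block(frame, "additional")


def cost_features(bundle: ClaimsBundle) -> FeatureMatrix:
    idx = _patient_index(bundle)
    y1 = bundle.costs.set_index("patient_id")["total_costs_y1"].reindex(idx)
    return _block(pd.DataFrame({"total_costs_y1": y1.astype(float)}, index=idx), "costs")


def additional_features(bundle: ClaimsBundle) -> FeatureMatrix:
    return (
        temporal_features(bundle)
        .concat(hospitalisation_features(bundle))
        .concat(mode_and_care_features(bundle))
    )


def assemble(
    bundle: ClaimsBundle,
    sets: Sequence[str],
    chronic_map: Mapping[str, Sequence[str]] | None = None,
    pharma_vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Column-concatenate the requested feature blocks in canonical order."""
    unknown = set(sets) - set(FEATURE_SETS)
    if unknown:
        raise ValueError(f"unknown feature-set label(s): {sorted(unknown)}")
    builders = {
        "demographic": lambda: demographic_features(bundle),
        "counts": lambda: count_features(bundle),
        "chronic": lambda: chronic_features(bundle, chronic_map),
        "pharmacotherapy": lambda: pharmacotherapy_features(bundle, pharma_vocabulary),
        "additional": lambda: additional_features(bundle),
        "costs": lambda: cost_features(bundle),
    }
    blocks = [builders[label]() for label in FEATURE_SETS if label in set(sets)]
    if not blocks:
        raise ValueError("at least one feature set must be requested")
    matrix = blocks[0]
    for block in blocks[1:]:
        matrix = matrix.concat(block)
    return matrix
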