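"""Feature engineering: hand-tallied oracles on the toy bundle, interval
statistics against a brute-force oracle, and structural invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import claimscope as cs
from claimscope.features import (
    DEFAULT_CHRONIC_MAP,
    FeatureMatrix,
    assemble,
    atc4_of,
    chronic_features,
    count_features,
    demographic_features,
    hospitalisation_features,
    interval_stats,
    mode_and_care_features,
    pharmacotherapy_features,
    temporal_features,
)


@pytest.mark.parametrize(
    "atc5,expected", [("B03BB01", "B03BB"), ("C01AA05", "C01AA"), ("N06DA02", "N06DA")]
)
def test_atc4_truncates_to_fourth_level(atc5, expected):
    assert atc4_of(atc5) == expected


@pytest.mark.parametrize("bad", ["X1", "b03bb01", "B03BB0", "B03BB012", "1234567", ""])
def test_atc4_rejects_malformed_codes(bad):
    with pytest.raises(ValueError):
        atc4_of(bad)


def test_count_features_hand_tally(toy_bundle):
    fm = count_features(toy_bundle)
    f = fm.frame
    # P1: 5 rx events, 4 distinct atc5, 2 office visits, 0 hospitalisations
    assert f.loc["P1", "n_prescriptions"] == 5
    assert f.loc["P1", "n_different_drugs"] == 4
    assert f.loc["P1", "n_office_visits"] == 2
    assert f.loc["P1", "n_hospitalisations"] == 0
    # P2: 5 rx of one drug, 2 stays, 1 office visit
    assert f.loc["P2", "n_different_drugs"] == 1
    assert f.loc["P2", "n_hospitalisations"] == 2
    # P3: no visits at all
    assert f.loc["P3", "n_office_visits"] == 0


def test_chronic_features_prefix_matching(toy_bundle):
    fm = chronic_features(toy_bundle, {"diabetes": ["A10"], "eye": ["S01"]})
    f = fm.frame
    # P1 has A10BB01 and A10AE04 -> two distinct codes under A10
    assert f.loc["P1", "chronic_diabetes"] == 2
    assert f.loc["P1", "chronic_eye"] == 0
    # P3 has S01BC01 and S01CA01
    assert f.loc["P3", "chronic_eye"] == 2


def test_chronic_overlapping_prefixes_count_in_both(toy_bundle):
    fm = chronic_features(toy_bundle, {"a": ["A10"], "b": ["A10B"]})
    f = fm.frame
    assert f.loc["P1", "chronic_a"] == 2  # A10BB01, A10AE04
    assert f.loc["P1", "chronic_b"] == 1  # A10BB01 counted again under the narrower prefix


def test_chronic_rejects_bad_prefix(toy_bundle):
    with pytest.raises(ValueError, match="prefix"):
        chronic_features(toy_bundle, {"bad": ["10A"]})


def test_pharmacotherapy_counts_and_vocabulary(toy_bundle):
    fm = pharmacotherapy_features(toy_bundle)
    f = fm.frame
    assert f.loc["P1", "A10BB"] == 2
    assert f.loc["P1", "B03BB"] == 1
    assert f.loc["P2", "C01AA"] == 5
    assert f.loc["P3", "S01BC"] == 2
    # only observed classes become columns
    assert "Z99ZZ" not in f.columns
    # restricted vocabulary drops unseen classes entirely
    fm2 = pharmacotherapy_features(toy_bundle, vocabulary=["C01AA"])
    assert fm2.feature_names == ["C01AA"]


def test_temporal_features_hand_calendar(toy_bundle):
    f = temporal_features(toy_bundle).frame
    # P1 visits: office Mar 1 (Saturday) + Mar 3; bedside Jul 15
    assert f.loc["P1", "office_month_3"] == 2
    assert f.loc["P1", "office_q1"] == 2
    assert f.loc["P1", "bedside_month_7"] == 1
    assert f.loc["P1", "bedside_q3"] == 1
    assert f.loc["P1", "weekend_visits"] == 1
    # P1 prescriptions: Jan 1, Jan 1, Jan 11, Jan 31 (4 in January), Mar 2
    assert f.loc["P1", "rx_month_1"] == 4
    assert f.loc["P1", "rx_q1"] == 5
    # P3 has no visits: all visit histograms zero
    assert f.loc["P3", ["office_month_5", "weekend_visits"]].eq(0).all()


def test_hospitalisation_features_length_of_stay(toy_bundle):
    f = hospitalisation_features(toy_bundle).frame
    # Mar 1 -> Mar 5 is 4 days; same-day stay adds 0
    assert f.loc["P2", "los_total_days"] == 4
    assert f.loc["P2", "mdc_05"] == 1
    assert f.loc["P2", "mdc_04"] == 1
    assert f.loc["P2", "hosp_type_university"] == 1
    assert f.loc["P2", "harm_accident"] == 1
    assert f.loc["P1", "los_total_days"] == 0


def test_mode_care_and_interval_features(toy_bundle):
    f = mode_and_care_features(toy_bundle).frame
    assert f.loc["P1", "mode_oral"] == 3
    assert f.loc["P1", "mode_intravenous"] == 1
    assert f.loc["P2", "dispenser_hospital"] == 1
    assert f.loc["P1", "specialty_gynaecology"] == 1
    assert f.loc["P2", "care_home_care"] == 2
    # P2 home-care gap: Apr 1 -> Apr 8 = 7 days, single gap -> sd 0
    assert f.loc["P2", "homecare_gap_mean"] == 7
    assert f.loc["P2", "homecare_gap_sd"] == 0
    assert f.loc["P2", "homecare_gap_has_intervals"] == 1
    # P1 has no home care: sentinel zeros with indicator 0
    assert f.loc["P1", "homecare_gap_has_intervals"] == 0
    assert f.loc["P1", "homecare_gap_max"] == 0
    # near-duplicate prescription-count conventions
    assert f.loc["P1", "n_purchase_dates"] == 4
    assert f.loc["P1", "n_distinct_atc4"] == 4
    assert f.loc["P2", "n_purchase_dates"] == 5


def test_interval_stats_two_gaps():
    stats = interval_stats([1, 11, 31])
    assert stats.mean == 15 and stats.median == 15
    assert stats.min == 10 and stats.max == 20
    assert stats.sd == pytest.approx(np.sqrt(50), abs=1e-9)  # sample sd of [10, 20]


def test_interval_stats_degenerate_and_errors():
    assert interval_stats([5]) == (0, 0, 0, 0, 0)
    assert interval_stats([]) == (0, 0, 0, 0, 0)
    with pytest.raises(ValueError, match="sorted"):
        interval_stats([5, 3, 9])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=365), min_size=2, max_size=30))
def test_interval_stats_matches_bruteforce(days):
    days = sorted(days)
    got = interval_stats(days)
    gaps = [b - a for a, b in zip(days, days[1:])]  # independent brute force
    assert got.mean == pytest.approx(sum(gaps) / len(gaps))
    assert got.min == min(gaps) and got.max == max(gaps)
    assert got.median == pytest.approx(float(np.median(gaps)))
    if len(gaps) > 1:
        m = sum(gaps) / len(gaps)
        sd = (sum((g - m) ** 2 for g in gaps) / (len(gaps) - 1)) ** 0.5
        assert got.sd == pytest.approx(sd)
    assert got.min <= got.median <= got.max
    assert got.min <= got.mean <= got.max


def test_demographic_block_shape_and_age_bands(toy_bundle):
    f = demographic_features(toy_bundle).frame
    age_cols = [c for c in f.columns if c.startswith("age_")]
    assert len(age_cols) == 18
    assert (f[age_cols].sum(axis=1) == 1).all()  # exactly one band per patient
    assert f.loc["P1", "age_28_32"] == 1
    assert f.loc["P2", "age_78_82"] == 1
    assert f.loc["P2", "deductible_y1_gt1000"] == 1
    assert f.loc["P2", "deductible_changed"] == 0
    assert f.loc["P3", "deductible_changed"] == 1


def test_assemble_block_additivity_and_costs(toy_bundle):
    widths = {}
    for label in cs.FEATURE_SETS:
        widths[label] = assemble(toy_bundle, [label]).width
    full = assemble(toy_bundle, list(cs.FEATURE_SETS))
    assert full.width == sum(widths.values())
    costs_only = assemble(toy_bundle, ["costs"])
    assert costs_only.feature_names == ["total_costs_y1"]
    assert costs_only.frame["total_costs_y1"].tolist() == [1000.0, 5000.0, 2000.0]
    with pytest.raises(ValueError, match="unknown"):
        assemble(toy_bundle, ["demographic", "nonsense"])


def test_event_order_permutation_invariance(toy_bundle):
    full = assemble(toy_bundle, list(cs.FEATURE_SETS))
    rng = np.random.default_rng(0)
    shuffled = cs.ClaimsBundle(
        patients=toy_bundle.patients,
        prescriptions=toy_bundle.prescriptions.sample(frac=1, random_state=1).reset_index(drop=True),
        visits=toy_bundle.visits.sample(frac=1, random_state=2).reset_index(drop=True),
        hospitalisations=toy_bundle.hospitalisations.sample(frac=1, random_state=3).reset_index(drop=True),
        care=toy_bundle.care.sample(frac=1, random_state=4).reset_index(drop=True),
        costs=toy_bundle.costs,
    )
    assert assemble(shuffled, list(cs.FEATURE_SETS)).equals(full)


def test_counts_are_nonnegative_integers_on_generated_data(split20k):
    frame = split20k.X.frame
    count_cols = [
        c for c, s in split20k.X.set_membership.items()
        if s in ("counts", "chronic", "pharmacotherapy")
    ]
    block = frame[count_cols].to_numpy()
    assert (block >= 0).all()
    assert np.allclose(block, np.round(block))
    # interval-statistic ordering
    for prefix in ("rx", "visit", "homecare"):
        has = frame[f"{prefix}_gap_has_intervals"] == 1
        sub = frame.loc[has]
        assert (sub[f"{prefix}_gap_min"] <= sub[f"{prefix}_gap_median"] + 1e-9).all()
        assert (sub[f"{prefix}_gap_median"] <= sub[f"{prefix}_gap_max"] + 1e-9).all()
        assert (sub[f"{prefix}_gap_min"] <= sub[f"{prefix}_gap_mean"] + 1e-9).all()


def test_feature_matrix_rejects_inconsistencies():
    frame = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=pd.Index(["P1"], name="patient_id"))
    with pytest.raises(ValueError, match="set label"):
        FeatureMatrix(frame, {"a": "counts"})
    with pytest.raises(ValueError, match="unknown"):
        FeatureMatrix(frame, {"a": "counts", "b": "bogus"})
    fm = FeatureMatrix(frame, {"a": "counts", "b": "costs"})
    with pytest.raises(ValueError, match="overlap"):
        fm.concat(fm)


def test_feature_matrix_csv_roundtrip(toy_bundle, tmp_path):
    fm = assemble(toy_bundle, ["demographic", "counts"])
    fm.to_csv(tmp_path / "f.csv")
    back = FeatureMatrix.read_csv(tmp_path / "f.csv")
    assert back.equals(fm)
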