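"""Shared fixtures: a hand-written three-patient bundle with enumerable
events, and session-scoped generated cohorts/models reused by the heavier
statistical tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import claimscope as cs
from claimscope.synthetic import ClaimsBundle, _coerce


def _frame(name, rows, columns):
    return _coerce(name, pd.DataFrame(rows, columns=columns))


@pytest.fixture()
def toy_bundle() -> ClaimsBundle:
    """Three patients with hand-listed events (all tallies checkable by hand).

    P1: 5 prescription events (4 distinct ATC-5, 4 purchase dates), 2 office
        visits (one Saturday), 1 bedside visit, no hospitalisation.
    P2: 5 prescriptions of one drug, two hospital stays (Mar 1->5 and a
        same-day stay), two home-care events, high unchanged deductible.
    P3: 5 prescriptions, nothing else; tie costs (decrease by convention).
    """
    patients = _frame(
        "patients",
        [
            ["P1", 30, "female", "German", "300", "300", "standard", 6],
            ["P2", 80, "male", "French", ">1000", ">1000", "telmed", 9],
            ["P3", 45, "female", "Italian", "500-1000", ">1000", "family_doctor", 5],
        ],
        list(cs.synthetic.SCHEMAS["patients"]),
    )
    rx_cols = list(cs.synthetic.SCHEMAS["prescriptions"])
    prescriptions = _frame(
        "prescriptions",
        [
            ["P1", "2014-01-01", "GA10BB01-1", "A10BB01", "oral", "pharmacy"],
            ["P1", "2014-01-01", "GB03BB01-1", "B03BB01", "oral", "pharmacy"],
            ["P1", "2014-01-11", "GA10BB01-1", "A10BB01", "oral", "physician"],
            ["P1", "2014-01-31", "GA10AE04-1", "A10AE04", "intravenous", "hospital"],
            ["P1", "2014-03-02", "GN02BE01-1", "N02BE01", "topical", "pharmacy"],
            ["P2", "2014-02-01", "GC01AA05-1", "C01AA05", "oral", "pharmacy"],
            ["P2", "2014-02-03", "GC01AA05-1", "C01AA05", "oral", "pharmacy"],
            ["P2", "2014-02-05", "GC01AA05-1", "C01AA05", "intravenous", "hospital"],
            ["P2", "2014-08-01", "GC01AA05-1", "C01AA05", "oral", "pharmacy"],
            ["P2", "2014-12-01", "GC01AA05-1", "C01AA05", "oral", "pharmacy"],
            ["P3", "2014-05-01", "GS01BC01-1", "S01BC01", "topical", "pharmacy"],
            ["P3", "2014-05-02", "GS01BC01-1", "S01BC01", "topical", "pharmacy"],
            ["P3", "2014-05-03", "GS01CA01-1", "S01CA01", "topical", "physician"],
            ["P3", "2014-06-01", "GN06DA01-1", "N06DA01", "oral", "pharmacy"],
            ["P3", "2014-07-01", "GB01AA01-1", "B01AA01", "oral", "pharmacy"],
        ],
        rx_cols,
    )
    visits = _frame(
        "visits",
        [
            ["P1", "2014-03-01", "office", "gynaecology", 1],  # Saturday
            ["P1", "2014-03-03", "office", "general", 0],
            ["P1", "2014-07-15", "bedside", "internal", 0],
            ["P2", "2014-04-02", "office", "general", 0],
        ],
        list(cs.synthetic.SCHEMAS["visits"]),
    )
    hospitalisations = _frame(
        "hospitalisations",
        [
            ["P2", "2014-03-01", "2014-03-05", 5, "general", "disease"],
            ["P2", "2014-06-10", "2014-06-10", 4, "university", "accident"],
        ],
        list(cs.synthetic.SCHEMAS["hospitalisations"]),
    )
    care = _frame(
        "care",
        [
            ["P2", "2014-04-01", "home_care"],
            ["P2", "2014-04-08", "home_care"],
        ],
        list(cs.synthetic.SCHEMAS["care"]),
    )
    costs = _frame(
        "costs",
        [
            ["P1", 1000.0, 1093.0],   # increase
            ["P2", 5000.0, 4000.0],   # decrease
            ["P3", 2000.0, 2000.0],   # tie -> decrease
        ],
        list(cs.synthetic.SCHEMAS["costs"]),
    )
    bundle = ClaimsBundle(patients, prescriptions, visits, hospitalisations, care, costs)
    bundle.validate()
    return bundle


@pytest.fixture(scope="session")
def bundle20k() -> ClaimsBundle:
    return cs.generate(cs.GeneratorConfig(n_patients=20_000, seed=11))


@pytest.fixture(scope="session")
def split20k(bundle20k) -> cs.LabeledSplit:
    return cs.build_labeled_split(bundle20k, list(cs.FEATURE_SETS), seed=7)


@pytest.fixture(scope="session")
def bdt20k(split20k) -> cs.CostChangeResults:
    return cs.CostChangeModel(split20k, cs.TrainConfig.bdt()).fit()


@pytest.fixture(scope="session")
def ensemble20k(bdt20k) -> cs.TreeEnsemble:
    return bdt20k.export_ensemble()


def make_split(X: np.ndarray, y: np.ndarray, seed: int = 0,
               set_label: str = "additional", names=None) -> cs.LabeledSplit:
    """LabeledSplit from plain arrays (helper for model/interpretation tests)."""
    from claimscope.cohort import LabeledSplit, split_partition
    from claimscope.features import FeatureMatrix

    n, f = X.shape
    names = names or [f"f{i}" for i in range(f)]
    index = pd.Index([f"P{i}" for i in range(n)], name="patient_id")
    frame = pd.DataFrame(X, columns=names, index=index)
    fm = FeatureMatrix(frame, {c: set_label for c in names})
    part = split_partition(index, seed)
    return LabeledSplit(fm, pd.Series(y, index=index), part, seed)


@pytest.fixture(scope="session")
def planted_noise_split() -> cs.LabeledSplit:
    """5 informative + 40 noise features; labels from a logit with an
    interaction term (used by backward-deletion recovery)."""
    rng = np.random.default_rng(42)
    n, n_noise = 10_000, 40
    info = rng.normal(size=(n, 5))
    logit = (1.2 * info[:, 0] - 1.0 * info[:, 1] + 0.8 * info[:, 2] * info[:, 3]
             + 0.9 * np.tanh(info[:, 4]))
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    noise = rng.normal(size=(n, n_noise))
    names = [f"inf_{i}" for i in range(5)] + [f"noise_{i:02d}" for i in range(n_noise)]
    return make_split(np.hstack([info, noise]), y, seed=42, names=names)
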