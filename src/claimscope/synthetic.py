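"""Synthetic two-year claims data with planted cost-change structure.

Real Swiss claims data of the kind this package analyses (patient
demographics, GTIN/ATC-coded prescriptions, outpatient visits, DRG-coded
hospitalisations, care events and annual totals) are confidential and cannot
be shipped.  This module generates a cohort with the same table schema and
with the statistical structure the downstream analysis relies on:

* regression to the mean after hospitalisation -- hospitalised patients have
  expensive first years and a low probability of a further increase;
* a chronic-progressive drug class (anticholinesterase analogue ``N06DA``)
  whose users tend towards cost increases;
* an acute-proxy drug class (intravenous anaesthetic analogue ``N01AX``)
  whose users tend towards decreases;
* a pregnancy-like latent subgroup (young women, folic-acid analogue
  ``B03BB``, repeated gynaecology visits, a quiet first quarter) with a very
  high probability of increase;
* a mild "self-assessed healthy" signal carried by a high, unchanged
  deductible.

The binary increase/decrease outcome is drawn from an explicit per-stratum
Bernoulli, so the planted conditional probabilities are exact by
construction; year-2 costs are then synthesised to agree with the drawn
label.  Generation is a pure function of the :class:`GeneratorConfig`
(including its seed).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ATC5_PATTERN",
    "ClaimsBundle",
    "GeneratorConfig",
    "SchemaError",
    "generate",
    "read_bundle",
    "write_bundle",
]

ATC5_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: Named drug classes (4th ATC level) that the planted scenarios use.  The
#: codes follow the real ATC grammar but the cohort around them is synthetic.
NAMED_ATC4 = [
    "B03BB",  # folic acid analogue -- pregnancy scenario marker
    "A12CC",  # magnesium analogue -- pregnancy co-medication
    "N06DA",  # anticholinesterase analogue -- chronic-progressive scenario
    "N01AX",  # other general anaesthetics analogue -- acute proxy (intravenous)
    "A03BA",  # belladonna alkaloid analogue
    "B01AA",  # vitamin-K antagonist analogue
    "S01BC",  # ophthalmic NSAID analogue
    "S01CA",  # ophthalmic corticosteroid analogue
]

TABLE_NAMES = ("patients", "prescriptions", "visits", "hospitalisations", "care", "costs")

# Column -> pandas dtype for each table.  Dates are ISO "YYYY-MM-DD" strings
# so that CSV round-trips are the identity.
SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str",
        "age_years": "int64",
        "gender": "str",
        "language_area": "str",
        "deductible_y1": "str",
        "deductible_y2": "str",
        "insurance_model": "str",
        "rx_count_y2": "int64",
    },
    "prescriptions": {
        "patient_id": "str",
        "date": "str",
        "gtin": "str",
        "atc5": "str",
        "mode": "str",
        "dispenser": "str",
    },
    "visits": {
        "patient_id": "str",
        "date": "str",
        "setting": "str",
        "specialty": "str",
        "weekend": "int64",
    },
    "hospitalisations": {
        "patient_id": "str",
        "admit_date": "str",
        "discharge_date": "str",
        "mdc": "int64",
        "hospital_type": "str",
        "harm_type": "str",
    },
    "care": {
        "patient_id": "str",
        "date": "str",
        "kind": "str",
    },
    "costs": {
        "patient_id": "str",
        "total_costs_y1": "float64",
        "total_costs_y2": "float64",
    },
}

DEDUCTIBLE_BANDS = ("300", "500-1000", ">1000")
MODES = ("oral", "intravenous", "topical", "inhaled", "other")
DISPENSERS = ("pharmacy", "physician", "hospital")
SPECIALTIES = ("general", "internal", "gynaecology", "cardiology", "dermatology")
CARE_KINDS = ("home_care", "nursing_home", "rehabilitation", "psychiatric")
HOSPITAL_TYPES = ("general", "university", "specialised")
HARM_TYPES = ("disease", "accident", "other")
INSURANCE_MODELS = ("standard", "family_doctor", "telmed")


class SchemaError(ValueError):
    """A table read from disk does not match the documented schema."""


def _empty_table(name: str) -> pd.DataFrame:
    schema = SCHEMAS[name]
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in schema.items()})


def _coerce(name: str, frame: pd.DataFrame) -> pd.DataFrame:
    schema = SCHEMAS[name]
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise SchemaError(f"table {name!r} is missing column {missing[0]!r}")
    out = frame[list(schema)].copy()
    for col, dtype in schema.items():
        if dtype == "str":
            out[col] = out[col].astype("object").where(out[col].notna(), None)
            out[col] = out[col].astype(str) if len(out) else out[col].astype(object)
        else:
            out[col] = out[col].astype(dtype)
    return out.reset_index(drop=True)


@dataclass
class ClaimsBundle:
    """Event-level two-year claims dataset (year-2 kept as aggregates only)."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    visits: pd.DataFrame
    hospitalisations: pd.DataFrame
    care: pd.DataFrame
    costs: pd.DataFrame

    @classmethod
    def empty(cls) -> "ClaimsBundle":
        return cls(**{name: _empty_table(name) for name in TABLE_NAMES})

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        """Check the domain invariants; raise ``ValueError`` on violation."""
        for name in TABLE_NAMES:
            frame = self.table(name)
            missing = [c for c in SCHEMAS[name] if c not in frame.columns]
            if missing:
                raise SchemaError(f"table {name!r} is missing column {missing[0]!r}")
        if len(self.patients) and (self.patients["age_years"] < 18).any():
            raise ValueError("patients with age_years < 18 present")
        if self.patients.isna().any().any():
            raise ValueError("missing demographic values present")
        if len(self.prescriptions):
            bad = ~self.prescriptions["atc5"].map(lambda c: bool(ATC5_PATTERN.match(c)))
            if bad.any():
                raise ValueError(
                    f"malformed atc5 code {self.prescriptions.loc[bad, 'atc5'].iloc[0]!r}"
                )
        if len(self.hospitalisations):
            admit = pd.to_datetime(self.hospitalisations["admit_date"])
            discharge = pd.to_datetime(self.hospitalisations["discharge_date"])
            if (discharge < admit).any():
                raise ValueError("hospitalisation with discharge_date < admit_date")
        ids = set(self.patients["patient_id"])
        if set(self.costs["patient_id"]) != ids:
            raise ValueError("costs table does not cover exactly the patient set")
        if ((self.costs["total_costs_y1"] < 0) | (self.costs["total_costs_y2"] < 0)).any():
            raise ValueError("negative annual costs present")

    def filter_patients(self, keep_ids) -> "ClaimsBundle":
        keep = set(keep_ids)
        tables = {}
        for name in TABLE_NAMES:
            frame = self.table(name)
            tables[name] = frame[frame["patient_id"].isin(keep)].reset_index(drop=True)
        return ClaimsBundle(**tables)

    def equals(self, other: "ClaimsBundle") -> bool:
        return all(self.table(n).equals(other.table(n)) for n in TABLE_NAMES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    The planted probabilities are conditional probabilities of a year-2 cost
    *increase* given the stratum; ``base_increase_prob`` is the marginal
    increase probability targeted for the whole cohort (the residual stratum
    absorbs the difference, which lands near the 0.58 seen for
    non-hospitalised patients in large claims cohorts).
    """

    n_patients: int = 20_000
    seed: int = 0
    year: int = 2014
    n_drug_classes: int = 60

    base_increase_prob: float = 0.52
    hosp_increase_prob: float = 0.23
    hosp_rate: float = 0.178

    chronic_rate: float = 0.075          # among eligible (not hospitalised/pregnant)
    chronic_increase_prob: float = 0.80
    acute_rate: float = 0.10             # among remaining eligible
    acute_increase_prob: float = 0.25

    pregnancy_assign_prob: float = 0.50  # among non-hospitalised women < 35
    pregnancy_increase_prob: float = 0.85

    deductible_signal: float = 0.06      # shift for high unchanged deductible
    utilisation_signal: float = 0.10     # heavy office use -> regression to the mean
    interaction_signal: float = 0.18     # discordant visit/prescription intensity

    #: Background exposure rates for the scenario drug classes.  Scenario
    #: classes are excluded from the ordinary prescription repertoire and
    #: instead prescribed independently at these per-patient rates, so that
    #: each class mixes planted members with label-neutral background users
    #: (as real drug classes mix indications).
    background_b03bb: float = 0.030
    background_a12cc: float = 0.040
    background_n06da: float = 0.020
    background_n01ax: float = 0.050

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_drug_classes < len(NAMED_ATC4):
            raise ValueError(f"n_drug_classes must be >= {len(NAMED_ATC4)}")
        probs = {
            "base_increase_prob": self.base_increase_prob,
            "hosp_increase_prob": self.hosp_increase_prob,
            "hosp_rate": self.hosp_rate,
            "chronic_rate": self.chronic_rate,
            "chronic_increase_prob": self.chronic_increase_prob,
            "acute_rate": self.acute_rate,
            "acute_increase_prob": self.acute_increase_prob,
            "pregnancy_assign_prob": self.pregnancy_assign_prob,
            "pregnancy_increase_prob": self.pregnancy_increase_prob,
            "background_b03bb": self.background_b03bb,
            "background_a12cc": self.background_a12cc,
            "background_n06da": self.background_n06da,
            "background_n01ax": self.background_n01ax,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    def scenarios(self) -> dict[str, dict[str, float]]:
        """The planted scenarios as a name -> parameter map."""
        return {
            "hospitalisation": {"rate": self.hosp_rate, "p_increase": self.hosp_increase_prob},
            "chronic_progressive": {
                "rate": self.chronic_rate,
                "p_increase": self.chronic_increase_prob,
                "atc4": 0.0,  # placeholder; class name is N06DA
            },
            "acute_proxy": {"rate": self.acute_rate, "p_increase": self.acute_increase_prob},
            "pregnancy": {
                "rate": self.pregnancy_assign_prob,
                "p_increase": self.pregnancy_increase_prob,
            },
        }


def atc_vocabulary(n_classes: int, seed: int) -> list[str]:
    """Deterministic list of ATC-4 class codes, named analogues first."""
    rng = np.random.default_rng(seed + 903)
    letters = np.array(list("ABCDGHJLMNPRSV"))
    sub = np.array(list("ABCDEFGHX"))
    vocab = list(NAMED_ATC4)
    seen = set(vocab)
    while len(vocab) < n_classes:
        code = (
            rng.choice(letters)
            + f"{rng.integers(1, 17):02d}"
            + rng.choice(sub)
            + rng.choice(sub)
        )
        if code not in seen:
            seen.add(code)
            vocab.append(code)
    return vocab


def _dates_from_days(year: int, days: np.ndarray) -> np.ndarray:
    """Day-of-year (1-based) -> ISO date strings within ``year``."""
    base = np.datetime64(f"{year}-01-01")
    return np.datetime_as_string(base + (days - 1).astype("timedelta64[D]"), unit="D")


def generate(config: GeneratorConfig) -> ClaimsBundle:
    """Generate a :class:`ClaimsBundle` from ``config`` (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    year = config.year

    # --- demographics -----------------------------------------------------
    patient_id = np.array([f"P{i:07d}" for i in range(n)])
    young = rng.random(n) < 0.25
    age = np.where(
        young,
        rng.integers(18, 46, size=n),
        np.clip(np.round(rng.normal(67, 12, size=n)), 30, 103).astype(int),
    ).astype(int)
    gender = np.where(rng.random(n) < 0.606, "female", "male")
    language = rng.choice(
        ["German", "French", "Italian"], size=n, p=[0.737, 0.185, 0.078]
    )
    ded1 = rng.choice(DEDUCTIBLE_BANDS, size=n, p=[0.671, 0.247, 0.082])
    keep_band = rng.random(n) < 0.9
    ded2 = np.where(keep_band, ded1, rng.choice(DEDUCTIBLE_BANDS, size=n, p=[0.671, 0.247, 0.082]))
    insurance = rng.choice(INSURANCE_MODELS, size=n, p=[0.50, 0.35, 0.15])

    # --- strata -----------------------------------------------------------
    hospitalised = rng.random(n) < config.hosp_rate
    eligible_preg = (~hospitalised) & (gender == "female") & (age < 35)
    pregnancy = eligible_preg & (rng.random(n) < config.pregnancy_assign_prob)
    eligible_chronic = ~hospitalised & ~pregnancy
    chronic = eligible_chronic & (rng.random(n) < config.chronic_rate)
    eligible_acute = eligible_chronic & ~chronic
    acute = eligible_acute & (rng.random(n) < config.acute_rate)
    residual = ~(hospitalised | pregnancy | chronic | acute)

    # --- labels: per-stratum Bernoulli ------------------------------------
    p = np.empty(n)
    p[hospitalised] = config.hosp_increase_prob
    p[pregnancy] = config.pregnancy_increase_prob
    p[chronic] = config.chronic_increase_prob
    p[acute] = config.acute_increase_prob
    # utilisation intensities drawn up-front: they shape the label below and
    # drive the visit and prescription tables later
    n_office = rng.poisson(8.0, size=n)
    n_rx = 5 + rng.poisson(14.0, size=n)
    n_res = int(residual.sum())
    if n_res:
        planted = p[~residual].sum()
        p_res = (config.base_increase_prob * n - planted) / n_res
        p_res = float(np.clip(p_res, 0.02, 0.98))
        # within-stratum modifiers, centred so the residual mean stays p_res:
        #  - high unchanged deductible = self-assessed good health -> fewer increases
        #  - heavy office utilisation -> regression to the mean
        delta = np.zeros(n)
        delta[(ded1 == ">1000") & (ded2 == ">1000")] -= config.deductible_signal
        delta[n_office >= 13] -= config.utilisation_signal
        # discordant utilisation: frequent visits with few drugs (diagnostic
        # phase) or many drugs with rare visits both point to an evolving
        # condition -- an interaction invisible to additive models
        discordant = (n_office >= 8) != (n_rx >= 19)
        delta[discordant] += config.interaction_signal
        d = delta[residual]
        p[residual] = np.clip(p_res + d - d.mean(), 0.02, 0.98)
    increase = rng.random(n) < p

    # --- costs ------------------------------------------------------------
    y1 = rng.lognormal(mean=np.log(3500.0), sigma=1.05, size=n)
    y1 = np.where(hospitalised, y1 * 2.8, y1)
    y1 = np.where(chronic, y1 * 1.3, y1)
    g = np.abs(rng.normal(0.35, 0.25, size=n)) + 0.01
    y2 = np.where(increase, y1 * np.exp(g), y1 * np.exp(-g))
    costs = pd.DataFrame(
        {
            "patient_id": patient_id,
            "total_costs_y1": np.round(y1, 2),
            "total_costs_y2": np.round(y2, 2),
        }
    )

    # --- prescriptions ----------------------------------------------------
    vocab4 = atc_vocabulary(config.n_drug_classes, config.seed)
    # two 5th-level children per class
    atc5_vocab = np.array([c + s for c in vocab4 for s in ("01", "02")])
    # scenario classes are prescribed via planted membership or explicit
    # background rates, never through the ordinary repertoire
    scenario4 = ("B03BB", "A12CC", "N06DA", "N01AX")
    background_pool = np.flatnonzero(
        ~np.isin([c[:5] for c in atc5_vocab], scenario4)
    )
    v5 = len(background_pool)

    rep_size = 2 + rng.poisson(6.0, size=n)
    max_rep = int(rep_size.max())
    rep_matrix = background_pool[rng.integers(0, v5, size=(n, max_rep))]

    pat_of_event = np.repeat(np.arange(n), n_rx)
    rep_idx = rng.integers(0, rep_size[pat_of_event])
    code_idx = rep_matrix[pat_of_event, rep_idx]

    days = rng.integers(1, 366, size=len(pat_of_event))
    mode = rng.choice(MODES, size=len(pat_of_event), p=[0.85, 0.03, 0.06, 0.04, 0.02])
    dispenser = rng.choice(DISPENSERS, size=len(pat_of_event), p=[0.70, 0.25, 0.05])

    # planted drug exposure (events appended per scenario member)
    extra_pat, extra_code, extra_mode = [], [], []

    def plant(mask: np.ndarray, atc5: str, low: int, high: int, iv: bool = False) -> None:
        idx = np.where(mask)[0]
        counts = rng.integers(low, high + 1, size=len(idx))
        reps = np.repeat(idx, counts)
        extra_pat.append(reps)
        extra_code.append(np.full(len(reps), np.where(atc5_vocab == atc5)[0][0]))
        extra_mode.append(np.full(len(reps), "intravenous" if iv else "oral"))

    # scenario members refill their marker class; background users are one-off
    plant(pregnancy, "B03BB01", 2, 3)
    plant(pregnancy & (rng.random(n) < 0.6), "A12CC01", 1, 2)
    plant(chronic, "N06DA01", 2, 4)
    plant(acute, "N01AX01", 1, 3, iv=True)
    plant(~pregnancy & (rng.random(n) < config.background_b03bb), "B03BB01", 1, 1)
    plant(~pregnancy & (rng.random(n) < config.background_a12cc), "A12CC01", 1, 2)
    plant(~chronic & (rng.random(n) < config.background_n06da), "N06DA01", 1, 2)
    plant(~acute & (rng.random(n) < config.background_n01ax), "N01AX01", 1, 2, iv=True)

    if extra_pat:
        e_pat = np.concatenate(extra_pat)
        e_code = np.concatenate(extra_code)
        e_mode = np.concatenate(extra_mode)
        pat_of_event = np.concatenate([pat_of_event, e_pat])
        code_idx = np.concatenate([code_idx, e_code])
        mode = np.concatenate([mode, e_mode])
        days = np.concatenate([days, rng.integers(1, 366, size=len(e_pat))])
        dispenser = np.concatenate(
            [dispenser, rng.choice(DISPENSERS, size=len(e_pat), p=[0.70, 0.25, 0.05])]
        )

    order = np.lexsort((days, code_idx, pat_of_event))
    pat_of_event, code_idx, days = pat_of_event[order], code_idx[order], days[order]
    mode, dispenser = mode[order], dispenser[order]
    atc5 = atc5_vocab[code_idx]
    gtin = np.char.add(
        np.char.add("G", atc5), np.where(rng.random(len(atc5)) < 0.5, "-1", "-2")
    )
    prescriptions = pd.DataFrame(
        {
            "patient_id": patient_id[pat_of_event],
            "date": _dates_from_days(year, days),
            "gtin": gtin,
            "atc5": atc5,
            "mode": mode,
            "dispenser": dispenser,
        }
    )

    # --- visits -----------------------------------------------------------
    n_office = np.where(pregnancy, 0, n_office)  # pregnancy visits planted below
    n_bed = rng.poisson(np.where(age > 70, 0.6, 0.1))
    v_pat = np.repeat(np.arange(n), n_office)
    v_days = rng.integers(1, 366, size=len(v_pat))
    v_spec = rng.choice(SPECIALTIES, size=len(v_pat), p=[0.60, 0.15, 0.05, 0.10, 0.10])
    v_setting = np.full(len(v_pat), "office")

    b_pat = np.repeat(np.arange(n), n_bed)
    b_days = rng.integers(1, 366, size=len(b_pat))
    b_spec = rng.choice(SPECIALTIES, size=len(b_pat), p=[0.70, 0.20, 0.02, 0.05, 0.03])
    b_setting = np.full(len(b_pat), "bedside")

    # pregnancy pattern: >=5 gynaecology office visits in Q2-Q4, sparse Q1
    pg_idx = np.where(pregnancy)[0]
    n_gyn = 5 + rng.poisson(2.0, size=len(pg_idx))
    g_pat = np.repeat(pg_idx, n_gyn)
    g_days = rng.integers(100, 366, size=len(g_pat))
    g_spec = np.full(len(g_pat), "gynaecology")
    g_setting = np.full(len(g_pat), "office")
    q1 = pg_idx[rng.random(len(pg_idx)) < 0.4]  # at most one early visit
    q1_days = rng.integers(1, 91, size=len(q1))

    vis_pat = np.concatenate([v_pat, b_pat, g_pat, q1])
    vis_days = np.concatenate([v_days, b_days, g_days, q1_days])
    vis_spec = np.concatenate([v_spec, b_spec, g_spec, np.full(len(q1), "general")])
    vis_setting = np.concatenate([v_setting, b_setting, g_setting, np.full(len(q1), "office")])
    order = np.lexsort((vis_days, vis_setting, vis_pat))
    vis_pat, vis_days = vis_pat[order], vis_days[order]
    vis_spec, vis_setting = vis_spec[order], vis_setting[order]
    vis_dates = _dates_from_days(year, vis_days)
    weekend = (
        pd.to_datetime(pd.Series(vis_dates)).dt.dayofweek.to_numpy() >= 5
    ).astype(int)
    visits = pd.DataFrame(
        {
            "patient_id": patient_id[vis_pat],
            "date": vis_dates,
            "setting": vis_setting,
            "specialty": vis_spec,
            "weekend": weekend,
        }
    )

    # --- hospitalisations -------------------------------------------------
    h_idx = np.where(hospitalised)[0]
    n_events = 1 + rng.poisson(0.35, size=len(h_idx))
    h_pat = np.repeat(h_idx, n_events)
    admit = rng.integers(1, 340, size=len(h_pat))
    los = rng.poisson(4.0, size=len(h_pat))  # length of stay in days, may be 0
    discharge = np.minimum(admit + los, 365)
    order = np.lexsort((admit, h_pat))
    h_pat, admit, discharge = h_pat[order], admit[order], discharge[order]
    hospitalisations = pd.DataFrame(
        {
            "patient_id": patient_id[h_pat],
            "admit_date": _dates_from_days(year, admit),
            "discharge_date": _dates_from_days(year, discharge),
            "mdc": rng.integers(1, 26, size=len(h_pat)),
            "hospital_type": rng.choice(HOSPITAL_TYPES, size=len(h_pat), p=[0.6, 0.25, 0.15]),
            "harm_type": rng.choice(HARM_TYPES, size=len(h_pat), p=[0.80, 0.15, 0.05]),
        }
    )

    # --- care events --------------------------------------------------------
    care_pat, care_days, care_kind = [], [], []
    home = (age > 75) & (rng.random(n) < 0.15)
    hc_idx = np.where(home)[0]
    n_hc = 1 + rng.poisson(6.0, size=len(hc_idx))
    care_pat.append(np.repeat(hc_idx, n_hc))
    care_kind.append(np.full(int(n_hc.sum()), "home_care"))
    for kind, rate in [("nursing_home", 0.03), ("rehabilitation", 0.05), ("psychiatric", 0.04)]:
        idx = np.where(rng.random(n) < rate)[0]
        n_ev = 1 + rng.poisson(0.5, size=len(idx))
        care_pat.append(np.repeat(idx, n_ev))
        care_kind.append(np.full(int(n_ev.sum()), kind))
    care_pat = np.concatenate(care_pat)
    care_kind = np.concatenate(care_kind)
    care_days = rng.integers(1, 366, size=len(care_pat))
    order = np.lexsort((care_days, care_kind, care_pat))
    care = pd.DataFrame(
        {
            "patient_id": patient_id[care_pat[order]],
            "date": _dates_from_days(year, care_days[order]),
            "kind": care_kind[order],
        }
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_id,
            "age_years": age,
            "gender": gender,
            "language_area": language,
            "deductible_y1": ded1,
            "deductible_y2": ded2,
            "insurance_model": insurance,
            "rx_count_y2": 5 + rng.poisson(13.0, size=n),
        }
    )

    bundle = ClaimsBundle(
        patients=_coerce("patients", patients),
        prescriptions=_coerce("prescriptions", prescriptions),
        visits=_coerce("visits", visits),
        hospitalisations=_coerce("hospitalisations", hospitalisations),
        care=_coerce("care", care),
        costs=_coerce("costs", costs),
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: ClaimsBundle, directory: str | Path) -> dict[str, Path]:
    """Write one CSV per table; returns the table -> path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        bundle.table(name).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_bundle(directory: str | Path) -> ClaimsBundle:
    """Read a bundle written by :func:`write_bundle`; validates the schema."""
    directory = Path(directory)
    tables = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing table file {path.name!r} in {directory}")
        frame = pd.read_csv(path, dtype=object)
        tables[name] = _coerce(name, frame)
    return ClaimsBundle(**tables)
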