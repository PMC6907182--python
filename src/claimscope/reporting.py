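"""Pipeline orchestration and cohort-level reporting.

:func:`summarize_cohort` produces the descriptive cohort table (medians,
IQRs, percentages per partition); :func:`run_all` drives the full pipeline
(simulate -> featurise -> cohort -> stepwise model grid -> interpretation
reports) from a single :class:`RunConfig`, writing CSV reports, a ROC curve
and a JSON manifest with every seed, the config hash and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interpret
from .cohort import LabeledSplit, PARTS, build_labeled_split
from .features import DEFAULT_CHRONIC_MAP, FEATURE_SETS
from .model import (
    CostChangeModel,
    TrainConfig,
    rank_auc,
    reports_frame,
    stepwise_experiment,
)
from .synthetic import ClaimsBundle, GeneratorConfig, generate, write_bundle

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "summarize_cohort", "run_all"]


def _median_iqr(values: pd.Series) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75]) if len(values) else (0, 0, 0)
    return f"{med:.1f} [{q1:.1f}, {q3:.1f}]"


def summarize_cohort(split: LabeledSplit, bundle: ClaimsBundle) -> pd.DataFrame:
    """Descriptive cohort statistics per partition and overall.

    Raises ``ValueError`` naming the partition if one is empty.
    """
    pat = bundle.patients.set_index("patient_id")
    costs = bundle.costs.set_index("patient_id")
    rx = bundle.prescriptions
    office = bundle.visits[bundle.visits["setting"] == "office"]
    n_drugs = rx.groupby("patient_id")["atc5"].nunique() if len(rx) else pd.Series(dtype=float)
    n_rx = rx.groupby("patient_id").size() if len(rx) else pd.Series(dtype=float)
    n_visits = office.groupby("patient_id").size() if len(office) else pd.Series(dtype=float)
    hosp_ids = set(bundle.hospitalisations["patient_id"])

    columns = {}
    for part in ("all",) + PARTS:
        ids = pd.Index(split.X.patient_ids) if part == "all" else pd.Index(
            np.array(split.X.patient_ids)[split.mask(part)]
        )
        if len(ids) == 0:
            raise ValueError(f"partition {part!r} is empty")
        sub_pat = pat.loc[ids]
        sub_cost = costs.loc[ids]
        diff = sub_cost["total_costs_y2"] - sub_cost["total_costs_y1"]
        labels = split.y.loc[ids]
        columns[part] = {
            "n": len(ids),
            "age_median_iqr": _median_iqr(sub_pat["age_years"]),
            "female_pct": round(100 * float((sub_pat["gender"] == "female").mean()), 1),
            "costs_y1_median_iqr": _median_iqr(sub_cost["total_costs_y1"]),
            "cost_diff_median_iqr": _median_iqr(diff),
            "increase_pct": round(100 * float(labels.mean()), 1),
            "n_drugs_median": float(n_drugs.reindex(ids, fill_value=0).median()),
            "n_prescriptions_median": float(n_rx.reindex(ids, fill_value=0).median()),
            "n_visits_median": float(n_visits.reindex(ids, fill_value=0).median()),
            "hospitalised_pct": round(
                100 * float(ids.isin(hosp_ids).mean()), 1
            ),
        }
    return pd.DataFrame(columns)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    feature_sets: tuple[str, ...] = tuple(FEATURE_SETS)
    split_seed: int = 7
    train_seed: int = 0
    bdt: TrainConfig = field(default_factory=TrainConfig.bdt)
    interpretation_drug: str = "B03BB"
    weight_threshold: float = 0.05
    min_support: int = 100
    min_n_nohosp: int = 150

    def to_dict(self) -> dict:
        return {
            "generator": dataclasses.asdict(self.generator),
            "feature_sets": list(self.feature_sets),
            "split_seed": self.split_seed,
            "train_seed": self.train_seed,
            "bdt": dataclasses.asdict(self.bdt),
            "interpretation_drug": self.interpretation_drug,
            "weight_threshold": self.weight_threshold,
            "min_support": self.min_support,
            "min_n_nohosp": self.min_n_nohosp,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        return cls(
            generator=GeneratorConfig(**obj.get("generator", {})),
            feature_sets=tuple(obj.get("feature_sets", FEATURE_SETS)),
            split_seed=obj.get("split_seed", 7),
            train_seed=obj.get("train_seed", 0),
            bdt=TrainConfig(**obj.get("bdt", {"kind": "bdt"})),
            interpretation_drug=obj.get("interpretation_drug", "B03BB"),
            weight_threshold=obj.get("weight_threshold", 0.05),
            min_support=obj.get("min_support", 100),
            min_n_nohosp=obj.get("min_n_nohosp", 150),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature-set label(s): {sorted(unknown)}")
        self.generator.validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig, outdir: str | Path, stepwise: bool = False) -> Path:
    """Run the full pipeline; returns the report directory.

    Stages: simulate -> featurise/cohort -> train -> (optional stepwise model
    grid) -> interpretation reports (weights, conditional probabilities,
    subgroups) -> cohort summary -> ROC curve -> manifest.  Any stage failure
    aborts with the stage name in the exception.
    """
    cfg.validate()  # fail fast before any work
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }
    stage_ctx = {"name": "init"}

    def stage(name):
        stage_ctx["name"] = name
        logger.info("stage %s ...", name)
        return time.perf_counter()

    def done(t0, rows=None):
        manifest["stages"][stage_ctx["name"]] = {
            "seconds": round(time.perf_counter() - t0, 2),
            **({"rows": rows} if rows is not None else {}),
        }

    try:
        t0 = stage("simulate")
        bundle = generate(cfg.generator)
        write_bundle(bundle, outdir / "bundle")
        done(t0, rows=bundle.n_patients)

        t0 = stage("cohort")
        split = build_labeled_split(bundle, list(cfg.feature_sets), cfg.split_seed,
                                    chronic_map=DEFAULT_CHRONIC_MAP)
        split.X.to_csv(outdir / "features.csv")
        pd.DataFrame({"patient_id": split.y.index, "label": split.y.to_numpy()}).to_csv(
            outdir / "labels.csv", index=False
        )
        pd.DataFrame(
            {"patient_id": split.partition.index, "part": split.partition.to_numpy()}
        ).to_csv(outdir / "partition.csv", index=False)
        done(t0, rows=len(split.y))

        t0 = stage("summarize")
        summarize_cohort(split, bundle).to_csv(outdir / "cohort_summary.csv")
        done(t0)

        t0 = stage("train")
        results = CostChangeModel(split, cfg.bdt).fit()
        ens = results.export_ensemble()
        ens.to_json(outdir / "model.json")
        (outdir / "model_summary.txt").write_text(results.summary() + "\n")
        done(t0)

        if stepwise:
            t0 = stage("stepwise")
            reports = stepwise_experiment(bundle, split_seed=cfg.split_seed)
            reports_frame(reports).to_csv(outdir / "model_grid.csv", index=False)
            done(t0)

        t0 = stage("roc")
        _write_roc(results, outdir / "roc.png")
        done(t0)

        t0 = stage("interpret")
        interpret.weight_analysis(
            ens, split, threshold=cfg.weight_threshold
        ).to_csv(outdir / "weight_analysis.csv", index=False)
        interpret.drug_probability_table(
            split, min_n_nohosp=cfg.min_n_nohosp
        ).to_csv(outdir / "drug_probabilities.csv", index=False)
        rules = interpret.mine_subgroups(
            ens, split, atc4=cfg.interpretation_drug, min_support=cfg.min_support
        )
        interpret.subgroup_frame(rules).to_csv(outdir / "subgroups.csv", index=False)
        (outdir / "subgroups.txt").write_text(
            "\n".join(r.describe() for r in rules) + ("\n" if rules else "")
        )
        done(t0, rows=len(rules))
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage_ctx['name']!r} failed: {exc}") from exc

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def _write_roc(results, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Xv, yv = results.split.Xy("validation")
    prob = results.predict_proba(Xv)
    order = np.argsort(-prob)
    y_sorted = yv[order]
    tpr = np.concatenate([[0], np.cumsum(y_sorted) / max(y_sorted.sum(), 1)])
    fpr = np.concatenate([[0], np.cumsum(1 - y_sorted) / max((1 - y_sorted).sum(), 1)])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, label=f"BDT (AUC {rank_auc(yv, prob):.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
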