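"""End-to-end study orchestration.

Reproduces the study skeleton: a demographically/event-balanced 3:1
train/validation split; three model variants (clinical-only, image-only "AI
grade", and the combined model) each PSO-tuned and fitted on training only;
risk-score thresholding at the six-year horizon; Kaplan-Meier / Cox / 2x2
evaluation of both arms; redistribution of histologic grade into risk
strata; a rule-based binary clinical-risk comparator; and optional
combination with an externally supplied 0-100 recurrence score on the
sub-cohort where it exists. Validation data never touch fitting, tuning or
threshold selection.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ._util import derive_seed, round_half_up
from .curation import build_age_size_composite
from .metrics import (
    CoxHR,
    HorizonConfusion,
    concordance_index,
    cox_hr_binary,
    horizon_confusion,
    km_estimate,
    logrank_test,
)
from .morphometry import FEATURE_NAMES
from .svrc import (
    SVRcHyperparams,
    SVRcModel,
    fit_svrc,
    pso_optimize,
    raw_to_score,
    select_threshold,
)

STAGE_CODES = {"I": 1.0, "II": 2.0, "IIIA/B": 3.0, "IIIC": 4.0, "IV": 5.0}
LN_CODES = {"0": 0.0, "micro": 1.0, "1-3": 2.0, ">3": 3.0}

CLINICAL_FEATURES = ["age", "age_size_composite", "stage_code", "ln_code"]
IMAGE_FEATURES = list(FEATURE_NAMES)

VARIANT_FEATURES = {
    "clinical_only": CLINICAL_FEATURES,
    "image_only": IMAGE_FEATURES,
    "full": CLINICAL_FEATURES + IMAGE_FEATURES,
}


@dataclass
class StudyConfig:
    horizon_months: float = 72.0
    validation_fraction: float = 0.25  # 3:1 split
    seed: int = 0
    use_pso: bool = True
    pso_particles: int = 20
    pso_iters: int = 50
    cv_folds: int = 5
    hyperparams: SVRcHyperparams = field(default_factory=SVRcHyperparams)
    censored_as_negative: bool = False


@dataclass
class CohortSplit:
    train_ids: list[str]
    validation_ids: list[str]
    stratify_keys: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"split arms overlap: {sorted(overlap)[:5]}")


@dataclass
class ArmReport:
    n: int
    n_events: int
    cindex: float
    threshold_reported: int
    confusion: HorizonConfusion
    cox: Optional[CoxHR]
    logrank_p: Optional[float]
    n_high: int
    n_low: int
    km_high: Optional[pd.DataFrame]
    km_low: Optional[pd.DataFrame]


@dataclass
class ModelVariant:
    name: str
    feature_names: list[str]
    model: SVRcModel
    train_report: ArmReport
    validation_report: ArmReport
    scores: pd.DataFrame  # patient_id, arm, score, stratum
    info: dict = field(default_factory=dict)


def encode_clinical(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric clinical covariates (indexed by patient_id): age, tumour size,
    age-size composite, ordinal stage and nodal codes, receptor flags and
    grade."""
    df = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["tumor_size"] = df["tumor_size"].astype(float)
    out["age_size_composite"] = build_age_size_composite(df["age"], df["tumor_size"])
    out["stage_code"] = df["stage"].map(STAGE_CODES).astype(float)
    out["ln_code"] = df["ln_category"].map(LN_CODES).astype(float)
    for c in ("er", "pr", "her2", "ngs_grade"):
        out[c] = df[c].astype(float)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"unencodable clinical values in columns {bad}")
    return out


def split_cohort(
    cohort: pd.DataFrame, validation_fraction: float = 0.25, seed: int = 0
) -> CohortSplit:
    """Stratified random split on (event, grade, ER); falls back to coarser
    stratification (with a warning) when a stratum has fewer than 2 members."""
    if len(cohort) < 8:
        raise ValueError("cohort too small to split")
    keys_by_priority = [("event", "ngs_grade", "er"), ("event", "ngs_grade"), ("event",)]
    for keys in keys_by_priority:
        strat = cohort[list(keys)].astype(str).agg("|".join, axis=1)
        if strat.value_counts().min() >= 2:
            if keys != keys_by_priority[0]:
                warnings.warn(
                    f"sparse strata; falling back to stratification on {keys}",
                    stacklevel=2,
                )
            break
    else:
        strat = None
        warnings.warn("stratification disabled (all keys too sparse)", stacklevel=2)
    tr, va = train_test_split(
        cohort["patient_id"].tolist(),
        test_size=validation_fraction,
        random_state=derive_seed(seed, 3),
        stratify=None if strat is None else strat.tolist(),
    )
    return CohortSplit(
        train_ids=sorted(tr),
        validation_ids=sorted(va),
        stratify_keys=keys if strat is not None else (),
    )


def _evaluate_arm(
    scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    threshold: int,
    config: StudyConfig,
) -> ArmReport:
    high = scores >= threshold
    confusion = horizon_confusion(
        scores, threshold, time, event, config.horizon_months,
        config.censored_as_negative,
    )
    cox = logrank_p = km_high = km_low = None
    if 0 < high.sum() < len(high):
        try:
            cox = cox_hr_binary(high.astype(int), time, event)
        except ValueError:
            cox = None
        _, logrank_p = logrank_test(high.astype(int), time, event)
        km_high = km_estimate(time[high], event[high]).to_frame()
        km_low = km_estimate(time[~high], event[~high]).to_frame()
    return ArmReport(
        n=len(scores),
        n_events=int(event.sum()),
        cindex=concordance_index(scores, time, event),
        threshold_reported=threshold,
        confusion=confusion,
        cox=cox,
        logrank_p=logrank_p,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        km_high=km_high,
        km_low=km_low,
    )


def run_variant(
    split: CohortSplit,
    variant_name: str,
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    config: StudyConfig,
    feature_subset: Optional[list[str]] = None,
) -> ModelVariant:
    """Tune (PSO) + fit one model variant on the training arm only, select
    the threshold on training, and evaluate both arms."""
    if feature_subset is None:
        if variant_name not in VARIANT_FEATURES:
            raise ValueError(
                f"unknown variant {variant_name!r}; pass feature_subset for custom sets"
            )
        feature_subset = VARIANT_FEATURES[variant_name]
    missing = [c for c in feature_subset if c not in features.columns]
    if missing:
        raise ValueError(f"variant {variant_name}: missing features {missing}")

    coh = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    seen = set(features.index)
    for ids, arm in ((split.train_ids, "train"), (split.validation_ids, "validation")):
        lack = [i for i in ids if i not in seen]
        if lack:
            raise ValueError(f"{arm} ids missing from feature table: {lack[:5]}")

    Xtr = features.loc[split.train_ids, feature_subset]
    ytr = coh.loc[split.train_ids, "time_months"].to_numpy(float)
    dtr = coh.loc[split.train_ids, "event"].to_numpy(int)

    if config.use_pso:
        hp = pso_optimize(
            Xtr, ytr, dtr,
            cv_folds=config.cv_folds,
            seed=derive_seed(config.seed, zlib.crc32(variant_name.encode()) % 1000),
            n_particles=config.pso_particles,
            n_iter=config.pso_iters,
        )
    else:
        hp = config.hyperparams
    model = fit_svrc(Xtr, ytr, dtr, hp, mode="exact")
    scores_tr = raw_to_score(model, model.predict_raw(Xtr))
    thr_raw, thr_rep = select_threshold(
        scores_tr, ytr, dtr, config.horizon_months, config.censored_as_negative
    )
    model.threshold_raw, model.threshold_reported = thr_raw, thr_rep

    score_rows = []
    reports = {}
    for ids, arm in ((split.train_ids, "train"), (split.validation_ids, "validation")):
        s = raw_to_score(model, model.predict_raw(features.loc[ids, feature_subset]))
        t = coh.loc[ids, "time_months"].to_numpy(float)
        e = coh.loc[ids, "event"].to_numpy(int)
        reports[arm] = _evaluate_arm(s, t, e, thr_rep, config)
        score_rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "arm": arm,
                    "score": s,
                    "stratum": np.where(s >= thr_rep, "high", "low"),
                }
            )
        )
    return ModelVariant(
        name=variant_name,
        feature_names=list(feature_subset),
        model=model,
        train_report=reports["train"],
        validation_report=reports["validation"],
        scores=pd.concat(score_rows, ignore_index=True),
        info={"n_train": len(split.train_ids), "n_validation": len(split.validation_ids)},
    )


# ---------------------------------------------------------------------------
# Rule-based clinical risk comparator
# ---------------------------------------------------------------------------


def load_clinical_risk_rules(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load the binary clinical-risk rule table (editable CSV; first matching
    row wins, anything unmatched is low risk). The shipped default
    approximates the Adjuvant!-derived trial categorisation: grade and
    receptor status are used, age is not."""
    if path is None:
        src = resources.files("morphrisk").joinpath("data/clinical_risk_rules.csv")
        with resources.as_file(src) as p:
            rules = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        rules = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"er", "her2", "grade", "nodal", "size_gt_cm", "risk"}
    if set(rules.columns) != required:
        raise ValueError(f"rule table must have columns {sorted(required)}")
    return rules


def clinical_risk_binary(record, rules: Optional[pd.DataFrame] = None) -> str:
    """Classify one patient as "low"/"high" by the rule table."""
    rules = load_clinical_risk_rules() if rules is None else rules
    get = record.get if hasattr(record, "get") else lambda k: getattr(record, k)
    fields = {
        "er": get("er"),
        "her2": get("her2"),
        "grade": get("ngs_grade"),
        "nodal": get("ln_category"),
        "size": get("tumor_size"),
    }
    missing = [k for k, v in fields.items() if v is None or (isinstance(v, float) and np.isnan(v))]
    if missing:
        raise ValueError(f"clinical risk needs fields {missing}")
    for row in rules.itertuples(index=False):
        if row.er != "*" and str(int(fields["er"])) != row.er:
            continue
        if row.her2 != "*" and str(int(fields["her2"])) != row.her2:
            continue
        if row.grade != "*" and str(int(fields["grade"])) != row.grade:
            continue
        if row.nodal != "*" and str(fields["nodal"]) != row.nodal:
            continue
        if row.size_gt_cm != "" and not float(fields["size"]) > float(row.size_gt_cm):
            continue
        return row.risk
    return "low"


def clinical_risk_strata(cohort: pd.DataFrame, rules: Optional[pd.DataFrame] = None) -> pd.Series:
    rules = load_clinical_risk_rules() if rules is None else rules
    df = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    return pd.Series(
        [clinical_risk_binary(row, rules) for _, row in df.iterrows()],
        index=df.index,
        name="clinical_risk",
    )


# ---------------------------------------------------------------------------
# Grade redistribution / external-score combination / report bundle
# ---------------------------------------------------------------------------


def grade_redistribution(strata: pd.Series, cohort: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate histologic grade against risk stratum.

    ``strata`` maps patient_id -> "low"/"high". Percentages use half-up
    rounding (e.g. 187 of 868 high -> 22%)."""
    df = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    if df["ngs_grade"].isna().any():
        raise ValueError("grade missing for some patients")
    aligned = strata.reindex(df.index)
    if aligned.isna().any():
        raise ValueError("strata missing for some patients")
    rows = []
    for grade, grp in df.groupby("ngs_grade"):
        s = aligned.loc[grp.index]
        n, n_high = len(grp), int((s == "high").sum())
        rows.append(
            {
                "ngs_grade": int(grade),
                "n": n,
                "n_high": n_high,
                "n_low": n - n_high,
                "pct_high": round_half_up(100.0 * n_high / n),
                "pct_low": round_half_up(100.0 * (n - n_high) / n),
            }
        )
    return pd.DataFrame(rows)


def combine_external_score(
    split: CohortSplit,
    external_scores: pd.Series,
    base_variant: str,
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    config: StudyConfig,
) -> ModelVariant:
    """Refit the base variant plus an externally supplied 0-100 score as one
    more covariate, restricted to the sub-cohort where the score exists."""
    avail = external_scores.dropna()
    sub_train = [i for i in split.train_ids if i in avail.index]
    sub_val = [i for i in split.validation_ids if i in avail.index]
    coh = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    if not sub_train or coh.loc[sub_train, "event"].sum() == 0:
        raise ValueError("external-score sub-cohort has no training events")
    sub_split = CohortSplit(
        train_ids=sub_train, validation_ids=sub_val, stratify_keys=split.stratify_keys
    )
    feats = features.copy()
    feats["external_score"] = avail.reindex(feats.index)
    base_cols = VARIANT_FEATURES.get(base_variant)
    if base_cols is None:
        raise ValueError(f"unknown base variant {base_variant!r}")
    variant = run_variant(
        sub_split,
        f"{base_variant}_plus_external",
        feats.loc[sub_train + sub_val],
        coh,
        config,
        feature_subset=base_cols + ["external_score"],
    )
    variant.info.update(
        {
            "sub_cohort_n": len(sub_train) + len(sub_val),
            "sub_cohort_events": int(coh.loc[sub_train + sub_val, "event"].sum()),
        }
    )
    return variant


def _arm_metrics_row(name: str, arm: str, rep: ArmReport) -> dict:
    c = rep.confusion
    return {
        "variant": name,
        "arm": arm,
        "n": rep.n,
        "n_events": rep.n_events,
        "cindex": rep.cindex,
        "threshold": rep.threshold_reported,
        "n_high": rep.n_high,
        "n_low": rep.n_low,
        "sensitivity": c.sensitivity,
        "specificity": c.specificity,
        "ppv": c.ppv,
        "npv": c.npv,
        "excluded": c.excluded,
        "hr": rep.cox.hr if rep.cox else np.nan,
        "hr_ci_lower": rep.cox.ci_lower if rep.cox else np.nan,
        "hr_ci_upper": rep.cox.ci_upper if rep.cox else np.nan,
        "hr_p": rep.cox.p_value if rep.cox else np.nan,
        "logrank_p": rep.logrank_p if rep.logrank_p is not None else np.nan,
    }


def _stratum_table(variant: ModelVariant, cohort: pd.DataFrame) -> pd.DataFrame:
    """Events/censored x high/low counts per arm (the published layout)."""
    coh = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    rows = []
    for arm, grp in variant.scores.groupby("arm"):
        ev = coh.loc[grp["patient_id"], "event"].to_numpy(int)
        for stratum in ("high", "low"):
            m = (grp["stratum"] == stratum).to_numpy()
            rows.append(
                {
                    "arm": arm,
                    "stratum": stratum,
                    "events": int(ev[m].sum()),
                    "censored": int((1 - ev[m]).sum()),
                    "total": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


def make_report(
    variants: dict[str, ModelVariant],
    redistributions: dict[str, pd.DataFrame],
    out_dir: str | Path,
    cohort: pd.DataFrame,
    config: Optional[StudyConfig] = None,
) -> dict[str, Path]:
    """Write the report bundle (metrics, per-patient scores, stratum tables,
    KM curves, grade redistribution, run config) as CSV/JSON files."""
    if not variants:
        raise ValueError("need at least one variant to report")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cannot write report bundle to {out}: {exc}") from exc

    paths: dict[str, Path] = {}
    metrics = pd.DataFrame(
        [
            _arm_metrics_row(v.name, arm, rep)
            for v in variants.values()
            for arm, rep in (("train", v.train_report), ("validation", v.validation_report))
        ]
    )
    paths["metrics"] = out / "metrics.csv"
    metrics.to_csv(paths["metrics"], index=False)

    for key, v in variants.items():
        p = out / f"scores_{key}.csv"
        v.scores.to_csv(p, index=False)
        paths[f"scores_{key}"] = p
        p = out / f"stratum_table_{key}.csv"
        _stratum_table(v, cohort).to_csv(p, index=False)
        paths[f"stratum_table_{key}"] = p
        for arm, rep in (("train", v.train_report), ("validation", v.validation_report)):
            for stratum, km in (("high", rep.km_high), ("low", rep.km_low)):
                if km is not None:
                    p = out / f"km_{key}_{arm}_{stratum}.csv"
                    km.to_csv(p, index=False)
                    paths[f"km_{key}_{arm}_{stratum}"] = p

    for key, table in redistributions.items():
        p = out / f"grade_redistribution_{key}.csv"
        table.to_csv(p, index=False)
        paths[f"grade_redistribution_{key}"] = p

    run_info = {
        "variants": {
            k: {
                "features": v.feature_names,
                "threshold_raw": v.model.threshold_raw,
                "threshold_reported": v.model.threshold_reported,
                "hyperparams": v.model.hyperparams.__dict__,
                **v.info,
            }
            for k, v in variants.items()
        },
    }
    if config is not None:
        run_info["config"] = {
            "horizon_months": config.horizon_months,
            "validation_fraction": config.validation_fraction,
            "seed": config.seed,
            "use_pso": config.use_pso,
            "pso_particles": config.pso_particles,
            "pso_iters": config.pso_iters,
            "cv_folds": config.cv_folds,
        }
    paths["run_config"] = out / "run_config.json"
    paths["run_config"].write_text(json.dumps(run_info, indent=2, sort_keys=True))
    return paths
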