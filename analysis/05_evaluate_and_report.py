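#!/usr/bin/env python
"""Evaluate the fitted variants and write the full report bundle.

Re-runs the variants deterministically from the saved split/seed, then
writes metrics, stratum tables, Kaplan-Meier curves, the grade-redistribution
table, the rule-based clinical-risk comparison, and the external-score
combination under results/report/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import morphrisk as mr

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--no-pso", action="store_true")
    args = ap.parse_args()

    results = ROOT / "results"
    cohort = pd.read_csv(results / "cohort.csv")
    image = pd.read_csv(results / "image_features.csv", index_col="patient_id")
    features = image.join(mr.encode_clinical(cohort))
    sp = json.loads((results / "split.json").read_text())
    split = mr.CohortSplit(sp["train_ids"], sp["validation_ids"],
                           tuple(sp["stratify_keys"]))
    config = mr.StudyConfig(use_pso=not args.no_pso, seed=args.seed)

    variants = {
        name: mr.run_variant(split, name, features, cohort, config)
        for name in ("clinical_only", "image_only", "full")
    }

    # grade redistribution under the combined and image-only models
    reds = {
        name: mr.grade_redistribution(
            v.scores.set_index("patient_id")["stratum"], cohort
        )
        for name, v in variants.items()
    }
    for name in ("full", "image_only"):
        g2 = reds[name].set_index("ngs_grade").loc[2]
        print(f"{name}: grade-2 redistribution {g2.pct_high}% high / "
              f"{g2.pct_low}% low (n={g2.n})")

    # rule-based binary clinical risk comparator
    strata = mr.clinical_risk_strata(cohort)
    coh = cohort.set_index("patient_id")
    ci = mr.concordance_index(
        (strata == "high").astype(float), coh.time_months, coh.event
    )
    print(f"rule-based clinical risk: {(strata=='high').mean():.0%} high, "
          f"C-index {ci:.3f}")

    # external gene-expression-style score on its sub-cohort
    try:
        combined = mr.combine_external_score(
            split, coh["oncotype_rs"], "full", features, cohort, config
        )
        variants["full_plus_external"] = combined
        print(f"external+full: trainC={combined.train_report.cindex:.3f} "
              f"(sub-cohort n={combined.info['sub_cohort_n']}, "
              f"events={combined.info['sub_cohort_events']})")
    except ValueError as exc:
        print(f"external-score combination skipped: {exc}")

    paths = mr.make_report(variants, reds, results / "report", cohort, config)
    full = variants["full"]
    tr = full.train_report
    print(f"full model: threshold {full.model.threshold_reported}, "
          f"sens {tr.confusion.sensitivity:.3f}, spec {tr.confusion.specificity:.3f}, "
          f"HR {tr.cox.hr:.2f}" if tr.cox else "")
    print(f"wrote {len(paths)} report files under {results/'report'}")


if __name__ == "__main__":
    main()
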