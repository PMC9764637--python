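#!/usr/bin/env python
"""Split the cohort 3:1 and fit the three model variants.

Each variant (clinical-only, image-only, combined) is PSO-tuned and fitted
on the training arm only; the 0-100 risk threshold is chosen on training at
the six-year horizon. Writes per-variant model JSONs and per-patient scores
to results/.
"""

import argparse
import json
import time
from pathlib import Path

import pandas as pd

import morphrisk as mr

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--pso-particles", type=int, default=20)
    ap.add_argument("--pso-iters", type=int, default=50)
    ap.add_argument("--no-pso", action="store_true",
                    help="use default hyperparameters (fast smoke run)")
    args = ap.parse_args()

    results = ROOT / "results"
    cohort = pd.read_csv(results / "cohort.csv")
    image = pd.read_csv(results / "image_features.csv", index_col="patient_id")
    features = image.join(mr.encode_clinical(cohort))

    split = mr.split_cohort(cohort, seed=args.seed)
    config = mr.StudyConfig(
        use_pso=not args.no_pso,
        seed=args.seed,
        pso_particles=args.pso_particles,
        pso_iters=args.pso_iters,
    )
    (results / "split.json").write_text(json.dumps(
        {"train_ids": split.train_ids, "validation_ids": split.validation_ids,
         "stratify_keys": list(split.stratify_keys)}, indent=2))

    for name in ("clinical_only", "image_only", "full"):
        t0 = time.time()
        v = mr.run_variant(split, name, features, cohort, config)
        (results / f"model_{name}.json").write_text(v.model.to_json())
        v.scores.to_csv(results / f"scores_{name}.csv", index=False)
        print(f"{name:14s} trainC={v.train_report.cindex:.3f} "
              f"valC={v.validation_report.cindex:.3f} "
              f"threshold={v.model.threshold_reported} "
              f"({time.time()-t0:.0f}s)")


if __name__ == "__main__":
    main()
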