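#!/usr/bin/env python
"""Epoch-by-epoch sleep/wake classification against consensus scoring.

Builds the scorer-consensus hypnogram per subject, collapses it to
sleep/wake, tallies the device predictions, and reports the per-subject
metric battery (sensitivity, specificity, accuracy, balanced accuracy,
precision, kappa, PABAK, d′) plus the pooled ROC/AUC.  Writes
``results/classification.json`` (ROC decimated to ~200 points).
"""

import json
from pathlib import Path

import numpy as np

from sleepvalid import classification, pipeline
from sleepvalid.epochs import to_binary
from sleepvalid.io import read_cohort
from sleepvalid.synthetic import CohortConfig, gen_cohort

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    cdir = ROOT / "scratch" / "cohort"
    if (cdir / "subjects.csv").exists():
        return read_cohort(cdir)
    return gen_cohort(CohortConfig(seed=0))


def main() -> None:
    records = load_cohort()
    per_subject = {}
    scores, truths = [], []
    for rec in records:
        a = pipeline.align_subject(rec)
        truth = to_binary(a.consensus)
        counts = classification.confusion_counts(a.pred_sleep, truth,
                                                 mask=a.class_mask)
        per_subject[rec.subject_id] = classification.class_metrics(counts)
        ok = a.class_mask & np.isfinite(a.score)
        scores.append(a.score[ok])
        truths.append(truth[ok])
    pooled_scores = np.concatenate(scores)
    pooled_truth = np.concatenate(truths)
    points, auc = classification.pooled_roc(pooled_scores, pooled_truth)
    summary = classification.cohort_class_summary(
        per_subject, pooled_scores=pooled_scores, pooled_truth=pooled_truth
    )
    print(f"pooled epochs: {len(pooled_scores)}  "
          f"sleep prevalence: {pooled_truth.mean():.3f}")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    step = max(1, len(points) // 200)
    out = {
        "summary": summary.to_dict(orient="records"),
        "per_subject": {k: v.as_dict() for k, v in per_subject.items()},
        "auc": auc,
        "roc_points": points[::step].tolist(),
        "n_pooled_epochs": int(len(pooled_scores)),
    }
    dest = ROOT / "results" / "classification.json"
    dest.parent.mkdir(exist_ok=True)
    dest.write_text(json.dumps(out, indent=1))
    print(f"\nclassification results -> {dest}")


if __name__ == "__main__":
    main()
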