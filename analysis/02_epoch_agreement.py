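#!/usr/bin/env python
"""Epoch-by-epoch and all-night HR/BR agreement (Bland–Altman + Pearson).

Reads the cohort simulated by ``01_simulate_cohort.py`` (regenerating it
if absent), clock-aligns each subject via the movement channels, curates
epoch pairs against the reference, and runs the full agreement decision
tree per channel.  Writes ``results/epoch_agreement.json``.
"""

import json
from pathlib import Path

import numpy as np

from sleepvalid import blandaltman, pipeline
from sleepvalid.io import read_cohort
from sleepvalid.synthetic import CohortConfig, gen_cohort

ROOT = Path(__file__).resolve().parents[1]


def load_cohort():
    cdir = ROOT / "scratch" / "cohort"
    if (cdir / "subjects.csv").exists():
        return read_cohort(cdir)
    return gen_cohort(CohortConfig(seed=0))


def describe(res: dict) -> str:
    if res["kind"] == "plain":
        return (
            f"bias {res['bias']:+.3f} (95% CI {res['ci_bias'][0]:.3f}, "
            f"{res['ci_bias'][1]:.3f}); LOA ({res['loa_lower']:.3f}, "
            f"{res['loa_upper']:.3f})"
        )
    return (
        f"modeled bias {res['b0']:.3f} + {res['b1']:.3f} x ref; "
        f"LOA half-width 2.46 x ({res['c0']:.3f} + {res['c1']:.3f} x ref); "
        f"transform={res['transform']}"
    )


def main() -> None:
    records = load_cohort()
    aligned = [pipeline.align_subject(r) for r in records]
    out = {}
    for key, get in (("hr", lambda a: a.pairs_hr), ("br", lambda a: a.pairs_br)):
        groups = [(get(a).reference, get(a).device) for a in aligned]
        epoch = blandaltman.analyze_agreement(groups, mode="epoch", seed=0)
        pooled_r = blandaltman.pearson_ci(
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )
        nights = [(np.array([g[0].mean()]), np.array([g[1].mean()])) for g in groups]
        night = blandaltman.analyze_agreement(nights, mode="summary", seed=1)
        night_r = blandaltman.pearson_ci(
            np.array([g[0].mean() for g in groups]),
            np.array([g[1].mean() for g in groups]),
        )
        coverage = float(np.mean([get(a).coverage for a in aligned]))
        out[key] = {
            "epoch": dict(epoch.as_dict(), pearson=pooled_r.as_dict()),
            "night": dict(night.as_dict(), pearson=night_r.as_dict()),
            "coverage": coverage,
        }
        print(f"{key.upper()} epoch-by-epoch: {describe(out[key]['epoch'])}; "
              f"r = {pooled_r.r:.3f}")
        print(f"{key.upper()} all-night:      {describe(out[key]['night'])}; "
              f"r = {night_r.r:.3f}")
        print(f"{key.upper()} coverage: {coverage:.3f}")
    dest = ROOT / "results" / "epoch_agreement.json"
    dest.parent.mkdir(exist_ok=True)
    dest.write_text(json.dumps(out, indent=1))
    print(f"\nagreement results -> {dest}")


if __name__ == "__main__":
    main()
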