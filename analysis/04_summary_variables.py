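#!/usr/bin/env python
"""All-night summary-variable agreement (SOL, WASO, TST, SE).

Derives each subject's reference summaries from the consensus hypnogram
and the device summaries from its predicted sleep/wake series (same
definitions, reference lights-off/on), then runs the Bland–Altman
decision tree per variable.  Writes ``results/summary_agreement.json``:
per-method mean (SD) and either a scalar bias/LOA or regression
coefficients b0/b1 and c0/c1 with the 2.46 multiplier.
"""

import json
from pathlib import Path

import numpy as np

from sleepvalid import blandaltman, pipeline
from sleepvalid.io import read_cohort
from sleepvalid.synthetic import CohortConfig, gen_cohort

ROOT = Path(__file__).resolve().parents[1]
VARIABLES = ("sol", "waso", "tst", "se")


def load_cohort():
    cdir = ROOT / "scratch" / "cohort"
    if (cdir / "subjects.csv").exists():
        return read_cohort(cdir)
    return gen_cohort(CohortConfig(seed=0))


def main() -> None:
    records = load_cohort()
    aligned = [pipeline.align_subject(r) for r in records]
    out = {}
    for var in VARIABLES:
        refs = np.array([getattr(a.ref_summary, var) for a in aligned])
        devs = np.array([getattr(a.dev_summary, var) for a in aligned])
        groups = [(np.array([r]), np.array([d])) for r, d in zip(refs, devs)]
        res = blandaltman.analyze_agreement(groups, mode="summary", seed=3)
        block = dict(
            res.as_dict(),
            reference_mean=float(refs.mean()),
            reference_sd=float(refs.std(ddof=1)),
            device_mean=float(devs.mean()),
            device_sd=float(devs.std(ddof=1)),
        )
        out[var] = block
        print(f"{var.upper():5s} reference {refs.mean():7.2f} ({refs.std(ddof=1):.2f})"
              f"  device {devs.mean():7.2f} ({devs.std(ddof=1):.2f})")
        if block["kind"] == "plain":
            print(f"      bias {block['bias']:+.2f} "
                  f"(95% CI {block['ci_bias'][0]:.2f}, {block['ci_bias'][1]:.2f}); "
                  f"LOA ({block['loa_lower']:.2f}, {block['loa_upper']:.2f})")
        else:
            print(f"      bias {block['b0']:.2f} + {block['b1']:.2f} x ref; "
                  f"LOA half-width 2.46 x ({block['c0']:.2f} + {block['c1']:.2f} x ref); "
                  f"transform={block['transform']}")
    dest = ROOT / "results" / "summary_agreement.json"
    dest.parent.mkdir(exist_ok=True)
    dest.write_text(json.dumps(out, indent=1))
    print(f"\nsummary-variable agreement -> {dest}")


if __name__ == "__main__":
    main()
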