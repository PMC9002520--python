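"""Overnight temporal concordance and its demographic correlates.

Concordance asks a different question from epoch-level agreement: do the
device's overnight heart-rate and breathing-rate *profiles* rise and
fall in parallel with the reference?  It is quantified as the lag-zero
Pearson correlation of the 15-min-smoothed, clock-aligned profiles, one
coefficient per subject per vital sign.

The cohort layer averages subject coefficients, compares HR vs BR
concordance with a paired t-test, and regresses HR concordance on sex,
age and BMI by OLS (female coded 1).

Also here: the Fisher-z sample-size calculator used to plan correlation
studies — the smallest n whose back-transformed 95 % confidence interval
for an anticipated r has a given width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

from . import alignment

__all__ = [
    "ConcordanceRecord",
    "RegressionResult",
    "subject_concordance",
    "cohort_concordance",
    "covariate_regression",
    "sample_size_correlation",
]


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-subject profile correlations with covariates."""

    subject_id: str
    r_hr: float
    p_hr: float
    r_br: float
    p_br: float
    age: float
    sex_female: int
    bmi: float
    ahi: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "r_hr": self.r_hr, "p_hr": self.p_hr,
            "r_br": self.r_br, "p_br": self.p_br,
            "age": self.age, "sex_female": self.sex_female,
            "bmi": self.bmi, "ahi": self.ahi,
        }


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of concordance on demographic covariates."""

    params: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    group_means: dict[str, tuple[float, float]]  # sex group: (mean, SE)
    n: int

    def as_dict(self) -> dict:
        return {
            "params": self.params, "se": self.se, "t": self.t, "p": self.p,
            "group_means": {k: list(v) for k, v in self.group_means.items()},
            "n": self.n,
        }


def subject_concordance(
    record, window_minutes: float = 15.0
) -> ConcordanceRecord:
    """Smooth and correlate one subject's HR and BR profile pairs.

    ``record`` is a :class:`~sleepvalid.synthetic.SubjectRecord` (or any
    object exposing ``ref_hr/dev_hr/ref_br/dev_br`` epoch series and the
    covariates).  Device series are assumed already clock-aligned.
    """
    out = {}
    for key, ref, dev in (
        ("hr", record.ref_hr, record.dev_hr),
        ("br", record.ref_br, record.dev_br),
    ):
        sr = alignment.smooth_profile(ref, window_minutes)
        sd = alignment.smooth_profile(dev, window_minutes)
        r, p = alignment.profile_xcorr(sr, sd)
        out[key] = (r, p)
    return ConcordanceRecord(
        subject_id=str(record.subject_id),
        r_hr=out["hr"][0], p_hr=out["hr"][1],
        r_br=out["br"][0], p_br=out["br"][1],
        age=float(record.age), sex_female=int(record.sex_female),
        bmi=float(record.bmi), ahi=float(record.ahi),
    )


def cohort_concordance(
    records: Sequence[ConcordanceRecord],
) -> dict:
    """Cohort mean ± SD of HR and BR concordance and their paired test.

    The HR-vs-BR comparison is a two-sided paired t-test on the
    per-subject differences r_hr − r_br; a degenerate all-zero
    difference vector yields a NaN p-value.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 subjects")
    r_hr = np.array([rec.r_hr for rec in records])
    r_br = np.array([rec.r_br for rec in records])
    d = r_hr - r_br
    if np.ptp(d) == 0 and d[0] == 0:
        p_paired = math.nan
    else:
        p_paired = float(stats.ttest_rel(r_hr, r_br)[1])
    return {
        "hr_mean": float(r_hr.mean()), "hr_sd": float(r_hr.std(ddof=1)),
        "br_mean": float(r_br.mean()), "br_sd": float(r_br.std(ddof=1)),
        "paired_p": p_paired,
        "n": len(records),
    }


def covariate_regression(
    records: Sequence[ConcordanceRecord],
    response: str = "r_hr",
    include_ahi: bool = False,
) -> RegressionResult:
    """OLS of a concordance coefficient on sex, age and BMI.

    Sex enters as a female indicator.  AHI can be added as an optional
    fourth covariate.  A rank-deficient design raises ``ValueError``
    naming the collinear columns.
    """
    y = np.array([getattr(r, response) for r in records], dtype=float)
    cols = {
        "sex_female": np.array([r.sex_female for r in records], dtype=float),
        "age": np.array([r.age for r in records], dtype=float),
        "bmi": np.array([r.bmi for r in records], dtype=float),
    }
    if include_ahi:
        cols["ahi"] = np.array([r.ahi for r in records], dtype=float)
    names = ["intercept"] + list(cols)
    X = np.column_stack([np.ones(len(y))] + list(cols.values()))
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > {X.shape[1]} subjects")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        degenerate = [n for n, v in cols.items() if np.ptp(v) == 0]
        raise ValueError(
            f"rank-deficient design; collinear or constant columns: "
            f"{degenerate or 'unknown'}"
        )
    fit = sm.OLS(y, X).fit()

    female = cols["sex_female"] == 1
    groups = {}
    for label, sel in (("female", female), ("male", ~female)):
        if sel.any():
            vals = y[sel]
            se = vals.std(ddof=1) / np.sqrt(sel.sum()) if sel.sum() > 1 else math.nan
            groups[label] = (float(vals.mean()), float(se))
    return RegressionResult(
        params=dict(zip(names, map(float, fit.params))),
        se=dict(zip(names, map(float, fit.bse))),
        t=dict(zip(names, map(float, fit.tvalues))),
        p=dict(zip(names, map(float, fit.pvalues))),
        group_means=groups,
        n=len(y),
    )


def fisher_ci_width(r: float, n: int, level: float = 0.95) -> float:
    """Width of the back-transformed Fisher-z CI for a correlation."""
    zc = float(stats.norm.ppf(0.5 + level / 2))
    z = math.atanh(r)
    half = zc / math.sqrt(n - 3)
    return math.tanh(z + half) - math.tanh(z - half)


def sample_size_correlation(
    r: float, half_width: float, level: float = 0.95, n_max: int = 100_000
) -> int:
    """Smallest n giving a Fisher-z CI no wider than 2×half_width.

    Searches n = 4, 5, … for the first n at which
    tanh(atanh(r) + z/√(n−3)) − tanh(atanh(r) − z/√(n−3)) ≤ 2·half_width.
    The width is monotone decreasing in n, so the first hit is minimal.
    """
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    target = 2.0 * half_width
    for n in range(4, n_max + 1):
        if fisher_ci_width(r, n, level) <= target:
            return n
    raise ValueError(
        f"no n <= {n_max} achieves width {target} at r={r}; "
        "the requested precision is unattainable at this correlation"
    )
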