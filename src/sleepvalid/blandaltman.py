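"""Bland–Altman agreement battery for device-vs-reference comparisons.

Differences are oriented ``reference − device`` throughout, so a positive
bias means the device *underestimates* the reference.

Two plain variants are provided:

* :func:`simple_ba` — one measurement per subject; bias is the mean
  difference and the limits of agreement (LOA) are bias ± 1.96 SD, with
  the classical Bland–Altman confidence intervals.
* :func:`rm_ba` — repeated measures (epoch-by-epoch data); the total SD
  combines within- and between-subject variance components from a one-way
  random-effects ANOVA with the unequal-group-size correction
  ``n0 = (N − Σnᵢ²/N) / (m − 1)``.

When the differences show a proportional bias (their OLS regression on
the reference has a significant slope) or heteroscedasticity (the
absolute residuals regress on the reference with a significant slope),
:func:`analyze_agreement` switches to a regression-modeled report:
bias(ref) = b0 + b1·ref and 95 % LOA = bias ± 2.46·(c0 + c1·ref).  The
2.46 multiplier is 1.96·√(π/2): the absolute-residual regression
estimates the mean absolute deviation, and E|e| = σ·√(2/π) for normal
errors, so 2.46·E|e| ≈ 1.96·σ.  Coefficient CIs come from the basic
(reflected-percentile) bootstrap, resampling whole subjects.

A Shapiro–Wilk gate precedes everything; non-normal strictly-nonnegative
differences (sleep-onset-latency-like variables) are re-analyzed on the
ln(x + 1) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "BAResult",
    "ModeledBA",
    "CorrelationResult",
    "RegressionFit",
    "simple_ba",
    "rm_ba",
    "proportional_bias_test",
    "heteroscedasticity_test",
    "normality_test",
    "bootstrap_ci",
    "pearson_ci",
    "analyze_agreement",
    "bias_from_loa",
    "MAD_TO_LOA",
]

#: Converts a mean absolute deviation to a 95 % normal band half-width.
MAD_TO_LOA = 2.46

_Z95 = 1.959963984540054


class InsufficientDataError(ValueError):
    pass


class UndefinedRegressionError(ValueError):
    pass


@dataclass(frozen=True)
class BAResult:
    """Plain Bland–Altman result: bias, LOA, and their 95 % CIs."""

    bias: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    sd_total: float
    n: int
    m: int | None = None               # number of subjects (repeated measures)
    var_between: float | None = None
    var_within: float | None = None
    gates: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "kind": "plain",
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "ci_bias": list(self.ci_bias),
            "ci_loa_lower": list(self.ci_loa_lower),
            "ci_loa_upper": list(self.ci_loa_upper),
            "sd_total": self.sd_total,
            "n": self.n,
            "m": self.m,
            "var_between": self.var_between,
            "var_within": self.var_within,
            "gates": self.gates,
        }


@dataclass(frozen=True)
class RegressionFit:
    """OLS slope/intercept with t-test p-value and 95 % CIs."""

    intercept: float
    slope: float
    p_slope: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]


@dataclass(frozen=True)
class ModeledBA:
    """Regression-modeled Bland–Altman result (original measurement scale).

    ``bias(ref) = b0 + b1·ref``; 95 % LOA = bias(ref) ± half_width(ref)
    where ``half_width(ref) = 2.46·(c0 + c1·ref)`` under
    heteroscedasticity, or the constant ``1.96·residual SD`` otherwise.
    ``transform == "log"`` records that the differences failed the
    normality gate and were retested on the ln(x + 1) scale; the reported
    coefficients stay in the original units so they can be read against
    the measurements directly.
    """

    b0: float
    b1: float
    c0: float
    c1: float
    ci_b0: tuple[float, float]
    ci_b1: tuple[float, float]
    ci_c0: tuple[float, float]
    ci_c1: tuple[float, float]
    proportional_bias_detected: bool
    heteroscedastic: bool
    non_normal: bool
    transform: str                      # "none" | "log"
    resid_sd: float
    n: int
    m: int
    mean_bias: float                    # raw-scale mean difference, for reference
    gates: dict = field(default_factory=dict)

    def bias_at(self, ref: np.ndarray) -> np.ndarray:
        """Modeled bias at reference values."""
        ref = np.asarray(ref, dtype=float)
        return self.b0 + self.b1 * ref

    def half_width_at(self, ref: np.ndarray) -> np.ndarray:
        ref = np.asarray(ref, dtype=float)
        if self.heteroscedastic:
            hw = MAD_TO_LOA * (self.c0 + self.c1 * ref)
            return np.maximum(hw, 0.0)
        return np.full_like(ref, _Z95 * self.resid_sd)

    def loa_at(self, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper 95 % LOA as functions of the reference."""
        b = self.bias_at(ref)
        hw = self.half_width_at(ref)
        return b - hw, b + hw

    def as_dict(self) -> dict:
        return {
            "kind": "modeled",
            "b0": self.b0, "b1": self.b1, "c0": self.c0, "c1": self.c1,
            "ci_b0": list(self.ci_b0), "ci_b1": list(self.ci_b1),
            "ci_c0": list(self.ci_c0), "ci_c1": list(self.ci_c1),
            "proportional_bias_detected": self.proportional_bias_detected,
            "heteroscedastic": self.heteroscedastic,
            "non_normal": self.non_normal,
            "transform": self.transform,
            "resid_sd": self.resid_sd,
            "n": self.n, "m": self.m,
            "mean_bias": self.mean_bias,
            "gates": self.gates,
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci: tuple[float, float]
    n: int

    def as_dict(self) -> dict:
        return {"r": self.r, "ci": list(self.ci), "n": self.n}


def bias_from_loa(loa_lower: float, loa_upper: float) -> float:
    """Recover the bias from symmetric limits of agreement.

    The plain construction LOA = bias ± 1.96 SD implies
    bias = (lower + upper) / 2 exactly.
    """
    return (loa_lower + loa_upper) / 2.0


def simple_ba(reference: np.ndarray, device: np.ndarray) -> BAResult:
    """One-measurement-per-subject Bland–Altman analysis.

    bias = mean(ref − dev); LOA = bias ± 1.96 s (sample SD, n − 1);
    CI(bias) = bias ± t·s/√n and CI(LOA) = LOA ± t·s·√(3/n) with
    t = t(0.975, n − 1).
    """
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    if ref.shape != dev.shape:
        raise ValueError("reference/device length mismatch")
    d = ref - dev
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {n}")
    bias = float(d.mean())
    s = float(d.std(ddof=1))
    t = float(stats.t.ppf(0.975, n - 1))
    half_bias = t * s / np.sqrt(n)
    half_loa = t * s * np.sqrt(3.0 / n)
    lo, hi = bias - 1.96 * s, bias + 1.96 * s
    return BAResult(
        bias=bias, loa_lower=lo, loa_upper=hi,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(lo - half_loa, lo + half_loa),
        ci_loa_upper=(hi - half_loa, hi + half_loa),
        sd_total=s, n=n,
    )


def rm_ba(diff_groups: Sequence[np.ndarray]) -> BAResult:
    """Repeated-measures Bland–Altman from per-subject difference series.

    The grand mean of all differences is the bias.  A one-way
    random-effects ANOVA with subject as the factor yields
    within-subject variance MSW and between-subject variance
    ``max(0, (MSB − MSW)/n0)``; their sum is the total variance used for
    LOA = bias ± 1.96·sd_total.  The bias CI uses the estimated variance
    of the pooled mean on m − 1 degrees of freedom; the LOA CIs add the
    delta-method variance of sd_total (MSB, MSW treated as independent
    scaled chi-squares).

    Subjects contributing fewer than 2 differences trigger a fallback to
    :func:`simple_ba` on the per-subject means, with a warning.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in diff_groups]
    groups = [g for g in groups if g.size > 0]
    m = len(groups)
    if m < 2:
        raise InsufficientDataError(f"need >= 2 subjects, got {m}")
    if any(g.size < 2 for g in groups):
        warnings.warn(
            "subject with a single difference: falling back to the "
            "single-measurement Bland-Altman on subject means",
            stacklevel=2,
        )
        means = np.array([g.mean() for g in groups])
        return simple_ba(means, np.zeros_like(means))

    ni = np.array([g.size for g in groups], dtype=float)
    N = float(ni.sum())
    alld = np.concatenate(groups)
    grand = float(alld.mean())
    means = np.array([g.mean() for g in groups])

    ssb = float(np.sum(ni * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (m - 1)
    msw = ssw / (N - m)
    n0 = (N - float(np.sum(ni**2)) / N) / (m - 1)
    var_b = max(0.0, (msb - msw) / n0)
    var_w = msw
    sd_total = float(np.sqrt(var_b + var_w))
    lo, hi = grand - 1.96 * sd_total, grand + 1.96 * sd_total

    # Var of the pooled mean: Σ nᵢ²(σ_b² + σ_w²/nᵢ) / N²
    var_bias = (var_b * float(np.sum(ni**2)) + var_w * N) / N**2
    t = float(stats.t.ppf(0.975, m - 1))
    half_bias = t * np.sqrt(var_bias)

    # delta method for sd_total
    s2 = var_b + var_w
    if s2 > 0:
        var_msb = 2.0 * msb**2 / (m - 1)
        var_msw = 2.0 * msw**2 / (N - m)
        var_s2 = var_msb / n0**2 + (1.0 - 1.0 / n0) ** 2 * var_msw
        var_sd = var_s2 / (4.0 * s2)
    else:
        var_sd = 0.0
    half_loa = t * np.sqrt(var_bias + 1.96**2 * var_sd)

    return BAResult(
        bias=grand, loa_lower=lo, loa_upper=hi,
        ci_bias=(grand - half_bias, grand + half_bias),
        ci_loa_lower=(lo - half_loa, lo + half_loa),
        ci_loa_upper=(hi - half_loa, hi + half_loa),
        sd_total=sd_total, n=int(N), m=m,
        var_between=var_b, var_within=var_w,
    )


def _ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 points, got {x.size}")
    if np.ptp(x) == 0:
        raise UndefinedRegressionError("zero variance in the regressor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        p_slope=float(fit.pvalues[1]),
        ci_intercept=(float(ci[0, 0]), float(ci[0, 1])),
        ci_slope=(float(ci[1, 0]), float(ci[1, 1])),
    )


def proportional_bias_test(
    reference: np.ndarray, device: np.ndarray
) -> RegressionFit:
    """OLS of (reference − device) on reference; slope t-test.

    A significant slope (p < 0.05) indicates proportional bias: the
    device error changes with the magnitude of the measurement.
    """
    ref = np.asarray(reference, dtype=float)
    dev = np.asarray(device, dtype=float)
    return _ols_fit(ref, ref - dev)


def heteroscedasticity_test(
    reference: np.ndarray, residuals: np.ndarray
) -> RegressionFit:
    """OLS of |residuals from the bias model| on reference.

    The fitted line c0 + c1·ref estimates the mean absolute deviation of
    the differences as a function of the reference; multiplying by 2.46
    (= 1.96·√(π/2)) turns it into a 95 % LOA half-width under normality.
    """
    ref = np.asarray(reference, dtype=float)
    res = np.asarray(residuals, dtype=float)
    return _ols_fit(ref, np.abs(res))


def normality_test(differences: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk test of the differences.  Supports 3 <= n <= 5000.

    For larger samples, draw a random subsample first (the test's power
    at such n flags trivial departures anyway).
    """
    d = np.asarray(differences, dtype=float)
    if not 3 <= d.size <= 5000:
        raise ValueError(
            f"Shapiro-Wilk supported for 3 <= n <= 5000 (got {d.size}); "
            "subsample before testing"
        )
    w, p = stats.shapiro(d)
    return float(w), float(p)


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    data: Sequence,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Basic (reflected-percentile) bootstrap confidence interval.

    Resamples the elements of ``data`` (the resampling unit — pass
    subjects for summary variables, per-subject arrays for clustered
    epoch data) with replacement and returns
    ``(2θ̂ − q_{1−α/2}, 2θ̂ − q_{α/2})``.
    """
    if B < 200:
        raise ValueError("need B >= 200 resamples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    data = list(data)
    n = len(data)
    theta = float(statistic(data))
    reps = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic([data[i] for i in idx])
    alpha = 1.0 - level
    qlo, qhi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    if np.ptp(reps) == 0:
        warnings.warn("degenerate bootstrap distribution", stacklevel=2)
        return (theta, theta)
    return (2 * theta - float(qhi), 2 * theta - float(qlo))


def pearson_ci(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> CorrelationResult:
    """Pearson correlation with the Fisher-z confidence interval.

    CI = tanh(atanh(r) ± z·/√(n − 3)).  Perfect correlation collapses to
    the degenerate interval (r, r).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedRegressionError("zero variance input")
    r = float(stats.pearsonr(x, y)[0])
    if 1.0 - abs(r) < 1e-12:  # numerically perfect: Fisher z diverges
        r = 1.0 if r > 0 else -1.0
        return CorrelationResult(r=r, ci=(r, r), n=n)
    z = np.arctanh(r)
    zc = float(stats.norm.ppf(0.5 + level / 2))
    half = zc / np.sqrt(n - 3)
    return CorrelationResult(
        r=r, ci=(float(np.tanh(z - half)), float(np.tanh(z + half))), n=n
    )


def analyze_agreement(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
    mode: str,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> BAResult | ModeledBA:
    """Full agreement decision tree for one channel.

    ``groups`` holds one ``(reference, device)`` pair of arrays per
    subject — single values for summary variables, epoch series for
    epoch-by-epoch channels.  The procedure:

    1. Shapiro–Wilk on the differences (a seeded subsample of 5000 when
       larger); if non-normal and both measurements are nonnegative,
       retest on the ln(x + 1) scale and record the transform.
    2. OLS of differences on reference → proportional bias gate.
    3. OLS of |bias-model residuals| on reference → heteroscedasticity
       gate.
    4. All gates negative → plain result (:func:`simple_ba` in
       ``summary`` mode, :func:`rm_ba` in ``epoch`` mode); otherwise a
       :class:`ModeledBA` with original-scale coefficients and
       subject-resampled basic-bootstrap CIs.

    Fewer than 4 pairs cannot support the regression gates; such inputs
    go straight to the plain result.
    """
    if mode not in ("epoch", "summary"):
        raise ValueError("mode must be 'epoch' or 'summary'")
    groups = [
        (np.asarray(r, dtype=float).ravel(), np.asarray(d, dtype=float).ravel())
        for r, d in groups
    ]
    ref = np.concatenate([r for r, _ in groups])
    dev = np.concatenate([d for _, d in groups])
    diff = ref - dev
    rng = np.random.default_rng(seed)

    def _plain(gates: dict) -> BAResult:
        if mode == "summary":
            res = simple_ba(np.array([r.mean() for r, _ in groups]),
                            np.array([d.mean() for _, d in groups]))
        else:
            res = rm_ba([r - d for r, d in groups])
        return BAResult(
            bias=res.bias, loa_lower=res.loa_lower, loa_upper=res.loa_upper,
            ci_bias=res.ci_bias, ci_loa_lower=res.ci_loa_lower,
            ci_loa_upper=res.ci_loa_upper, sd_total=res.sd_total,
            n=res.n, m=res.m, var_between=res.var_between,
            var_within=res.var_within, gates=gates,
        )

    if np.ptp(diff) == 0:
        # identical differences (e.g. an error-free channel): the gates
        # are vacuous and the plain result is exact
        return _plain({})
    if diff.size < 4:
        return _plain({"note": "too few pairs for the regression gates"})

    sample = diff if diff.size <= 5000 else rng.choice(diff, 5000, replace=False)
    _, p_norm = normality_test(sample)
    non_normal = p_norm < alpha
    transform = "none"
    gates = {"shapiro_p": p_norm}
    if non_normal and ref.min() >= 0 and dev.min() >= 0:
        transform = "log"
        log_diff = np.log1p(ref) - np.log1p(dev)
        if log_diff.size > 5000:
            log_diff = rng.choice(log_diff, 5000, replace=False)
        _, gates["shapiro_p_transformed"] = normality_test(log_diff)

    prop = proportional_bias_test(ref, dev)
    prop_flag = prop.p_slope < alpha
    bias_resid = diff - (prop.intercept + prop.slope * ref)
    het = heteroscedasticity_test(ref, bias_resid)
    het_flag = het.p_slope < alpha
    gates.update(
        proportional_bias_p=prop.p_slope,
        heteroscedasticity_p=het.p_slope,
    )

    if not prop_flag and not het_flag and not non_normal:
        return _plain(gates)

    # regression-modeled path; bias model constant when no proportional bias
    if prop_flag:
        b0, b1 = prop.intercept, prop.slope
    else:
        b0, b1 = float(diff.mean()), 0.0
    resid = diff - (b0 + b1 * ref)
    resid_sd = float(resid.std(ddof=1))
    c0, c1 = het.intercept, het.slope

    def _coeffs(gs):
        rr = np.concatenate([r for r, _ in gs])
        dd = np.concatenate([d for _, d in gs])
        yy = rr - dd
        if np.ptp(rr) == 0:
            return np.array([yy.mean(), 0.0, np.abs(yy - yy.mean()).mean(), 0.0])
        X = np.column_stack([np.ones_like(rr), rr])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        if not prop_flag:
            beta = np.array([yy.mean(), 0.0])
        gamma, *_ = np.linalg.lstsq(X, np.abs(yy - X @ beta), rcond=None)
        return np.concatenate([beta, gamma])

    theta = np.array([b0, b1, c0, c1])
    m = len(groups)
    reps = np.empty((B, 4))
    for b in range(B):
        idx = rng.integers(0, m, size=m)
        reps[b] = _coeffs([groups[i] for i in idx])
    qlo = np.quantile(reps, 0.025, axis=0)
    qhi = np.quantile(reps, 0.975, axis=0)
    ci = [(float(2 * t - h), float(2 * t - l)) for t, l, h in zip(theta, qlo, qhi)]

    return ModeledBA(
        b0=float(b0), b1=float(b1), c0=float(c0), c1=float(c1),
        ci_b0=ci[0], ci_b1=ci[1], ci_c0=ci[2], ci_c1=ci[3],
        proportional_bias_detected=bool(prop_flag),
        heteroscedastic=bool(het_flag),
        non_normal=bool(non_normal),
        transform=transform,
        resid_sd=resid_sd,
        n=int(diff.size), m=m,
        mean_bias=float(diff.mean()),
        gates=gates,
    )
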