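"""Clock synchronization and overnight profile correlation.

The device and the reference recorder run on independent clocks, so a
residual offset can remain after timestamp-based synchronization.  Large
body movements are visible in both systems' movement channels, which
makes normalized cross-correlation of the two movement series a robust
estimator of the residual shift (in whole epochs).

The sign convention is: positive lag means the device clock is *behind*
the reference, i.e. ``device[i]`` corresponds to ``reference[i − lag]``.
To undo an estimated lag, shift the device stream by ``−lag``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .epochs import EpochSeries
from .hypnogram import EPOCH_SECONDS

__all__ = [
    "AlignmentResult",
    "estimate_offset",
    "apply_offset",
    "smooth_profile",
    "profile_xcorr",
]


class AlignmentUndefinedError(ValueError):
    """Raised when cross-correlation is undefined (e.g. zero variance)."""


class InsufficientOverlapError(ValueError):
    """Raised when too few jointly covered epochs remain."""


@dataclass(frozen=True)
class AlignmentResult:
    """Estimated clock offset between device and reference streams."""

    lag: int              # epochs; positive = device behind reference
    correlation: float    # peak normalized cross-correlation
    max_lag: int          # half-width of the search range

    def __post_init__(self) -> None:
        if abs(self.lag) > self.max_lag:
            raise ValueError("lag outside the search range")


def estimate_offset(
    ref_movement: EpochSeries,
    dev_movement: EpochSeries,
    max_lag: int = 20,
) -> AlignmentResult:
    """Find the epoch lag maximizing movement cross-correlation.

    Scans every integer lag in ``[−max_lag, +max_lag]``, computing the
    Pearson correlation of the jointly covered overlap at each lag.
    Ties are broken toward the smallest ``|lag|``, then toward the
    negative lag.
    """
    a, b = ref_movement, dev_movement
    n = len(a)
    if len(b) != n:
        raise ValueError("movement series are on different grids")
    if n < 2 * max_lag + 1:
        raise ValueError(
            f"series of {n} epochs too short for max_lag={max_lag}"
        )
    for name, s in (("reference", a), ("device", b)):
        vals = s.values[s.usable]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise AlignmentUndefinedError(
                f"{name} movement has zero variance; alignment undefined"
            )

    best: tuple[float, int, int] | None = None
    best_r = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        # device[i] ~ reference[i - lag]  =>  compare b[i] with a[i - lag]
        if lag >= 0:
            av, bv = a.values[: n - lag], b.values[lag:]
            am, bm = a.usable[: n - lag], b.usable[lag:]
        else:
            av, bv = a.values[-lag:], b.values[: n + lag]
            am, bm = a.usable[-lag:], b.usable[: n + lag]
        joint = am & bm
        if joint.sum() < 3:
            continue
        x, y = av[joint], bv[joint]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        key = (-r, abs(lag), lag)
        if best is None or key < best:
            best = key
            best_r = r
            best_lag = lag
    if best is None:
        raise AlignmentUndefinedError("no lag with a well-defined correlation")
    return AlignmentResult(lag=best_lag, correlation=best_r, max_lag=max_lag)


def apply_offset(series: EpochSeries, lag: int) -> EpochSeries:
    """Shift a series by ``lag`` epochs, masking what falls off the grid.

    Positive lag delays the series: ``out[i] = in[i − lag]``.  Length is
    preserved; epochs shifted in from outside the recording are marked
    uncovered.
    """
    n = len(series)
    if abs(lag) >= n:
        raise ValueError(f"|lag|={abs(lag)} must be smaller than length {n}")
    out = series.copy()
    if lag == 0:
        return out
    values = np.full(n, np.nan)
    covered = np.zeros(n, dtype=bool)
    artifact = np.zeros(n, dtype=bool)
    if lag > 0:
        values[lag:] = series.values[:-lag]
        covered[lag:] = series.covered[:-lag]
        artifact[lag:] = series.artifact[:-lag]
    else:
        values[:lag] = series.values[-lag:]
        covered[:lag] = series.covered[-lag:]
        artifact[:lag] = series.artifact[-lag:]
    out.values, out.covered, out.artifact = values, covered, artifact
    return out


def smooth_profile(series: EpochSeries, window_minutes: float = 15.0) -> EpochSeries:
    """Centered moving average over a time window, ignoring masked epochs.

    The default 15 min window spans 30 epochs.  Masked (uncovered or
    artifact) entries are excluded from the average rather than
    interpolated, and the window shrinks at the recording edges.  Epochs
    whose entire window is masked come out masked.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    w = max(1, int(round(window_minutes * 60.0 / EPOCH_SECONDS)))
    ok = series.usable
    vals = np.where(ok, series.values, 0.0)
    num = uniform_filter1d(vals, size=w, mode="constant", cval=0.0)
    den = uniform_filter1d(ok.astype(float), size=w, mode="constant", cval=0.0)
    out = np.full(len(series), np.nan)
    good = den > 0
    out[good] = num[good] / den[good]
    return EpochSeries(out, covered=good)


def profile_xcorr(a: EpochSeries, b: EpochSeries) -> tuple[float, float]:
    """Lag-zero Pearson correlation of two (smoothed) overnight profiles.

    Returns ``(r, p)`` with the two-sided p-value from the t distribution
    on n − 2 degrees of freedom, computed over jointly covered epochs.
    Requires at least 10 joint epochs.
    """
    if len(a) != len(b):
        raise ValueError("profiles are on different grids")
    joint = a.usable & b.usable
    n = int(joint.sum())
    if n < 10:
        raise InsufficientOverlapError(
            f"only {n} jointly covered epochs (need >= 10)"
        )
    x, y = a.values[joint], b.values[joint]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AlignmentUndefinedError("zero-variance profile")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
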