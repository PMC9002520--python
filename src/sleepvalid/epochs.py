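"""Epoch-gridded series: aggregation, curation and coverage accounting.

Everything downstream of raw signals lives on a common 0-based 30 s epoch
grid anchored at lights-off; epochs are half-open intervals [t, t+30).
An :class:`EpochSeries` carries a numeric value per epoch plus two boolean
masks: ``covered`` (the instrument produced a reading) and ``artifact``
(the reading is unusable, e.g. a PSG artifact epoch).

Curation follows the reference-first rule: reference-artifact epochs are
excluded outright, and only among the remainder are device-uncovered
epochs counted against the device's coverage rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypnogram import EPOCH_SECONDS, STAGES, Hypnogram

__all__ = [
    "EpochSeries",
    "PairedEpochs",
    "aggregate_epochs",
    "curate_pairs",
    "to_binary",
    "stage_stratified_stats",
]


class NoAnalyzableEpochsError(ValueError):
    """Raised when curation leaves no jointly analyzable epochs."""


@dataclass
class EpochSeries:
    """One numeric value per 30 s epoch with coverage/artifact masks."""

    values: np.ndarray
    covered: np.ndarray | None = None
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("epoch series must be 1-dimensional")
        n = len(self.values)
        if self.covered is None:
            self.covered = np.ones(n, dtype=bool)
        else:
            self.covered = np.asarray(self.covered, dtype=bool)
        if self.artifact is None:
            self.artifact = np.zeros(n, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if len(self.covered) != n or len(self.artifact) != n:
            raise ValueError("mask length differs from value length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def usable(self) -> np.ndarray:
        """Covered and artifact-free epochs."""
        return self.covered & ~self.artifact

    def copy(self) -> "EpochSeries":
        return EpochSeries(self.values.copy(), self.covered.copy(),
                           self.artifact.copy())


@dataclass
class PairedEpochs:
    """Jointly analyzable (reference, device) epoch pairs for one subject.

    ``analyzed = total − psg_artifact_excluded − not_covered`` always
    holds; ``coverage`` is the device coverage rate computed after
    reference-artifact removal.
    """

    reference: np.ndarray
    device: np.ndarray
    total: int
    psg_artifact_excluded: int
    not_covered: int
    subject_id: str | None = None
    epoch_index: np.ndarray = field(default=None, repr=False)

    @property
    def analyzed(self) -> int:
        return self.total - self.psg_artifact_excluded - self.not_covered

    @property
    def coverage(self) -> float:
        remaining = self.total - self.psg_artifact_excluded
        return (remaining - self.not_covered) / remaining if remaining else float("nan")

    @property
    def differences(self) -> np.ndarray:
        """reference − device (positive = device underestimates)."""
        return self.reference - self.device


def aggregate_epochs(
    timestamps: np.ndarray,
    values: np.ndarray,
    n_epochs: int,
    epoch_seconds: float = EPOCH_SECONDS,
) -> EpochSeries:
    """Average instantaneous samples into 30 s epoch means.

    Sample at time ``t`` (seconds after lights-off) belongs to epoch
    ``floor(t / 30)`` — the half-open convention, so a sample at exactly
    ``t + 30`` falls in the next epoch.  Epochs containing no samples are
    masked as uncovered.
    """
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("timestamps and values must have equal length")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite timestamps")
    idx = np.floor(t / epoch_seconds).astype(int)
    keep = (idx >= 0) & (idx < n_epochs)
    idx, v = idx[keep], v[keep]
    counts = np.bincount(idx, minlength=n_epochs)
    sums = np.bincount(idx, weights=v, minlength=n_epochs)
    covered = counts > 0
    out = np.full(n_epochs, np.nan)
    out[covered] = sums[covered] / counts[covered]
    return EpochSeries(out, covered=covered)


def curate_pairs(
    reference: EpochSeries,
    device: EpochSeries,
    subject_id: str | None = None,
) -> PairedEpochs:
    """Select jointly analyzable epochs and tally every exclusion.

    Reference artifact (or reference-uncovered) epochs are removed first;
    among the remainder, device-uncovered epochs are counted as
    ``not_covered``.  Device artifact epochs also count as not covered —
    the device produced no usable reading there.
    """
    if len(reference) != len(device):
        raise ValueError("reference and device series are on different grids")
    total = len(reference)
    ref_ok = reference.usable
    n_artifact = int((~ref_ok).sum())
    dev_ok = device.usable
    joint = ref_ok & dev_ok
    n_uncovered = int((ref_ok & ~dev_ok).sum())
    if not joint.any():
        raise NoAnalyzableEpochsError(
            f"no analyzable epochs (total={total}, artifact={n_artifact}, "
            f"not covered={n_uncovered})"
        )
    return PairedEpochs(
        reference=reference.values[joint],
        device=device.values[joint],
        total=total,
        psg_artifact_excluded=n_artifact,
        not_covered=n_uncovered,
        subject_id=subject_id,
        epoch_index=np.flatnonzero(joint),
    )


def to_binary(hyp: Hypnogram) -> np.ndarray:
    """Collapse a hypnogram to per-epoch sleep (True) / wake (False).

    W maps to wake; N1, N2, N3 and REM all map to sleep.  Unknown labels
    are rejected by the :class:`~sleepvalid.hypnogram.Hypnogram`
    constructor, so any array reaching here is valid.
    """
    return hyp.is_sleep()


def stage_stratified_stats(
    hyp: Hypnogram, series: EpochSeries
) -> pd.DataFrame:
    """Mean, SD and epoch count of a signal within each sleep stage.

    Only usable (covered, artifact-free) epochs contribute.  Stages that
    never occur are omitted from the table.
    """
    if len(hyp) != len(series):
        raise ValueError("hypnogram and series are on different grids")
    ok = series.usable
    rows = []
    for stage in STAGES:
        sel = (hyp.stages == stage) & ok
        n = int(sel.sum())
        if n == 0:
            continue
        vals = series.values[sel]
        rows.append({
            "stage": stage,
            "n": n,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
        })
    return pd.DataFrame(rows, columns=["stage", "n", "mean", "sd"])
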