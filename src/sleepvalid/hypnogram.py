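"""Hypnograms, scorer consensus, and all-night summary variables.

A hypnogram is the per-epoch sequence of sleep stages (W, N1, N2, N3, REM)
scored on 30 s epochs between lights-off and lights-on.  The summary
variables derived from it are the standard clinical quantities:

* SOL  — sleep onset latency, minutes from lights-off to the first
  non-wake epoch;
* WASO — wake after sleep onset, wake minutes strictly between sleep
  onset and sleep offset (last non-wake epoch);
* TST  — total sleep time, minutes scored as any sleep stage;
* SE   — sleep efficiency, TST divided by time in bed.

Together with the terminal wake bout these partition time in bed exactly:
SOL + WASO + TST + terminal wake = TIB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STAGES",
    "EPOCH_SECONDS",
    "Hypnogram",
    "SummaryVars",
    "consensus",
    "summary_vars",
    "summary_vars_binary",
]

#: Canonical stage labels in the conventional plotting order.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")

#: Scoring epoch length in seconds (AASM standard).
EPOCH_SECONDS: float = 30.0

#: Minutes per epoch.
_MIN_PER_EPOCH = EPOCH_SECONDS / 60.0


@dataclass
class Hypnogram:
    """Per-epoch stage labels on the lights-off-anchored 30 s grid.

    Parameters
    ----------
    stages
        Array of stage labels drawn from :data:`STAGES`; element ``i``
        covers the half-open interval ``[30 i, 30 (i+1))`` seconds after
        lights-off.
    lights_off
        First in-bed epoch index (inclusive).  Defaults to 0.
    lights_on
        One past the last in-bed epoch (exclusive).  Defaults to the
        series length.
    """

    stages: np.ndarray
    lights_off: int = 0
    lights_on: int | None = None

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="U3")
        if self.lights_on is None:
            self.lights_on = len(self.stages)
        if self.stages.ndim != 1 or len(self.stages) == 0:
            raise ValueError("hypnogram must be a non-empty 1-d sequence")
        bad = set(np.unique(self.stages)) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if not (0 <= self.lights_off < self.lights_on <= len(self.stages)):
            raise ValueError(
                f"invalid in-bed window [{self.lights_off}, {self.lights_on}) "
                f"for {len(self.stages)} epochs"
            )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def in_bed(self) -> np.ndarray:
        """Stage labels restricted to the lights-off..lights-on window."""
        return self.stages[self.lights_off : self.lights_on]

    @property
    def time_in_bed_min(self) -> float:
        return (self.lights_on - self.lights_off) * _MIN_PER_EPOCH

    def is_sleep(self) -> np.ndarray:
        """Boolean per-epoch sleep indicator (every non-W stage is sleep)."""
        return self.stages != "W"


@dataclass(frozen=True)
class SummaryVars:
    """All-night summary variables, in minutes (SE as a fraction)."""

    sol: float
    waso: float
    tst: float
    se: float
    terminal_wake: float
    time_in_bed: float = field(default=float("nan"))

    def as_dict(self) -> dict[str, float]:
        return {
            "sol": self.sol,
            "waso": self.waso,
            "tst": self.tst,
            "se": self.se,
            "terminal_wake": self.terminal_wake,
            "time_in_bed": self.time_in_bed,
        }


def consensus(
    scorer1: Hypnogram,
    scorer2: Hypnogram,
    scorer3: Hypnogram,
    expert: Hypnogram | None = None,
) -> Hypnogram:
    """Combine three technicians' scores into a consensus hypnogram.

    Each epoch takes the stage assigned by at least two of the three
    scorers.  When all three disagree the expert's label is used; if no
    expert hypnogram was supplied, a three-way tie raises ``ValueError``.
    The result inherits the in-bed window from scorer 1.
    """
    hyps = (scorer1, scorer2, scorer3)
    n = len(scorer1)
    if any(len(h) != n for h in hyps):
        raise ValueError("scorer hypnograms differ in length")
    if expert is not None and len(expert) != n:
        raise ValueError("expert hypnogram length mismatch")

    s1, s2, s3 = (h.stages for h in hyps)
    out = s1.copy()
    # majority: s1 already covers (s1==s2) and (s1==s3); remaining majority
    # case is s2==s3 != s1
    pair23 = (s2 == s3) & (s1 != s2)
    out[pair23] = s2[pair23]
    tie = (s1 != s2) & (s2 != s3) & (s1 != s3)
    if tie.any():
        if expert is None:
            raise ValueError(
                f"{int(tie.sum())} epochs with three-way scorer disagreement "
                "and no expert hypnogram to adjudicate"
            )
        out[tie] = expert.stages[tie]
    return Hypnogram(out, scorer1.lights_off, scorer1.lights_on)


def summary_vars_binary(
    sleep: np.ndarray, lights_off: int = 0, lights_on: int | None = None
) -> SummaryVars:
    """Summary variables from a boolean per-epoch sleep indicator.

    This is the common core used both for the reference hypnogram and for
    a device's predicted sleep/wake series (which has no stage labels).
    An all-wake night has SOL equal to the whole time in bed and zero
    WASO/TST/SE/terminal wake.
    """
    sleep = np.asarray(sleep, dtype=bool)
    if sleep.ndim != 1 or len(sleep) == 0:
        raise ValueError("empty sleep/wake series")
    if lights_on is None:
        lights_on = len(sleep)
    window = sleep[lights_off:lights_on]
    tib_epochs = len(window)
    if tib_epochs == 0:
        raise ValueError("empty in-bed window")
    tib = tib_epochs * _MIN_PER_EPOCH

    idx = np.flatnonzero(window)
    if idx.size == 0:
        return SummaryVars(sol=tib, waso=0.0, tst=0.0, se=0.0,
                           terminal_wake=0.0, time_in_bed=tib)
    onset, offset = idx[0], idx[-1]
    sol = onset * _MIN_PER_EPOCH
    tst = idx.size * _MIN_PER_EPOCH
    waso = ((offset - onset + 1) - idx.size) * _MIN_PER_EPOCH
    terminal = (tib_epochs - 1 - offset) * _MIN_PER_EPOCH
    return SummaryVars(sol=sol, waso=waso, tst=tst, se=tst / tib,
                       terminal_wake=terminal, time_in_bed=tib)


def summary_vars(hyp: Hypnogram) -> SummaryVars:
    """SOL / WASO / TST / SE / terminal wake for one hypnogram.

    Minutes are epochs × 0.5 with no rounding; SE is TST over time in
    bed (lights-off to lights-on).
    """
    return summary_vars_binary(hyp.is_sleep(), hyp.lights_off, hyp.lights_on)
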