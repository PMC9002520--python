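"""Cohort directory layout: plain-text serialization of subject-nights.

One directory per cohort::

    <cohort>/
      subjects.csv          # one row per subject: covariates + window
      config.yaml           # the generator configuration (when simulated)
      truth.json            # injected parameters per subject (when simulated)
      <subject_id>/epochs.csv

``epochs.csv`` columns: epoch_index, epoch_start_s, stage_truth,
stage_scorer1..3, stage_expert, ref_hr, dev_hr, ref_br, dev_br,
dev_score, dev_pred_sleep, ref_move, dev_move, hr_covered, br_covered,
psg_artifact.  Readers validate column presence and types and reject
malformed rows with their line numbers rather than silently coercing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .epochs import EpochSeries
from .hypnogram import EPOCH_SECONDS, STAGES, Hypnogram
from .synthetic import SubjectRecord

__all__ = ["write_cohort", "read_cohort", "read_epochs_csv"]

EPOCH_COLUMNS = [
    "epoch_index", "epoch_start_s", "stage_truth",
    "stage_scorer1", "stage_scorer2", "stage_scorer3", "stage_expert",
    "ref_hr", "dev_hr", "ref_br", "dev_br",
    "dev_score", "dev_pred_sleep", "ref_move", "dev_move",
    "hr_covered", "br_covered", "psg_artifact",
]

_STAGE_COLS = ["stage_truth", "stage_scorer1", "stage_scorer2",
               "stage_scorer3", "stage_expert"]
_NUMERIC_COLS = ["ref_hr", "dev_hr", "ref_br", "dev_br", "dev_score",
                 "ref_move", "dev_move"]
_BOOL_COLS = ["dev_pred_sleep", "hr_covered", "br_covered", "psg_artifact"]


def _epochs_frame(rec: SubjectRecord) -> pd.DataFrame:
    n = rec.n_epochs
    idx = np.arange(n)
    return pd.DataFrame({
        "epoch_index": idx,
        "epoch_start_s": idx * EPOCH_SECONDS,
        "stage_truth": rec.hyp_truth.stages,
        "stage_scorer1": rec.scorers[0].stages,
        "stage_scorer2": rec.scorers[1].stages,
        "stage_scorer3": rec.scorers[2].stages,
        "stage_expert": rec.expert.stages,
        "ref_hr": rec.ref_hr.values,
        "dev_hr": rec.dev_hr.values,
        "ref_br": rec.ref_br.values,
        "dev_br": rec.dev_br.values,
        "dev_score": rec.score,
        "dev_pred_sleep": rec.pred_sleep.astype(int),
        "ref_move": rec.ref_move.values,
        "dev_move": rec.dev_move.values,
        "hr_covered": rec.dev_hr.covered.astype(int),
        "br_covered": rec.dev_br.covered.astype(int),
        "psg_artifact": rec.ref_hr.artifact.astype(int),
    })


def write_cohort(
    records: list[SubjectRecord],
    outdir: str | Path,
    config: dict | None = None,
) -> Path:
    """Serialize a cohort; returns the cohort directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects = pd.DataFrame([{
        "subject_id": r.subject_id,
        "age": r.age,
        "sex_female": r.sex_female,
        "bmi": r.bmi,
        "ahi": r.ahi,
        "lights_off": r.lights_off,
        "lights_on": r.lights_on,
        "n_epochs": r.n_epochs,
    } for r in records])
    subjects.to_csv(outdir / "subjects.csv", index=False)
    truth = {r.subject_id: r.truth for r in records}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    if config is not None:
        serializable = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in config.items()
        }
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(_to_builtin(serializable), sort_keys=True)
        )
    for r in records:
        sdir = outdir / r.subject_id
        sdir.mkdir(exist_ok=True)
        _epochs_frame(r).to_csv(sdir / "epochs.csv", index=False,
                                float_format="%.6g")
    return outdir


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_epochs_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate one subject's epoch table.

    Raises ``ValueError`` naming missing columns, or listing the 1-based
    data line numbers of rows with unparseable values or unknown stage
    labels.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_lines: list[int] = []
    for col in _STAGE_COLS:
        bad = ~df[col].isin(STAGES)
        bad_lines.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
    num = {}
    for col in _NUMERIC_COLS + _BOOL_COLS + ["epoch_index", "epoch_start_s"]:
        converted = pd.to_numeric(df[col].replace("", "nan"), errors="coerce")
        # empty/NaN numeric cells are legal only for uncovered device values
        illegal = converted.isna() & (df[col] != "") & (df[col].str.lower() != "nan")
        bad_lines.extend((df.index[illegal] + 2).tolist())
        num[col] = converted
    if bad_lines:
        raise ValueError(
            f"{path}: malformed rows at lines {sorted(set(bad_lines))[:20]}"
        )
    out = df[_STAGE_COLS].copy()
    for col, vals in num.items():
        out[col] = vals
    idx = out["epoch_index"].to_numpy()
    if not np.all(np.diff(idx) > 0):
        raise ValueError(f"{path}: epoch_index must be strictly increasing")
    return out[EPOCH_COLUMNS]


def _hyp(stages: pd.Series, lights_off: int, lights_on: int) -> Hypnogram:
    return Hypnogram(stages.to_numpy(dtype="U3"), lights_off, lights_on)


def read_cohort(cohort_dir: str | Path) -> list[SubjectRecord]:
    """Load a cohort directory back into :class:`SubjectRecord` objects."""
    cohort_dir = Path(cohort_dir)
    subjects = pd.read_csv(cohort_dir / "subjects.csv")
    truth_path = cohort_dir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    records = []
    for _, row in subjects.iterrows():
        sid = str(row["subject_id"])
        df = read_epochs_csv(cohort_dir / sid / "epochs.csv")
        lo, hi = int(row["lights_off"]), int(row["lights_on"])
        artifact = df["psg_artifact"].to_numpy() > 0
        ref_hr = EpochSeries(df["ref_hr"].to_numpy(), artifact=artifact.copy())
        ref_br = EpochSeries(df["ref_br"].to_numpy(), artifact=artifact.copy())
        dev_hr = EpochSeries(df["dev_hr"].to_numpy(),
                             covered=df["hr_covered"].to_numpy() > 0)
        dev_br = EpochSeries(df["dev_br"].to_numpy(),
                             covered=df["br_covered"].to_numpy() > 0)
        records.append(SubjectRecord(
            subject_id=sid,
            age=float(row["age"]), sex_female=int(row["sex_female"]),
            bmi=float(row["bmi"]), ahi=float(row["ahi"]),
            hyp_truth=_hyp(df["stage_truth"], lo, hi),
            scorers=tuple(_hyp(df[f"stage_scorer{i}"], lo, hi) for i in (1, 2, 3)),
            expert=_hyp(df["stage_expert"], lo, hi),
            ref_hr=ref_hr, dev_hr=dev_hr, ref_br=ref_br, dev_br=dev_br,
            score=df["dev_score"].to_numpy(),
            pred_sleep=df["dev_pred_sleep"].to_numpy() > 0,
            ref_move=EpochSeries(df["ref_move"].to_numpy()),
            dev_move=EpochSeries(df["dev_move"].to_numpy()),
            lights_off=lo, lights_on=hi,
            truth=truth.get(sid, {}),
        ))
    return records
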