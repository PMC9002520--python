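"""End-to-end validation of a cohort of subject-nights.

Per subject: estimate the residual clock offset from the movement
channels, undo it on every device stream, curate HR/BR epoch pairs
against the reference, and build the sleep/wake classification stream
against the scorer-consensus hypnogram.  Cohort level: the Bland–Altman
battery per channel (epoch-by-epoch and all-night HR/BR; SOL, WASO, TST,
SE), the classification summary with pooled ROC, and the concordance
analysis with its covariate regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import alignment, blandaltman, classification, concordance
from .epochs import EpochSeries, PairedEpochs, curate_pairs, to_binary
from .hypnogram import Hypnogram, SummaryVars, consensus, summary_vars, summary_vars_binary
from .synthetic import SubjectRecord

__all__ = ["AlignedSubject", "align_subject", "run_validation"]

SUMMARY_VARIABLES = ("sol", "waso", "tst", "se")


@dataclass
class AlignedSubject:
    """One subject after clock alignment, curation and consensus scoring."""

    record: SubjectRecord
    lag: int
    dev_hr: EpochSeries
    dev_br: EpochSeries
    score: np.ndarray
    pred_sleep: np.ndarray
    dev_move: EpochSeries
    consensus: Hypnogram
    pairs_hr: PairedEpochs
    pairs_br: PairedEpochs
    ref_summary: SummaryVars
    dev_summary: SummaryVars
    class_mask: np.ndarray = field(default=None, repr=False)


def align_subject(
    rec: SubjectRecord,
    max_lag: int = 20,
    exclude_uncovered_from_classification: bool = False,
) -> AlignedSubject:
    """Align, curate and summarize one subject-night.

    The estimated movement lag is removed from every device stream
    (positive lag means the device clock ran behind, so streams shift
    back by −lag).  The classification stream keeps device-uncovered HR
    epochs by default — the classifier always emits a state — but can
    exclude them via ``exclude_uncovered_from_classification``.
    """
    est = alignment.estimate_offset(rec.ref_move, rec.dev_move, max_lag=max_lag)
    lag = est.lag
    dev_hr = alignment.apply_offset(rec.dev_hr, -lag)
    dev_br = alignment.apply_offset(rec.dev_br, -lag)
    dev_move = alignment.apply_offset(rec.dev_move, -lag)
    score_series = alignment.apply_offset(EpochSeries(rec.score), -lag)
    pred_series = alignment.apply_offset(
        EpochSeries(rec.pred_sleep.astype(float)), -lag
    )

    cons = consensus(*rec.scorers, rec.expert)
    pairs_hr = curate_pairs(rec.ref_hr, dev_hr, rec.subject_id)
    pairs_br = curate_pairs(rec.ref_br, dev_br, rec.subject_id)

    mask = score_series.covered.copy()
    if exclude_uncovered_from_classification:
        mask &= dev_hr.usable
    pred = pred_series.values > 0.5

    ref_sum = summary_vars(cons)
    # the device always emits a state, so its summaries use the full
    # predicted series regardless of HR coverage
    dev_sum = summary_vars_binary(pred, cons.lights_off, cons.lights_on)
    return AlignedSubject(
        record=rec, lag=lag, dev_hr=dev_hr, dev_br=dev_br,
        score=score_series.values, pred_sleep=pred, dev_move=dev_move,
        consensus=cons, pairs_hr=pairs_hr, pairs_br=pairs_br,
        ref_summary=ref_sum, dev_summary=dev_sum, class_mask=mask,
    )


def run_validation(
    records: list[SubjectRecord],
    max_lag: int = 20,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Run the full agreement battery over a cohort.

    Returns a JSON-serializable dict with blocks ``agreement`` (epoch and
    all-night HR/BR plus the four summary variables), ``classification``,
    ``concordance``, and per-subject tallies.
    """
    aligned = [align_subject(r, max_lag=max_lag) for r in records]

    report: dict = {"n_subjects": len(records)}

    def _pearson(x, y):
        try:
            return blandaltman.pearson_ci(x, y).as_dict()
        except blandaltman.InsufficientDataError:
            return None

    # --- HR/BR agreement -------------------------------------------------
    agreement = {}
    for key, get in (
        ("hr", lambda a: a.pairs_hr),
        ("br", lambda a: a.pairs_br),
    ):
        groups = [(get(a).reference, get(a).device) for a in aligned]
        epoch_res = blandaltman.analyze_agreement(
            groups, mode="epoch", alpha=alpha, B=B, seed=seed
        )
        pooled_ref = np.concatenate([g[0] for g in groups])
        pooled_dev = np.concatenate([g[1] for g in groups])
        epoch_r = _pearson(pooled_ref, pooled_dev)

        night_groups = [
            (np.array([g[0].mean()]), np.array([g[1].mean()])) for g in groups
        ]
        night_res = blandaltman.analyze_agreement(
            night_groups, mode="summary", alpha=alpha, B=B, seed=seed + 1
        )
        night_r = _pearson(
            np.array([g[0].mean() for g in groups]),
            np.array([g[1].mean() for g in groups]),
        )
        agreement[f"{key}_epoch"] = dict(epoch_res.as_dict(), pearson=epoch_r)
        agreement[f"{key}_night"] = dict(night_res.as_dict(), pearson=night_r)
        agreement[f"{key}_coverage"] = float(
            np.mean([get(a).coverage for a in aligned])
        )
    # summary variables (Bland–Altman per variable across subjects)
    for var in SUMMARY_VARIABLES:
        groups = [
            (np.array([getattr(a.ref_summary, var)]),
             np.array([getattr(a.dev_summary, var)]))
            for a in aligned
        ]
        res = blandaltman.analyze_agreement(
            groups, mode="summary", alpha=alpha, B=B, seed=seed + 2
        )
        refs = np.array([getattr(a.ref_summary, var) for a in aligned])
        devs = np.array([getattr(a.dev_summary, var) for a in aligned])
        agreement[var] = dict(
            res.as_dict(),
            reference_mean=float(refs.mean()), reference_sd=float(refs.std(ddof=1)),
            device_mean=float(devs.mean()), device_sd=float(devs.std(ddof=1)),
        )
    report["agreement"] = agreement

    # --- sleep/wake classification ---------------------------------------
    per_subject = {}
    pooled_scores, pooled_truth = [], []
    for a in aligned:
        truth = to_binary(a.consensus)
        counts = classification.confusion_counts(
            a.pred_sleep, truth, mask=a.class_mask
        )
        per_subject[a.record.subject_id] = classification.class_metrics(counts)
        ok = a.class_mask & np.isfinite(a.score)
        pooled_scores.append(a.score[ok])
        pooled_truth.append(truth[ok])
    summary = classification.cohort_class_summary(
        per_subject,
        pooled_scores=np.concatenate(pooled_scores),
        pooled_truth=np.concatenate(pooled_truth),
    )
    report["classification"] = {
        "per_subject": {k: v.as_dict() for k, v in per_subject.items()},
        "summary": summary.to_dict(orient="records"),
    }

    # --- concordance ------------------------------------------------------
    conc_records = []
    for a in aligned:
        proxy = replace(a.record, dev_hr=a.dev_hr, dev_br=a.dev_br)
        conc_records.append(concordance.subject_concordance(proxy))
    conc = {
        "per_subject": [c.as_dict() for c in conc_records],
        "cohort": concordance.cohort_concordance(conc_records),
    }
    # the covariate regression needs more subjects than coefficients
    if len(conc_records) > 5:
        for key, resp in (("regression_hr", "r_hr"), ("regression_br", "r_br")):
            try:
                conc[key] = concordance.covariate_regression(
                    conc_records, resp
                ).as_dict()
            except ValueError as exc:
                conc[key] = {"error": str(exc)}
    else:
        conc["regression_hr"] = conc["regression_br"] = None
    report["concordance"] = conc

    # --- per-subject summary variables --------------------------------------
    report["summary_vars"] = {
        a.record.subject_id: {
            "reference": a.ref_summary.as_dict(),
            "device": a.dev_summary.as_dict(),
        }
        for a in aligned
    }

    # --- exclusion tallies -------------------------------------------------
    report["curation"] = {
        a.record.subject_id: {
            "lag": a.lag,
            "hr": {
                "total": a.pairs_hr.total,
                "psg_artifact_excluded": a.pairs_hr.psg_artifact_excluded,
                "not_covered": a.pairs_hr.not_covered,
                "analyzed": a.pairs_hr.analyzed,
            },
            "br": {
                "total": a.pairs_br.total,
                "psg_artifact_excluded": a.pairs_br.psg_artifact_excluded,
                "not_covered": a.pairs_br.not_covered,
                "analyzed": a.pairs_br.analyzed,
            },
        }
        for a in aligned
    }
    return report
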