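"""Pottel (Q-score) rescaling of serum creatinine and drug-free-day summaries.

The Pottel score of a measurement is Scr divided by the reference
population's median Scr at the same postnatal day (Scr / Q).  In a healthy
reference population the score is distributed around 1 irrespective of age,
which turns the strongly time-dependent neonatal creatinine trajectory into a
stationary biomarker that can be read from a single observation.

"Drug-free" days — no ibuprofen, amikacin or vancomycin administered on the
day before the measurement — calibrate the score's null distribution; its
mean and SD give a cohort-specific flagging threshold (the school-age cut-off
of 1.33 is not assumed to transfer to ELBW neonates, so the threshold is
always an explicit parameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exposure import ALL_DRUGS, ExposureCalendar
from .reference import ReferenceTable

SCORED_CSV_COLUMNS = ("patient_id", "pna_day", "scr_mg_dl", "pottel_score", "drug_free")


def pottel_score(scr: float, pna_day: int, ref: ReferenceTable, patient_id=None) -> float:
    """Scr (mg/dL) divided by the day's reference p50; dimensionless, unrounded.

    Raises :class:`~neoscr.errors.ReferenceRangeError` when ``pna_day`` lies
    outside the reference coverage — scores are never extrapolated silently.
    """
    if scr <= 0:
        raise ValidationError(f"Scr must be positive, got {scr}")
    return scr / ref.lookup(pna_day, patient_id=patient_id)


def drug_free_days(cal: ExposureCalendar, day: int, patient_id) -> bool:
    """True iff no nephrotoxic drug was administered on ``day - 1``.

    Day 1 has no prior day and is always drug-free (the lag-1 rule is
    vacuously satisfied).
    """
    return cal.lag_indicator(patient_id, ALL_DRUGS, day) == 0


def score_cohort(obs: pd.DataFrame, ref: ReferenceTable, cal: ExposureCalendar) -> pd.DataFrame:
    """Score every observation and mark drug-free days.

    Parameters
    ----------
    obs : DataFrame with columns ``patient_id, pna_day, scr_mg_dl``.
    ref : reference table covering every observed day.
    cal : exposure calendar for the same cohort.

    Returns one row per input observation with ``pottel_score`` and
    ``drug_free`` columns appended.
    """
    out = obs.reset_index(drop=True).copy()
    scores = np.empty(len(out))
    free = np.empty(len(out), dtype=bool)
    for i, r in enumerate(out.itertuples()):
        scores[i] = pottel_score(r.scr_mg_dl, int(r.pna_day), ref, patient_id=r.patient_id)
        free[i] = drug_free_days(cal, int(r.pna_day), r.patient_id)
    out["pottel_score"] = scores
    out["drug_free"] = free
    return out


def summarize_drug_free(scored: pd.DataFrame) -> dict:
    """Moments of the Pottel score over drug-free days only.

    Returns ``{n, mean, sd, skewness, excess_kurtosis}``; the SD uses the
    n − 1 denominator and skewness/kurtosis are the bias-corrected sample
    versions.  Normality is reported descriptively, never tested.
    """
    x = scored.loc[scored["drug_free"], "pottel_score"]
    if len(x) < 2:
        raise ValidationError(
            f"need at least 2 drug-free scored observations, got {len(x)}"
        )
    return {
        "n": int(len(x)),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "skewness": float(x.skew()),
        "excess_kurtosis": float(x.kurt()),
    }


@dataclass
class FlagResult:
    """Per-observation threshold flags plus patient- and cohort-level summaries."""

    flags: pd.Series               # aligned with the scored frame
    first_flag_day: pd.Series      # patient_id -> first flagged pna_day (flagged patients only)
    flag_rate: float               # flagged observations / all observations
    threshold: float


def flag_scores(scored: pd.DataFrame, threshold: float) -> FlagResult:
    """Flag observations with ``pottel_score > threshold``.

    The threshold is a required, explicit parameter: no default is assumed
    because the adult/child upper limit (1.33) does not transfer to ELBW
    neonates.  A cohort-specific choice is drug-free mean + 1.96·SD.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    flags = scored["pottel_score"] > threshold
    flagged = scored[flags]
    first = flagged.groupby("patient_id")["pna_day"].min()
    rate = float(flags.mean()) if len(flags) else 0.0
    return FlagResult(flags=flags, first_flag_day=first, flag_rate=rate, threshold=threshold)
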