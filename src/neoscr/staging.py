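"""Neonatal modified-KDIGO stage-1 creatinine rule — the comparator detector.

Stage 1 is a rise of >= 0.3 mg/dL or >= 50% versus the previous measured
value.  "Previous value" is the immediately preceding measurement of the same
patient, exactly as the rule is stated for neonates — not a 48-hour window or
a lowest-prior baseline.  Because the rule compares consecutive raw Scr
values, the physiologic day 1→3-4 creatinine rise of ELBW neonates can cross
its thresholds without any pathology; contrasting it with threshold flags on
the rescaled score quantifies that divergence.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

ABSOLUTE_RISE_MG_DL = 0.3
RELATIVE_RISE_RATIO = 1.5
# guard so exact decimal boundaries (e.g. 0.50 -> 0.80) flag despite binary floats
_EPS = 1e-9

STAGED_CSV_COLUMNS = ("patient_id", "pna_day", "scr_mg_dl", "stage1_flag", "trigger")


def mkdigo_stage1(series: pd.DataFrame) -> pd.DataFrame:
    """Apply the stage-1 rule to one patient's day-ordered Scr series.

    Parameters
    ----------
    series : DataFrame with columns ``patient_id, pna_day, scr_mg_dl``,
        sorted by ``pna_day`` (non-decreasing); at least one row.

    Returns the input with ``stage1_flag`` (bool), ``trigger``
    (``absolute_rise`` / ``relative_rise`` / ``none``; when both criteria hold
    the absolute rise takes priority and ``relative_also`` records the other)
    and ``reference_previous_scr`` columns.  The first observation is never
    flagged: it has no previous value.
    """
    if series.empty:
        raise ValidationError("empty series: at least one observation is required")
    days = series["pna_day"].to_numpy()
    if (days[1:] < days[:-1]).any():
        raise ValidationError("series must be sorted by pna_day")
    out = series.reset_index(drop=True).copy()
    scr = out["scr_mg_dl"].to_numpy()
    n = len(out)
    flag = [False] * n
    trigger = ["none"] * n
    relative_also = [False] * n
    prev = [float("nan")] * n
    for i in range(1, n):
        prev[i] = scr[i - 1]
        abs_hit = scr[i] - scr[i - 1] >= ABSOLUTE_RISE_MG_DL - _EPS
        rel_hit = scr[i] / scr[i - 1] >= RELATIVE_RISE_RATIO - _EPS
        if abs_hit or rel_hit:
            flag[i] = True
            trigger[i] = "absolute_rise" if abs_hit else "relative_rise"
            relative_also[i] = abs_hit and rel_hit
    out["stage1_flag"] = flag
    out["trigger"] = trigger
    out["relative_also"] = relative_also
    out["reference_previous_scr"] = prev
    return out


def stage_cohort(obs: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`mkdigo_stage1` per patient over a long-format cohort table."""
    parts = [
        mkdigo_stage1(g.sort_values("pna_day", kind="stable"))
        for _, g in obs.groupby("patient_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True) if parts else obs.copy()


def compare_detectors(staged: pd.DataFrame, flags: pd.Series) -> dict:
    """2×2 concordance between mKDIGO stage-1 and Pottel-threshold flags.

    ``staged`` is the output of :func:`stage_cohort`; ``flags`` is a boolean
    Series over the *same* observations (same patient/day sequence after
    sorting).  Counts are reported at observation level and at patient level
    (a patient counts as detected if flagged on any day).

    Returns ``{"observation": {...}, "patient": {...}}`` with keys
    ``both, mkdigo_only, pottel_only, neither``.
    """
    if len(staged) != len(flags):
        raise ValidationError(
            f"detector outputs cover different observation sets "
            f"({len(staged)} vs {len(flags)} rows)"
        )
    mk = staged["stage1_flag"].to_numpy()
    po = flags.to_numpy()

    def table(a, b):
        return {
            "both": int((a & b).sum()),
            "mkdigo_only": int((a & ~b).sum()),
            "pottel_only": int((~a & b).sum()),
            "neither": int((~a & ~b).sum()),
        }

    obs_level = table(mk, po)
    pat = staged[["patient_id"]].copy()
    pat["mk"] = mk
    pat["po"] = po
    per = pat.groupby("patient_id")[["mk", "po"]].any()
    patient_level = table(per["mk"].to_numpy(), per["po"].to_numpy())
    return {"observation": obs_level, "patient": patient_level}
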