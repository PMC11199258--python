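"""Postnatal-day-specific median (p50) serum-creatinine reference tables.

The denominator of the Pottel score (often written Qcrea) is the median serum
creatinine of the reference population at the same postnatal age.  In neonates
the reference is day-specific only: the physiologic creatinine trajectory
changes from day to day during the first weeks of life, while the sex split of
the original school-age rescaling does not apply yet.

A :class:`ReferenceTable` maps postnatal day (day of birth = day 1) to a p50
serum creatinine in mg/dL.  Tables can be loaded from CSV
(``day,p50_scr_mg_dl``), constructed directly, or estimated from a cohort with
:func:`build_reference`, which uses the median of drug-free-day observations
and linearly interpolates days that are too sparse to estimate.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferenceRangeError, ValidationError

#: analysis window used throughout the pipeline (postnatal days, inclusive)
ANALYSIS_WINDOW = (1, 28)

CSV_COLUMNS = ("day", "p50_scr_mg_dl")


@dataclass(frozen=True)
class ReferenceTable:
    """Contiguous map from postnatal day to p50 serum creatinine (mg/dL).

    Parameters
    ----------
    p50 : dict[int, float]
        Mapping from 1-based postnatal day to a strictly positive p50 Scr.
        Days must form a contiguous range.
    interpolated_days : tuple[int, ...]
        Days whose value was filled by interpolation rather than estimated
        directly (empty for loaded tables).
    provenance : dict
        Free-form build log (per-day sample sizes, estimator settings).
    """

    p50: dict
    interpolated_days: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.p50:
            raise ValidationError("reference table has no entries")
        days = sorted(self.p50)
        for d in days:
            if int(d) != d or d < 1:
                raise ValidationError(f"invalid postnatal day {d!r}: days are integers >= 1")
            v = self.p50[d]
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"non-positive or missing p50 at day {d}: {v!r}")
        lo, hi = days[0], days[-1]
        missing = sorted(set(range(lo, hi + 1)) - set(days))
        if missing:
            raise ValidationError(
                f"gap in day sequence: day {missing[0]} missing within [{lo}, {hi}]"
            )
        object.__setattr__(self, "p50", {int(d): float(self.p50[d]) for d in days})

    @property
    def day_range(self) -> tuple:
        days = sorted(self.p50)
        return (days[0], days[-1])

    @property
    def covers_analysis_window_only(self) -> bool:
        """False (flagged) when the table extends beyond days 1-28."""
        lo, hi = self.day_range
        return lo >= ANALYSIS_WINDOW[0] and hi <= ANALYSIS_WINDOW[1]

    def lookup(self, day: int, patient_id=None) -> float:
        try:
            return self.p50[int(day)]
        except KeyError:
            raise ReferenceRangeError(day, self.day_range, patient_id) from None

    def __contains__(self, day) -> bool:
        return int(day) in self.p50

    def to_frame(self) -> pd.DataFrame:
        days = sorted(self.p50)
        return pd.DataFrame({"day": days, "p50_scr_mg_dl": [self.p50[d] for d in days]})


def load_reference(path) -> ReferenceTable:
    """Load a reference table from a ``day,p50_scr_mg_dl`` CSV.

    Lines starting with ``#`` (provenance headers) are ignored.  Raises
    :class:`ValidationError` on duplicate days, gaps in the day sequence, or
    non-positive p50 values, naming the offending day.
    """
    if not os.path.exists(path):
        raise ValidationError(f"reference CSV not found: {path}")
    df = pd.read_csv(path, comment="#")
    if list(df.columns) != list(CSV_COLUMNS):
        raise ValidationError(
            f"reference CSV {path} must have header 'day,p50_scr_mg_dl', got {list(df.columns)}"
        )
    dup = df["day"][df["day"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate day rows in {path}: day {int(dup.iloc[0])}")
    if df["p50_scr_mg_dl"].isna().any():
        bad = int(df.loc[df["p50_scr_mg_dl"].isna(), "day"].iloc[0])
        raise ValidationError(f"missing p50 at day {bad} in {path}")
    return ReferenceTable({int(r.day): float(r.p50_scr_mg_dl) for r in df.itertuples()})


def write_reference(table: ReferenceTable, path, provenance: str | None = None) -> None:
    """Write a table as CSV; round-trips through :func:`load_reference`."""
    buf = io.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    table.to_frame().to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def build_reference(obs: pd.DataFrame, calendar, min_n_per_day: int = 5) -> ReferenceTable:
    """Estimate a p50 reference from a cohort's drug-free-day observations.

    For every postnatal day inside the observed range, the p50 is the median
    of serum creatinine values measured on drug-free days (no ibuprofen,
    amikacin or vancomycin administered the day before; see
    :func:`neoscr.scoring.drug_free_days`).  Days with fewer than
    ``min_n_per_day`` eligible values are filled by linear interpolation
    between the nearest directly estimated days (the nearest estimated value
    at the ends) and listed in ``interpolated_days``.

    Parameters
    ----------
    obs : DataFrame with columns ``patient_id, pna_day, scr_mg_dl``.
    calendar : :class:`neoscr.exposure.ExposureCalendar` for the same cohort.
    min_n_per_day : minimum eligible values for a direct median estimate.
    """
    from .scoring import drug_free_days  # local import avoids a cycle

    if obs.empty:
        raise ValidationError("no observations: cannot build a reference table")
    bad = obs[(obs["pna_day"] < 1) | (obs["pna_day"] > ANALYSIS_WINDOW[1])]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValidationError(
            f"observation outside days [1, {ANALYSIS_WINDOW[1]}]: "
            f"patient {r['patient_id']!r} day {int(r['pna_day'])}"
        )

    eligible = obs[
        [
            drug_free_days(calendar, int(r.pna_day), r.patient_id)
            for r in obs.itertuples()
        ]
    ]
    if eligible.empty:
        raise ValidationError("no drug-free observations: cannot build a reference table")

    lo, hi = int(obs["pna_day"].min()), int(obs["pna_day"].max())
    days = list(range(lo, hi + 1))
    grouped = eligible.groupby("pna_day")["scr_mg_dl"]
    medians = grouped.median()
    counts = grouped.size()

    direct = {d: float(medians[d]) for d in days if counts.get(d, 0) >= min_n_per_day}
    if not direct:
        raise ValidationError(
            f"no day has >= {min_n_per_day} drug-free observations; cannot estimate p50"
        )
    if len(direct) == 1:
        raise ValidationError(
            "only a single day is estimable; interpolation to other days is impossible"
        )

    est_days = np.array(sorted(direct))
    est_vals = np.array([direct[d] for d in est_days])
    # linear interpolation inside, nearest estimated value at the ends
    filled = np.interp(days, est_days, est_vals)
    p50 = dict(zip(days, filled))
    interpolated = tuple(d for d in days if d not in direct)
    provenance = {
        "estimator": "median of drug-free-day Scr",
        "min_n_per_day": min_n_per_day,
        "n_eligible_per_day": {int(d): int(counts.get(d, 0)) for d in days},
        "interpolated_days": list(interpolated),
    }
    return ReferenceTable(p50, interpolated_days=interpolated, provenance=provenance)
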