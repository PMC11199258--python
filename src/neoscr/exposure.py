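"""Drug-administration calendars, lagged exposure coding, cohort exclusions.

The three nephrotoxic drugs tracked are ibuprofen (PDA closure), amikacin and
vancomycin (the late-onset-sepsis regimen).  Exposure enters the models with a
one-day lag: an observation on day *d* is "exposed" when the drug was given on
day *d − 1*, and its cumulative exposure is the length of the uninterrupted
run of administration days ending on day *d − 1*, capped at the "5+" category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import pandas as pd

from .errors import ValidationError

DRUGS = ("ibuprofen", "amikacin", "vancomycin")

IBUPROFEN = frozenset({"ibuprofen"})
AMIKACIN = frozenset({"amikacin"})
VANCOMYCIN = frozenset({"vancomycin"})
ANTIBIOTICS = frozenset({"amikacin", "vancomycin"})
ALL_DRUGS = frozenset(DRUGS)

#: cap for the consecutive-days category ("5+" pools runs of five or more)
CATEGORY_CAP = 5

CSV_COLUMNS = ("patient_id", "drug", "pna_day")


def group_label(drug_group) -> str:
    """Human-readable label for a drug group (used in tables and logs)."""
    group = frozenset(drug_group)
    if group == ANTIBIOTICS:
        return "antibiotics"
    if group == ALL_DRUGS:
        return "any_nephrotoxic"
    return "+".join(sorted(group))


class ExposureCalendar:
    """Set of (patient, drug, postnatal day) administration events.

    Backed by per-patient, per-drug day sets for O(1) lag and run-length
    queries.  Duplicate (patient, drug, day) triples are rejected.
    """

    def __init__(self, records: pd.DataFrame | None = None):
        if records is None:
            records = pd.DataFrame(columns=list(CSV_COLUMNS))
        missing = set(CSV_COLUMNS) - set(records.columns)
        if missing:
            raise ValidationError(f"exposure table is missing columns {sorted(missing)}")
        records = records.loc[:, list(CSV_COLUMNS)].copy()
        if not records.empty:
            unknown = set(records["drug"]) - set(DRUGS)
            if unknown:
                raise ValidationError(f"unknown drug name(s) {sorted(unknown)}; expected {DRUGS}")
            if (records["pna_day"] < 1).any():
                raise ValidationError("administration days must be >= 1 (day of birth = day 1)")
            if records.duplicated().any():
                r = records[records.duplicated()].iloc[0]
                raise ValidationError(
                    f"duplicate administration record: patient {r['patient_id']!r} "
                    f"{r['drug']} day {int(r['pna_day'])}"
                )
            records["pna_day"] = records["pna_day"].astype(int)
        self._records = records.sort_values(list(CSV_COLUMNS), kind="stable").reset_index(drop=True)
        self._days: dict = {}
        for r in self._records.itertuples():
            self._days.setdefault(r.patient_id, {}).setdefault(r.drug, set()).add(r.pna_day)

    @classmethod
    def from_records(cls, records) -> "ExposureCalendar":
        """Build from an iterable of (patient_id, drug, pna_day) triples."""
        df = pd.DataFrame(list(records), columns=list(CSV_COLUMNS))
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "ExposureCalendar":
        return cls(pd.read_csv(path, comment="#"))

    def to_frame(self) -> pd.DataFrame:
        return self._records.copy()

    @property
    def patients(self):
        return set(self._days)

    def __len__(self):
        return len(self._records)

    def days(self, patient_id, drug_group) -> set:
        """Union of administration days for the patient over ``drug_group``."""
        per_drug = self._days.get(patient_id, {})
        out: set = set()
        for drug in drug_group:
            out |= per_drug.get(drug, set())
        return out

    def lag_indicator(self, patient_id, drug_group, day: int) -> int:
        """1 iff any drug of the group was administered on ``day - 1``.

        Day 1 has no prior day and is always 0.
        """
        if day < 1:
            raise ValidationError(f"day must be >= 1, got {day}")
        if day == 1:
            return 0
        per_drug = self._days.get(patient_id, {})
        return int(any(day - 1 in per_drug.get(drug, ()) for drug in drug_group))

    def consecutive_days(self, patient_id, drug_group, day: int) -> int:
        """Length of the uninterrupted administration run ending on ``day - 1``.

        Consistent with the one-day lag: the run counted is the one ending the
        day before outcome evaluation; a gap of one or more days resets the
        count to 0.  Returned capped at :data:`CATEGORY_CAP` (the "5+"
        category).
        """
        if day < 1:
            raise ValidationError(f"day must be >= 1, got {day}")
        admin = self.days(patient_id, drug_group)
        run = 0
        d = day - 1
        while d >= 1 and d in admin and run < CATEGORY_CAP:
            run += 1
            d -= 1
        return run

    def restricted_to(self, patient_ids) -> "ExposureCalendar":
        keep = self._records["patient_id"].isin(set(patient_ids))
        return ExposureCalendar(self._records[keep])


def lag_indicator(cal: ExposureCalendar, patient_id, drug_group, day: int) -> int:
    return cal.lag_indicator(patient_id, drug_group, day)


def consecutive_days(cal: ExposureCalendar, patient_id, drug_group, day: int) -> int:
    return cal.consecutive_days(patient_id, drug_group, day)


# ---------------------------------------------------------------------------
# cohort exclusions and windowing
# ---------------------------------------------------------------------------

EXCLUSION_REASONS = ("duplicate", "early_death", "late_referral", "insufficient_baseline")

DEMOGRAPHICS_COLUMNS = ("patient_id", "ga_weeks", "bw_g", "sex", "admission_day", "death_day")


@dataclass
class ExclusionConfig:
    """Operational definitions for the cohort-selection rules.

    min_baseline_obs : minimum number of Scr observations on days 1-3 for a
        patient to count as having baseline data (the source criterion
        "insufficient baseline data" is not given a numeric definition, so
        this is configurable and logged).
    early_death_before_day / late_referral_from_day : the stated cut-offs
        (death before day 7; admission on or after day 15).
    """

    min_baseline_obs: int = 1
    early_death_before_day: int = 7
    late_referral_from_day: int = 15


@dataclass
class CohortFilterLog:
    """Per-patient disposition after :func:`apply_exclusions`."""

    disposition: dict = field(default_factory=dict)  # patient_id -> "included" | reason

    @property
    def included(self):
        return [p for p, d in self.disposition.items() if d == "included"]

    @property
    def excluded(self):
        return {p: d for p, d in self.disposition.items() if d != "included"}

    @property
    def counts(self) -> dict:
        c = Counter(self.disposition.values())
        return {"included": c.get("included", 0), **{r: c.get(r, 0) for r in EXCLUSION_REASONS}}

    def __str__(self):
        c = self.counts
        lines = [f"included: {c['included']}"]
        lines += [f"excluded ({r}): {c[r]}" for r in EXCLUSION_REASONS if c[r]]
        return "\n".join(lines)


def apply_exclusions(
    demographics: pd.DataFrame,
    obs: pd.DataFrame,
    cal: ExposureCalendar,
    config: ExclusionConfig | None = None,
):
    """Apply the cohort-selection rules and account for every input patient.

    Reasons are evaluated in fixed priority order — duplicate, early death
    (death day < 7), late referral (admission day >= 15), insufficient
    baseline (< ``min_baseline_obs`` Scr values on days 1-3) — so each patient
    receives exactly one disposition.

    Returns ``(demographics, obs, cal, log)`` restricted to included patients.
    """
    config = config or ExclusionConfig()
    missing = set(DEMOGRAPHICS_COLUMNS) - set(demographics.columns)
    if missing:
        raise ValidationError(f"demographics table is missing columns {sorted(missing)}")

    duplicated_ids = set(demographics.loc[demographics["patient_id"].duplicated(keep=False), "patient_id"])
    baseline_counts = (
        obs[obs["pna_day"].between(1, 3)].groupby("patient_id").size()
        if not obs.empty
        else pd.Series(dtype=int)
    )

    log = CohortFilterLog()
    for r in demographics.drop_duplicates("patient_id").itertuples():
        pid = r.patient_id
        death_day = getattr(r, "death_day")
        if pid in duplicated_ids:
            log.disposition[pid] = "duplicate"
        elif pd.notna(death_day) and death_day < config.early_death_before_day:
            log.disposition[pid] = "early_death"
        elif r.admission_day >= config.late_referral_from_day:
            log.disposition[pid] = "late_referral"
        elif baseline_counts.get(pid, 0) < config.min_baseline_obs:
            log.disposition[pid] = "insufficient_baseline"
        else:
            log.disposition[pid] = "included"

    keep = set(log.included)
    demo_f = demographics[demographics["patient_id"].isin(keep)].reset_index(drop=True)
    obs_f = obs[obs["patient_id"].isin(keep)].reset_index(drop=True)
    return demo_f, obs_f, cal.restricted_to(keep), log


def restrict_window(obs: pd.DataFrame, max_day: int = 28):
    """Keep observations with ``1 <= pna_day <= max_day`` (boundary inclusive).

    Returns ``(restricted, n_removed)``.
    """
    keep = obs["pna_day"].between(1, max_day) if not obs.empty else pd.Series(dtype=bool)
    restricted = obs[keep].reset_index(drop=True) if not obs.empty else obs.copy()
    return restricted, int(len(obs) - len(restricted))
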