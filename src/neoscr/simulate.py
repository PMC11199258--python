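"""Synthetic ELBW cohort generator with known ground truth.

The real study population (a single-centre cohort of extremely-low-birth-weight
neonates with dense creatinine sampling and nephrotoxic-drug calendars) is not
public, so every stage of the pipeline is exercised on simulated cohorts whose
generative model mirrors the statistical structure the analysis assumes:

* a physiologic serum-creatinine trajectory Q(d) rising from birth to a peak
  on days 3–4 and declining slowly thereafter;
* multiplicative between-patient variability (random intercept and random
  slope on log postnatal day, log-normal residual), calibrated so drug-free
  Pottel scores are distributed around 1 with SD ≈ 0.26;
* ibuprofen courses (PDA window, median 3 days) and amikacin/vancomycin
  courses (sepsis episodes, medians 6–7 days) whose effects multiply Scr and
  accumulate over consecutive treatment days with a one-day lag;
* irregular sampling with decreasing intensity and dropout by late death.

Creatinine is generated as

    Scr(i, d) = Q(d) · exp(b0_i + b1_i·log d + ε_i,d − c(d)) · M(i, d)

where M is the product of the active drug multipliers for the consecutive-
exposure runs ending on day d − 1 and c(d) is a calibration offset: under the
default ``calibration="mean"`` it is half the total log-scale variance at day
d, so the *expected* drug-free score is exactly 1; under
``calibration="median"`` it is 0, so the *median* drug-free Scr equals Q(d)
exactly (the natural target when estimating reference centiles).

The ``ground_truth`` table suffices to reconstruct every noiseless Scr value,
which is what the parameter-recovery and type-I-error harnesses check the
fitted models against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exposure import CATEGORY_CAP, ExposureCalendar
from .reference import ReferenceTable


def default_reference_curve(day) -> np.ndarray:
    """Synthetic physiologic p50 Scr curve (mg/dL), peaking at day 3.5.

    Gamma-shaped bump on a 0.40 mg/dL floor: rises from ≈0.59 at day 1 to
    0.95 at the peak, then declines to ≈0.40 by day 28.  This curve is a
    plausible ELBW shape constructed for simulation; it is *not* a published
    reference table.
    """
    d = np.asarray(day, dtype=float)
    return 0.40 + 0.55 * (d / 3.5) ** 2 * np.exp(2.0 * (1.0 - d / 3.5))


@dataclass(frozen=True)
class DrugEffectProfile:
    """Multiplicative Scr effect by consecutive-exposure category 0..5+.

    ``multipliers[k]`` applies when the run of administration days ending the
    day before the observation has (capped) length k; ``multipliers[0]`` must
    be 1.  A saturating profile rises over the first categories then
    flattens.
    """

    multipliers: tuple

    def __post_init__(self):
        m = tuple(float(x) for x in self.multipliers)
        if len(m) != CATEGORY_CAP + 1:
            raise ValidationError(f"need {CATEGORY_CAP + 1} multipliers (categories 0..5+)")
        if m[0] != 1.0:
            raise ValidationError("category-0 (unexposed) multiplier must be 1")
        if any(x <= 0 for x in m):
            raise ValidationError("effect multipliers must be positive")
        object.__setattr__(self, "multipliers", m)

    def multiplier(self, category: int) -> float:
        return self.multipliers[min(int(category), CATEGORY_CAP)]

    @classmethod
    def null(cls) -> "DrugEffectProfile":
        return cls((1.0,) * (CATEGORY_CAP + 1))

    @classmethod
    def constant(cls, delta: float) -> "DrugEffectProfile":
        """Same multiplier 1 + delta on every exposed category."""
        return cls((1.0,) + (1.0 + delta,) * CATEGORY_CAP)


# default profiles: ibuprofen rises over the first 3 exposure days then
# flattens; antibiotics are a much smaller effect appearing late
DEFAULT_IBUPROFEN_PROFILE = DrugEffectProfile((1.0, 1.03, 1.058, 1.085, 1.10, 1.113))
DEFAULT_ANTIBIOTIC_PROFILE = DrugEffectProfile((1.0, 1.005, 1.007, 1.010, 1.020, 1.035))


@dataclass(frozen=True)
class SimParams:
    """Full generative specification of a synthetic cohort.

    Defaults reproduce the scale of the motivating cohort: 201 patients,
    ≈3200 creatinine observations over days 1–28, ibuprofen exposure ≈62%,
    each antibiotic ≈75% (70% both), drug-free score SD ≈ 0.26.
    """

    n_patients: int = 201
    day_range: tuple = (1, 28)
    reference_curve: object = default_reference_curve  # callable day -> mg/dL

    # log-scale variability
    sigma_between: float = 0.22   # random intercept SD
    sigma_slope: float = 0.05     # random slope SD (per log-day)
    sigma_resid: float = 0.10     # residual SD
    calibration: str = "mean"     # "mean": E[score]=1; "median": median Scr = Q(d)

    # ibuprofen (PDA window): start days 2-6, duration 1 + Poisson(2.2), median 3
    p_ibuprofen: float = 0.62
    ibu_start_days: tuple = (2, 3, 4, 5, 6)
    ibu_start_weights: tuple = (0.30, 0.30, 0.20, 0.12, 0.08)
    ibu_duration_poisson: float = 2.2
    ibu_duration_max: int = 14
    ibuprofen_profile: DrugEffectProfile = DEFAULT_IBUPROFEN_PROFILE

    # antibiotics: joint exposure categories matched to the cohort prevalences
    p_both_antibiotics: float = 0.705
    p_amikacin_only: float = 0.050
    p_vancomycin_only: float = 0.055
    p_early_onset_course: float = 0.25   # extra short amikacin course, days 1-3
    los_start_min: int = 4               # late-onset sepsis: > 72 h postnatal age
    los_start_max: int = 20
    amik_duration_poisson: float = 5.0   # 1 + Poisson -> median ≈ 6 (range 1-17)
    amik_duration_max: int = 17
    vanc_duration_poisson: float = 6.0   # 1 + Poisson -> median ≈ 7 (range 1-21)
    vanc_duration_max: int = 21
    antibiotic_profile: DrugEffectProfile = DEFAULT_ANTIBIOTIC_PROFILE

    # sampling: per-day observation probability by week, decreasing
    sampling_probs: tuple = (0.95, 0.65, 0.50, 0.40)  # days 1-7, 8-14, 15-21, 22-28

    # dropout: late neonatal death truncates the series
    p_late_death: float = 0.085
    death_day_range: tuple = (7, 28)

    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.day_range[0] < 1 or self.day_range[1] < self.day_range[0]:
            raise ValidationError(f"invalid day_range {self.day_range}")
        for name in ("sigma_between", "sigma_slope", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.calibration not in ("mean", "median"):
            raise ValidationError("calibration must be 'mean' or 'median'")
        for p in (self.p_ibuprofen, self.p_late_death):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.p_both_antibiotics + self.p_amikacin_only + self.p_vancomycin_only > 1:
            raise ValidationError("antibiotic category probabilities exceed 1")
        days = np.arange(self.day_range[0], self.day_range[1] + 1)
        if np.any(np.asarray(self.reference_curve(days)) <= 0):
            raise ValidationError("reference_curve must be positive on the day range")

    def replace(self, **overrides) -> "SimParams":
        return dataclasses.replace(self, **overrides)

    def reference_table(self) -> ReferenceTable:
        """The generator's own Q(d) as a ReferenceTable (scoring oracle)."""
        days = range(self.day_range[0], self.day_range[1] + 1)
        return ReferenceTable({d: float(self.reference_curve(d)) for d in days})


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the ground truth that generated it."""

    demographics: pd.DataFrame   # patient_id, ga_weeks, bw_g, sex, admission_day, death_day
    observations: pd.DataFrame   # patient_id, pna_day, scr_mg_dl
    calendar: ExposureCalendar
    ground_truth: pd.DataFrame   # per observation: q, b0, b1, drug_multiplier, scr_noiseless
    params: SimParams

    @property
    def reference_table(self) -> ReferenceTable:
        return self.params.reference_table()

    def write_csvs(self, outdir, provenance: str | None = None) -> dict:
        """Write the cohort tables as CSV; returns {name: path}."""
        import os

        os.makedirs(outdir, exist_ok=True)
        frames = {
            "demographics": self.demographics,
            "observations": self.observations,
            "exposures": self.calendar.to_frame(),
            "ground_truth": self.ground_truth,
        }
        paths = {}
        for name, df in frames.items():
            path = os.path.join(outdir, f"{name}.csv")
            with open(path, "w", encoding="utf-8") as fh:
                if provenance:
                    fh.write(f"# {provenance}\n")
                df.to_csv(fh, index=False)
            paths[name] = path
        return paths


def _course(start: int, duration: int, last_day: int) -> list:
    return [d for d in range(start, start + duration) if d <= last_day]


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """Generate a cohort; identical params (incl. seed) give identical output."""
    rng = np.random.default_rng(params.seed)
    lo, hi = params.day_range
    q = {d: float(params.reference_curve(d)) for d in range(lo, hi + 1)}

    demo_rows, obs_rows, exp_rows, truth_rows = [], [], [], []
    for i in range(params.n_patients):
        pid = f"P{i + 1:04d}"
        ga = float(np.clip(rng.normal(27.0, 2.0), 23.0, 34.0))
        bw = float(np.clip(rng.normal(808.0, 135.0), 370.0, 1000.0))
        sex = "F" if rng.random() < 0.532 else "M"
        death_day = (
            int(rng.integers(params.death_day_range[0], params.death_day_range[1] + 1))
            if rng.random() < params.p_late_death
            else None
        )
        last_day = min(hi, death_day) if death_day is not None else hi
        demo_rows.append((pid, round(ga, 1), round(bw), sex, 1, death_day))

        b0 = rng.normal(0.0, params.sigma_between)
        b1 = rng.normal(0.0, params.sigma_slope)

        drug_days: dict = {"ibuprofen": set(), "amikacin": set(), "vancomycin": set()}
        if rng.random() < params.p_ibuprofen:
            start = int(rng.choice(params.ibu_start_days, p=_norm(params.ibu_start_weights)))
            dur = int(min(1 + rng.poisson(params.ibu_duration_poisson), params.ibu_duration_max))
            drug_days["ibuprofen"].update(_course(start, dur, last_day))
        u = rng.random()
        has_amik = u < params.p_both_antibiotics + params.p_amikacin_only
        has_vanc = (u < params.p_both_antibiotics) or (
            params.p_both_antibiotics + params.p_amikacin_only
            <= u
            < params.p_both_antibiotics + params.p_amikacin_only + params.p_vancomycin_only
        )
        if has_amik or has_vanc:
            # sepsis onset falls within the patient's actual stay
            start_hi = max(params.los_start_min, min(params.los_start_max, last_day))
            los_start = int(rng.integers(params.los_start_min, start_hi + 1))
            if has_amik:
                dur = int(min(1 + rng.poisson(params.amik_duration_poisson), params.amik_duration_max))
                drug_days["amikacin"].update(_course(los_start, dur, last_day))
                if rng.random() < params.p_early_onset_course:
                    eos_start = int(rng.integers(1, 4))
                    eos_dur = int(min(1 + rng.poisson(1.5), 3))
                    drug_days["amikacin"].update(_course(eos_start, eos_dur, last_day))
            if has_vanc:
                dur = int(min(1 + rng.poisson(params.vanc_duration_poisson), params.vanc_duration_max))
                drug_days["vancomycin"].update(_course(los_start, dur, last_day))
        for drug, days in drug_days.items():
            exp_rows.extend((pid, drug, d) for d in sorted(days))

        ibu_set = drug_days["ibuprofen"]
        abx_set = drug_days["amikacin"] | drug_days["vancomycin"]
        for d in range(lo, last_day + 1):
            week = min((d - 1) // 7, len(params.sampling_probs) - 1)
            if rng.random() >= params.sampling_probs[week]:
                continue
            cat_ibu = _run_ending(ibu_set, d - 1)
            cat_abx = _run_ending(abx_set, d - 1)
            mult = params.ibuprofen_profile.multiplier(cat_ibu) * params.antibiotic_profile.multiplier(cat_abx)
            ld = np.log(d)
            v = params.sigma_between**2 + (params.sigma_slope * ld) ** 2 + params.sigma_resid**2
            c = 0.5 * v if params.calibration == "mean" else 0.0
            noiseless = q[d] * np.exp(b0 + b1 * ld - c) * mult
            scr = noiseless * np.exp(rng.normal(0.0, params.sigma_resid))
            obs_rows.append((pid, d, scr))
            truth_rows.append((pid, d, q[d], b0, b1, mult, noiseless))

    demographics = pd.DataFrame(
        demo_rows, columns=["patient_id", "ga_weeks", "bw_g", "sex", "admission_day", "death_day"]
    )
    observations = pd.DataFrame(obs_rows, columns=["patient_id", "pna_day", "scr_mg_dl"])
    calendar = ExposureCalendar(
        pd.DataFrame(exp_rows, columns=["patient_id", "drug", "pna_day"])
    )
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "pna_day", "q", "b0", "b1", "drug_multiplier", "scr_noiseless"],
    )
    return SyntheticCohort(demographics, observations, calendar, ground_truth, params)


def _norm(w):
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def _run_ending(admin_days: set, day: int) -> int:
    """Length (capped) of the uninterrupted administration run ending on ``day``."""
    run = 0
    d = day
    while d >= 1 and d in admin_days and run < CATEGORY_CAP:
        run += 1
        d -= 1
    return run


def null_cohort(params: SimParams) -> SyntheticCohort:
    """Cohort with all drug multipliers forced to 1; exposures still assigned.

    Courses are generated exactly as in :func:`simulate_cohort` so the design
    matrices of subsequent model fits are non-degenerate; only the effect on
    creatinine is removed.  The type-I-error harness runs on these cohorts.
    """
    return simulate_cohort(
        params.replace(
            ibuprofen_profile=DrugEffectProfile.null(),
            antibiotic_profile=DrugEffectProfile.null(),
        )
    )


# ---------------------------------------------------------------------------
# named recovery scenarios (fixed a priori; used by tests and `neoscr recover`)
# ---------------------------------------------------------------------------

def constant_effect_params(delta: float = 0.10, n_patients: int = 200, seed: int = 0) -> SimParams:
    """Ibuprofen raises Scr by a constant factor 1 + delta on every exposed
    day; antibiotics are inert.  Under mean calibration the true day-wise
    exposed-vs-unexposed score difference is exactly delta."""
    return SimParams(
        n_patients=n_patients,
        ibuprofen_profile=DrugEffectProfile.constant(delta),
        antibiotic_profile=DrugEffectProfile.null(),
        seed=seed,
    )


def saturating_effect_params(n_patients: int = 200, seed: int = 0) -> SimParams:
    """Cumulative-shape scenario: score increments ≈0.10/0.08/0.06 over
    consecutive exposure days 1-3, then ≈0.01/0.005 (flattening).  Courses
    are lengthened (duration 4-8 days) so the upper categories are occupied."""
    return SimParams(
        n_patients=n_patients,
        p_ibuprofen=0.70,
        ibu_duration_poisson=5.0,
        ibu_duration_max=9,
        ibuprofen_profile=DrugEffectProfile((1.0, 1.10, 1.18, 1.24, 1.25, 1.255)),
        antibiotic_profile=DrugEffectProfile.null(),
        seed=seed,
    )


def confounded_params(n_patients: int = 150, seed: int = 0) -> SimParams:
    """Constructed confounding: antibiotics act (factor 1.15), ibuprofen is
    inert, and exposures are strongly correlated.  Built by
    :func:`simulate_confounded`; the plain field values here only carry the
    effect profiles and noise settings."""
    return SimParams(
        n_patients=n_patients,
        ibuprofen_profile=DrugEffectProfile.null(),
        antibiotic_profile=DrugEffectProfile.constant(0.15),
        seed=seed,
    )


def simulate_confounded(params: SimParams) -> SyntheticCohort:
    """Cohort in which antibiotic courses enclose ibuprofen courses.

    Half the patients receive an ibuprofen course (days 2-6 start, duration
    ~3); of those, 90% also receive an antibiotic course starting one day
    earlier and ending three days later, so on almost every
    ibuprofen-exposed day the antibiotic lag indicator is 1 as well.
    Patients without ibuprofen receive antibiotics with probability 0.15.
    An unadjusted ibuprofen analysis therefore absorbs the antibiotic effect;
    the two-drug adjusted analysis separates them (identified by the
    antibiotic-only days flanking each course and by antibiotic-only
    patients).
    """
    # separate stream from the base cohort's so course assignment is
    # independent of the patient-level noise draws
    rng = np.random.default_rng([params.seed, 1])
    base = simulate_cohort(params.replace(
        p_ibuprofen=0.0,
        p_both_antibiotics=0.0, p_amikacin_only=0.0, p_vancomycin_only=0.0,
    ))
    lo, hi = params.day_range
    last = {
        r.patient_id: (int(r.death_day) if pd.notna(r.death_day) else hi)
        for r in base.demographics.itertuples()
    }
    exp_rows = []
    ibu_days_by_pid, abx_days_by_pid = {}, {}
    for pid in base.demographics["patient_id"]:
        ibu: set = set()
        abx: set = set()
        if rng.random() < 0.5:
            start = int(rng.choice((2, 3, 4, 5, 6)))
            dur = int(min(1 + rng.poisson(2.2), 9))
            ibu.update(_course(start, dur, last[pid]))
            if rng.random() < 0.9:
                abx.update(_course(max(1, start - 1), dur + 4, last[pid]))
        elif rng.random() < 0.15:
            start = int(rng.integers(4, 15))
            abx.update(_course(start, int(1 + rng.poisson(5.0)), last[pid]))
        exp_rows.extend((pid, "ibuprofen", d) for d in sorted(ibu))
        exp_rows.extend((pid, "amikacin", d) for d in sorted(abx))
        ibu_days_by_pid[pid], abx_days_by_pid[pid] = ibu, abx
    calendar = ExposureCalendar(pd.DataFrame(exp_rows, columns=["patient_id", "drug", "pna_day"]))

    # re-apply drug multipliers to the drug-free base cohort
    obs = base.observations.copy()
    truth = base.ground_truth.copy()
    mults = np.ones(len(obs))
    for idx, r in enumerate(obs.itertuples()):
        m = params.ibuprofen_profile.multiplier(_run_ending(ibu_days_by_pid[r.patient_id], r.pna_day - 1))
        m *= params.antibiotic_profile.multiplier(_run_ending(abx_days_by_pid[r.patient_id], r.pna_day - 1))
        mults[idx] = m
    obs["scr_mg_dl"] = obs["scr_mg_dl"].to_numpy() * mults
    truth["drug_multiplier"] = mults
    truth["scr_noiseless"] = truth["scr_noiseless"].to_numpy() * mults
    return SyntheticCohort(base.demographics, obs, calendar, truth, params)
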