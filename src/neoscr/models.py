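"""Linear mixed models for lagged drug-exposure effects on the Pottel score.

Two model families, both with patient-level random intercept and random slope
on log postnatal day, estimated by REML:

* **Day-wise model** — score ~ 1 + log(day) + exposed + exposed:log(day)
  (+ the same pair for a co-drug adjustment group), where ``exposed`` is the
  lag-1 binary indicator (drug given the day before the measurement).  The
  exposed-vs-unexposed mean difference at day *d* is
  β_exposed + β_interaction·log d, with Wald (normal) confidence intervals
  from the fixed-effect covariance.
* **Cumulative model** — score ~ 1 + log(day) + C(consecutive-days category),
  where the category is the length of the uninterrupted administration run
  ending the day before the measurement, capped at "5+".  Category means are
  evaluated at the sample-average log day with co-drug indicators fixed at 0,
  and each category is contrasted against category 0.

Time enters the fixed and random parts on the same (log) scale.  When the
full random structure is singular or fails to converge the fit is retried
with uncorrelated intercept/slope and then with a random intercept only;
every downgrade is recorded in ``fit_info``.

The classes follow the statsmodels Model/Results convention; the
module-level functions (``fit_daywise_model`` …) are thin wrappers kept for
pipeline scripting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import CollinearityError, ConvergenceError, ValidationError
from .exposure import ExposureCalendar, group_label

ALPHA_DEFAULT = 0.05

EFFECTS_CSV_COLUMNS = (
    "analysis", "drug_group", "day_or_category",
    "mean_exposed", "mean_unexposed", "diff", "ci_lo", "ci_hi", "p_value",
)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_daywise_design(
    scored: pd.DataFrame,
    calendar: ExposureCalendar,
    drug_group,
    adjust_for=None,
) -> pd.DataFrame:
    """Long-format design with lag-1 exposure coding.

    Returns columns ``patient_id, pna_day, log_day, pottel_score, exposed``
    and, when ``adjust_for`` is given, ``co_exposed``.
    """
    df = scored.reset_index(drop=True).copy()
    df["log_day"] = np.log(df["pna_day"].astype(float))
    df["exposed"] = [
        calendar.lag_indicator(r.patient_id, drug_group, int(r.pna_day))
        for r in df.itertuples()
    ]
    if adjust_for is not None:
        df["co_exposed"] = [
            calendar.lag_indicator(r.patient_id, adjust_for, int(r.pna_day))
            for r in df.itertuples()
        ]
    keep = ["patient_id", "pna_day", "log_day", "pottel_score", "exposed"]
    if adjust_for is not None:
        keep.append("co_exposed")
    return df[keep]


def build_cumulative_design(
    scored: pd.DataFrame,
    calendar: ExposureCalendar,
    drug_group,
    adjust_for=None,
) -> pd.DataFrame:
    """Design with the consecutive-days category coding (0..5, 5 = "5+")."""
    df = scored.reset_index(drop=True).copy()
    df["log_day"] = np.log(df["pna_day"].astype(float))
    df["category"] = [
        calendar.consecutive_days(r.patient_id, drug_group, int(r.pna_day))
        for r in df.itertuples()
    ]
    if adjust_for is not None:
        df["co_exposed"] = [
            calendar.lag_indicator(r.patient_id, adjust_for, int(r.pna_day))
            for r in df.itertuples()
        ]
    keep = ["patient_id", "pna_day", "log_day", "pottel_score", "category"]
    if adjust_for is not None:
        keep.append("co_exposed")
    return df[keep]


def _check_estimable(data: pd.DataFrame) -> None:
    per = data.groupby("patient_id").size()
    if len(per) < 2 or (per >= 2).sum() < 2:
        raise ValidationError(
            "mixed model needs at least 2 patients with at least 2 observations each "
            f"(got {len(per)} patient(s))"
        )


def _drop_empty_co(data: pd.DataFrame, fit_info: dict) -> pd.DataFrame:
    if "co_exposed" in data.columns and data["co_exposed"].sum() == 0:
        # adjustment group was never administered: identical to unadjusted fit
        data = data.drop(columns="co_exposed")
        fit_info["co_drug_dropped"] = "no administrations in adjustment group"
    return data


def _check_collinear(data: pd.DataFrame, primary_label: str, co_label: str) -> None:
    if "co_exposed" in data.columns and (data["exposed"] == data["co_exposed"]).all():
        raise CollinearityError(
            f"exposure indicators for {primary_label!r} and {co_label!r} are identical "
            "on every row; the two effects are not separable"
        )


# ---------------------------------------------------------------------------
# shared REML machinery with the fallback ladder
# ---------------------------------------------------------------------------

_LADDER = ("intercept_slope", "intercept_slope_uncorrelated", "intercept_only")


def _fit_mixedlm(endog, exog: pd.DataFrame, groups, log_day, reml: bool, fit_info: dict):
    """Fit with the random-structure fallback ladder; returns a MixedLMResults."""
    last_err = None
    for structure in _LADDER:
        if structure == "intercept_only":
            exog_re = pd.DataFrame({"const_re": np.ones(len(endog))}, index=exog.index)
        else:
            exog_re = pd.DataFrame(
                {"const_re": np.ones(len(endog)), "log_day_re": log_day}, index=exog.index
            )
        free = None
        if structure == "intercept_slope_uncorrelated":
            free = MixedLMParams.from_components(
                fe_params=np.ones(exog.shape[1]), cov_re=np.eye(2)
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
                res = model.fit(reml=reml, free=free, method=["lbfgs", "bfgs"], maxiter=300)
        except Exception as err:  # singular matrices etc.
            last_err = err
            continue
        if not res.converged or not np.all(np.isfinite(res.fe_params)):
            last_err = ConvergenceError(f"optimiser did not converge ({structure})")
            continue
        eig = np.linalg.eigvalsh(np.atleast_2d(res.cov_re))
        if structure != "intercept_only" and eig.min() <= 1e-8 * max(eig.max(), 1e-8):
            last_err = ConvergenceError(f"singular random-effects covariance ({structure})")
            continue
        fit_info["re_structure"] = structure
        if structure != _LADDER[0]:
            fit_info.setdefault("downgrades", []).append(
                f"random structure downgraded to {structure}: {last_err}"
            )
        return res
    raise ConvergenceError(
        f"mixed model failed to converge after the fallback ladder: {last_err}"
    )


def _wald(est, se, alpha):
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    h = stats.norm.ppf(1 - alpha / 2) * se
    return est - h, est + h, max(p, np.finfo(float).tiny)


def _summary_text(title: str, fit_info: dict, params: pd.Series, cov: pd.DataFrame,
                  varcomp: dict, alpha: float) -> str:
    lines = [title, "=" * len(title)]
    lines.append(
        f"n_obs: {fit_info['n_obs']}   n_patients: {fit_info['n_patients']}   "
        f"REML: {fit_info['reml']}   random: {fit_info['re_structure']}"
    )
    if fit_info.get("downgrades"):
        lines.extend(f"note: {d}" for d in fit_info["downgrades"])
    if fit_info.get("co_drug_dropped"):
        lines.append(f"note: co-drug terms dropped ({fit_info['co_drug_dropped']})")
    lines.append(f"log-likelihood: {fit_info['llf']:.3f}   AIC: {fit_info['aic']:.3f}")
    lines.append("")
    lines.append(f"{'term':<22}{'coef':>10}{'se':>10}{'z':>9}{'p':>12}{'ci_lo':>10}{'ci_hi':>10}")
    for name in params.index:
        est = params[name]
        se = np.sqrt(cov.loc[name, name])
        lo, hi, p = _wald(est, se, alpha)
        lines.append(
            f"{name:<22}{est:>10.4f}{se:>10.4f}{est / se:>9.2f}{p:>12.3g}{lo:>10.4f}{hi:>10.4f}"
        )
    lines.append("")
    lines.append("variance components: " + ", ".join(f"{k}={v:.5f}" for k, v in varcomp.items()))
    return "\n".join(lines)


class _BaseResults:
    """Estimates, covariance and diagnostics shared by both model families."""

    def __init__(self, params, cov_params, varcomp, fit_info, data, drug_label, co_label):
        self.params: pd.Series = params
        self.cov_params: pd.DataFrame = cov_params
        self.variance_components: dict = varcomp
        self.fit_info: dict = fit_info
        self.data: pd.DataFrame = data
        self.drug_label: str = drug_label
        self.co_label = co_label

    @property
    def converged(self) -> bool:
        return True  # non-convergence raises; a Results object implies success

    @property
    def aic(self) -> float:
        return self.fit_info["aic"]

    @property
    def llf(self) -> float:
        return self.fit_info["llf"]

    def _se(self, contrast: pd.Series) -> float:
        v = float(contrast @ self.cov_params @ contrast)
        return float(np.sqrt(max(v, 0.0)))


# ---------------------------------------------------------------------------
# day-wise model
# ---------------------------------------------------------------------------

class DaywiseExposureModel:
    """Score ~ log(day) × lag-1 exposure, random intercept + slope per patient.

    Parameters
    ----------
    data : design frame from :func:`build_daywise_design`.
    drug_label, co_label : names used in summaries and effect tables.
    time_scale : ``"log"`` (default) or ``"linear"``; the linear variant
        exists for AIC comparison of the time transform and uses the same
        scale in the random part.
    """

    def __init__(self, data: pd.DataFrame, drug_label="drug", co_label=None, time_scale="log"):
        if time_scale not in ("log", "linear"):
            raise ValidationError("time_scale must be 'log' or 'linear'")
        _check_estimable(data)
        if data["exposed"].nunique() < 2:
            raise ValidationError("exposure indicator is constant; effect not estimable")
        self.data = data.reset_index(drop=True)
        self.drug_label = drug_label
        self.co_label = co_label
        self.time_scale = time_scale

    @classmethod
    def from_scored(cls, scored, calendar, drug_group, adjust_for=None, time_scale="log"):
        data = build_daywise_design(scored, calendar, drug_group, adjust_for)
        co = group_label(adjust_for) if adjust_for is not None else None
        return cls(data, drug_label=group_label(drug_group), co_label=co, time_scale=time_scale)

    def fit(self, reml: bool = True, alpha: float = ALPHA_DEFAULT) -> "DaywiseExposureResults":
        fit_info: dict = {"reml": reml, "alpha": alpha, "time_scale": self.time_scale}
        data = _drop_empty_co(self.data.copy(), fit_info)
        _check_collinear(data, self.drug_label, self.co_label)
        t = data["log_day"] if self.time_scale == "log" else data["pna_day"].astype(float)
        exog = pd.DataFrame(
            {
                "const": 1.0,
                "time": t,
                "exposed": data["exposed"].astype(float),
                "exposed:time": data["exposed"].astype(float) * t,
            },
            index=data.index,
        )
        if "co_exposed" in data.columns:
            exog["co_exposed"] = data["co_exposed"].astype(float)
            exog["co_exposed:time"] = exog["co_exposed"] * t
        fit_info["n_obs"] = int(len(data))
        fit_info["n_patients"] = int(data["patient_id"].nunique())
        res = _fit_mixedlm(
            data["pottel_score"].to_numpy(), exog, data["patient_id"], t, reml, fit_info
        )
        k_fe = exog.shape[1]
        params = pd.Series(res.fe_params, index=exog.columns)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k_fe, :k_fe], index=exog.columns, columns=exog.columns
        )
        varcomp = _extract_varcomp(res, fit_info["re_structure"])
        fit_info["llf"] = float(res.llf)
        fit_info["aic"] = float(-2.0 * res.llf + 2.0 * (k_fe + _n_varcomp(fit_info["re_structure"])))
        return DaywiseExposureResults(
            params, cov, varcomp, fit_info, data, self.drug_label, self.co_label
        )


class DaywiseExposureResults(_BaseResults):
    """Fitted day-wise exposure model; contrasts via :meth:`day_contrasts`."""

    def exposed_patient_counts(self) -> pd.Series:
        """Unique exposed patients contributing at each postnatal day."""
        d = self.data[self.data["exposed"] == 1]
        return d.groupby("pna_day")["patient_id"].nunique()

    def reportable_days(self, min_exposed_patients: int = 2) -> list:
        """Days with at least ``min_exposed_patients`` exposed patients.

        Day-wise predicted means are only reported for these days, mirroring
        the practice of hiding days on which (almost) nobody was exposed.
        """
        counts = self.exposed_patient_counts()
        return [int(d) for d in counts.index[counts >= min_exposed_patients]]

    def day_contrasts(self, days, alpha: float | None = None) -> pd.DataFrame:
        """Exposed-vs-unexposed model means and differences at given days.

        The difference at day *d* is β_exposed + β_interaction·t(d); means fix
        the co-drug indicator at 0.  Requesting a day outside the fitted data
        raises (no extrapolation).
        """
        alpha = self.fit_info["alpha"] if alpha is None else alpha
        lo_d, hi_d = int(self.data["pna_day"].min()), int(self.data["pna_day"].max())
        rows = []
        for day in days:
            if not lo_d <= day <= hi_d:
                raise ValidationError(
                    f"day {day} outside the fitted day range [{lo_d}, {hi_d}]; "
                    "contrasts are not extrapolated"
                )
            t = np.log(day) if self.fit_info["time_scale"] == "log" else float(day)
            c_diff = pd.Series(0.0, index=self.params.index)
            c_diff["exposed"] = 1.0
            c_diff["exposed:time"] = t
            diff = float(c_diff @ self.params)
            se = self._se(c_diff)
            ci_lo, ci_hi, p = _wald(diff, se, alpha)
            c_un = pd.Series(0.0, index=self.params.index)
            c_un["const"] = 1.0
            c_un["time"] = t
            mean_un = float(c_un @ self.params)
            un_lo, un_hi, _ = _wald(mean_un, self._se(c_un), alpha)
            c_ex = c_un + c_diff
            mean_ex = float(c_ex @ self.params)
            ex_lo, ex_hi, _ = _wald(mean_ex, self._se(c_ex), alpha)
            rows.append(
                {
                    "analysis": "daywise" + ("_adjusted" if self.co_label else ""),
                    "drug_group": self.drug_label,
                    "day_or_category": day,
                    "mean_exposed": mean_ex,
                    "mean_exposed_lo": ex_lo,
                    "mean_exposed_hi": ex_hi,
                    "mean_unexposed": mean_un,
                    "mean_unexposed_lo": un_lo,
                    "mean_unexposed_hi": un_hi,
                    "diff": diff,
                    "ci_lo": ci_lo,
                    "ci_hi": ci_hi,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        title = f"Day-wise lag-1 exposure model: {self.drug_label}"
        if self.co_label:
            title += f" (adjusted for {self.co_label})"
        return _summary_text(
            title, self.fit_info, self.params, self.cov_params,
            self.variance_components, self.fit_info["alpha"],
        )

    def plot_effect_curve(self, days=None, ax=None):
        """Estimated exposed/unexposed score curves with CI band on the difference."""
        import matplotlib.pyplot as plt

        days = days if days is not None else self.reportable_days()
        tab = self.day_contrasts(days)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(tab["day_or_category"], tab["mean_unexposed"], label="unexposed")
        ax.plot(tab["day_or_category"], tab["mean_exposed"], label="exposed")
        ax.fill_between(
            tab["day_or_category"], tab["mean_exposed_lo"], tab["mean_exposed_hi"], alpha=0.2
        )
        ax.set_xlabel("postnatal day")
        ax.set_ylabel("Pottel score")
        ax.set_title(f"{self.drug_label}: model means")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# cumulative (consecutive-days) model
# ---------------------------------------------------------------------------

class CumulativeExposureModel:
    """Score ~ log(day) + consecutive-days category, same random structure.

    Categories with fewer than two observations are merged into the adjacent
    category (upward, the top category merging downward) and the merge is
    logged in ``fit_info['merged_categories']``.
    """

    def __init__(self, data: pd.DataFrame, drug_label="drug", co_label=None):
        _check_estimable(data)
        self.data = data.reset_index(drop=True)
        self.drug_label = drug_label
        self.co_label = co_label

    @classmethod
    def from_scored(cls, scored, calendar, drug_group, adjust_for=None):
        data = build_cumulative_design(scored, calendar, drug_group, adjust_for)
        co = group_label(adjust_for) if adjust_for is not None else None
        return cls(data, drug_label=group_label(drug_group), co_label=co)

    def fit(self, reml: bool = True, alpha: float = ALPHA_DEFAULT) -> "CumulativeExposureResults":
        fit_info: dict = {"reml": reml, "alpha": alpha, "time_scale": "log"}
        data = _drop_empty_co(self.data.copy(), fit_info)
        cat, merges = _merge_sparse_categories(data["category"])
        data["category"] = cat
        if merges:
            fit_info["merged_categories"] = merges
        levels = sorted(data["category"].unique())
        t = data["log_day"]
        cols = {"const": 1.0, "time": t}
        for lev in levels:
            if lev == 0:
                continue
            cols[f"cat_{lev}"] = (data["category"] == lev).astype(float)
        exog = pd.DataFrame(cols, index=data.index)
        if "co_exposed" in data.columns:
            exog["co_exposed"] = data["co_exposed"].astype(float)
            exog["co_exposed:time"] = exog["co_exposed"] * t
        fit_info["n_obs"] = int(len(data))
        fit_info["n_patients"] = int(data["patient_id"].nunique())
        fit_info["category_levels"] = levels
        if len(levels) == 1:
            # no drug ever given: intercept + time only, no contrasts
            fit_info["note"] = "single exposure category present; no contrasts estimable"
        res = _fit_mixedlm(
            data["pottel_score"].to_numpy(), exog, data["patient_id"], t, reml, fit_info
        )
        k_fe = exog.shape[1]
        params = pd.Series(res.fe_params, index=exog.columns)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k_fe, :k_fe], index=exog.columns, columns=exog.columns
        )
        varcomp = _extract_varcomp(res, fit_info["re_structure"])
        fit_info["llf"] = float(res.llf)
        fit_info["aic"] = float(-2.0 * res.llf + 2.0 * (k_fe + _n_varcomp(fit_info["re_structure"])))
        return CumulativeExposureResults(
            params, cov, varcomp, fit_info, data, self.drug_label, self.co_label
        )


class CumulativeExposureResults(_BaseResults):
    """Fitted cumulative model; per-category means via :meth:`category_effects`."""

    def category_effects(self, alpha: float | None = None) -> pd.DataFrame:
        """Model-based mean score per consecutive-days category.

        Means are evaluated at the sample-average log day with co-drug
        indicators fixed at 0; each category is contrasted with category 0
        (difference, CI, p).  Category labels follow the ``0,1,…,5+``
        convention; merged categories carry their merged label.
        """
        alpha = self.fit_info["alpha"] if alpha is None else alpha
        lbar = float(self.data["log_day"].mean())
        levels = self.fit_info["category_levels"]
        rows = []
        for lev in levels:
            c_mean = pd.Series(0.0, index=self.params.index)
            c_mean["const"] = 1.0
            c_mean["time"] = lbar
            if lev != 0:
                c_mean[f"cat_{lev}"] = 1.0
            mean = float(c_mean @ self.params)
            m_lo, m_hi, _ = _wald(mean, self._se(c_mean), alpha)
            if lev == 0:
                diff = 0.0
                ci_lo = ci_hi = 0.0
                p = np.nan
            else:
                c_diff = pd.Series(0.0, index=self.params.index)
                c_diff[f"cat_{lev}"] = 1.0
                diff = float(self.params[f"cat_{lev}"])
                ci_lo, ci_hi, p = _wald(diff, self._se(c_diff), alpha)
            label = "5+" if lev == 5 else str(lev)
            rows.append(
                {
                    "analysis": "cumulative" + ("_adjusted" if self.co_label else ""),
                    "drug_group": self.drug_label,
                    "day_or_category": label,
                    "mean_exposed": mean,
                    "mean_exposed_lo": m_lo,
                    "mean_exposed_hi": m_hi,
                    "mean_unexposed": rows[0]["mean_exposed"] if rows else mean,
                    "diff": diff,
                    "ci_lo": ci_lo,
                    "ci_hi": ci_hi,
                    "p_value": p,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        title = f"Cumulative consecutive-days model: {self.drug_label}"
        if self.co_label:
            title += f" (adjusted for {self.co_label})"
        return _summary_text(
            title, self.fit_info, self.params, self.cov_params,
            self.variance_components, self.fit_info["alpha"],
        )


def _merge_sparse_categories(cat: pd.Series, min_n: int = 2):
    """Merge categories with < min_n observations into the next one (top: down)."""
    cat = cat.copy()
    merges = []
    for lev in range(1, 5):
        n = int((cat == lev).sum())
        if 0 < n < min_n:
            cat[cat == lev] = lev + 1
            merges.append(f"category {lev} (n={n}) merged into {lev + 1}")
    n5 = int((cat == 5).sum())
    if 0 < n5 < min_n:
        target = max(v for v in cat.unique() if v < 5) if (cat < 5).any() else 5
        cat[cat == 5] = target
        merges.append(f"category 5+ (n={n5}) merged into {target}")
    return cat, merges


def _n_varcomp(structure: str) -> int:
    return {"intercept_slope": 4, "intercept_slope_uncorrelated": 3, "intercept_only": 2}[structure]


def _extract_varcomp(res, structure: str) -> dict:
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    out = {"residual_var": float(res.scale), "intercept_var": float(cov_re[0, 0])}
    if structure != "intercept_only":
        out["slope_var"] = float(cov_re[1, 1])
        out["intercept_slope_cov"] = float(cov_re[0, 1])
    return out


# ---------------------------------------------------------------------------
# pipeline-style wrappers
# ---------------------------------------------------------------------------

def fit_daywise_model(scored, calendar, drug_group, adjust_for=None, reml=True,
                      time_scale="log") -> DaywiseExposureResults:
    """Fit the day-wise lag-1 exposure model (see :class:`DaywiseExposureModel`)."""
    return DaywiseExposureModel.from_scored(
        scored, calendar, drug_group, adjust_for, time_scale=time_scale
    ).fit(reml=reml)


def estimate_day_contrasts(results: DaywiseExposureResults, days) -> pd.DataFrame:
    """Effect table of exposed-vs-unexposed differences at the given days."""
    return results.day_contrasts(days)


def fit_cumulative_model(scored, calendar, drug_group, adjust_for=None, reml=True):
    """Fit the consecutive-days model; returns ``(results, effect_table)``."""
    results = CumulativeExposureModel.from_scored(scored, calendar, drug_group, adjust_for).fit(reml=reml)
    return results, results.category_effects()


def adjusted_analysis(scored, calendar, primary_drug_group, adjustment_drug_group,
                      days=None) -> pd.DataFrame:
    """Day-wise effect table for the primary drug, adjusted for the other.

    The model contains both drugs' lag indicators and their log-time
    interactions; the returned contrasts are the primary drug's.  When the
    adjustment group has no administrations this reduces exactly to the
    unadjusted fit.
    """
    results = fit_daywise_model(scored, calendar, primary_drug_group, adjust_for=adjustment_drug_group)
    days = days if days is not None else results.reportable_days()
    return results.day_contrasts(days)
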