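"""The four exposure-effect models for two-timepoint telomere data.

All four models estimate the difference in annual telomere change between an
exposed and an unexposed group, harmonized to bp/yr with exposure coded
0 = unexposed, 1 = exposed (negative estimates mean faster attrition in the
exposed group):

1. change score      -- measured per-year change ~ exposure
2. ANCOVA on change  -- measured per-year change ~ measured baseline + exposure
3. ANCOVA on follow-up -- measured follow-up ~ measured baseline + exposure
   (exposure coefficient divided by the follow-up interval)
4. repeated measures -- measured LTL ~ timepoint * exposure with a random
   intercept per participant; the interaction, divided by the interval,
   is the exposure effect.

Models 2 and 3 condition on the measured baseline, which is a collider
between true baseline length and baseline measurement error; with a real
baseline group difference and nonzero assay error they are biased.  Models
1 and 4 are algebraically equivalent in this balanced design, as are 2 and 3.

Also provided is the Verhulst-style regression-to-the-mean correction ``D``:
a per-participant change score from which the within-group linear dependence
of measured change on measured baseline implied by the baseline--follow-up
correlation has been removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simcohort import CohortDataset

__all__ = [
    "FitResult",
    "RtmCorrectedOutcome",
    "FitConvergenceError",
    "fit_change_score",
    "fit_ancova_change",
    "fit_ancova_followup",
    "fit_repeated_measures",
    "fit_model",
    "rtm_correct",
    "standardize_beta",
]

ALPHA = 0.05

CohortLike = Union[CohortDataset, pd.DataFrame]


class FitConvergenceError(RuntimeError):
    """A mixed-model fit failed to converge (distinct from bad-data errors)."""


@dataclass(frozen=True)
class FitResult:
    """Harmonized exposure-effect estimate from one model.

    beta_bp_yr is the exposure effect on annual telomere change in bp/yr;
    beta_std is the same contrast with outcome and (0/1) exposure z-scored.
    """

    model_id: int
    beta_bp_yr: float
    se_bp_yr: float
    p_value: float
    beta_std: float
    n_used: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class RtmCorrectedOutcome:
    """Per-participant change (bp/yr) corrected for regression to the mean."""

    d_bp_yr: np.ndarray

    def __len__(self) -> int:
        return len(self.d_bp_yr)


# ---------------------------------------------------------------------------
# table plumbing


def as_cohort_table(ds: CohortLike) -> pd.DataFrame:
    """Normalize a CohortDataset or wide cohort frame to the model columns.

    The result has exposed, m_ltl_b, m_ltl_fu, interval_years and m_delta_yr.
    """
    if isinstance(ds, CohortDataset):
        tab = ds.records[["exposed", "m_ltl_b", "m_ltl_fu", "m_delta_yr"]].copy()
        tab["interval_years"] = ds.follow_up_years
        return tab
    tab = ds.copy()
    required = {"exposed", "m_ltl_b", "m_ltl_fu"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if "interval_years" not in tab.columns:
        if {"age_b", "age_fu"} <= set(tab.columns):
            tab["interval_years"] = tab["age_fu"] - tab["age_b"]
        else:
            raise ValueError("cohort table needs interval_years or age_b/age_fu")
    if (tab["interval_years"] <= 0).any():
        raise ValueError("follow-up intervals must be positive")
    if "m_delta_yr" not in tab.columns:
        tab["m_delta_yr"] = (tab["m_ltl_fu"] - tab["m_ltl_b"]) / tab["interval_years"]
    return tab


def _check_two_groups(tab: pd.DataFrame) -> None:
    counts = tab["exposed"].value_counts()
    if set(counts.index) != {0, 1} or (counts < 2).any():
        raise ValueError(
            "exposure contrast is inestimable: need >=2 participants in each "
            "of the exposed and unexposed groups"
        )


def _constant_interval(tab: pd.DataFrame) -> float:
    iv = tab["interval_years"].to_numpy(dtype=float)
    if not np.allclose(iv, iv[0]):
        raise ValueError("this model requires a constant follow-up interval")
    return float(iv[0])


def _outcome(tab: pd.DataFrame, ds: CohortLike, outcome: str) -> np.ndarray:
    if outcome == "raw":
        return tab["m_delta_yr"].to_numpy(dtype=float)
    if outcome == "rtm_corrected":
        return rtm_correct(ds).d_bp_yr
    raise ValueError(f"unknown outcome {outcome!r}")


def _std_beta(beta: float, x: np.ndarray, y: np.ndarray) -> float:
    sy = float(np.std(y, ddof=1))
    if sy == 0:
        if beta == 0:  # degenerate but consistent: a null contrast stays null
            return 0.0
        raise ValueError("outcome has zero variance; standardized beta undefined")
    return beta * float(np.std(x, ddof=1)) / sy


# ---------------------------------------------------------------------------
# the four models


def fit_change_score(ds: CohortLike, outcome: str = "raw") -> FitResult:
    """Model 1: per-year measured change regressed on exposure alone.

    The exposure coefficient is exactly the exposed-minus-unexposed mean
    difference in measured annual change (a two-sample t-test).
    """
    tab = as_cohort_table(ds)
    _check_two_groups(tab)
    y = _outcome(tab, ds, outcome)
    x = tab["exposed"].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(
        model_id=1,
        beta_bp_yr=float(res.params[1]),
        se_bp_yr=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        beta_std=_std_beta(float(res.params[1]), x, y),
        n_used=len(tab),
    )


def fit_ancova_change(ds: CohortLike, outcome: str = "raw") -> FitResult:
    """Model 2: per-year measured change on measured baseline plus exposure."""
    tab = as_cohort_table(ds)
    _check_two_groups(tab)
    b = tab["m_ltl_b"].to_numpy(dtype=float)
    if np.std(b) == 0:
        raise ValueError("measured baseline is constant; covariate is collinear")
    y = _outcome(tab, ds, outcome)
    x = tab["exposed"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([b, x]))
    res = sm.OLS(y, X).fit()
    return FitResult(
        model_id=2,
        beta_bp_yr=float(res.params[2]),
        se_bp_yr=float(res.bse[2]),
        p_value=float(res.pvalues[2]),
        beta_std=_std_beta(float(res.params[2]), x, y),
        n_used=len(tab),
    )


def fit_ancova_followup(ds: CohortLike) -> FitResult:
    """Model 3: measured follow-up on measured baseline plus exposure.

    The raw exposure coefficient is in bp over the follow-up interval and is
    divided by the (constant) interval for the harmonized bp/yr scale; it is
    algebraically identical to model 2's because the two outcomes differ by
    baseline/interval, terms absorbed by the covariate.
    """
    tab = as_cohort_table(ds)
    _check_two_groups(tab)
    interval = _constant_interval(tab)
    b = tab["m_ltl_b"].to_numpy(dtype=float)
    if np.std(b) == 0:
        raise ValueError("measured baseline is constant; covariate is collinear")
    y = tab["m_ltl_fu"].to_numpy(dtype=float)
    x = tab["exposed"].to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([b, x]))
    res = sm.OLS(y, X).fit()
    beta_raw = float(res.params[2])
    return FitResult(
        model_id=3,
        beta_bp_yr=beta_raw / interval,
        se_bp_yr=float(res.bse[2]) / interval,
        p_value=float(res.pvalues[2]),
        beta_std=_std_beta(beta_raw, x, y),
        n_used=len(tab),
    )


def fit_repeated_measures(ds: CohortLike, engine: str = "closed") -> FitResult:
    """Model 4: mixed model of measured LTL on timepoint * exposure with a
    random intercept per participant.

    With exactly two time points per participant and every participant
    observed at both, the GLS fixed-effect estimates do not depend on the
    variance components: the timepoint x exposure interaction equals the
    difference-in-differences of the four timepoint-by-group cell means, and
    its sampling variance involves only the residual variance, estimated from
    the within-participant change regression.  The default "closed" engine
    computes that solution directly; engine="mixedlm" delegates to the
    numeric REML fit in statsmodels and is retained as a cross-check.  The
    interaction test is the asymptotic normal (Wald) test in both engines.
    """
    tab = as_cohort_table(ds)
    _check_two_groups(tab)
    interval = _constant_interval(tab)
    x = tab["exposed"].to_numpy(dtype=float)
    d_total = (tab["m_ltl_fu"] - tab["m_ltl_b"]).to_numpy(dtype=float)
    if engine == "closed":
        n0 = int((x == 0).sum())
        n1 = int((x == 1).sum())
        coef = d_total[x == 1].mean() - d_total[x == 0].mean()
        resid = d_total - np.where(x == 1, d_total[x == 1].mean(), d_total[x == 0].mean())
        # residual variance of the change regression estimates 2*sigma_e^2
        s2 = float(resid @ resid) / (n0 + n1 - 2)
        se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
    elif engine == "mixedlm":
        from .simcohort import to_long_format

        if not isinstance(ds, CohortDataset):
            raise ValueError("engine='mixedlm' requires a CohortDataset")
        long = to_long_format(ds)
        t = (long["timepoint"] == "follow_up").to_numpy(dtype=float)
        e = long["exposed"].to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([t, e, t * e]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(long["m_ltl"].to_numpy(), X, groups=long["id"]).fit()
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise FitConvergenceError(str(exc)) from exc
        if not res.converged:
            raise FitConvergenceError("mixed model did not converge")
        coef = float(res.params[3])
        se = float(res.bse[3])
    else:
        raise ValueError(f"unknown engine {engine!r}")
    if se == 0:  # degenerate: no residual variation in the change scores
        p = 1.0 if coef == 0 else 0.0
    else:
        p = 2.0 * stats.norm.sf(abs(coef / se))
    return FitResult(
        model_id=4,
        beta_bp_yr=coef / interval,
        se_bp_yr=se / interval,
        p_value=float(p),
        beta_std=_std_beta(coef / interval, x, d_total / interval),
        n_used=len(tab),
    )


def fit_model(ds: CohortLike, model_id: int, outcome: str = "raw") -> FitResult:
    """Dispatch on model id 1-4.

    The rtm_corrected outcome replaces measured change with the Verhulst D
    and is defined for models 1 and 2 only (3 and 4 are redundant with them
    and are dropped from the corrected analysis).
    """
    if outcome == "rtm_corrected" and model_id not in (1, 2):
        raise ValueError("rtm_corrected outcome is supported for models 1 and 2")
    if model_id == 1:
        return fit_change_score(ds, outcome=outcome)
    if model_id == 2:
        return fit_ancova_change(ds, outcome=outcome)
    if model_id == 3:
        return fit_ancova_followup(ds)
    if model_id == 4:
        return fit_repeated_measures(ds)
    raise ValueError(f"unknown model id {model_id!r}")


# ---------------------------------------------------------------------------
# regression-to-the-mean correction


def rtm_correct(ds: CohortLike) -> RtmCorrectedOutcome:
    """Per-participant change corrected for regression to the mean.

    Within each exposure group, measurement error makes measured change
    depend negatively on measured baseline.  The corrected total change adds
    back that dependence using the group's baseline--follow-up correlation:

        D_i = (m_fu_i - m_b_i) + (1 - r_g) * (m_b_i - mean_g(m_b)),

    where r_g is the Pearson correlation of baseline and follow-up
    measurements in participant i's exposure group.  D is returned per year.
    Computing the correction within exposure groups leaves every group mean
    of change untouched, so the unadjusted group contrast (model 1) is
    invariant under the correction.
    """
    tab = as_cohort_table(ds)
    if len(tab) < 3:
        raise ValueError("need at least 3 participants for the correction")
    d = np.empty(len(tab))
    m_b = tab["m_ltl_b"].to_numpy(dtype=float)
    m_fu = tab["m_ltl_fu"].to_numpy(dtype=float)
    iv = tab["interval_years"].to_numpy(dtype=float)
    exposed = tab["exposed"].to_numpy()
    for g in np.unique(exposed):
        i = exposed == g
        if np.std(m_b[i]) == 0 or np.std(m_fu[i]) == 0:
            raise ValueError(
                f"zero variance at a time point in exposure group {g}; "
                "correction undefined"
            )
        r = float(np.corrcoef(m_b[i], m_fu[i])[0, 1])
        d[i] = (m_fu[i] - m_b[i]) + (1.0 - r) * (m_b[i] - m_b[i].mean())
    return RtmCorrectedOutcome(d_bp_yr=d / iv)


def standardize_beta(fit: FitResult, ds: CohortLike) -> float:
    """Rescale a fit's exposure effect to standard-deviation units.

    Outcome and the 0/1 exposure indicator are both z-scored, so the result
    is dimensionless and invariant to rescaling the telomere measurements.
    For model 3 the outcome is the follow-up measurement (and the raw, not
    per-year, coefficient is standardized); for the others it is per-year
    change.
    """
    tab = as_cohort_table(ds)
    x = tab["exposed"].to_numpy(dtype=float)
    if fit.model_id == 3:
        y = tab["m_ltl_fu"].to_numpy(dtype=float)
        beta = fit.beta_bp_yr * _constant_interval(tab)
    else:
        y = tab["m_delta_yr"].to_numpy(dtype=float)
        beta = fit.beta_bp_yr
    return _std_beta(beta, x, y)
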