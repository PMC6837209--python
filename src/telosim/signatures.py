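"""Data-internal signatures of telomere measurement error.

Assay coefficients of variation reported by labs are not comparable across
studies, but two correlations computable from the measurements themselves
track error magnitude: the correlation of baseline with follow-up LTL is
attenuated toward zero by error, and the correlation of baseline with
per-year change is pushed negative by error (regression to the mean).  The
per-participant change uses each participant's own interval,
(m_ltl_fu - m_ltl_b) / (age_fu - age_b), when ages are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CohortLike, as_cohort_table
from .simcohort import ErrorModel, ScenarioSpec, simulate_cohort

__all__ = ["SignatureSet", "compute_signatures", "cv_to_signature_curve"]


@dataclass(frozen=True)
class SignatureSet:
    """Cohort-level error signatures and the baseline group difference.

    r_b_fu, r_b_delta: Pearson correlations of measured baseline with
    measured follow-up and with per-year change.  slope_fu_on_b and
    slope_delta_on_b are the corresponding simple-regression slopes
    (dimensionless and per-year).  cohen_d_baseline is the exposed-minus-
    unexposed standardized mean difference in measured baseline (pooled sd);
    negative means shorter baseline telomeres in the exposed group.
    """

    r_b_fu: float
    r_b_delta: float
    slope_fu_on_b: float
    slope_delta_on_b: float
    cohen_d_baseline: float


def _require_variance(x: np.ndarray, name: str) -> None:
    if np.std(x) == 0:
        raise ValueError(f"zero variance in {name}; signature undefined")


def compute_signatures(ds: CohortLike) -> SignatureSet:
    """Compute all five signature statistics for one cohort."""
    tab = as_cohort_table(ds)
    if len(tab) < 3:
        raise ValueError("need at least 3 participants")
    m_b = tab["m_ltl_b"].to_numpy(dtype=float)
    m_fu = tab["m_ltl_fu"].to_numpy(dtype=float)
    d_yr = tab["m_delta_yr"].to_numpy(dtype=float)
    exposed = tab["exposed"].to_numpy()
    _require_variance(m_b, "m_ltl_b")
    _require_variance(m_fu, "m_ltl_fu")
    _require_variance(d_yr, "m_delta_yr")

    fu_fit = stats.linregress(m_b, m_fu)
    d_fit = stats.linregress(m_b, d_yr)

    b1, b0 = m_b[exposed == 1], m_b[exposed == 0]
    if len(b1) < 2 or len(b0) < 2:
        raise ValueError("need >=2 participants per exposure group for Cohen's d")
    pooled = np.sqrt(
        ((len(b1) - 1) * b1.var(ddof=1) + (len(b0) - 1) * b0.var(ddof=1))
        / (len(b1) + len(b0) - 2)
    )
    if pooled == 0:
        raise ValueError("zero within-group baseline variance; Cohen's d undefined")
    return SignatureSet(
        r_b_fu=float(fu_fit.rvalue),
        r_b_delta=float(d_fit.rvalue),
        slope_fu_on_b=float(fu_fit.slope),
        slope_delta_on_b=float(d_fit.slope),
        cohen_d_baseline=float((b1.mean() - b0.mean()) / pooled),
    )


def cv_to_signature_curve(
    scenario: ScenarioSpec,
    cvs: Sequence[float],
    reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo mean signatures as a function of assay CV.

    A calibration aid: simulator CVs are not directly comparable to reported
    laboratory CVs, but the resulting signature correlations are, so this
    maps one onto the other.  Both correlations decrease (the
    baseline--change one becomes more negative) as CV grows.
    """
    rows = []
    for c_idx, cv in enumerate(cvs):
        err = ErrorModel.none() if cv == 0 else ErrorModel.proportional(cv)
        acc = np.zeros(5)
        for rep in range(reps):
            ss = np.random.SeedSequence([int(seed), c_idx, rep])
            ds = simulate_cohort(scenario, err, int(ss.generate_state(1)[0] & 0x7FFFFFFF))
            sig = compute_signatures(ds)
            acc += [
                sig.r_b_fu,
                sig.r_b_delta,
                sig.slope_fu_on_b,
                sig.slope_delta_on_b,
                sig.cohen_d_baseline,
            ]
        acc /= reps
        rows.append(
            {
                "cv": float(cv),
                "r_b_fu": acc[0],
                "r_b_delta": acc[1],
                "slope_fu_on_b": acc[2],
                "slope_delta_on_b": acc[3],
                "cohen_d_baseline": acc[4],
                "n_replicates": reps,
            }
        )
    return pd.DataFrame(rows)
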