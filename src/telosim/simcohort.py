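"""Synthetic two-timepoint telomere cohorts with configurable measurement error.

A cohort consists of an exposed group (e.g. smokers) and an unexposed group
(e.g. never-smokers).  Each participant has a true baseline leucocyte telomere
length (LTL, base pairs) and a true constant annual rate of change (bp/yr),
both drawn from group-specific normal distributions.  True follow-up length is
baseline plus rate times the follow-up interval.  Measured lengths add
independent normal error at each time point, with a standard deviation either
proportional to the true length (CV, in percent) or a fixed number of base
pairs.  The measured per-year change is the difference of the two measured
lengths divided by the interval.

Because measured baseline is a common effect of true baseline and baseline
measurement error, conditioning on it in downstream models opens a collider
path; this module only generates the data, the bias itself is examined in
:mod:`telosim.models` and :mod:`telosim.experiment`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec",
    "ScenarioSpec",
    "ErrorModel",
    "CohortDataset",
    "make_scenario",
    "simulate_cohort",
    "to_long_format",
]

# Population parameters for the smoking scenarios, taken from a Southern-blot
# cohort with low assay error (inter-assay CV 1.4%): baseline LTL 7430 +/- 777
# bp, annual change -40.7 +/- 46 bp/yr, smokers' baseline deficit 141 bp,
# smokers' excess attrition -2 bp/yr.
BASELINE_MEAN = 7430.0
BASELINE_SD = 777.0
DELTA_SD = 46.0
SHARED_DELTA_MEAN = -40.7
UNEXPOSED_BASELINE_ANCHOR = 7500.0
DEFAULT_BASELINE_DIFF = 141.0
DEFAULT_DELTA_DIFF = 2.0

SCENARIO_LABELS = ("A", "B", "C", "D", "REV")


@dataclass(frozen=True)
class GroupSpec:
    """Normal population parameters for one exposure group.

    mean_ltl_b / sd_ltl_b are in bp; mean_delta / sd_delta in bp/yr.
    """

    mean_ltl_b: float
    sd_ltl_b: float
    mean_delta: float
    sd_delta: float

    def __post_init__(self) -> None:
        if self.sd_ltl_b < 0 or self.sd_delta < 0:
            raise ValueError("group standard deviations must be non-negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario: two groups, a follow-up interval and group sizes."""

    label: str
    exposed: GroupSpec
    unexposed: GroupSpec
    follow_up_years: float = 10.0
    n_exposed: int = 1000
    n_unexposed: int = 1000

    def __post_init__(self) -> None:
        if self.follow_up_years <= 0:
            raise ValueError("follow_up_years must be positive")
        if self.n_exposed < 2 or self.n_unexposed < 2:
            raise ValueError("need at least 2 participants per group")

    @property
    def true_delta_diff(self) -> float:
        """True exposed-minus-unexposed difference in annual change (bp/yr)."""
        return self.exposed.mean_delta - self.unexposed.mean_delta

    @property
    def true_baseline_diff(self) -> float:
        """True unexposed-minus-exposed baseline difference (bp); positive
        means the exposed group starts with shorter telomeres."""
        return self.unexposed.mean_ltl_b - self.exposed.mean_ltl_b

    def with_sizes(self, n_exposed: int, n_unexposed: int) -> "ScenarioSpec":
        return replace(self, n_exposed=n_exposed, n_unexposed=n_unexposed)


@dataclass(frozen=True)
class ErrorModel:
    """Measurement-error model for the telomere assay.

    mode "proportional": error sd at each time point is true LTL * cv / 100.
    mode "additive": error sd is a fixed number of base pairs.
    mode "none": measurements equal true values.
    """

    mode: str = "proportional"
    cv: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "additive", "none"):
            raise ValueError(f"unknown error mode {self.mode!r}")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def none(cls) -> "ErrorModel":
        return cls(mode="none")

    @classmethod
    def proportional(cls, cv: float) -> "ErrorModel":
        return cls(mode="proportional", cv=cv)

    @classmethod
    def additive(cls, sd: float) -> "ErrorModel":
        return cls(mode="additive", sd=sd)

    def error_sd(self, true_ltl: np.ndarray) -> np.ndarray:
        if self.mode == "proportional":
            return np.abs(true_ltl) * self.cv / 100.0
        if self.mode == "additive":
            return np.full_like(true_ltl, float(self.sd))
        return np.zeros_like(true_ltl)


#: Column order of the per-participant records table.
RECORD_COLUMNS = [
    "id",
    "exposed",
    "true_ltl_b",
    "true_delta",
    "true_ltl_fu",
    "m_ltl_b",
    "m_ltl_fu",
    "m_delta_yr",
    "error_b",
    "error_fu",
]


@dataclass
class CohortDataset:
    """One simulated cohort: per-participant records plus its provenance."""

    records: pd.DataFrame
    scenario: ScenarioSpec
    error: ErrorModel
    seed: int

    @property
    def follow_up_years(self) -> float:
        return self.scenario.follow_up_years

    def __len__(self) -> int:
        return len(self.records)


def make_scenario(
    label: str,
    baseline_diff: float = DEFAULT_BASELINE_DIFF,
    delta_diff: float = DEFAULT_DELTA_DIFF,
    *,
    follow_up_years: float = 10.0,
    n_exposed: int = 1000,
    n_unexposed: int = 1000,
) -> ScenarioSpec:
    """Return a preset scenario.

    A: no baseline difference, no attrition difference (both groups
       7430 +/- 777 bp, -40.7 +/- 46 bp/yr).
    B: no baseline difference, true attrition difference ``delta_diff``
       (split about -41 bp/yr: -40 vs -42 at the default).
    C: baseline difference ``baseline_diff`` (unexposed 7500, exposed
       7500 - baseline_diff), no attrition difference.
    D: both differences.
    REV: the C baseline deficit but *slower* true attrition in the exposed
       group (-40 vs -42 bp/yr), the direction-reversal scenario.
    """
    if label not in SCENARIO_LABELS:
        raise ValueError(
            f"unsupported scenario {label!r}; expected one of {SCENARIO_LABELS}"
        )
    shared = GroupSpec(BASELINE_MEAN, BASELINE_SD, SHARED_DELTA_MEAN, DELTA_SD)
    slow = GroupSpec(BASELINE_MEAN, BASELINE_SD, -41.0 + delta_diff / 2.0, DELTA_SD)
    fast = GroupSpec(BASELINE_MEAN, BASELINE_SD, -41.0 - delta_diff / 2.0, DELTA_SD)
    hi_b = UNEXPOSED_BASELINE_ANCHOR
    lo_b = UNEXPOSED_BASELINE_ANCHOR - baseline_diff

    if label == "A":
        exposed, unexposed = shared, shared
    elif label == "B":
        exposed, unexposed = fast, slow
    elif label == "C":
        exposed = replace(shared, mean_ltl_b=lo_b)
        unexposed = replace(shared, mean_ltl_b=hi_b)
    elif label == "D":
        exposed = replace(fast, mean_ltl_b=lo_b)
        unexposed = replace(slow, mean_ltl_b=hi_b)
    else:  # REV: exposed start shorter but truly lose telomeres more slowly
        exposed = GroupSpec(lo_b, BASELINE_SD, -40.0, DELTA_SD)
        unexposed = GroupSpec(hi_b, BASELINE_SD, -42.0, DELTA_SD)
    return ScenarioSpec(
        label=label,
        exposed=exposed,
        unexposed=unexposed,
        follow_up_years=follow_up_years,
        n_exposed=n_exposed,
        n_unexposed=n_unexposed,
    )


def simulate_cohort(spec: ScenarioSpec, error: ErrorModel, seed: int) -> CohortDataset:
    """Simulate one cohort under ``spec`` with measurement error ``error``.

    Draw order from the single root generator is fixed (baseline lengths,
    annual changes, baseline errors, follow-up errors; unexposed block before
    exposed block within each draw) so identical seeds give bit-identical
    datasets.
    """
    rng = np.random.default_rng(seed)
    n0, n1 = spec.n_unexposed, spec.n_exposed
    exposed_flag = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]

    true_b = np.r_[
        rng.normal(spec.unexposed.mean_ltl_b, spec.unexposed.sd_ltl_b, n0),
        rng.normal(spec.exposed.mean_ltl_b, spec.exposed.sd_ltl_b, n1),
    ]
    true_delta = np.r_[
        rng.normal(spec.unexposed.mean_delta, spec.unexposed.sd_delta, n0),
        rng.normal(spec.exposed.mean_delta, spec.exposed.sd_delta, n1),
    ]
    true_fu = true_b + spec.follow_up_years * true_delta

    sd_b = error.error_sd(true_b)
    sd_fu = error.error_sd(true_fu)
    # rng.normal with scale 0 is valid and returns the mean, so the
    # error-free model flows through the same path.
    error_b = rng.normal(0.0, sd_b)
    error_fu = rng.normal(0.0, sd_fu)

    m_b = true_b + error_b
    m_fu = true_fu + error_fu
    m_delta_yr = (m_fu - m_b) / spec.follow_up_years

    records = pd.DataFrame(
        {
            "id": np.arange(n0 + n1),
            "exposed": exposed_flag,
            "true_ltl_b": true_b,
            "true_delta": true_delta,
            "true_ltl_fu": true_fu,
            "m_ltl_b": m_b,
            "m_ltl_fu": m_fu,
            "m_delta_yr": m_delta_yr,
            "error_b": error_b,
            "error_fu": error_fu,
        },
        columns=RECORD_COLUMNS,
    )
    return CohortDataset(records=records, scenario=spec, error=error, seed=int(seed))


def to_long_format(ds: CohortDataset) -> pd.DataFrame:
    """Two rows per participant: (id, exposed, timepoint, m_ltl)."""
    rec = ds.records
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": rec["id"],
                    "exposed": rec["exposed"],
                    "timepoint": "baseline",
                    "m_ltl": rec["m_ltl_b"],
                }
            ),
            pd.DataFrame(
                {
                    "id": rec["id"],
                    "exposed": rec["exposed"],
                    "timepoint": "follow_up",
                    "m_ltl": rec["m_ltl_fu"],
                }
            ),
        ],
        ignore_index=True,
    )
    return long
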