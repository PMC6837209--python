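"""Reading and writing the wide cohort CSV dialect.

One row per participant with columns ``id, exposed, age_b, age_fu, m_ltl_b,
m_ltl_fu`` (lengths in bp, ages in years, exposed in {0,1}).  A leading
comment line ``# units: bp, years`` is written and tolerated on read.
Simulated cohorts may additionally carry ``true_ltl_b`` and ``true_delta``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simcohort import CohortDataset

__all__ = ["read_cohort_csv", "write_cohort_csv", "cohort_to_wide"]

REQUIRED_COLUMNS = ["id", "exposed", "age_b", "age_fu", "m_ltl_b", "m_ltl_fu"]
UNITS_COMMENT = "# units: bp, years"

#: nominal baseline age written for simulated participants (the simulator
#: parameterizes only the interval; every computation uses age differences)
NOMINAL_BASELINE_AGE = 50.0


def cohort_to_wide(ds: CohortDataset, include_truth: bool = False) -> pd.DataFrame:
    """Wide frame for a simulated cohort in the interchange dialect."""
    rec = ds.records
    wide = pd.DataFrame(
        {
            "id": rec["id"],
            "exposed": rec["exposed"],
            "age_b": NOMINAL_BASELINE_AGE,
            "age_fu": NOMINAL_BASELINE_AGE + ds.follow_up_years,
            "m_ltl_b": rec["m_ltl_b"],
            "m_ltl_fu": rec["m_ltl_fu"],
        }
    )
    if include_truth:
        wide["true_ltl_b"] = rec["true_ltl_b"]
        wide["true_delta"] = rec["true_delta"]
    return wide


def write_cohort_csv(
    ds: CohortDataset | pd.DataFrame, path: str | Path, include_truth: bool = False
) -> None:
    wide = cohort_to_wide(ds, include_truth) if isinstance(ds, CohortDataset) else ds
    with open(path, "w") as fh:
        fh.write(UNITS_COMMENT + "\n")
        # shortest round-trip float representation, so write->read is exact
        wide.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide cohort CSV into a typed table.

    Returns the frame with interval_years and m_delta_yr appended; raises
    with an explicit message for missing columns, non-numeric cells,
    non-binary exposure or fewer than 3 participants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    for col in REQUIRED_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            raise ValueError(f"{path.name}: non-numeric or missing values in {col!r}")
    if not df["exposed"].isin([0, 1]).all():
        raise ValueError(f"{path.name}: exposed must be 0 or 1")
    df["exposed"] = df["exposed"].astype(int)
    if len(df) < 3:
        raise ValueError(f"{path.name}: need at least 3 participants, got {len(df)}")
    df["interval_years"] = df["age_fu"] - df["age_b"]
    if (df["interval_years"] <= 0).any():
        raise ValueError(f"{path.name}: age_fu must exceed age_b for every row")
    df["m_delta_yr"] = (df["m_ltl_fu"] - df["m_ltl_b"]) / df["interval_years"]
    return df
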