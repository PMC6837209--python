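"""Monte-Carlo grids: bias, type-I error and power surfaces.

For every (scenario, error level, model) cell the engine simulates
independent replicate cohorts, fits the requested models to each, and
summarizes the exposure-effect estimates: mean, a normal-approximation 95%
confidence interval of the mean over replicates, and the proportion of
replicates significant at p < 0.05.  That proportion is the type-I error
rate when the scenario's true attrition difference is zero and the power
otherwise.

Replicate seeds are derived deterministically from the grid seed and the
cell coordinates, so any cell can be recomputed in isolation and results do
not depend on execution order or on which models are requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .simcohort import ErrorModel, ScenarioSpec, make_scenario, simulate_cohort

__all__ = [
    "GridSpec",
    "CellSummary",
    "run_grid",
    "run_sensitivity",
    "summarize_bias",
    "SENSITIVITY_KINDS",
]

logger = logging.getLogger("telosim")

#: exact column order of the grid output table
CELL_COLUMNS = [
    "scenario",
    "cv",
    "model",
    "mean_beta",
    "ci_low",
    "ci_high",
    "prop_significant",
    "n_replicates",
]

#: maximum tolerated share of failed replicate fits per cell
MAX_FAILURE_RATE = 0.01


@dataclass(frozen=True)
class GridSpec:
    """One grid request: scenarios x error levels, models, replicate count."""

    scenarios: Sequence[ScenarioSpec]
    cvs: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
    n_replicates: int = 1000
    models: Sequence[int] = (1, 2, 3, 4)
    seed: int = 0
    outcome: str = "raw"
    #: additive error sds (bp) instead of proportional cvs, when set
    additive_sds: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(cv < 0 for cv in self.cvs):
            raise ValueError("cvs must be non-negative")


@dataclass(frozen=True)
class CellSummary:
    scenario: str
    cv: float
    model: int
    mean_beta: float
    ci_low: float
    ci_high: float
    prop_significant: float
    n_replicates: int


def replicate_seed(grid_seed: int, scenario_idx: int, cv_idx: int, rep: int) -> int:
    """Deterministic per-replicate seed, independent of the model list."""
    ss = np.random.SeedSequence([int(grid_seed), scenario_idx, cv_idx, rep])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _error_levels(g: GridSpec) -> list[tuple[float, ErrorModel]]:
    if g.additive_sds is not None:
        return [(float(sd), ErrorModel.additive(sd)) for sd in g.additive_sds]
    return [
        (float(cv), ErrorModel.none() if cv == 0 else ErrorModel.proportional(cv))
        for cv in g.cvs
    ]


def run_grid(g: GridSpec) -> pd.DataFrame:
    """Run the full grid and return one row per (scenario, cv, model) cell.

    All requested models are fitted to the *same* replicate datasets within a
    cell, so model contrasts are paired.  Replicates whose fit raises are
    counted and excluded; a cell aborts if more than 1% of fits fail.
    """
    rows: list[CellSummary] = []
    for s_idx, scen in enumerate(g.scenarios):
        for c_idx, (level, err) in enumerate(_error_levels(g)):
            betas: dict[int, list[float]] = {m: [] for m in g.models}
            sig: dict[int, list[bool]] = {m: [] for m in g.models}
            failures = 0
            for rep in range(g.n_replicates):
                seed = replicate_seed(g.seed, s_idx, c_idx, rep)
                ds = simulate_cohort(scen, err, seed)
                try:
                    for m in g.models:
                        fit = _models.fit_model(ds, m, outcome=g.outcome)
                        betas[m].append(fit.beta_bp_yr)
                        sig[m].append(fit.significant)
                except (ValueError, _models.FitConvergenceError) as exc:
                    failures += 1
                    logger.warning(
                        "event=replicate_failed scenario=%s level=%s rep=%d "
                        "seed=%d error=%r",
                        scen.label, level, rep, seed, exc,
                    )
            if failures > MAX_FAILURE_RATE * g.n_replicates:
                raise RuntimeError(
                    f"cell ({scen.label}, {level}) had {failures} failed "
                    f"replicates of {g.n_replicates}"
                )
            for m in g.models:
                b = np.asarray(betas[m])
                half = 1.96 * b.std(ddof=1) / np.sqrt(len(b)) if len(b) > 1 else 0.0
                rows.append(
                    CellSummary(
                        scenario=scen.label,
                        cv=level,
                        model=m,
                        mean_beta=float(b.mean()),
                        ci_low=float(b.mean() - half),
                        ci_high=float(b.mean() + half),
                        prop_significant=float(np.mean(sig[m])),
                        n_replicates=len(b),
                    )
                )
            logger.info(
                "event=cell_done scenario=%s level=%s reps=%d failures=%d",
                scen.label, level, g.n_replicates, failures,
            )
    return pd.DataFrame([r.__dict__ for r in rows], columns=CELL_COLUMNS)


def summarize_bias(cells: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Append bias = mean_beta - truth (bp/yr) to a grid output table."""
    out = cells.copy()
    out["bias"] = out["mean_beta"] - truth
    return out


# ---------------------------------------------------------------------------
# sensitivity analyses

BASELINE_DIFF_GRID = (0.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
SAMPLE_SIZE_GRID = (200, 400, 800, 1600, 3200, 6400)
ADDITIVE_SD_GRID = (0.0, 70.0, 140.0, 280.0, 560.0, 1120.0)

SENSITIVITY_KINDS = (
    "baseline_diff",
    "sample_size",
    "effect_size",
    "additive_error",
    "rtm",
    "reversed",
)


def _enlarged_effect_scenario(label: str) -> ScenarioSpec:
    """Scenario B or D with a -20 bp/yr true attrition difference
    (-50 bp/yr in the exposed, -30 bp/yr in the unexposed group)."""
    base = make_scenario(label)
    return replace(
        base,
        exposed=replace(base.exposed, mean_delta=-50.0),
        unexposed=replace(base.unexposed, mean_delta=-30.0),
    )


def run_sensitivity(kind: str, base: GridSpec) -> pd.DataFrame:
    """Re-run the grid along one sensitivity axis.

    baseline_diff: scenario-C/D baseline differences 0..1600 bp (adds a
        ``baseline_diff`` column);
    sample_size: total cohort sizes 200..6400, split equally (adds
        ``n_total``);
    effect_size: true attrition difference enlarged to -20 bp/yr;
    additive_error: fixed-bp error sds 0..1120 in place of proportional CVs
        (the cv column then holds the sd, and an ``error_sd`` column is added);
    rtm: the regression-to-the-mean-corrected outcome, models 1 and 2;
    reversed: the direction-reversal scenario (shorter baseline but slower
        true attrition in the exposed group).
    """
    if kind not in SENSITIVITY_KINDS:
        raise ValueError(f"unknown sensitivity kind {kind!r}")

    if kind == "baseline_diff":
        out = []
        for diff in BASELINE_DIFF_GRID:
            scens = [
                make_scenario(s.label, baseline_diff=diff).with_sizes(
                    s.n_exposed, s.n_unexposed
                )
                for s in base.scenarios
                if s.label in ("C", "D")
            ] or [make_scenario("C", baseline_diff=diff)]
            cells = run_grid(replace(base, scenarios=scens))
            cells.insert(0, "baseline_diff", diff)
            out.append(cells)
        return pd.concat(out, ignore_index=True)

    if kind == "sample_size":
        out = []
        for n_total in SAMPLE_SIZE_GRID:
            scens = [s.with_sizes(n_total // 2, n_total // 2) for s in base.scenarios]
            cells = run_grid(replace(base, scenarios=scens))
            cells.insert(0, "n_total", n_total)
            out.append(cells)
        return pd.concat(out, ignore_index=True)

    if kind == "effect_size":
        scens = [
            _enlarged_effect_scenario(s.label) if s.label in ("B", "D") else s
            for s in base.scenarios
        ] or [_enlarged_effect_scenario("B")]
        return run_grid(replace(base, scenarios=scens))

    if kind == "additive_error":
        cells = run_grid(replace(base, additive_sds=ADDITIVE_SD_GRID))
        cells["error_sd"] = cells["cv"]
        return cells

    if kind == "rtm":
        mods = tuple(m for m in base.models if m in (1, 2)) or (1, 2)
        return run_grid(replace(base, outcome="rtm_corrected", models=mods))

    # reversed
    rev = make_scenario("REV")
    sizes = base.scenarios[0] if len(base.scenarios) else rev
    rev = rev.with_sizes(sizes.n_exposed, sizes.n_unexposed)
    return run_grid(replace(base, scenarios=[rev]))
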