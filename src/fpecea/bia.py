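"""Budget impact: national annual cost of reimbursing the exercise program.

The per-person incremental cost of the intervention (from the cohort
model) is extrapolated to a payer population: for each (age, sex) stratum
of independently living individuals the model is re-run with that entry
age, the horizon truncated at the stratum's remaining life expectancy, and
the incremental cost annualised (total over the truncated horizon divided
by the horizon in years) and multiplied by the head count.

Population counts and remaining life expectancies are not part of the
bundled inputs — they come from national statistics and must be supplied
as a CSV with columns ``age, sex, count, remaining_life_expectancy_years``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cea import run_cea
from .parameters import SEXES, ParameterSet

__all__ = ["load_population", "budget_impact"]

REQUIRED_COLUMNS = ("age", "sex", "count", "remaining_life_expectancy_years")


def load_population(path: str | Path) -> pd.DataFrame:
    """Read and validate a population table."""
    pop = pd.read_csv(path)
    return validate_population(pop)


def validate_population(pop: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in pop.columns]
    if missing:
        raise ValueError(f"population table is missing columns: {missing}")
    pop = pop.copy()
    pop["age"] = pop["age"].astype(int)
    if (pop["age"] < 75).any():
        raise ValueError("population table contains ages below 75")
    if (pop["count"] < 0).any():
        raise ValueError("population counts must be non-negative")
    bad_sex = set(pop["sex"]) - set(SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values in population table: {sorted(bad_sex)}")
    return pop


def budget_impact(params: ParameterSet, pop: pd.DataFrame) -> pd.DataFrame:
    """Annual incremental cost to the payer, by sex.

    Returns one row per sex (plus a ``total`` row) with the aggregate
    annual cost in € and the population covered.  Linear in the population
    counts.
    """
    pop = validate_population(pop)
    rows = []
    for rec in pop.itertuples():
        horizon = min(float(rec.remaining_life_expectancy_years), 100 - rec.age)
        if horizon <= 0 or rec.count == 0:
            rows.append({"sex": rec.sex, "annual_cost": 0.0, "count": rec.count})
            continue
        ps = params.with_settings(
            sex=rec.sex, entry_age=int(rec.age), horizon_years=horizon
        )
        result = run_cea(ps)
        annual_per_person = result.d_cost / horizon
        rows.append({
            "sex": rec.sex,
            "annual_cost": annual_per_person * rec.count,
            "count": rec.count,
        })
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=["sex", "annual_cost", "count"])
    by_sex = frame.groupby("sex", sort=False, as_index=False).sum(numeric_only=True)
    total = pd.DataFrame([{
        "sex": "total",
        "annual_cost": by_sex["annual_cost"].sum(),
        "count": by_sex["count"].sum(),
    }])
    return pd.concat([by_sex, total], ignore_index=True)
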