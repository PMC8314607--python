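"""Model inputs: transition probabilities, costs, and the intervention effect.

All inputs of the cost-effectiveness model live in a :class:`ParameterSet`:
age-band × sex transition probabilities per 6-month cycle, cost inputs in
euros (intervention fees by program year, per-fracture treatment components,
long-term-care costs per 6 months), and the intervention effect (risk ratio
with its 95% CI, participation rate and annual adherence decay).

Parameters are stored in tidy tables with one row per (parameter, age band,
sex) cell, mirroring the on-disk CSV schema, so that deterministic runs,
one-way sensitivity analyses and probabilistic draws all address the same
rows.  Uncertainty ranges that the sources do not publish are auto-filled
with the conventional assumptions: ±20% around point probabilities, a 40%
standard deviation for treatment and long-term-care costs and 50% for the
intervention fees.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEXES",
    "PROBABILITY_PARAMS",
    "COST_PARAMS",
    "InterventionEffect",
    "ModelSettings",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameters",
    "write_parameters",
    "base_case",
    "lookup",
]

SEXES = ("women", "men")

#: Clinical (probability) parameters; one value per age band and sex.
PROBABILITY_PARAMS = (
    "p_first_fracture",
    "p_first_fracture_late",
    "p_refracture_acute",
    "p_refracture_late",
    "p_refracture_nh",
    "p_nh_admission",
    "p_mort_well",
    "p_mort_acute_fracture",
    "p_mort_post_fracture",
    "p_mort_nh",
    "p_mort_nh_refracture",
)

#: Cost parameters (euros).  Treatment components are per fracture, the
#: long-term-care entries per 6-month cycle spent in the respective state.
COST_PARAMS = (
    "hospital_care",
    "revision",
    "rehabilitation",
    "outpatient_care",
    "ltc_well",
    "ltc_post_fracture",
    "ltc_nursing_home",
)

TREATMENT_COMPONENTS = ("hospital_care", "revision", "rehabilitation", "outpatient_care")

# Default uncertainty assumptions for cells without published intervals.
PROB_RANGE_FRACTION = 0.20
COST_SD_FRACTION = 0.40
INTERVENTION_SD_FRACTION = 0.50


class ParameterValidationError(ValueError):
    """Raised when an input file violates the model's invariants.

    Carries enough context (parameter name, sex, age band) for the message
    to point at the offending cell.
    """

    def __init__(self, message, *, parameter=None, sex=None, age_band=None):
        parts = [message]
        if parameter is not None:
            parts.append(f"parameter={parameter!r}")
        if sex is not None:
            parts.append(f"sex={sex!r}")
        if age_band is not None:
            parts.append(f"age_band={age_band}")
        super().__init__(" ".join(parts))
        self.parameter = parameter
        self.sex = sex
        self.age_band = age_band


@dataclass(frozen=True)
class InterventionEffect:
    """Risk ratio of the exercise program and its waning over time.

    The program reduces the first-hip-fracture probability by the factor
    ``rr`` (point estimate with 95% CI ``rr_low``–``rr_high``).  The effect
    is diluted by the participation rate (fraction of the offered cohort
    actually taking part; uptake of group-exercise offers among German
    elderly is around 70%) and decays proportionally by
    ``annual_decay_fraction`` per program year to reflect non-persistence;
    it is zero from ``effect_zero_after_years`` onwards.
    """

    rr: float = 0.73
    rr_low: float = 0.56
    rr_high: float = 0.95
    participation_rate: float = 0.7
    annual_decay_fraction: float = 0.28
    effect_zero_after_years: int = 4

    def __post_init__(self):
        if not 0 < self.rr <= 1:
            raise ParameterValidationError(
                f"risk ratio must be in (0, 1], got {self.rr}", parameter="rr"
            )
        if not self.rr_low <= self.rr <= self.rr_high:
            raise ParameterValidationError(
                f"risk-ratio CI ({self.rr_low}, {self.rr_high}) does not "
                f"bracket the point estimate {self.rr}",
                parameter="rr",
            )
        if not 0 <= self.participation_rate <= 1:
            raise ParameterValidationError(
                "participation_rate must be in [0, 1]", parameter="participation_rate"
            )

    def decay_multiplier(self, program_year: int) -> float:
        """Residual effect fraction in a given program year (0-based).

        Proportional decay: each year retains ``1 - annual_decay_fraction``
        of the previous year's effect (multipliers 1, 0.72, 0.72², ... for
        the default), truncated to exactly zero from
        ``effect_zero_after_years`` on.  Non-increasing in time.
        """
        if program_year >= self.effect_zero_after_years:
            return 0.0
        return (1.0 - self.annual_decay_fraction) ** program_year


@dataclass(frozen=True)
class ModelSettings:
    """Run-level settings: cohort entry, horizon, cycle length, discounting.

    Costs and, when ``discount_outcomes`` is set, outcome counts are
    discounted at ``discount_rate`` per year (default 3%, the German
    health-economic guideline convention).
    """

    sex: str = "women"
    entry_age: int = 75
    horizon_years: int = 25
    cycle_length_months: int = 6
    discount_rate: float = 0.03
    discount_outcomes: bool = True
    half_cycle_correction: bool = False
    use_late_first_fracture: bool = False

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ParameterValidationError(f"unknown sex {self.sex!r}", sex=self.sex)
        if 12 % self.cycle_length_months:
            raise ParameterValidationError(
                "cycle_length_months must divide 12", parameter="cycle_length_months"
            )

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_months / 12.0

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years / self.cycle_years))

    @property
    def cycles_per_year(self) -> int:
        return int(round(1.0 / self.cycle_years))


@dataclass
class ParameterSet:
    """Complete, validated model input.

    Attributes
    ----------
    clinical : DataFrame
        One row per (parameter, age band, sex) transition probability with
        columns ``parameter, age_lower, age_upper, sex, value, low, high,
        dist``.  Probabilities are per 6-month cycle, as published.
    costs : DataFrame
        Cost cells with the same band columns plus ``sd`` (PSA standard
        deviation in €).  ``sex == 'all'`` marks sex-independent cells.
    intervention : DataFrame
        Program fees per program year (1-based) and sex, € per year.
    effect : InterventionEffect
    settings : ModelSettings
    variant : dict or None
        Structural-variant block (see :mod:`fpecea.variants`); ``None`` for
        the base-case structure.
    """

    clinical: pd.DataFrame
    costs: pd.DataFrame
    intervention: pd.DataFrame
    effect: InterventionEffect = field(default_factory=InterventionEffect)
    settings: ModelSettings = field(default_factory=ModelSettings)
    variant: dict | None = None

    # -- construction -------------------------------------------------

    def __post_init__(self):
        self.clinical = _normalise_table(self.clinical, kind="clinical")
        self.costs = _normalise_table(self.costs, kind="cost")
        self.intervention = _normalise_intervention(self.intervention)
        self.validate()

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            clinical=self.clinical.copy(),
            costs=self.costs.copy(),
            intervention=self.intervention.copy(),
            effect=self.effect,
            settings=self.settings,
            variant=None if self.variant is None else dict(self.variant),
        )

    def with_settings(self, **kwargs) -> "ParameterSet":
        ps = self.copy()
        ps.settings = replace(self.settings, **kwargs)
        return ps

    def with_effect(self, **kwargs) -> "ParameterSet":
        ps = self.copy()
        ps.effect = replace(self.effect, **kwargs)
        return ps

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Check every invariant the file format promises.

        Raises :class:`ParameterValidationError` naming the first offending
        cell.  Called automatically on construction; safe to re-run after
        in-place edits (sensitivity analyses do).
        """
        core = [p for p in PROBABILITY_PARAMS if p in set(self.clinical["parameter"])]
        missing = set(PROBABILITY_PARAMS) - set(core)
        if missing:
            raise ParameterValidationError(
                f"clinical table is missing parameters: {sorted(missing)}"
            )
        for (name, sex), grp in self.clinical.groupby(["parameter", "sex"], sort=False):
            if sex not in SEXES:
                raise ParameterValidationError(
                    "unknown sex in clinical table", parameter=name, sex=sex
                )
            _check_band_coverage(grp, name, sex)
            for row in grp.itertuples():
                band = (row.age_lower, row.age_upper)
                if not 0.0 <= row.value <= 1.0:
                    raise ParameterValidationError(
                        f"probability {row.value} outside [0, 1]",
                        parameter=name, sex=sex, age_band=band,
                    )
                if not row.low <= row.value <= row.high:
                    raise ParameterValidationError(
                        f"range ({row.low}, {row.high}) does not bracket {row.value}",
                        parameter=name, sex=sex, age_band=band,
                    )
                if not (0.0 <= row.low and row.high <= 1.0):
                    raise ParameterValidationError(
                        "probability range outside [0, 1]",
                        parameter=name, sex=sex, age_band=band,
                    )
        for sex in SEXES:
            for name in PROBABILITY_PARAMS:
                sub = self.clinical[
                    (self.clinical["parameter"] == name) & (self.clinical["sex"] == sex)
                ]
                if sub.empty:
                    raise ParameterValidationError(
                        "no cells for this parameter/sex", parameter=name, sex=sex
                    )
        for row in self.costs.itertuples():
            band = (row.age_lower, row.age_upper)
            if row.value < 0 or row.low < 0:
                raise ParameterValidationError(
                    "cost must be non-negative",
                    parameter=row.parameter, sex=row.sex, age_band=band,
                )
            if not row.low <= row.value <= row.high:
                raise ParameterValidationError(
                    f"range ({row.low}, {row.high}) does not bracket {row.value}",
                    parameter=row.parameter, sex=row.sex, age_band=band,
                )
        for name in COST_PARAMS:
            if name not in set(self.costs["parameter"]):
                raise ParameterValidationError("cost table is missing", parameter=name)
        for sex in SEXES:
            years = self.intervention.loc[self.intervention["sex"] == sex, "program_year"]
            if sorted(years) != list(range(1, len(years) + 1)):
                raise ParameterValidationError(
                    "intervention cost schedule must cover program years 1..n",
                    parameter="intervention_cost", sex=sex,
                )
        covered = any(
            row.age_lower <= self.settings.entry_age <= row.age_upper
            for row in self.clinical.itertuples()
            if row.parameter == "p_first_fracture" and row.sex == self.settings.sex
        )
        if not covered or self.settings.entry_age > 100:
            raise ParameterValidationError(
                f"entry age {self.settings.entry_age} not covered by any age band"
            )

    # -- access -------------------------------------------------------

    def treatment_cost_total(self) -> float:
        """Base-case per-fracture treatment cost (sum of the components)."""
        sub = self.costs[self.costs["parameter"].isin(TREATMENT_COMPONENTS)]
        return float(sub["value"].sum())

    def clinical_values(self, name: str, sex: str) -> pd.DataFrame:
        sub = self.clinical[
            (self.clinical["parameter"] == name) & (self.clinical["sex"] == sex)
        ]
        if sub.empty:
            raise KeyError(f"no clinical parameter {name!r} for sex {sex!r}")
        return sub.sort_values("age_lower").reset_index(drop=True)

    def cost_values(self, name: str, sex: str) -> pd.DataFrame:
        sub = self.costs[
            (self.costs["parameter"] == name)
            & (self.costs["sex"].isin([sex, "all"]))
        ]
        if sub.empty:
            raise KeyError(f"no cost parameter {name!r} for sex {sex!r}")
        return sub.sort_values("age_lower").reset_index(drop=True)

    def intervention_schedule(self, sex: str) -> np.ndarray:
        sub = self.intervention[self.intervention["sex"] == sex]
        return sub.sort_values("program_year")["value"].to_numpy(float)

    def param_hash(self) -> str:
        """Stable digest over all parameter values, for run metadata."""
        h = hashlib.sha256()
        for frame in (self.clinical, self.costs, self.intervention):
            h.update(frame.to_csv(index=False).encode())
        h.update(repr(self.effect).encode())
        h.update(repr(self.settings).encode())
        h.update(repr(self.variant).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# table normalisation helpers

def _coerce_band(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["age_lower"] = pd.to_numeric(frame["age_lower"], errors="coerce").fillna(75).astype(int)
    upper = pd.to_numeric(frame.get("age_upper"), errors="coerce")
    frame["age_upper"] = upper.fillna(np.inf)
    return frame


def _normalise_table(frame: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Coerce dtypes and auto-fill absent uncertainty ranges.

    Probabilities get the ±20% convention (clipped to [0, 1]); costs get a
    ±40% range and a 40% SD (50% for nothing here — the intervention table
    is handled separately).
    """
    frame = _coerce_band(frame)
    frame["value"] = pd.to_numeric(frame["value"]).astype(float)
    low = pd.to_numeric(frame.get("low"), errors="coerce")
    high = pd.to_numeric(frame.get("high"), errors="coerce")
    if kind == "clinical":
        fill_low = np.clip(frame["value"] * (1 - PROB_RANGE_FRACTION), 0.0, 1.0)
        fill_high = np.clip(frame["value"] * (1 + PROB_RANGE_FRACTION), 0.0, 1.0)
        frame["dist"] = frame.get("dist", "beta")
        frame["dist"] = frame["dist"].fillna("beta")
    else:
        fill_low = frame["value"] * (1 - COST_SD_FRACTION)
        fill_high = frame["value"] * (1 + COST_SD_FRACTION)
        sd = pd.to_numeric(frame.get("sd"), errors="coerce")
        frame["sd"] = sd.fillna(frame["value"] * COST_SD_FRACTION)
        frame["dist"] = frame.get("dist", "gamma")
        frame["dist"] = frame["dist"].fillna("gamma")
    frame["low"] = low.fillna(fill_low)
    frame["high"] = high.fillna(fill_high)
    return frame.reset_index(drop=True)


def _normalise_intervention(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["program_year"] = frame["program_year"].astype(int)
    frame["value"] = pd.to_numeric(frame["value"]).astype(float)
    low = pd.to_numeric(frame.get("low"), errors="coerce")
    high = pd.to_numeric(frame.get("high"), errors="coerce")
    sd = pd.to_numeric(frame.get("sd"), errors="coerce")
    frame["low"] = low.fillna(frame["value"] * (1 - INTERVENTION_SD_FRACTION))
    frame["high"] = high.fillna(frame["value"] * (1 + INTERVENTION_SD_FRACTION))
    frame["sd"] = sd.fillna(frame["value"] * INTERVENTION_SD_FRACTION)
    frame["dist"] = frame.get("dist", "gamma")
    frame["dist"] = frame["dist"].fillna("gamma")
    return frame.reset_index(drop=True)


def _check_band_coverage(grp: pd.DataFrame, name: str, sex: str) -> None:
    bands = sorted(zip(grp["age_lower"], grp["age_upper"]))
    if bands[0][0] > 75:
        raise ParameterValidationError(
            "age bands must start at or below 75", parameter=name, sex=sex
        )
    for (lo1, hi1), (lo2, _hi2) in zip(bands, bands[1:]):
        if lo2 != hi1 + 1:
            raise ParameterValidationError(
                f"age bands not contiguous around {hi1}/{lo2}",
                parameter=name, sex=sex, age_band=(lo1, hi1),
            )
    if bands[-1][1] < 100:
        raise ParameterValidationError(
            "age bands must cover up to 100", parameter=name, sex=sex
        )


# ---------------------------------------------------------------------------
# file I/O

def _resolve_dir(path: str | Path) -> tuple[Path, dict]:
    path = Path(path)
    if path.is_dir():
        settings_file = path / "settings.yaml"
    else:
        settings_file = path
        path = path.parent
    if not settings_file.exists():
        raise FileNotFoundError(settings_file)
    with open(settings_file) as fh:
        cfg = yaml.safe_load(fh) or {}
    return path, cfg


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter directory (or its ``settings.yaml``).

    The directory holds a YAML settings file plus the CSV tables it names
    (clinical probabilities, costs, intervention fee schedule).  Missing
    uncertainty ranges are auto-filled (±20% for probabilities, 40%/50% SD
    for treatment+care / intervention costs).  Raises
    :class:`ParameterValidationError` on any invariant violation, naming
    parameter, sex and age band.
    """
    root, cfg = _resolve_dir(path)
    tables = cfg.get("tables", {})
    read = lambda p: pd.read_csv(p, float_precision="round_trip")
    clinical = read(root / tables.get("clinical", "clinical.csv"))
    costs = read(root / tables.get("costs", "costs.csv"))
    interv = read(root / tables.get("intervention", "intervention_costs.csv"))
    effect = InterventionEffect(**cfg.get("effect", {}))
    settings_keys = {
        k: cfg[k]
        for k in (
            "sex", "entry_age", "horizon_years", "cycle_length_months",
            "discount_rate", "discount_outcomes", "half_cycle_correction",
            "use_late_first_fracture",
        )
        if k in cfg
    }
    settings = ModelSettings(**settings_keys)
    variant = cfg.get("variant")
    if variant is not None:
        variant = dict(variant)
        if "table" in variant:
            variant["table"] = str(root / variant["table"])
    return ParameterSet(
        clinical=clinical, costs=costs, intervention=interv,
        effect=effect, settings=settings, variant=variant,
    )


def write_parameters(params: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet back to the CSV/YAML schema (round-trippable)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    clinical = params.clinical.copy()
    costs = params.costs.copy()
    for frame in (clinical, costs):
        frame["age_upper"] = frame["age_upper"].replace(np.inf, np.nan)
    clinical.to_csv(root / "clinical.csv", index=False)
    costs.to_csv(root / "costs.csv", index=False)
    params.intervention.to_csv(root / "intervention_costs.csv", index=False)
    cfg = {
        "sex": params.settings.sex,
        "entry_age": params.settings.entry_age,
        "horizon_years": params.settings.horizon_years,
        "cycle_length_months": params.settings.cycle_length_months,
        "discount_rate": params.settings.discount_rate,
        "discount_outcomes": params.settings.discount_outcomes,
        "half_cycle_correction": params.settings.half_cycle_correction,
        "use_late_first_fracture": params.settings.use_late_first_fracture,
        "effect": {
            "rr": params.effect.rr,
            "rr_low": params.effect.rr_low,
            "rr_high": params.effect.rr_high,
            "participation_rate": params.effect.participation_rate,
            "annual_decay_fraction": params.effect.annual_decay_fraction,
            "effect_zero_after_years": params.effect.effect_zero_after_years,
        },
        "tables": {
            "clinical": "clinical.csv",
            "costs": "costs.csv",
            "intervention": "intervention_costs.csv",
        },
    }
    if params.variant is not None:
        cfg["variant"] = params.variant
    with open(root / "settings.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return root


def base_case() -> ParameterSet:
    """The bundled German base-case inputs (community-dwelling cohort, 75+)."""
    root = importlib.resources.files("fpecea") / "data" / "base_case"
    return load_parameters(Path(str(root)))


def lookup(params: ParameterSet, age: float, name: str, sex: str | None = None):
    """Return ``(value, low, high)`` of the age-band cell covering ``age``.

    Ages at or above the last band's lower edge map to that band (e.g. 99
    falls in 95+).  ``sex`` defaults to the configured model sex; raises if
    the age lies outside the modelled range [75, 100].
    """
    if not 75 <= age <= 100:
        raise ValueError(f"age {age} outside the modelled range [75, 100]")
    sex = sex or params.settings.sex
    if name in set(params.clinical["parameter"]):
        table = params.clinical_values(name, sex)
    else:
        table = params.cost_values(name, sex)
    for row in table.itertuples():
        if row.age_lower <= age <= row.age_upper:
            return float(row.value), float(row.low), float(row.high)
    raise ParameterValidationError(
        f"no age band covers age {age}", parameter=name, sex=sex
    )
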