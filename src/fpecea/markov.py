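"""Six-state Markov cohort engine for the fall-prevention exercise model.

A closed cohort of community-dwelling people enters the model at age 75 in
the WELL state and is tracked in 6-month cycles for 25 years (50 cycles).
States::

    WELL -> HIP_FRACTURE -> POST_FRACTURE -> (re-fracture back to acute)
                 |-> NURSING_HOME <-> NH_REFRACTURE
    every state -> DEAD (absorbing)

HIP_FRACTURE and NH_REFRACTURE are tunnel states: they are occupied for
exactly one cycle; a re-fracture in the acute window re-enters the tunnel
(a self-loop that counts as a new fracture event).  Admission to a nursing
home can only happen in the first cycle after a hip fracture and is
irreversible.

The exercise intervention multiplies the first-fracture probability by an
effective risk ratio that wanes with adherence (see
:func:`rr_effective`), and adds the program fees for WELL occupants during
the program years.

Transition-row composition (the published description leaves it open):
in the WELL row, fracture and death compete additively and the residual
stays WELL; in all post-fracture rows mortality is applied first and the
conditional splits (nursing-home admission, re-fracture) act on survivors,
so every row sums to one without renormalisation.

Internally everything is vectorised over ``R`` parameter draws: the same
engine serves the deterministic base case (R = 1) and the probabilistic
sensitivity analysis (R = 10,000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "ARMS",
    "StateSpace",
    "CohortTrace",
    "TransitionError",
    "rr_effective",
    "build_matrix",
    "build_matrices",
    "compile_arm",
    "run_cohort",
]

ARMS = ("fpe", "no-fpe")

BASE_STATES = ("WELL", "HIP_FRACTURE", "POST_FRACTURE", "NURSING_HOME",
               "NH_REFRACTURE", "DEAD")
VERT_STATES = ("WELL", "HIP_FRACTURE", "POST_FRACTURE", "NURSING_HOME",
               "NH_REFRACTURE", "VERT_FRACTURE", "VERT_POST", "DEAD")


class TransitionError(ValueError):
    """Competing transitions in one row exceed probability mass 1."""


@dataclass(frozen=True)
class StateSpace:
    """Ordered health states; DEAD is always last and absorbing."""

    names: tuple[str, ...] = BASE_STATES

    @classmethod
    def for_variant(cls, variant_id: str | None) -> "StateSpace":
        return cls(VERT_STATES) if variant_id == "II" else cls(BASE_STATES)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def has_vertebral(self) -> bool:
        return "VERT_FRACTURE" in self.names


def rr_effective(effect, multiplier: float | np.ndarray, rr: float | np.ndarray | None = None):
    """Effective risk ratio after participation dilution and effect decay.

    ``1 - participation * multiplier * (1 - rr)``: equals 1 when the
    residual-effect multiplier is 0 and equals the raw risk ratio at full
    participation and full effect.  ``rr`` overrides the point estimate
    (used for probabilistic draws).
    """
    multiplier = np.asarray(multiplier, dtype=float)
    if np.any(multiplier < 0) or np.any(multiplier > 1):
        raise ValueError("effect multiplier must lie in [0, 1]")
    rr = effect.rr if rr is None else rr
    return 1.0 - effect.participation_rate * multiplier * (1.0 - rr)


# ---------------------------------------------------------------------------
# compilation: ParameterSet -> per-cycle arrays

# clinical keys consumed by the engine (variant keys are optional)
ENGINE_PROBS = (
    "p_first_fracture", "p_refracture_acute", "p_refracture_late",
    "p_refracture_nh", "p_nh_admission", "p_mort_well",
    "p_mort_acute_fracture", "p_mort_post_fracture", "p_mort_nh",
    "p_mort_nh_refracture",
)
VARIANT1_PROBS = ("p_nh_other_well", "p_nh_other_post")
VARIANT2_PROBS = ("p_vert_fracture", "p_vert_refracture",
                  "p_mort_vert_acute", "p_mort_vert_post")
TREATMENT = ("hospital_care", "revision", "rehabilitation", "outpatient_care")


@dataclass
class CompiledArm:
    """Per-cycle parameter arrays for one arm; every array is (R, C)."""

    arm: str
    sex: str
    states: StateSpace
    n_cycles: int
    ages: np.ndarray                      # (C,) age at the start of each cycle
    p: dict[str, np.ndarray]              # transition probabilities
    rr_eff: np.ndarray                    # effective RR on first fractures
    cost_treat: np.ndarray                # € per hip fracture
    ltc_well: np.ndarray
    ltc_post: np.ndarray
    ltc_nh: np.ndarray
    cost_interv: np.ndarray               # € per WELL occupant per cycle
    discount: np.ndarray                  # (C,) end-of-cycle discount factors
    odiscount: np.ndarray = None          # (C,) factors applied to outcomes
    cost_vert: np.ndarray | None = None
    ltc_vert_post: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.rr_eff.shape[0]


def _band_series(table: pd.DataFrame, ages: np.ndarray,
                 draws: dict | None, key_prefix: str) -> np.ndarray:
    """Map a banded parameter table onto the cycle age grid -> (R, C)."""
    cols = []
    for age in ages:
        hit = None
        for i, row in enumerate(table.itertuples()):
            if row.age_lower <= int(age) <= row.age_upper:
                hit = i
                break
        if hit is None:
            raise ValueError(f"no age band covers age {age}")
        cols.append(hit)
    if draws is None:
        vals = table["value"].to_numpy(float)[None, :]      # (1, n_bands)
    else:
        vals = np.stack(
            [draws[f"{key_prefix}:{r.age_lower}"] for r in table.itertuples()],
            axis=1,
        )
    return vals[:, cols]


def compile_arm(params: ParameterSet, arm: str, sex: str | None = None,
                draws: dict | None = None) -> CompiledArm:
    """Gather all inputs of one arm onto the cycle grid.

    ``draws`` maps row keys (``"<parameter>:<sex>:<age_lower>"``,
    ``"interv:<sex>:<year>"``, ``"rr"``) to (R,) arrays of sampled values;
    ``None`` uses the point estimates (R = 1).
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    st = params.settings
    sex = sex or st.sex
    C = st.n_cycles
    ages = st.entry_age + st.cycle_years * np.arange(C)
    variant_id = (params.variant or {}).get("id")
    states = StateSpace.for_variant(variant_id)

    prob_keys = list(ENGINE_PROBS)
    if variant_id == "I":
        prob_keys += list(VARIANT1_PROBS)
    elif variant_id == "II":
        prob_keys += list(VARIANT2_PROBS)

    p = {}
    for name in prob_keys:
        src = name
        if name == "p_first_fracture" and st.use_late_first_fracture:
            src = "p_first_fracture_late"
        table = params.clinical_values(src, sex)
        sub = None if draws is None else {
            f"{src}:{r.age_lower}": draws[f"{src}:{sex}:{r.age_lower}"]
            for r in table.itertuples()
        }
        p[name] = _band_series(table, ages, sub, src)

    # effective risk ratio per cycle (FPE arm only)
    years = np.floor(np.arange(C) * st.cycle_years).astype(int)
    mult = np.array([params.effect.decay_multiplier(y) for y in years])
    if arm == "fpe":
        rr = params.effect.rr if draws is None else draws["rr"]
        rr_eff = rr_effective(params.effect, mult[None, :], np.asarray(rr).reshape(-1, 1))
    else:
        R = 1 if draws is None else len(np.atleast_1d(draws["rr"]))
        rr_eff = np.ones((R, C))

    # per-fracture treatment cost (sum of components; flat across ages)
    def flat_cost(name):
        row = params.cost_values(name, sex).iloc[0]
        if draws is None:
            return np.full((1, C), float(row["value"]))
        return np.repeat(draws[f"{name}:{row['sex']}:{int(row['age_lower'])}"][:, None], C, axis=1)

    cost_treat = sum(flat_cost(n) for n in TREATMENT)

    def banded_cost(name):
        table = params.cost_values(name, sex)
        sub = None if draws is None else {
            f"{name}:{r.age_lower}": draws[f"{name}:{r.sex}:{r.age_lower}"]
            for r in table.itertuples()
        }
        return _band_series(table, ages, sub, name)

    ltc_well = banded_cost("ltc_well")
    ltc_post = banded_cost("ltc_post_fracture")
    ltc_nh = flat_cost("ltc_nursing_home")

    # program fees: half the annual value per cycle, program years only
    sched = params.intervention_schedule(sex)
    if arm == "fpe":
        if draws is None:
            annual = sched[None, :]
        else:
            annual = np.stack(
                [draws[f"interv:{sex}:{y}"] for y in range(1, len(sched) + 1)], axis=1
            )
        per_cycle = np.zeros((annual.shape[0], C))
        in_range = years < annual.shape[1]
        per_cycle[:, in_range] = annual[:, years[in_range]] / st.cycles_per_year
        cost_interv = per_cycle
    else:
        cost_interv = np.zeros((rr_eff.shape[0], C))

    t_end = (np.arange(C) + 1) * st.cycle_years
    discount = (1.0 + st.discount_rate) ** (-t_end)
    odiscount = discount if st.discount_outcomes else np.ones(C)

    ca = CompiledArm(
        arm=arm, sex=sex, states=states, n_cycles=C, ages=ages, p=p,
        rr_eff=rr_eff, cost_treat=cost_treat, ltc_well=ltc_well,
        ltc_post=ltc_post, ltc_nh=ltc_nh, cost_interv=cost_interv,
        discount=discount, odiscount=odiscount,
    )
    if variant_id == "II":
        vtab = params.cost_values("vert_treatment_cost", sex)
        ca.cost_vert = _band_series(
            vtab, ages,
            None if draws is None else {
                f"vert_treatment_cost:{r.age_lower}":
                    draws[f"vert_treatment_cost:{r.sex}:{r.age_lower}"]
                for r in vtab.itertuples()
            },
            "vert_treatment_cost",
        )
        ltab = params.cost_values("ltc_vert_post", sex)
        ca.ltc_vert_post = _band_series(
            ltab, ages,
            None if draws is None else {
                f"ltc_vert_post:{r.age_lower}":
                    draws[f"ltc_vert_post:{r.sex}:{r.age_lower}"]
                for r in ltab.itertuples()
            },
            "ltc_vert_post",
        )
    return ca


# ---------------------------------------------------------------------------
# transition matrices

def _cycle_matrix(ca: CompiledArm, t: int) -> np.ndarray:
    """Row-stochastic transition matrix for cycle ``t`` -> (R, S, S)."""
    s = ca.states
    S = len(s)
    R = ca.n_draws
    W, H, P_, N, RE = (s.index(n) for n in BASE_STATES[:5])
    D = s.index("DEAD")
    g = {k: v[:, t] for k, v in ca.p.items()}
    M = np.zeros((R, S, S))

    # WELL: fracture and death compete additively; residual stays well
    f = g["p_first_fracture"] * ca.rr_eff[:, t]
    d = g["p_mort_well"]
    nho = g.get("p_nh_other_well", np.zeros(R))
    M[:, W, H] = f
    M[:, W, D] = d
    M[:, W, N] = nho
    if s.has_vertebral:
        V, VP = s.index("VERT_FRACTURE"), s.index("VERT_POST")
        vf = g["p_vert_fracture"] * ca.rr_eff[:, t]
        M[:, W, V] = vf
        rest = 1.0 - f - d - nho - vf
    else:
        rest = 1.0 - f - d - nho
    _check_mass(rest, "WELL", ca, t)
    M[:, W, W] = rest

    # acute hip fracture (tunnel): death first, survivors split
    d = g["p_mort_acute_fracture"]
    surv = 1.0 - d
    split = g["p_nh_admission"] + g["p_refracture_acute"]
    _check_mass(1.0 - split, "HIP_FRACTURE", ca, t)
    M[:, H, D] = d
    M[:, H, N] = surv * g["p_nh_admission"]
    M[:, H, H] = surv * g["p_refracture_acute"]
    M[:, H, P_] = surv * (1.0 - split)

    # post-fracture at home
    d = g["p_mort_post_fracture"]
    surv = 1.0 - d
    nho = g.get("p_nh_other_post", np.zeros(R))
    split = g["p_refracture_late"] + nho
    _check_mass(1.0 - split, "POST_FRACTURE", ca, t)
    M[:, P_, D] = d
    M[:, P_, H] = surv * g["p_refracture_late"]
    M[:, P_, N] = surv * nho
    M[:, P_, P_] = surv * (1.0 - split)

    # nursing home (irreversible)
    d = g["p_mort_nh"]
    M[:, N, D] = d
    M[:, N, RE] = (1.0 - d) * g["p_refracture_nh"]
    M[:, N, N] = (1.0 - d) * (1.0 - g["p_refracture_nh"])

    # re-fracture in nursing home (tunnel)
    d = g["p_mort_nh_refracture"]
    M[:, RE, D] = d
    M[:, RE, N] = 1.0 - d

    if s.has_vertebral:
        d = g["p_mort_vert_acute"]
        M[:, V, D] = d
        M[:, V, VP] = 1.0 - d
        d = g["p_mort_vert_post"]
        surv = 1.0 - d
        hip = g["p_first_fracture"] * ca.rr_eff[:, t]
        split = hip + g["p_vert_refracture"]
        _check_mass(1.0 - split, "VERT_POST", ca, t)
        M[:, VP, D] = d
        M[:, VP, H] = surv * hip
        M[:, VP, V] = surv * g["p_vert_refracture"]
        M[:, VP, VP] = surv * (1.0 - split)

    M[:, D, D] = 1.0
    return M


def _check_mass(residual: np.ndarray, state: str, ca: CompiledArm, t: int) -> None:
    if np.any(residual < -1e-12):
        raise TransitionError(
            f"competing transitions out of {state} exceed probability 1 "
            f"(cycle {t}, age {ca.ages[t]:.1f}, sex {ca.sex}, arm {ca.arm})"
        )


def build_matrix(params: ParameterSet, age: float, cycle: int, arm: str,
                 effect_multiplier: float | None = None,
                 sex: str | None = None) -> np.ndarray:
    """One cycle's transition matrix at a given age (deterministic inputs).

    ``effect_multiplier`` overrides the adherence-decay clock; by default it
    follows the program-year schedule implied by ``cycle``.
    """
    from .parameters import lookup as _lookup

    st = params.settings
    sex = sex or st.sex
    variant_id = (params.variant or {}).get("id")
    states = StateSpace.for_variant(variant_id)
    prob_keys = list(ENGINE_PROBS)
    if variant_id == "I":
        prob_keys += list(VARIANT1_PROBS)
    elif variant_id == "II":
        prob_keys += list(VARIANT2_PROBS)
    p = {}
    for name in prob_keys:
        src = name
        if name == "p_first_fracture" and st.use_late_first_fracture:
            src = "p_first_fracture_late"
        p[name] = np.array([[_lookup(params, age, src, sex)[0]]])
    if effect_multiplier is None:
        year = int(np.floor(cycle * st.cycle_years))
        effect_multiplier = params.effect.decay_multiplier(year)
    rr = (rr_effective(params.effect, effect_multiplier)
          if arm == "fpe" else 1.0)
    zeros = np.zeros((1, 1))
    ca = CompiledArm(
        arm=arm, sex=sex, states=states, n_cycles=1,
        ages=np.array([age]), p=p, rr_eff=np.array([[rr]]),
        cost_treat=zeros, ltc_well=zeros, ltc_post=zeros, ltc_nh=zeros,
        cost_interv=zeros, discount=np.ones(1),
        cost_vert=zeros if variant_id == "II" else None,
        ltc_vert_post=zeros if variant_id == "II" else None,
    )
    return _cycle_matrix(ca, 0)[0]


def build_matrices(ca: CompiledArm) -> np.ndarray:
    """All per-cycle matrices of a compiled arm, shape (C, R, S, S)."""
    return np.stack([_cycle_matrix(ca, t) for t in range(ca.n_cycles)])


# ---------------------------------------------------------------------------
# cohort trace

@dataclass
class CohortTrace:
    """State occupancy and accumulated costs/outcomes of one arm.

    Occupancy row 0 is the entry distribution (everyone WELL); row ``t`` is
    the distribution after cycle ``t``.  Costs accrue on entry into the
    cycle's destination state (no half-cycle correction by default):
    long-term care by state occupied, treatment per incident fracture,
    program fees per WELL occupant during the program years.  Per-cycle
    cost and event series are present values (both are discounted when the
    settings say so); occupancy itself is never discounted.
    """

    arm: str
    sex: str
    states: StateSpace
    ages: np.ndarray
    occupancy: np.ndarray                 # (C+1, S)
    cost_intervention_by_cycle: np.ndarray
    cost_treatment_by_cycle: np.ndarray
    cost_ltc_by_cycle: np.ndarray
    first_fractures_by_cycle: np.ndarray
    refractures_by_cycle: np.ndarray
    nh_admissions_by_cycle: np.ndarray
    cost_vert_by_cycle: np.ndarray | None = None
    vert_fractures_by_cycle: np.ndarray | None = None
    nh_admissions_other_by_cycle: np.ndarray | None = None

    # -- totals -------------------------------------------------------

    @property
    def cost_intervention(self) -> float:
        return float(self.cost_intervention_by_cycle.sum())

    @property
    def cost_treatment(self) -> float:
        return float(self.cost_treatment_by_cycle.sum())

    @property
    def cost_ltc(self) -> float:
        return float(self.cost_ltc_by_cycle.sum())

    @property
    def cost_vertebral(self) -> float:
        if self.cost_vert_by_cycle is None:
            return 0.0
        return float(self.cost_vert_by_cycle.sum())

    @property
    def cum_cost(self) -> float:
        return (self.cost_intervention + self.cost_treatment
                + self.cost_ltc + self.cost_vertebral)

    @property
    def cum_first_fractures(self) -> float:
        return float(self.first_fractures_by_cycle.sum())

    @property
    def cum_refractures(self) -> float:
        return float(self.refractures_by_cycle.sum())

    @property
    def cum_hip_fractures(self) -> float:
        return self.cum_first_fractures + self.cum_refractures

    @property
    def cum_vert_fractures(self) -> float:
        if self.vert_fractures_by_cycle is None:
            return 0.0
        return float(self.vert_fractures_by_cycle.sum())

    @property
    def cum_fractures_combined(self) -> float:
        return self.cum_hip_fractures + self.cum_vert_fractures

    @property
    def cum_nh_admissions(self) -> float:
        return float(self.nh_admissions_by_cycle.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (cycle, age, occupancies, costs, events)."""
        C = len(self.first_fractures_by_cycle)
        ages_end = np.concatenate([[self.ages[0]], self.ages + 0.5])
        occ = pd.DataFrame(self.occupancy, columns=list(self.states.names))
        occ.insert(0, "cycle", np.arange(C + 1))
        occ.insert(1, "age", ages_end[: C + 1])
        ev = pd.DataFrame({
            "cycle": np.arange(1, C + 1),
            "cost_intervention": self.cost_intervention_by_cycle,
            "cost_treatment": self.cost_treatment_by_cycle,
            "cost_ltc": self.cost_ltc_by_cycle,
            "first_fractures": self.first_fractures_by_cycle,
            "refractures": self.refractures_by_cycle,
            "nh_admissions": self.nh_admissions_by_cycle,
        })
        return occ.merge(ev, on="cycle", how="left").fillna(0.0)


@dataclass
class VectorResult:
    """Totals over R draws; the PSA consumes this directly."""

    total_cost: np.ndarray
    cost_intervention: np.ndarray
    cost_treatment: np.ndarray
    cost_ltc: np.ndarray
    cost_vert: np.ndarray
    hip_fractures: np.ndarray
    refractures: np.ndarray
    vert_fractures: np.ndarray
    nh_admissions: np.ndarray


def _simulate(ca: CompiledArm, keep_trace: bool = False):
    """Run the cohort recursion for all draws of a compiled arm."""
    s = ca.states
    S, R, C = len(s), ca.n_draws, ca.n_cycles
    W, H, P_, N, RE = (s.index(n) for n in BASE_STATES[:5])
    has_v = s.has_vertebral
    if has_v:
        V, VP = s.index("VERT_FRACTURE"), s.index("VERT_POST")

    occ = np.zeros((R, S))
    occ[:, W] = 1.0
    per_cycle = {k: np.zeros((R, C)) for k in (
        "interv", "treat", "ltc", "vert", "first", "re", "vfx", "nh", "nh_other")}
    trace_occ = np.zeros((C + 1, S)) if keep_trace else None
    if keep_trace:
        trace_occ[0] = occ[0]

    for t in range(C):
        M = _cycle_matrix(ca, t)
        flow = occ[:, :, None] * M
        new = flow.sum(axis=1)
        df = ca.discount[t]
        od = ca.odiscount[t]

        first = flow[:, W, H]
        re = flow[:, H, H] + flow[:, P_, H] + flow[:, N, RE]
        if has_v:
            first = first + flow[:, VP, H]
            vfx = flow[:, W, V] + flow[:, VP, V]
            per_cycle["vfx"][:, t] = vfx * od
            per_cycle["vert"][:, t] = vfx * ca.cost_vert[:, t] * df
        per_cycle["first"][:, t] = first * od
        per_cycle["re"][:, t] = re * od
        per_cycle["nh"][:, t] = flow[:, H, N] * od
        per_cycle["nh_other"][:, t] = (flow[:, W, N] + flow[:, P_, N]) * od

        per_cycle["treat"][:, t] = (first + re) * ca.cost_treat[:, t] * df
        ltc = (new[:, W] * ca.ltc_well[:, t]
               + (new[:, H] + new[:, P_]) * ca.ltc_post[:, t]
               + (new[:, N] + new[:, RE]) * ca.ltc_nh[:, t])
        if has_v:
            ltc = ltc + (new[:, V] + new[:, VP]) * ca.ltc_vert_post[:, t]
        per_cycle["ltc"][:, t] = ltc * df
        per_cycle["interv"][:, t] = new[:, W] * ca.cost_interv[:, t] * df

        occ = new
        if keep_trace:
            trace_occ[t + 1] = occ[0]

    result = VectorResult(
        total_cost=(per_cycle["interv"] + per_cycle["treat"]
                    + per_cycle["ltc"] + per_cycle["vert"]).sum(axis=1),
        cost_intervention=per_cycle["interv"].sum(axis=1),
        cost_treatment=per_cycle["treat"].sum(axis=1),
        cost_ltc=per_cycle["ltc"].sum(axis=1),
        cost_vert=per_cycle["vert"].sum(axis=1),
        hip_fractures=(per_cycle["first"] + per_cycle["re"]).sum(axis=1),
        refractures=per_cycle["re"].sum(axis=1),
        vert_fractures=per_cycle["vfx"].sum(axis=1),
        nh_admissions=per_cycle["nh"].sum(axis=1),
    )
    return result, per_cycle, trace_occ


def run_cohort(params: ParameterSet, arm: str, sex: str | None = None) -> CohortTrace:
    """Run the deterministic cohort trace for one arm.

    Returns a :class:`CohortTrace` with per-cycle occupancy (sums to 1 each
    cycle; DEAD non-decreasing), decomposed costs and the expected
    first-/re-fracture and nursing-home-admission counts per person.
    """
    ca = compile_arm(params, arm, sex=sex)
    _result, per_cycle, trace_occ = _simulate(ca, keep_trace=True)
    sq = {k: v[0] for k, v in per_cycle.items()}
    return CohortTrace(
        arm=arm, sex=ca.sex, states=ca.states, ages=ca.ages,
        occupancy=trace_occ,
        cost_intervention_by_cycle=sq["interv"],
        cost_treatment_by_cycle=sq["treat"],
        cost_ltc_by_cycle=sq["ltc"],
        first_fractures_by_cycle=sq["first"],
        refractures_by_cycle=sq["re"],
        nh_admissions_by_cycle=sq["nh"],
        cost_vert_by_cycle=sq["vert"] if ca.states.has_vertebral else None,
        vert_fractures_by_cycle=sq["vfx"] if ca.states.has_vertebral else None,
        nh_admissions_other_by_cycle=sq["nh_other"],
    )
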