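"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-runs the model with one parameter group at its stored
bounds (tornado diagram); best-/worst-case scenarios combine the favourable
or unfavourable bounds of intervention cost, treatment and post-fracture
care costs and the effect estimate.  The probabilistic analysis draws every
parameter from its assigned distribution — beta for probabilities (method
of moments from the point estimate and its range), gamma for costs (mean =
point estimate, SD 40%, intervention fees 50%) and lognormal for the risk
ratio (fitted to its 95% CI) — and summarises the Monte Carlo sample as a
cost-effectiveness acceptability curve over willingness-to-pay values.

Treatment and nursing-home costs are drawn once per iteration (they do not
vary by age); age-banded care costs and the per-year intervention fees get
independent draws per band/year, mirroring how the deterministic inputs are
structured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEAResult, run_cea
from .markov import _simulate, compile_arm
from .parameters import (
    PROBABILITY_PARAMS,
    COST_PARAMS,
    ParameterSet,
)

__all__ = [
    "OneWayResult",
    "PSAResult",
    "SA_PARAMETER_GROUPS",
    "one_way",
    "tornado",
    "scenario",
    "run_psa",
    "ceac",
    "draw_beta",
    "draw_gamma",
    "draw_lognormal_rr",
]

#: Parameter groups available to the one-way analysis: each group moves all
#: of its age-band cells to their bounds simultaneously.
SA_PARAMETER_GROUPS = (
    ("rr",) + ("intervention_cost",) + tuple(COST_PARAMS)
    + tuple(p for p in PROBABILITY_PARAMS if p != "p_first_fracture_late")
)

CI_WIDTH_SD = 3.92  # 2 x 1.96: a 95% interval spans ±1.96 SD


# ---------------------------------------------------------------------------
# distribution draws

def draw_beta(rng, value, low, high, size, scale=1.0):
    """Beta draw matched by moments to the point estimate and its range.

    The SD is taken as (high − low)/3.92.  When the implied variance is not
    attainable by a beta distribution the draw falls back to a uniform on
    ±20% around the point estimate (with a warning), as the published
    uncertainty assumption prescribes.
    """
    m = float(value)
    sd = (float(high) - float(low)) / CI_WIDTH_SD * scale
    if sd <= 0 or m <= 0 or m >= 1:
        return np.full(size, m)
    var = sd * sd
    if var >= m * (1 - m):
        warnings.warn(
            f"beta distribution not fittable for mean {m}, sd {sd}; "
            "falling back to a ±20% uniform range",
            stacklevel=2,
        )
        lo, hi = np.clip([0.8 * m, 1.2 * m], 0.0, 1.0)
        return rng.uniform(lo, hi, size)
    nu = m * (1 - m) / var - 1.0
    return rng.beta(m * nu, (1 - m) * nu, size)


def draw_gamma(rng, mean, sd, size, scale=1.0):
    """Gamma draw with the given mean and SD (degenerate when either is 0)."""
    m, s = float(mean), float(sd) * scale
    if s <= 0 or m <= 0:
        return np.full(size, m)
    shape = (m / s) ** 2
    return rng.gamma(shape, s * s / m, size)


def draw_lognormal_rr(rng, effect, size, scale=1.0):
    """Lognormal risk-ratio draw fitted to the 95% CI."""
    sigma = (np.log(effect.rr_high) - np.log(effect.rr_low)) / CI_WIDTH_SD * scale
    if sigma <= 0:
        return np.full(size, effect.rr)
    return rng.lognormal(np.log(effect.rr), sigma, size)


def draw_parameters(params: ParameterSet, sex: str, n: int,
                    rng: np.random.Generator, scale: float = 1.0) -> dict:
    """Draw all inputs used by one sex's model run.

    Returns the draw dictionary consumed by
    :func:`fpecea.markov.compile_arm`: clinical cells (beta, independent per
    parameter and age band), cost cells (gamma; flat cells shared across
    ages by construction), intervention fees (gamma, per program year) and
    the risk ratio (lognormal).  Iteration order is fixed by the parameter
    tables, so a seeded generator reproduces draws bit for bit.
    """
    draws = {}
    clin = params.clinical[params.clinical["sex"] == sex]
    for row in clin.itertuples():
        draws[f"{row.parameter}:{sex}:{int(row.age_lower)}"] = draw_beta(
            rng, row.value, row.low, row.high, n, scale
        )
    costs = params.costs[params.costs["sex"].isin([sex, "all"])]
    for row in costs.itertuples():
        key = f"{row.parameter}:{row.sex}:{int(row.age_lower)}"
        if key not in draws:  # sex == 'all' rows appear once
            draws[key] = draw_gamma(rng, row.value, row.sd, n, scale)
    interv = params.intervention[params.intervention["sex"] == sex]
    for row in interv.itertuples():
        draws[f"interv:{sex}:{int(row.program_year)}"] = draw_gamma(
            rng, row.value, row.sd, n, scale
        )
    draws["rr"] = draw_lognormal_rr(rng, params.effect, n, scale)
    return draws


# ---------------------------------------------------------------------------
# one-way deterministic analysis

@dataclass(frozen=True)
class OneWayResult:
    """ICERs with one parameter group at its lower/upper bound."""

    parameter: str
    sex: str
    low_result: CEAResult
    high_result: CEAResult

    @property
    def icer_low(self) -> float:
        return self.low_result.icer_value

    @property
    def icer_high(self) -> float:
        return self.high_result.icer_value

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _at_bound(params: ParameterSet, parameter: str, sex: str, bound: str) -> ParameterSet:
    """Copy of ``params`` with one parameter group moved to a bound."""
    ps = params.copy()
    if parameter == "rr":
        value = ps.effect.rr_low if bound == "low" else ps.effect.rr_high
        return ps.with_effect(rr=value, rr_low=min(value, ps.effect.rr_low),
                              rr_high=max(value, ps.effect.rr_high))
    if parameter == "intervention_cost":
        mask = ps.intervention["sex"] == sex
        ps.intervention.loc[mask, "value"] = ps.intervention.loc[mask, bound]
        ps.validate()
        return ps
    if parameter in set(ps.clinical["parameter"]):
        mask = (ps.clinical["parameter"] == parameter) & (ps.clinical["sex"] == sex)
        ps.clinical.loc[mask, "value"] = ps.clinical.loc[mask, bound]
        ps.validate()
        return ps
    if parameter in set(ps.costs["parameter"]):
        mask = (ps.costs["parameter"] == parameter) & (
            ps.costs["sex"].isin([sex, "all"])
        )
        ps.costs.loc[mask, "value"] = ps.costs.loc[mask, bound]
        ps.validate()
        return ps
    raise KeyError(f"unknown sensitivity parameter {parameter!r}")


def one_way(params: ParameterSet, parameter: str,
            sex: str | None = None) -> OneWayResult:
    """Re-run the model with one parameter group at each of its bounds."""
    sex = sex or params.settings.sex
    return OneWayResult(
        parameter=parameter,
        sex=sex,
        low_result=run_cea(_at_bound(params, parameter, sex, "low"), sex=sex),
        high_result=run_cea(_at_bound(params, parameter, sex, "high"), sex=sex),
    )


def tornado(params: ParameterSet, sex: str | None = None,
            parameters: tuple[str, ...] = SA_PARAMETER_GROUPS) -> pd.DataFrame:
    """One-way results for every parameter group, sorted by ICER spread."""
    sex = sex or params.settings.sex
    base = run_cea(params, sex=sex)
    rows = []
    for pid in parameters:
        res = one_way(params, pid, sex=sex)
        rows.append({
            "parameter": pid,
            "icer_low": res.icer_low,
            "icer_high": res.icer_high,
            "spread": res.spread,
        })
    frame = pd.DataFrame(rows).sort_values("spread", ascending=False)
    frame.insert(1, "icer_base", base.icer_value)
    return frame.reset_index(drop=True)


def scenario(params: ParameterSet, kind: str, sex: str | None = None) -> CEAResult:
    """Best- or worst-case scenario.

    Best case: lowest intervention fees, highest treatment and
    post-fracture/nursing care costs, risk ratio at the lower CI bound.
    Worst case is the mirror image.
    """
    if kind not in ("best", "worst"):
        raise ValueError("kind must be 'best' or 'worst'")
    sex = sex or params.settings.sex
    interv_bound = "low" if kind == "best" else "high"
    care_bound = "high" if kind == "best" else "low"
    rr = params.effect.rr_low if kind == "best" else params.effect.rr_high
    ps = _at_bound(params, "intervention_cost", sex, interv_bound)
    for name in ("hospital_care", "revision", "rehabilitation",
                 "outpatient_care", "ltc_post_fracture", "ltc_nursing_home"):
        ps = _at_bound(ps, name, sex, care_bound)
    ps = ps.with_effect(rr=rr, rr_low=min(rr, ps.effect.rr_low),
                        rr_high=max(rr, ps.effect.rr_high))
    return run_cea(ps, sex=sex)


# ---------------------------------------------------------------------------
# probabilistic analysis

@dataclass
class PSAResult:
    """Monte Carlo sample of incremental results.

    ``samples`` has one row per iteration: per-arm totals, Δcost,
    fractures averted (positive = the intervention prevents fractures) and
    Δ nursing-home admissions.
    """

    sex: str
    seed: int
    samples: pd.DataFrame

    @property
    def n_iter(self) -> int:
        return len(self.samples)

    def prob_cost_effective(self, wtp: float) -> float:
        """Fraction of iterations with positive net monetary benefit.

        NMB = WTP × fractures averted − Δcost; a tie at exactly 0 counts as
        not cost-effective.
        """
        nmb = wtp * self.samples["averted"] - self.samples["d_cost"]
        return float((nmb > 0).mean())


def _is_cost_key(key: str) -> bool:
    name = key.split(":")[0]
    return (key.startswith("interv:") or name in COST_PARAMS
            or name in ("vert_treatment_cost", "ltc_vert_post"))


def run_psa(params: ParameterSet, n_iter: int, seed: int,
            sex: str | None = None, scale: float = 1.0,
            cost_draws: str = "per-arm") -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty (default 10,000 runs).

    Each iteration draws one parameter set, runs both arms on it and
    records the increments.  Transition probabilities and the risk ratio
    are drawn once per iteration and shared by both arms; cost parameters
    are assigned per strategy branch (``cost_draws="per-arm"``), so cost
    uncertainty does not cancel in the increments — the incremental cost
    distribution is then dominated by the care-cost dispersion, which is
    what gives the acceptability curve its characteristic near-50% start
    and shallow rise.  Set ``cost_draws="shared"`` for fully common draws.
    All iterations are propagated through the cohort engine in one
    vectorised pass; results are deterministic for a given seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if cost_draws not in ("per-arm", "shared"):
        raise ValueError("cost_draws must be 'per-arm' or 'shared'")
    sex = sex or params.settings.sex
    rng = np.random.default_rng(seed)
    draws = draw_parameters(params, sex, n_iter, rng, scale)
    if cost_draws == "per-arm":
        redraw = draw_parameters(params, sex, n_iter, rng, scale)
        draws_ref = {k: (redraw[k] if _is_cost_key(k) else v)
                     for k, v in draws.items()}
    else:
        draws_ref = draws
    res_fpe, _, _ = _simulate(compile_arm(params, "fpe", sex=sex, draws=draws))
    res_ref, _, _ = _simulate(compile_arm(params, "no-fpe", sex=sex, draws=draws_ref))
    effect_combined = (params.variant or {}).get("id") == "II"
    fx_fpe = res_fpe.hip_fractures + (res_fpe.vert_fractures if effect_combined else 0)
    fx_ref = res_ref.hip_fractures + (res_ref.vert_fractures if effect_combined else 0)
    samples = pd.DataFrame({
        "iteration": np.arange(n_iter),
        "rr": np.atleast_1d(draws["rr"]),
        "cost_fpe": res_fpe.total_cost,
        "cost_ref": res_ref.total_cost,
        "fractures_fpe": fx_fpe,
        "fractures_ref": fx_ref,
        "d_cost": res_fpe.total_cost - res_ref.total_cost,
        "averted": fx_ref - fx_fpe,
        "d_nh_admissions": res_fpe.nh_admissions - res_ref.nh_admissions,
    })
    return PSAResult(sex=sex, seed=seed, samples=samples)


DEFAULT_WTP_GRID = np.arange(0, 500_001, 10_000, dtype=float)


def ceac(psa: PSAResult, wtp_grid: np.ndarray = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from a PSA sample.

    At each willingness-to-pay λ the curve gives the fraction of iterations
    whose net monetary benefit λ·(fractures averted) − Δcost is positive.
    """
    if psa.n_iter < 1:
        raise ValueError("need at least one PSA sample")
    averted = psa.samples["averted"].to_numpy()
    d_cost = psa.samples["d_cost"].to_numpy()
    probs = [(wtp * averted - d_cost > 0).mean() for wtp in np.asarray(wtp_grid)]
    return pd.DataFrame({"wtp": np.asarray(wtp_grid, float),
                         "prob_cost_effective": probs})
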