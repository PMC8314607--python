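"""Synthetic inputs and an independent microsimulation oracle.

Two jobs live here.  :func:`generate_parameter_set` draws a complete,
valid parameter set around the bundled base case using the same
distributional assumptions as the probabilistic sensitivity analysis
(beta / gamma / lognormal), with an overall perturbation scale — scale 0
returns the base case exactly.  :func:`microsimulate` is a brute-force
individual-level simulation that pushes sampled individuals through the
same per-cycle transition matrices and accrues the same costs and events
as the cohort engine; its sample means converge to the cohort trace's
expectations, which is the package's central cross-validation property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import BASE_STATES, _cycle_matrix, compile_arm
from .parameters import ParameterSet, base_case
from .sensitivity import draw_parameters

__all__ = ["MicrosimResult", "generate_parameter_set", "microsimulate"]


def generate_parameter_set(seed: int, scale: float = 1.0,
                           params: ParameterSet | None = None) -> ParameterSet:
    """Draw a random but valid parameter set around the base case.

    All probability cells are drawn from their beta distributions, cost
    cells from gamma and the risk ratio from its lognormal, each with the
    dispersion multiplied by ``scale``; uncertainty ranges are re-derived
    around the drawn values.  Deterministic for a given seed.
    """
    if scale < 0:
        raise ValueError("perturbation scale must be >= 0")
    params = params or base_case()
    rng = np.random.default_rng(seed)
    ps = params.copy()
    if scale == 0:
        return ps

    for sex in ("women", "men"):
        draws = draw_parameters(params, sex, 1, rng, scale)
        mask = ps.clinical["sex"] == sex
        ps.clinical.loc[mask, "value"] = [
            float(draws[f"{r.parameter}:{sex}:{int(r.age_lower)}"][0])
            for r in ps.clinical[mask].itertuples()
        ]
        cmask = ps.costs["sex"] == sex
        ps.costs.loc[cmask, "value"] = [
            float(draws[f"{r.parameter}:{sex}:{int(r.age_lower)}"][0])
            for r in ps.costs[cmask].itertuples()
        ]
        if sex == "women":  # sex-independent cost cells: one draw
            amask = ps.costs["sex"] == "all"
            ps.costs.loc[amask, "value"] = [
                float(draws[f"{r.parameter}:all:{int(r.age_lower)}"][0])
                for r in ps.costs[amask].itertuples()
            ]
            rr = float(np.clip(draws["rr"][0], 1e-6, 1.0))
        imask = ps.intervention["sex"] == sex
        ps.intervention.loc[imask, "value"] = [
            float(draws[f"interv:{sex}:{int(r.program_year)}"][0])
            for r in ps.intervention[imask].itertuples()
        ]

    # clear ranges/SDs so they are re-derived around the drawn values
    for frame in (ps.clinical, ps.costs, ps.intervention):
        frame["low"] = np.nan
        frame["high"] = np.nan
        if "sd" in frame.columns:
            frame["sd"] = np.nan
    out = ParameterSet(
        clinical=ps.clinical, costs=ps.costs, intervention=ps.intervention,
        effect=ps.effect, settings=ps.settings, variant=ps.variant,
    )
    return out.with_effect(rr=rr, rr_low=min(out.effect.rr_low, rr),
                           rr_high=max(out.effect.rr_high, rr))


@dataclass(frozen=True)
class MicrosimResult:
    """Per-person means and standard errors from the microsimulation."""

    n_individuals: int
    mean_cost: float
    se_cost: float
    mean_hip_fractures: float
    se_hip_fractures: float
    mean_nh_admissions: float
    se_nh_admissions: float
    mean_vert_fractures: float = 0.0
    se_vert_fractures: float = 0.0


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(x.mean()), se


def microsimulate(params: ParameterSet, arm: str, n_individuals: int,
                  seed: int, sex: str | None = None) -> MicrosimResult:
    """Simulate individuals through the model's transition matrices.

    Each individual follows a categorical draw per cycle from the same
    matrices the cohort engine uses, accruing identical costs and events:
    long-term care by the state entered, treatment per fracture event
    (acute re-fractures included), program fees while WELL in the
    intervention arm.  Individual ``i`` consumes row ``i`` of a uniform
    random matrix derived from the master seed, so results do not depend
    on iteration order.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    ca = compile_arm(params, arm, sex=sex)
    s = ca.states
    C, n = ca.n_cycles, int(n_individuals)
    W, H, P_, N, RE = (s.index(x) for x in BASE_STATES[:5])
    has_v = s.has_vertebral
    if has_v:
        V, VP = s.index("VERT_FRACTURE"), s.index("VERT_POST")

    # per-state LTC vector per cycle
    ltc = np.zeros((C, len(s)))
    ltc[:, W] = ca.ltc_well[0]
    ltc[:, H] = ltc[:, P_] = ca.ltc_post[0]
    ltc[:, N] = ltc[:, RE] = ca.ltc_nh[0]
    if has_v:
        ltc[:, V] = ltc[:, VP] = ca.ltc_vert_post[0]

    rng = np.random.default_rng(seed)
    uniforms = rng.random((n, C))
    state = np.full(n, W, dtype=np.int64)
    cost = np.zeros(n)
    hip_fx = np.zeros(n)
    vert_fx = np.zeros(n)
    nh_adm = np.zeros(n)

    for t in range(C):
        M = _cycle_matrix(ca, t)[0]
        cum = np.cumsum(M, axis=1)
        cum[:, -1] = 1.0  # guard against float round-off in the last bin
        new = (uniforms[:, t][:, None] > cum[state]).sum(axis=1)
        df = ca.discount[t]

        od = ca.odiscount[t]
        fracture = ((state == W) & (new == H)) | ((state == P_) & (new == H)) \
            | ((state == H) & (new == H)) | ((state == N) & (new == RE))
        if has_v:
            fracture |= (state == VP) & (new == H)
            vert = ((state == W) & (new == V)) | ((state == VP) & (new == V))
            vert_fx += vert * od
            cost += vert * ca.cost_vert[0, t] * df
        hip_fx += fracture * od
        nh_adm += ((state == H) & (new == N)) * od
        cost += fracture * ca.cost_treat[0, t] * df
        cost += ltc[t, new] * df
        cost += (new == W) * ca.cost_interv[0, t] * df
        state = new

    mc, sc = _mean_se(cost)
    mf, sf = _mean_se(hip_fx)
    ma, sa = _mean_se(nh_adm)
    mv, sv = _mean_se(vert_fx)
    return MicrosimResult(
        n_individuals=n,
        mean_cost=mc, se_cost=sc,
        mean_hip_fractures=mf, se_hip_fractures=sf,
        mean_nh_admissions=ma, se_nh_admissions=sa,
        mean_vert_fractures=mv, se_vert_fractures=sv,
    )
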