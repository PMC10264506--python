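"""Six-state endometrial-cancer / cardiovascular-disease cohort model.

Women who completed curative-intent treatment for early-stage endometrial
cancer start in ``NO_CVD`` and face three competing annual exits: a first
cardiovascular event (split between stroke, coronary heart disease and heart
failure, each with a within-cycle case fatality), cancer recurrence, and
background (all-cause) mortality from the life table.  Survivors of an event
move to the matching post-event state and remain there — the states are
mutually exclusive, so post-event states see no further recurrence or CVD
risk, only disease-specific plus background mortality.  Death is absorbing.

A supervised 12-week exercise program is modelled as hazard ratios on the
CVD-event and recurrence rates (sustained over the whole horizon) plus a
one-off intervention cost in the first cycle; standard care has neither.

Competing risks within a cycle are combined multiplicatively on the survival
scale (independent constant rates) with exits allocated proportionally to
their rates — order-independent by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .conversions import (
    combine_mortality,
    prob_to_rate,
    survival_to_annual_death_prob,
)
from .markov import CycleRewards, StateSpace, accrue_outcomes, build_trace
from .synth import AgeUtilityTable, LifeTable

__all__ = [
    "HealthState",
    "EC_STATES",
    "StrategyArm",
    "EXERCISE",
    "STANDARD_CARE",
    "annualize_baseline_risks",
    "build_transition_matrix",
    "build_rewards",
    "run_arm",
]

#: Follow-up length (years) of the cohort study behind the cumulative
#: baseline CVD (0.158) and recurrence (0.240) probabilities.
BASELINE_FOLLOWUP_YEARS = 14.0

#: Horizon (years) of the published post-event and post-recurrence survival
#: fractions.
POST_EVENT_SURVIVAL_YEARS = 5.0


class HealthState(enum.IntEnum):
    NO_CVD = 0
    POST_STROKE = 1
    POST_CHD = 2
    POST_HF = 3
    POST_RECURRENCE = 4
    DEAD = 5


EC_STATES = StateSpace(
    states=("no_cvd", "post_stroke", "post_chd", "post_hf", "post_recurrence", "dead"),
    absorbing="dead",
)

_EVENTS = (  # (share param, fatality key, post state, treatment cost, follow-up cost, event disutility, post utility)
    ("share_stroke", "p_fatal_stroke", HealthState.POST_STROKE,
     "c_stroke_treatment", "c_post_stroke_fu", "du_stroke_event", "u_post_stroke"),
    ("share_chd", "p_fatal_chd_hf", HealthState.POST_CHD,
     "c_chd_treatment", "c_post_chd_fu", "du_chd_event", "u_post_chd"),
    ("share_hf", "p_fatal_chd_hf", HealthState.POST_HF,
     "c_hf_treatment", "c_post_hf_fu", "du_hf_event", "u_post_hf"),
)


@dataclass(frozen=True)
class StrategyArm:
    """One comparator arm of the evaluation.

    ``apply_hazard_ratios`` switches the exercise effect (the drawn CVD and
    recurrence hazard ratios) on; standard care keeps both at 1.
    ``intervention_cost_param`` names the first-cycle program cost parameter;
    ``extra_first_cycle_cost`` carries scenario add-ons (e.g. extended
    supervision) in AUD, also first cycle only.
    """

    label: str
    apply_hazard_ratios: bool = False
    intervention_cost_param: str | None = None
    extra_first_cycle_cost: float = 0.0

    def hr_cvd(self, draw):
        return draw["hr_cvd_exercise"] if self.apply_hazard_ratios else 1.0

    def hr_recurrence(self, draw):
        return draw["hr_recurrence_exercise"] if self.apply_hazard_ratios else 1.0

    def first_cycle_cost(self, draw):
        c = self.extra_first_cycle_cost
        if self.intervention_cost_param is not None:
            c = c + draw[self.intervention_cost_param]
        return c

    def with_extra_cost(self, extra: float) -> "StrategyArm":
        return replace(self, extra_first_cycle_cost=self.extra_first_cycle_cost + extra)


EXERCISE = StrategyArm("exercise", apply_hazard_ratios=True, intervention_cost_param="c_exercise")
STANDARD_CARE = StrategyArm("standard_care")


def _get(draw, key):
    try:
        return np.asarray(draw[key], dtype=float)
    except KeyError:
        raise KeyError(f"parameter draw is missing {key!r}") from None


def annualize_baseline_risks(draw) -> dict:
    """Convert the published cumulative/multi-year inputs to annual scale.

    Returns annual probabilities for: first CVD event, recurrence,
    disease-specific death in each post-event state and post-recurrence, and
    the within-cycle case fatalities (passed through unchanged).
    """
    rate_cvd = prob_to_rate(_get(draw, "p_cvd_baseline"), BASELINE_FOLLOWUP_YEARS)
    rate_rec = prob_to_rate(_get(draw, "p_recurrence"), BASELINE_FOLLOWUP_YEARS)
    return {
        "p_cvd_annual": -np.expm1(-rate_cvd),
        "p_recurrence_annual": -np.expm1(-rate_rec),
        "p_death_post_stroke": survival_to_annual_death_prob(
            _get(draw, "surv5_post_stroke"), POST_EVENT_SURVIVAL_YEARS),
        "p_death_post_chd": survival_to_annual_death_prob(
            _get(draw, "surv5_post_chd"), POST_EVENT_SURVIVAL_YEARS),
        "p_death_post_hf": survival_to_annual_death_prob(
            _get(draw, "surv5_post_hf"), POST_EVENT_SURVIVAL_YEARS),
        "p_death_post_recurrence": survival_to_annual_death_prob(
            _get(draw, "surv5_post_recurrence"), POST_EVENT_SURVIVAL_YEARS),
        "p_fatal_stroke": _get(draw, "p_fatal_stroke"),
        "p_fatal_chd_hf": _get(draw, "p_fatal_chd_hf"),
    }


def _no_cvd_exits(draw, arm: StrategyArm, q_background, risks=None) -> dict:
    """Decompose the annual exits from NO_CVD under competing risks.

    Rates for CVD event (hazard-ratio scaled), recurrence (likewise) and
    background death act simultaneously; the total exit probability
    ``1 - exp(-R)`` is allocated proportionally to the rates.  Returns the
    per-destination probabilities, including the fatal/non-fatal split of each
    event type.
    """
    if risks is None:
        risks = annualize_baseline_risks(draw)
    q_bg = np.minimum(np.asarray(q_background, dtype=float), 1.0 - 1e-12)
    # hazard-ratio scaling is multiplication on the rate scale
    r_cvd = prob_to_rate(risks["p_cvd_annual"]) * np.asarray(arm.hr_cvd(draw), dtype=float)
    r_rec = prob_to_rate(risks["p_recurrence_annual"]) * np.asarray(arm.hr_recurrence(draw), dtype=float)
    r_bg = prob_to_rate(q_bg)
    total = r_cvd + r_rec + r_bg
    p_exit = -np.expm1(-total)
    safe_total = np.where(total > 0, total, 1.0)
    p_cvd = np.where(total > 0, p_exit * r_cvd / safe_total, 0.0)
    p_rec = np.where(total > 0, p_exit * r_rec / safe_total, 0.0)
    p_bg = np.where(total > 0, p_exit * r_bg / safe_total, 0.0)
    out = {"p_recurrence": p_rec, "p_background_death": p_bg}
    for share_key, fatal_key, state, *_ in _EVENTS:
        p_event = p_cvd * _get(draw, share_key)
        fatal = np.asarray(risks[fatal_key], dtype=float)
        out[state] = {"fatal": p_event * fatal, "nonfatal": p_event * (1.0 - fatal)}
    return out


def build_transition_matrix(draw, arm: StrategyArm, attained_age, life_table: LifeTable,
                            risks=None) -> np.ndarray:
    """One-cycle transition matrix at ``attained_age`` (scalar or per-draw array).

    Batched draws produce an ``(n, 6, 6)`` stack.  Rows are renormalized to
    sum to exactly 1 (closing machine-epsilon leakage into the stay
    probability).
    """
    q_bg = life_table.qx_at(attained_age)
    exits = _no_cvd_exits(draw, arm, q_bg, risks=risks)
    if risks is None:
        risks = annualize_baseline_risks(draw)

    batch = np.broadcast(
        np.asarray(exits["p_recurrence"]), np.asarray(q_bg)
    ).shape
    n_s = len(EC_STATES)
    m = np.zeros(batch + (n_s, n_s))

    i = HealthState.NO_CVD
    dead = HealthState.DEAD
    p_dead = np.asarray(exits["p_background_death"], dtype=float).copy()
    for event in _EVENTS:
        state = event[2]
        m[..., i, state] = exits[state]["nonfatal"]
        p_dead = p_dead + exits[state]["fatal"]
    m[..., i, HealthState.POST_RECURRENCE] = exits["p_recurrence"]
    m[..., i, dead] = p_dead
    m[..., i, i] = 1.0 - m[..., i, :].sum(axis=-1)

    post_death = {
        HealthState.POST_STROKE: risks["p_death_post_stroke"],
        HealthState.POST_CHD: risks["p_death_post_chd"],
        HealthState.POST_HF: risks["p_death_post_hf"],
        HealthState.POST_RECURRENCE: risks["p_death_post_recurrence"],
    }
    for state, p_disease in post_death.items():
        p = combine_mortality(np.minimum(p_disease, 1 - 1e-12), np.minimum(q_bg, 1 - 1e-12))
        m[..., state, dead] = p
        m[..., state, state] = 1.0 - p
    m[..., dead, dead] = 1.0

    if np.any(m < -1e-12):
        bad = np.unravel_index(np.argmin(m), m.shape)
        raise ValueError(f"negative transition probability at cell {bad}")
    m = np.clip(m, 0.0, 1.0)
    m /= m.sum(axis=-1, keepdims=True)
    return m


def build_rewards(draw, arm: StrategyArm, attained_age, cycle: int,
                  utility_table: AgeUtilityTable, life_table: LifeTable,
                  fatal_event_cost: float | None = None, risks=None) -> CycleRewards:
    """Per-state and transition rewards for one cycle.

    State utilities: age-specific baseline in NO_CVD; absolute published
    utilities in the post-event states; baseline minus the recurrence
    disutility (floored at 0) in post-recurrence.  One-time event
    disutilities and acute treatment costs attach to the entering flows.
    Annual costs: cancer surveillance in every alive non-recurrence state,
    post-event follow-up on top, recurrence follow-up care replacing
    surveillance in post-recurrence.  The intervention cost lands in the
    first cycle's NO_CVD state cost.  The flow NO_CVD -> DEAD carries the
    expected acute cost of fatal events (cause-weighted; background deaths
    cost nothing), overridable with a flat ``fatal_event_cost``.
    """
    u_base = np.asarray(utility_table.utility_at(attained_age), dtype=float)
    q_bg = life_table.qx_at(attained_age)
    exits = _no_cvd_exits(draw, arm, q_bg, risks=risks)

    batchers = [u_base] + [np.asarray(_get(draw, k)) for k in ("c_surveillance",)]
    batch = np.broadcast(*batchers).shape
    n_s = len(EC_STATES)

    util = np.zeros(batch + (n_s,))
    util[..., HealthState.NO_CVD] = u_base
    util[..., HealthState.POST_RECURRENCE] = np.clip(u_base - _get(draw, "du_recurrence"), 0.0, 1.0)
    cost = np.zeros(batch + (n_s,))
    c_surv = _get(draw, "c_surveillance")
    cost[..., HealthState.NO_CVD] = c_surv
    cost[..., HealthState.POST_RECURRENCE] = _get(draw, "c_post_cancer_fu")

    t_cost = np.zeros(batch + (n_s, n_s))
    t_dis = np.zeros(batch + (n_s, n_s))
    i = HealthState.NO_CVD
    t_cost[..., i, HealthState.POST_RECURRENCE] = _get(draw, "c_recurrence_treatment")

    fatal_cost_flow = np.zeros(batch)
    p_fatal_total = np.zeros(batch)
    for share_key, fatal_key, state, treat_key, fu_key, du_key, u_key in _EVENTS:
        util[..., state] = np.clip(_get(draw, u_key), 0.0, 1.0)
        cost[..., state] = c_surv + _get(draw, fu_key)
        t_cost[..., i, state] = _get(draw, treat_key)
        t_dis[..., i, state] = _get(draw, du_key)
        c_fatal = fatal_event_cost if fatal_event_cost is not None else _get(draw, treat_key)
        fatal_cost_flow = fatal_cost_flow + exits[state]["fatal"] * c_fatal
        p_fatal_total = p_fatal_total + exits[state]["fatal"]
    # expected acute cost per unit of NO_CVD -> DEAD flow (fatal events only;
    # the background-death share of that flow carries no cost)
    p_dead_flow = p_fatal_total + exits["p_background_death"]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_cost[..., i, HealthState.DEAD] = np.where(
            p_dead_flow > 0, fatal_cost_flow / np.where(p_dead_flow > 0, p_dead_flow, 1.0), 0.0
        )

    if cycle == 1:
        cost[..., HealthState.NO_CVD] = cost[..., HealthState.NO_CVD] + arm.first_cycle_cost(draw)

    return CycleRewards(
        state_cost=cost, state_utility=util,
        transition_cost=t_cost, transition_disutility=t_dis,
    )


def run_arm(draw, arm: StrategyArm, horizon: int, life_table: LifeTable,
            utility_table: AgeUtilityTable, discount_rate: float = 0.05,
            half_cycle: bool = True, fatal_event_cost: float | None = None,
            return_trace: bool = False):
    """Run one strategy arm from a 100% NO_CVD start.

    The attained age in cycle ``t`` is the (rounded) start age plus ``t - 1``;
    it indexes both the life table and the baseline utility table.  ``draw``
    values may be scalars (base case) or equal-length arrays (vectorized PSA),
    in which case all outputs are batched.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    age0 = np.rint(np.asarray(_get(draw, "age"))).astype(int)
    if age0.ndim > 0:
        # vectorized PSA draws: keep extreme sampled ages inside the tables
        top = min(life_table.max_age, utility_table.max_age) - horizon + 1
        age0 = np.clip(age0, max(life_table.min_age, utility_table.min_age), top)
    risks = annualize_baseline_risks(draw)

    batch = np.broadcast(age0, np.asarray(risks["p_cvd_annual"])).shape
    initial = np.zeros(batch + (len(EC_STATES),))
    initial[..., HealthState.NO_CVD] = 1.0

    def matrix_fn(t):
        return build_transition_matrix(draw, arm, age0 + t, life_table, risks=risks)

    trace = build_trace(initial, matrix_fn, horizon, state_space=EC_STATES)
    rewards = [
        build_rewards(draw, arm, age0 + t - 1, t, utility_table, life_table,
                      fatal_event_cost=fatal_event_cost, risks=risks)
        for t in range(1, horizon + 1)
    ]
    outcomes = accrue_outcomes(trace, rewards, discount_rate, half_cycle=half_cycle)
    return (outcomes, trace) if return_trace else outcomes
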