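"""Cost-effectiveness analyses: base case, PSA, CEAC, tornado, horizon sweep
and the extended-supervision scenario.

All comparisons are exercise versus standard care.  The headline statistics
are the incremental cost ΔC, incremental QALYs ΔQ, the ICER ΔC/ΔQ, and the
incremental net monetary benefit iNMB = λ·ΔQ − ΔC at willingness-to-pay λ
(default AUD $50,000 per QALY).

Two ICERs are reported from a probabilistic analysis: the deterministic
base-case ICER (all parameters at their means) and the ratio of mean
increments across Monte Carlo iterations.  The ratio of means is preferred
over the mean of per-iteration ratios, which is unstable when ΔQ crosses
zero; percentile intervals for the ICER are taken over the per-iteration
ratios restricted to iterations with positive ΔQ and should be read as a
net-benefit-plane summary, not a confidence interval in the strict sense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import EXERCISE, STANDARD_CARE, run_arm
from .params import ParameterRegistry
from .synth import AgeUtilityTable, LifeTable

__all__ = [
    "CEResult",
    "PSAResult",
    "TornadoEntry",
    "HorizonSweepResult",
    "base_case",
    "run_psa",
    "ceac",
    "tornado",
    "horizon_sweep",
    "extended_supervision_scenario",
    "EXTENDED_SUPERVISION_COST",
]

logger = logging.getLogger(__name__)

DEFAULT_WTP = 50_000.0
DEFAULT_HORIZON = 5
DEFAULT_DISCOUNT = 0.05

#: Extended-supervision scenario: 36 additional supervised sessions at
#: $75/hour, added to the first-cycle intervention cost.
EXTENDED_SUPERVISION_COST = 36 * 75.0


@dataclass
class CEResult:
    """Incremental cost-effectiveness summary for one comparison."""

    cost_control: float
    cost_intervention: float
    qaly_control: float
    qaly_intervention: float
    wtp: float = DEFAULT_WTP
    ci: dict = field(default_factory=dict)

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_control

    @property
    def dominant(self) -> bool:
        """Intervention cheaper and more effective."""
        return self.delta_cost < 0 and self.delta_qaly > 0

    @property
    def dominated(self) -> bool:
        return self.delta_cost > 0 and self.delta_qaly < 0

    @property
    def icer(self) -> float:
        """ΔC/ΔQ; nan when ΔQ = 0 (undefined)."""
        if self.delta_qaly == 0:
            return float("nan")
        return self.delta_cost / self.delta_qaly

    @property
    def icer_defined(self) -> bool:
        return self.delta_qaly != 0

    @property
    def inmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost

    def cost_effective(self) -> bool:
        """iNMB > 0 at the stored willingness-to-pay."""
        return self.inmb > 0

    def to_dict(self) -> dict:
        return {
            "cost_standard_care": self.cost_control,
            "cost_exercise": self.cost_intervention,
            "qaly_standard_care": self.qaly_control,
            "qaly_exercise": self.qaly_intervention,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": None if not self.icer_defined else self.icer,
            "dominant": self.dominant,
            "dominated": self.dominated,
            "wtp": self.wtp,
            "inmb": self.inmb,
            "ci": self.ci,
        }


def _run_both_arms(draw, horizon, life_table, utility_table, discount_rate,
                   fatal_event_cost, extra_intervention_cost):
    ex = EXERCISE.with_extra_cost(extra_intervention_cost) if extra_intervention_cost else EXERCISE
    out_sc = run_arm(draw, STANDARD_CARE, horizon, life_table, utility_table,
                     discount_rate=discount_rate, fatal_event_cost=fatal_event_cost)
    out_ex = run_arm(draw, ex, horizon, life_table, utility_table,
                     discount_rate=discount_rate, fatal_event_cost=fatal_event_cost)
    return out_sc, out_ex


def base_case(registry: ParameterRegistry, life_table: LifeTable,
              utility_table: AgeUtilityTable, horizon: int = DEFAULT_HORIZON,
              wtp: float = DEFAULT_WTP, discount_rate: float = DEFAULT_DISCOUNT,
              fatal_event_cost: float | None = None,
              extra_intervention_cost: float = 0.0,
              overrides: dict | None = None) -> CEResult:
    """Deterministic evaluation with every parameter at its stated mean.

    ``overrides`` replaces individual point estimates (used by the tornado).
    """
    draw = registry.point_estimates()
    if overrides:
        draw.update(overrides)
    out_sc, out_ex = _run_both_arms(draw, horizon, life_table, utility_table,
                                    discount_rate, fatal_event_cost,
                                    extra_intervention_cost)
    return CEResult(out_sc.cost, out_ex.cost, out_sc.qaly, out_ex.qaly, wtp=wtp)


@dataclass
class PSAResult:
    """Per-iteration Monte Carlo outcomes for both arms."""

    cost_control: np.ndarray
    cost_intervention: np.ndarray
    qaly_control: np.ndarray
    qaly_intervention: np.ndarray
    seed: int
    wtp: float = DEFAULT_WTP

    @property
    def n_iter(self) -> int:
        return len(self.cost_control)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_control

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_control

    @property
    def inmb(self) -> np.ndarray:
        return self.wtp * self.delta_qaly - self.delta_cost

    def summary(self) -> CEResult:
        """Means across iterations with 2.5/97.5 percentile intervals.

        The summary ICER is the ratio of mean increments.
        """
        pct = lambda x: tuple(np.percentile(x, [2.5, 97.5]))
        dq = self.delta_qaly
        pos = dq > 0
        icer_ci = (
            pct(self.delta_cost[pos] / dq[pos]) if pos.any() else (float("nan"),) * 2
        )
        ci = {
            "cost_standard_care": pct(self.cost_control),
            "cost_exercise": pct(self.cost_intervention),
            "qaly_standard_care": pct(self.qaly_control),
            "qaly_exercise": pct(self.qaly_intervention),
            "delta_cost": pct(self.delta_cost),
            "delta_qaly": pct(dq),
            "inmb": pct(self.inmb),
            "icer": icer_ci,
        }
        return CEResult(
            float(self.cost_control.mean()), float(self.cost_intervention.mean()),
            float(self.qaly_control.mean()), float(self.qaly_intervention.mean()),
            wtp=self.wtp, ci=ci,
        )

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        wtp = self.wtp if wtp is None else wtp
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0))

    def to_frame(self) -> pd.DataFrame:
        """Long format: iteration, arm, cost, qaly."""
        n = self.n_iter
        return pd.DataFrame({
            "iteration": np.concatenate([np.arange(n), np.arange(n)]),
            "arm": ["standard_care"] * n + ["exercise"] * n,
            "cost": np.concatenate([self.cost_control, self.cost_intervention]),
            "qaly": np.concatenate([self.qaly_control, self.qaly_intervention]),
        })


def run_psa(registry: ParameterRegistry, life_table: LifeTable,
            utility_table: AgeUtilityTable, n_iter: int = 10_000,
            seed: int = 0, horizon: int = DEFAULT_HORIZON,
            wtp: float = DEFAULT_WTP, discount_rate: float = DEFAULT_DISCOUNT,
            fatal_event_cost: float | None = None,
            extra_intervention_cost: float = 0.0) -> PSAResult:
    """Probabilistic sensitivity analysis.

    One joint parameter draw per iteration drives both arms (common random
    parameters), so sampling noise cancels in the increments.  Fully
    reproducible from ``seed``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draw = registry.sample(rng, size=n_iter)
    out_sc, out_ex = _run_both_arms(draw, horizon, life_table, utility_table,
                                    discount_rate, fatal_event_cost,
                                    extra_intervention_cost)
    return PSAResult(
        cost_control=np.atleast_1d(out_sc.cost),
        cost_intervention=np.atleast_1d(out_ex.cost),
        qaly_control=np.atleast_1d(out_sc.qaly),
        qaly_intervention=np.atleast_1d(out_ex.qaly),
        seed=seed, wtp=wtp,
    )


def ceac(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each λ on the grid, the fraction of iterations with positive
    incremental net benefit λ·ΔQ − ΔC.  Default grid: 0–100,000 in steps of
    1,000 (brackets the $50k threshold symmetrically).
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 1_000)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    nb = wtp_grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return pd.DataFrame({"wtp": wtp_grid, "probability": (nb > 0).mean(axis=1)})


@dataclass
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def tornado(registry: ParameterRegistry, life_table: LifeTable,
            utility_table: AgeUtilityTable, horizon: int = DEFAULT_HORIZON,
            wtp: float = DEFAULT_WTP, discount_rate: float = DEFAULT_DISCOUNT,
            fatal_event_cost: float | None = None) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER.

    Each parameter with stated 95% CI bounds is set to its lower then upper
    bound with everything else at the base case; parameters without bounds
    (dirichlet shares, table rows, fixed values) are skipped with a notice.
    Entries are sorted by decreasing bar width.
    """
    kwargs = dict(horizon=horizon, wtp=wtp, discount_rate=discount_rate,
                  fatal_event_cost=fatal_event_cost)
    entries = []
    for spec in registry.specs:
        if spec.family == "table" or not spec.has_ci:
            logger.info("tornado: skipping %s (no CI bounds)", spec.name)
            continue
        icers = []
        for bound in (spec.ci_low, spec.ci_high):
            res = base_case(registry, life_table, utility_table,
                            overrides={spec.name: bound}, **kwargs)
            icers.append(res.icer)
        entries.append(TornadoEntry(spec.name, icers[0], icers[1]))
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": e.parameter, "icer_low": e.icer_low,
          "icer_high": e.icer_high, "width": e.width} for e in entries]
    )


@dataclass
class HorizonSweepResult:
    results: dict[int, CEResult]
    wtp: float

    @property
    def first_cost_effective_year(self) -> int | None:
        """First horizon with a defined ICER below λ (or dominance)."""
        for y in sorted(self.results):
            r = self.results[y]
            if r.dominant or (r.icer_defined and r.delta_qaly > 0 and r.icer < self.wtp):
                return y
        return None

    @property
    def first_dominant_year(self) -> int | None:
        for y in sorted(self.results):
            if self.results[y].dominant:
                return y
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for y in sorted(self.results):
            r = self.results[y]
            rows.append({
                "horizon": y, "delta_cost": r.delta_cost, "delta_qaly": r.delta_qaly,
                "icer": r.icer, "inmb": r.inmb, "dominant": r.dominant,
                "cost_effective": r.cost_effective(),
            })
        return pd.DataFrame(rows)


def horizon_sweep(registry: ParameterRegistry, life_table: LifeTable,
                  utility_table: AgeUtilityTable, years=range(1, 11),
                  wtp: float = DEFAULT_WTP, discount_rate: float = DEFAULT_DISCOUNT,
                  fatal_event_cost: float | None = None) -> HorizonSweepResult:
    """Re-run the base case over a range of time horizons (years)."""
    years = list(years)
    if any(y < 1 or y > 40 for y in years):
        raise ValueError("horizons must lie in [1, 40]")
    results = {
        int(y): base_case(registry, life_table, utility_table, horizon=int(y),
                          wtp=wtp, discount_rate=discount_rate,
                          fatal_event_cost=fatal_event_cost)
        for y in years
    }
    return HorizonSweepResult(results=results, wtp=wtp)


def extended_supervision_scenario(registry: ParameterRegistry, life_table: LifeTable,
                                  utility_table: AgeUtilityTable,
                                  horizon: int = DEFAULT_HORIZON,
                                  wtp: float = DEFAULT_WTP,
                                  discount_rate: float = DEFAULT_DISCOUNT,
                                  fatal_event_cost: float | None = None) -> CEResult:
    """Supervision extended to a full year: 36 extra sessions at $75/h
    ($2,700) added to the first-cycle intervention cost; all else unchanged."""
    return base_case(registry, life_table, utility_table, horizon=horizon, wtp=wtp,
                     discount_rate=discount_rate, fatal_event_cost=fatal_event_cost,
                     extra_intervention_cost=EXTENDED_SUPERVISION_COST)
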