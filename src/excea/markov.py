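"""Discrete-time Markov cohort engine.

Tracks cohort occupancy over annual cycles, decomposes each cycle into
transition flows, and accrues discounted costs and QALYs with an optional
half-cycle correction.

Conventions
-----------
* Cycle ``t`` (t = 1..horizon) runs from trace row ``t-1`` to row ``t``; its
  outcomes are discounted by ``(1 + rate)**(-t)`` (cycle-end discounting).
* Half-cycle correction is the within-cycle trapezoid: the state rewards of
  cycle ``t`` are weighted by the mean of the start- and end-of-cycle
  occupancy.  At zero discount this is exactly the classic half-weighting of
  the first and final trace rows.  Transition rewards are instantaneous event
  rewards attached to the flow entering a state and are never half-weighted.
* All arrays broadcast over an optional leading batch dimension, so a
  vectorized PSA can push ``n`` parameter draws through the engine at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "CohortTrace",
    "CycleRewards",
    "DiscountedOutcomes",
    "markov_step",
    "build_trace",
    "discount_factor",
    "accrue_outcomes",
    "validate_transition_matrix",
]

ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StateSpace:
    """Ordered health states with a single absorbing (death) state."""

    states: tuple
    absorbing: str

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("state names must be unique")
        if self.absorbing not in self.states:
            raise ValueError(f"absorbing state {self.absorbing!r} not in state list")

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state) -> int:
        return self.states.index(state)

    @property
    def absorbing_index(self) -> int:
        return self.index(self.absorbing)


def validate_transition_matrix(m: np.ndarray, state_space: StateSpace | None = None) -> np.ndarray:
    """Check row-stochasticity (and death-row identity when states are given)."""
    m = np.asarray(m, dtype=float)
    if m.shape[-1] != m.shape[-2]:
        raise ValueError(f"transition matrix must be square, got {m.shape}")
    if np.any(m < -ROW_SUM_TOL) or np.any(m > 1 + ROW_SUM_TOL):
        raise ValueError("transition probabilities must lie in [0, 1]")
    rows = m.sum(axis=-1)
    if np.any(np.abs(rows - 1.0) > 1e-6):
        worst = np.abs(rows - 1.0).max()
        raise ValueError(f"rows must sum to 1 (max deviation {worst:.3e})")
    if state_space is not None:
        d = state_space.absorbing_index
        expected = np.zeros(len(state_space))
        expected[d] = 1.0
        if np.any(np.abs(m[..., d, :] - expected) > ROW_SUM_TOL):
            raise ValueError("death row must be the identity (absorbing state)")
    return m


def markov_step(occupancy: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """One cohort step: ``occupancy @ matrix``, with mass conservation.

    ``occupancy`` is ``(S,)`` or ``(n, S)``; ``matrix`` is ``(S, S)`` or
    ``(n, S, S)``.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    matrix = validate_transition_matrix(matrix)
    if occupancy.ndim == 1 and matrix.ndim == 2:
        return occupancy @ matrix
    return np.einsum("...i,...ij->...j", occupancy, matrix)


@dataclass
class CohortTrace:
    """Occupancy per cycle plus the per-cycle transition flow decomposition.

    ``occupancy`` has shape ``(..., horizon+1, S)`` (row 0 = initial
    distribution); ``flows[..., t, i, j]`` is the cohort fraction moving
    i -> j during cycle ``t+1``.
    """

    occupancy: np.ndarray
    flows: np.ndarray
    state_space: StateSpace | None = None

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[-2] - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (cycle, state, occupancy); unbatched traces only."""
        occ = self.occupancy
        if occ.ndim != 2:
            raise ValueError("to_frame supports unbatched traces only")
        states = (
            list(self.state_space.states)
            if self.state_space
            else [f"state_{i}" for i in range(occ.shape[1])]
        )
        rows = [
            {"cycle": t, "state": s, "occupancy": occ[t, i]}
            for t in range(occ.shape[0])
            for i, s in enumerate(states)
        ]
        return pd.DataFrame(rows)


def build_trace(
    initial: np.ndarray,
    matrix_fn: Callable[[int], np.ndarray],
    horizon: int,
    state_space: StateSpace | None = None,
) -> CohortTrace:
    """Iterate the cohort ``horizon`` cycles; ``matrix_fn(t)`` supplies the
    matrix applied during cycle ``t+1`` (t = 0..horizon-1)."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    initial = np.asarray(initial, dtype=float)
    s = initial.shape[-1]
    occ = [initial]
    flows = []
    for t in range(horizon):
        try:
            m = validate_transition_matrix(matrix_fn(t), state_space)
        except Exception as exc:
            raise type(exc)(f"cycle {t + 1}: {exc}") from exc
        prev = occ[-1]
        flows.append(prev[..., :, None] * m)
        occ.append(markov_step(prev, m))
    return CohortTrace(
        occupancy=np.stack(occ, axis=-2),
        flows=np.stack(flows, axis=-3) if flows else np.zeros(initial.shape[:-1] + (0, s, s)),
        state_space=state_space,
    )


def discount_factor(rate: float, cycle: int):
    """``(1 + rate) ** -cycle``; cycle 0 is undiscounted."""
    cycle = np.asarray(cycle)
    if np.any(cycle < 0):
        raise ValueError("cycle must be non-negative")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    out = (1.0 + rate) ** (-cycle.astype(float))
    return float(out) if out.ndim == 0 else out


@dataclass
class CycleRewards:
    """Per-state and per-transition rewards for one cycle.

    ``state_cost`` / ``state_utility``: shape ``(..., S)``.
    ``transition_cost`` / ``transition_disutility``: shape ``(..., S, S)``,
    applied once to the flow entering each (from, to) pair; disutilities are
    subtracted.
    """

    state_cost: np.ndarray
    state_utility: np.ndarray
    transition_cost: np.ndarray | None = None
    transition_disutility: np.ndarray | None = None


@dataclass
class DiscountedOutcomes:
    """Totals plus the per-cycle breakdown (cycle index 1..horizon)."""

    cost: float | np.ndarray
    qaly: float | np.ndarray
    cycle_costs: np.ndarray
    cycle_qalys: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cc, cq = np.asarray(self.cycle_costs), np.asarray(self.cycle_qalys)
        if cc.ndim != 1:
            raise ValueError("to_frame supports unbatched outcomes only")
        return pd.DataFrame(
            {"cycle": np.arange(1, cc.shape[0] + 1), "cost": cc, "qaly": cq}
        )


def accrue_outcomes(
    trace: CohortTrace,
    rewards: CycleRewards | Sequence[CycleRewards],
    rate: float,
    half_cycle: bool = True,
) -> DiscountedOutcomes:
    """Aggregate discounted costs and QALYs over the trace.

    ``rewards`` is either one :class:`CycleRewards` applied to every cycle or
    a sequence with one entry per cycle.  See the module docstring for the
    half-cycle and discounting conventions.
    """
    occ = trace.occupancy
    flows = trace.flows
    h = trace.horizon
    if isinstance(rewards, CycleRewards):
        rewards = [rewards] * h
    if len(rewards) != h:
        raise ValueError(f"need {h} per-cycle rewards, got {len(rewards)}")

    cycle_costs, cycle_qalys = [], []
    for t in range(1, h + 1):
        r = rewards[t - 1]
        if half_cycle:
            w = 0.5 * (occ[..., t - 1, :] + occ[..., t, :])
        else:
            w = occ[..., t, :]
        sc = np.asarray(r.state_cost, dtype=float)
        su = np.asarray(r.state_utility, dtype=float)
        if sc.shape[-1] != occ.shape[-1]:
            raise ValueError("state reward length does not match state count")
        cost = (w * sc).sum(axis=-1)
        qaly = (w * su).sum(axis=-1)
        f = flows[..., t - 1, :, :]
        if r.transition_cost is not None:
            cost = cost + (f * np.asarray(r.transition_cost, dtype=float)).sum(axis=(-1, -2))
        if r.transition_disutility is not None:
            qaly = qaly - (f * np.asarray(r.transition_disutility, dtype=float)).sum(axis=(-1, -2))
        v = discount_factor(rate, t)
        cycle_costs.append(cost * v)
        cycle_qalys.append(qaly * v)

    cc = np.stack(cycle_costs, axis=-1)
    cq = np.stack(cycle_qalys, axis=-1)
    total_c, total_q = cc.sum(axis=-1), cq.sum(axis=-1)
    if np.ndim(total_c) == 0:
        total_c, total_q = float(total_c), float(total_q)
    return DiscountedOutcomes(cost=total_c, qaly=total_q, cycle_costs=cc, cycle_qalys=cq)
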