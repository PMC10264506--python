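"""Closed-form epidemiological conversions.

Probabilities, rates, hazard ratios and multi-year survival fractions are
interconverted under a constant-hazard (exponential) assumption, the standard
convention for annual-cycle cohort models: a cumulative probability ``p`` over
``t`` years corresponds to the rate ``r = -ln(1 - p) / t``, and a rate acts on
the survival scale as ``S = exp(-r t)``.

All functions accept scalars or numpy arrays and broadcast elementwise.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "prob_to_rate",
    "rate_to_prob",
    "apply_hazard_ratio",
    "survival_to_annual_death_prob",
    "combine_mortality",
]


def _check(cond: np.ndarray | bool, msg: str) -> None:
    if not np.all(cond):
        raise ValueError(msg)


def prob_to_rate(p, t: float = 1.0):
    """Convert a cumulative probability over ``t`` years to an event rate.

    Parameters
    ----------
    p : float or array
        Cumulative event probability, ``0 <= p < 1``.
    t : float
        Length of the observation window in years, ``t > 0``.

    Returns
    -------
    float or array
        Constant event rate in events per person-year, ``-ln(1 - p) / t``.
    """
    p = np.asarray(p, dtype=float)
    _check(t > 0, "time window t must be positive")
    _check((p >= 0) & (p <= 1), "probability must lie in [0, 1]")
    _check(p < 1, "p = 1 corresponds to an infinite rate")
    out = -np.log1p(-p) / t
    return float(out) if out.ndim == 0 else out


def rate_to_prob(r, t: float = 1.0):
    """Convert a constant event rate to a cumulative probability over ``t`` years."""
    r = np.asarray(r, dtype=float)
    _check(t > 0, "time window t must be positive")
    _check(r >= 0, "rate must be non-negative")
    out = -np.expm1(-r * t)
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(p, hr):
    """Scale an annual probability by a hazard ratio.

    The probability is moved to the rate scale, multiplied by ``hr``, and
    transformed back: ``1 - (1 - p)**hr``.  ``hr = 1`` is the identity;
    ``hr < 1`` strictly decreases any probability in (0, 1).
    """
    p = np.asarray(p, dtype=float)
    hr = np.asarray(hr, dtype=float)
    _check((p >= 0) & (p < 1), "probability must lie in [0, 1)")
    _check(hr > 0, "hazard ratio must be positive")
    out = -np.expm1(hr * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def survival_to_annual_death_prob(s, horizon: float):
    """Annual death probability implied by a ``horizon``-year survival fraction.

    Under constant hazard, ``horizon``-year survival ``S`` implies an annual
    death probability ``1 - S**(1/horizon)``.  ``S = 0`` is degenerate: the
    whole cohort is dead within the horizon, so 1.0 is returned with a warning.
    """
    s = np.asarray(s, dtype=float)
    _check(horizon > 0, "horizon must be positive")
    _check((s >= 0) & (s <= 1), "survival fraction must lie in [0, 1]")
    if np.any(s == 0):
        warnings.warn(
            "survival fraction of 0 implies certain death within the horizon",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        out = np.where(s > 0, -np.expm1(np.log(np.maximum(s, 1e-300)) / horizon), 1.0)
    return float(out) if out.ndim == 0 else out


def combine_mortality(p_disease, p_background):
    """Combine two within-cycle death probabilities from independent causes.

    Additive on the rate scale, i.e. multiplicative on the survival scale:
    ``1 - (1 - p_disease)(1 - p_background)``.  The result is never smaller
    than either input.
    """
    p_disease = np.asarray(p_disease, dtype=float)
    p_background = np.asarray(p_background, dtype=float)
    _check((p_disease >= 0) & (p_disease < 1), "p_disease must lie in [0, 1)")
    _check((p_background >= 0) & (p_background < 1), "p_background must lie in [0, 1)")
    out = 1.0 - (1.0 - p_disease) * (1.0 - p_background)
    return float(out) if out.ndim == 0 else out
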