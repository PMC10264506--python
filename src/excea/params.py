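"""Parameter table loading, validation and distribution calibration.

Model inputs are published as a point estimate (mean) plus a 95% CI and a
distribution family.  This module turns each row into a samplable
distribution whose analytic mean matches the stated mean exactly and whose
2.5%/97.5% quantiles match the stated CI as closely as the family allows:

* ``normal`` — sd = (ci_high - ci_low) / (2 * 1.96)
* ``lognormal`` — log-sd = (ln ci_high - ln ci_low) / (2 * 1.96); the log-mean
  carries the usual -sigma^2/2 adjustment so the arithmetic mean is exact
* ``beta`` and ``gamma`` — the mean is pinned and the remaining degree of
  freedom (concentration / shape) is found by least squares on the two
  quantiles
* ``dirichlet`` — components grouped by label; concentration = mean * n_eff
* ``fixed`` / ``table`` — degenerate; ``table`` rows point at external
  age-indexed inputs and contribute no sampled value

Sampled probabilities are clipped to [0, 1] and costs to [0, inf) to guard
against extreme tail draws.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ParameterSpec",
    "CalibratedDistribution",
    "ParameterRegistry",
    "parse_parameter_table",
    "SchemaError",
    "ValidationError",
    "CalibrationError",
]

FAMILIES = {"beta", "gamma", "lognormal", "normal", "dirichlet", "table", "fixed"}
REQUIRED_COLUMNS = ["name", "family", "mean", "ci_low", "ci_high", "group", "units", "source"]

#: Effective sample size for dirichlet groups published as bare means.
DEFAULT_DIRICHLET_N_EFF = 100.0

Z95 = 2.0 * 1.959963984540054  # width of a 95% normal interval in sd units


class SchemaError(ValueError):
    """Parameter table does not have the expected columns/rows."""


class ValidationError(ValueError):
    """A parameter row violates its family's invariants."""


class CalibrationError(RuntimeError):
    """Hyperparameter search failed to converge for a row."""


@dataclass
class ParameterSpec:
    """One row of the model's parameter table."""

    name: str
    family: str
    mean: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    group: str | None = None
    units: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def is_cost(self) -> bool:
        return self.units.strip().upper() == "AUD"

    def validate(self) -> None:
        if self.family == "table":
            return  # external age-indexed input; no scalar mean required
        if self.mean is None or not math.isfinite(self.mean):
            raise ValidationError(f"{self.name}: mean is required for family {self.family}")
        if self.has_ci:
            if not self.ci_low <= self.mean <= self.ci_high:
                raise ValidationError(
                    f"{self.name}: CI ({self.ci_low}, {self.ci_high}) does not bracket "
                    f"mean {self.mean}"
                )
        if self.family == "beta" and not 0.0 <= self.mean <= 1.0:
            raise ValidationError(f"{self.name}: beta mean {self.mean} outside [0, 1]")
        if self.family in ("gamma", "lognormal") and self.mean < 0:
            raise ValidationError(f"{self.name}: {self.family} mean {self.mean} negative")
        if self.family == "dirichlet":
            if not 0.0 <= self.mean <= 1.0:
                raise ValidationError(f"{self.name}: dirichlet share {self.mean} outside [0, 1]")
            if self.group is None:
                raise ValidationError(f"{self.name}: dirichlet row requires a group label")


@dataclass
class CalibratedDistribution:
    """A spec resolved to concrete hyperparameters.

    ``hyperparameters`` holds the family's natural parameters, e.g.
    ``{"alpha": ..., "beta": ...}`` for beta or ``{"shape": ..., "scale": ...}``
    for gamma.  Dirichlet groups are calibrated jointly and stored once per
    group on the registry, not here.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def _frozen(self):
        h = self.hyperparameters
        if self.family == "beta":
            return stats.beta(h["alpha"], h["beta"])
        if self.family == "gamma":
            return stats.gamma(h["shape"], scale=h["scale"])
        if self.family == "lognormal":
            return stats.lognorm(h["log_sd"], scale=math.exp(h["log_mean"]))
        if self.family == "normal":
            return stats.norm(h["mean"], h["sd"])
        raise TypeError(f"no frozen form for family {self.family}")

    def analytic_mean(self) -> float:
        if self.family in ("fixed", "table"):
            return self.hyperparameters.get("value", float("nan"))
        return float(self._frozen().mean())

    def quantile(self, q) -> float:
        if self.family in ("fixed", "table"):
            return self.hyperparameters.get("value", float("nan"))
        return float(self._frozen().ppf(q))

    def sample(self, rng: np.random.Generator, size=None):
        h = self.hyperparameters
        if self.family in ("fixed", "table"):
            v = h.get("value", float("nan"))
            return v if size is None else np.full(size, v)
        if self.family == "beta":
            return rng.beta(h["alpha"], h["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(h["shape"], h["scale"], size=size)
        if self.family == "lognormal":
            return np.exp(rng.normal(h["log_mean"], h["log_sd"], size=size))
        if self.family == "normal":
            return rng.normal(h["mean"], h["sd"], size=size)
        raise TypeError(f"cannot sample family {self.family}")


def calibrate_distribution(spec: ParameterSpec, n_eff: float = DEFAULT_DIRICHLET_N_EFF) -> CalibratedDistribution:
    """Resolve a spec to hyperparameters (see module docstring for the rules)."""
    spec.validate()
    m = spec.mean
    if spec.family == "fixed":
        return CalibratedDistribution("fixed", {"value": m})
    if spec.family == "table":
        return CalibratedDistribution("table", {})
    if spec.family == "dirichlet":
        return CalibratedDistribution("dirichlet", {"alpha": m * n_eff})
    if not spec.has_ci:
        # no stated uncertainty: degenerate at the mean
        return CalibratedDistribution("fixed", {"value": m})
    lo, hi = spec.ci_low, spec.ci_high

    if spec.family == "normal":
        return CalibratedDistribution("normal", {"mean": m, "sd": (hi - lo) / Z95})

    if spec.family == "lognormal":
        if lo <= 0 or m <= 0:
            raise ValidationError(f"{spec.name}: lognormal requires positive mean and CI")
        log_sd = (math.log(hi) - math.log(lo)) / Z95
        return CalibratedDistribution(
            "lognormal", {"log_mean": math.log(m) - 0.5 * log_sd**2, "log_sd": log_sd}
        )

    # beta / gamma: pin the mean, search the remaining shape parameter so the
    # 2.5/97.5% quantiles match the CI in least squares
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValidationError(f"{spec.name}: beta mean must be interior to (0, 1)")

        def loss(log_nu: float) -> float:
            nu = math.exp(log_nu)
            d = stats.beta(m * nu, (1.0 - m) * nu)
            return (d.ppf(0.025) - lo) ** 2 + (d.ppf(0.975) - hi) ** 2

        res = optimize.minimize_scalar(loss, bounds=(math.log(1e-2), math.log(1e9)), method="bounded")
        if not res.success:
            raise CalibrationError(f"{spec.name}: beta calibration did not converge")
        nu = math.exp(res.x)
        return CalibratedDistribution("beta", {"alpha": m * nu, "beta": (1.0 - m) * nu})

    if spec.family == "gamma":
        if m <= 0:
            raise ValidationError(f"{spec.name}: gamma mean must be positive")

        def loss(log_k: float) -> float:
            k = math.exp(log_k)
            d = stats.gamma(k, scale=m / k)
            return ((d.ppf(0.025) - lo) / m) ** 2 + ((d.ppf(0.975) - hi) / m) ** 2

        res = optimize.minimize_scalar(loss, bounds=(math.log(1e-2), math.log(1e9)), method="bounded")
        if not res.success:
            raise CalibrationError(f"{spec.name}: gamma calibration did not converge")
        k = math.exp(res.x)
        return CalibratedDistribution("gamma", {"shape": k, "scale": m / k})

    raise CalibrationError(f"{spec.name}: no calibration rule for family {spec.family}")


class ParameterRegistry:
    """Ordered collection of :class:`ParameterSpec` with calibrated distributions.

    A ``ParameterDraw`` is a plain ``dict`` mapping parameter name to a value
    (scalar for a single draw, 1-d array of length ``size`` for vectorized
    PSA draws).  ``table``-family rows contribute no draw entry.
    """

    def __init__(self, specs: list[ParameterSpec] | None = None,
                 dirichlet_n_eff: float = DEFAULT_DIRICHLET_N_EFF):
        self._specs: dict[str, ParameterSpec] = {}
        self.dirichlet_n_eff = dirichlet_n_eff
        self._calibrated: dict[str, CalibratedDistribution] | None = None
        for s in specs or []:
            self.add(s)

    def add(self, spec: ParameterSpec) -> None:
        if spec.name in self._specs:
            raise ValidationError(f"duplicate parameter name {spec.name!r}")
        spec.validate()
        self._specs[spec.name] = spec
        self._calibrated = None

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    @property
    def specs(self) -> list[ParameterSpec]:
        return list(self._specs.values())

    def names(self) -> list[str]:
        return list(self._specs)

    def dirichlet_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for s in self._specs.values():
            if s.family == "dirichlet":
                groups.setdefault(s.group, []).append(s.name)
        return groups

    def validate(self) -> None:
        for s in self._specs.values():
            s.validate()
        for g, names in self.dirichlet_groups().items():
            total = sum(self._specs[n].mean for n in names)
            if abs(total - 1.0) > 1e-3:
                raise ValidationError(f"dirichlet group {g!r} means sum to {total}, not 1")

    def calibrate(self) -> dict[str, CalibratedDistribution]:
        """Calibrate every row (cached)."""
        if self._calibrated is None:
            self.validate()
            self._calibrated = {
                name: calibrate_distribution(s, n_eff=self.dirichlet_n_eff)
                for name, s in self._specs.items()
            }
        return self._calibrated

    def distribution(self, name: str) -> CalibratedDistribution:
        return self.calibrate()[name]

    # -- draws ---------------------------------------------------------------

    def point_estimates(self) -> dict[str, float]:
        """Base-case vector: every parameter at its stated mean."""
        return {
            name: float(s.mean)
            for name, s in self._specs.items()
            if s.family != "table"
        }

    def sample(self, rng: np.random.Generator | int, size: int | None = None) -> dict:
        """Draw every parameter; dirichlet groups are drawn jointly.

        ``rng`` may be a Generator or a seed.  With ``size=None`` values are
        scalars; otherwise 1-d arrays of length ``size``.
        """
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        cal = self.calibrate()
        draw: dict = {}
        groups = self.dirichlet_groups()
        grouped = {n for names in groups.values() for n in names}
        for name, s in self._specs.items():
            if s.family == "table" or name in grouped:
                continue
            v = cal[name].sample(rng, size=size)
            units = s.units.strip().lower()
            if units in ("probability", "proportion", "utility") or s.family == "beta":
                v = np.clip(v, 0.0, 1.0)
            elif s.is_cost or s.family == "gamma":
                v = np.clip(v, 0.0, None)
            draw[name] = float(v) if size is None else np.asarray(v)
        for g, names in groups.items():
            alpha = np.array([cal[n].hyperparameters["alpha"] for n in names])
            v = rng.dirichlet(alpha, size=size)  # (k,) or (size, k)
            for i, n in enumerate(names):
                draw[n] = float(v[i]) if size is None else v[:, i]
        return draw

    # -- serialization -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self._specs.values():
            rows.append({
                "name": s.name, "family": s.family, "mean": s.mean,
                "ci_low": s.ci_low, "ci_high": s.ci_high,
                "group": s.group, "units": s.units, "source": s.source,
            })
        return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        records = self.to_frame().to_dict(orient="records")
        for r in records:
            for k, v in r.items():
                if isinstance(v, float) and math.isnan(v):
                    r[k] = None
        Path(path).write_text(json.dumps(records, indent=2))


def sample_parameters(registry: ParameterRegistry, rng_seed) -> dict:
    """One joint draw of every parameter (see :meth:`ParameterRegistry.sample`)."""
    return registry.sample(rng_seed)


def point_estimates(registry: ParameterRegistry) -> dict:
    return registry.point_estimates()


def _row_to_spec(row: Mapping) -> ParameterSpec:
    def _opt(v):
        if v is None:
            return None
        if isinstance(v, str):
            v = v.strip()
            if not v:
                return None
        v = float(v)
        return None if math.isnan(v) else v

    def _str(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        s = str(v).strip()
        return s or None

    return ParameterSpec(
        name=str(row["name"]).strip(),
        family=str(row["family"]).strip().lower(),
        mean=_opt(row["mean"]),
        ci_low=_opt(row["ci_low"]),
        ci_high=_opt(row["ci_high"]),
        group=_str(row["group"]),
        units=_str(row["units"]) or "",
        source=_str(row["source"]) or "",
    )


def parse_parameter_table(path) -> ParameterRegistry:
    """Load a parameter table from CSV (or an equivalent JSON array of records).

    The CSV header must be exactly the columns
    ``name,family,mean,ci_low,ci_high,group,units,source``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise SchemaError(f"{path}: empty parameter table")
    if path.suffix.lower() == ".json":
        records = json.loads(text)
        if not isinstance(records, list) or not records:
            raise SchemaError(f"{path}: expected a non-empty JSON array of rows")
        for r in records:
            missing = [c for c in REQUIRED_COLUMNS if c not in r]
            if missing:
                raise SchemaError(f"{path}: row missing columns {missing}")
        frame = pd.DataFrame(records)
    else:
        frame = pd.read_csv(io.StringIO(text))
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        if frame.empty:
            raise SchemaError(f"{path}: no parameter rows")
    registry = ParameterRegistry()
    for _, row in frame.iterrows():
        registry.add(_row_to_spec(row))
    registry.validate()
    return registry
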