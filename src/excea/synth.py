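"""Synthetic age-indexed inputs and the packaged parameter fixture.

The cohort model needs two age-indexed tables that are published elsewhere
and not shipped with the parameter table: a female period life table (annual
background death probability ``qx`` by integer age) and age-specific baseline
EQ-5D utilities.  This module generates realistic synthetic stand-ins so the
whole pipeline runs self-contained:

* :func:`generate_life_table` — Gompertz–Makeham hazard
  ``h(x) = a + b * c**x``, ``qx = 1 - exp(-h(x))``.  The defaults
  (``a=2e-4, b=1.2e-5, c=1.105``) give a period life expectancy at age 64 of
  about 23 years and ``q64 ≈ 0.007`` — consistent with a contemporary
  high-income-country female life table.  Both files use the CSV schema
  ``age,<value>``, so a real national life table (e.g. the ABS 2022 female
  table) can be dropped into the same slot for exact-reproduction runs.
* :func:`generate_utility_table` — linear decline
  ``u(age) = clamp(u_ref - slope * (age - 60) / 10, 0, 1)`` with
  ``u_ref = 0.81`` at age 60 and 0.03 lost per decade, the shape of published
  population EQ-5D-3L norms for older women.

:func:`write_fixture_bundle` writes these plus the packaged transcription of
the model's published parameter table and a default run config, giving a
complete, deterministic input set.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "AgeUtilityTable",
    "generate_life_table",
    "generate_utility_table",
    "life_expectancy",
    "packaged_parameter_table",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class _AgeTable:
    """Integer-age-indexed column of values (contiguous age range)."""

    ages: np.ndarray
    values: np.ndarray
    value_name: str = "value"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1:
            raise ValueError("ages and values must be equal-length 1-d arrays")
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise ValueError("ages must be contiguous integers")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def at(self, age):
        """Value(s) at integer age(s); raises if outside the table range."""
        age = np.asarray(age)
        idx = np.rint(age).astype(int) - self.min_age
        if np.any(idx < 0) or np.any(idx >= len(self.ages)):
            raise ValueError(
                f"age outside table range [{self.min_age}, {self.max_age}]"
            )
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, self.value_name: self.values})

    def to_csv(self, path) -> None:
        # %.17g keeps the float64 round trip exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, value_name: str):
        frame = pd.read_csv(path, float_precision="round_trip")
        if "age" not in frame.columns:
            raise ValueError(f"{path}: expected columns age,{value_name}")
        col = value_name if value_name in frame.columns else frame.columns[1]
        return cls(frame["age"].to_numpy(), frame[col].to_numpy(), value_name)


class LifeTable(_AgeTable):
    """age -> annual probability of death ``qx``."""

    def __init__(self, ages, qx):
        super().__init__(ages, qx, "qx")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("qx must lie in [0, 1]")

    def qx_at(self, age):
        return self.at(age)

    @classmethod
    def from_csv(cls, path, value_name: str = "qx"):
        t = _AgeTable.from_csv(path, value_name)
        return cls(t.ages, t.values)


class AgeUtilityTable(_AgeTable):
    """age -> baseline utility in [0, 1]."""

    def __init__(self, ages, utility):
        super().__init__(ages, utility, "utility")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("utility must lie in [0, 1]")

    def utility_at(self, age):
        return self.at(age)

    @classmethod
    def from_csv(cls, path, value_name: str = "utility"):
        t = _AgeTable.from_csv(path, value_name)
        return cls(t.ages, t.values)


def generate_life_table(
    makeham_a: float = 2e-4,
    gompertz_b: float = 1.2e-5,
    gompertz_c: float = 1.105,
    max_age: int = 110,
) -> LifeTable:
    """Gompertz–Makeham synthetic female life table (see module docstring)."""
    if makeham_a < 0 or gompertz_b <= 0 or gompertz_c <= 1:
        raise ValueError("require a >= 0, b > 0, c > 1")
    ages = np.arange(0, max_age + 1)
    hazard = makeham_a + gompertz_b * gompertz_c ** ages.astype(float)
    qx = np.clip(-np.expm1(-hazard), 0.0, 1.0)
    if np.any(qx[ages < 90] >= 1.0):
        warnings.warn(
            "hazard parameters drive qx to 1 before age 90", RuntimeWarning, stacklevel=2
        )
    qx[-1] = 1.0  # closure of the table
    return LifeTable(ages, qx)


def generate_utility_table(
    u_ref: float = 0.81,
    slope: float = 0.03,
    age_range: tuple[int, int] = (0, 110),
) -> AgeUtilityTable:
    """Linear age-declining baseline utility anchored at ``u_ref`` at age 60."""
    if not 0.0 < u_ref <= 1.0:
        raise ValueError("u_ref must lie in (0, 1]")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    ages = np.arange(age_range[0], age_range[1] + 1)
    u = np.clip(u_ref - slope * (ages - 60) / 10.0, 0.0, 1.0)
    return AgeUtilityTable(ages, u)


def life_expectancy(life_table: LifeTable, age: int) -> float:
    """Period life expectancy at ``age`` (trapezoid within the year of death)."""
    q = life_table.values[int(age) - life_table.min_age:]
    survival = np.cumprod(1.0 - q)
    return float(survival.sum() + 0.5)


def packaged_parameter_table() -> Path:
    """Path to the packaged transcription of the published parameter table."""
    return Path(resources.files("excea").joinpath("data/parameters.csv"))


DEFAULT_CONFIG = {
    "horizon": 5,
    "discount_rate": 0.05,
    "wtp": 50000.0,
    "iterations": 10000,
    "seed": 2023,
    "fatal_event_cost": None,
    "extended_supervision": False,
    "sweep": [1, 10],
}


def write_fixture_bundle(outdir, seed: int = 2023) -> dict[str, Path]:
    """Write the complete input set: parameter table, life table, utility
    table, default run config and a manifest.  Byte-deterministic for a given
    seed (the tables themselves are deterministic; the seed is recorded for
    downstream Monte Carlo runs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params_path = outdir / "parameters.csv"
    params_path.write_text(packaged_parameter_table().read_text())

    life = generate_life_table()
    util = generate_utility_table()
    life_path = outdir / "life_table.csv"
    util_path = outdir / "utility_table.csv"
    life.to_csv(life_path)
    util.to_csv(util_path)

    # paths are bundle-relative so the bundle is byte-identical wherever written
    config = dict(DEFAULT_CONFIG, seed=int(seed))
    config.update(
        params=params_path.name, life_table=life_path.name, utilities=util_path.name
    )
    config_path = outdir / "config.json"
    config_path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")

    files = {
        "parameters": params_path,
        "life_table": life_path,
        "utility_table": util_path,
        "config": config_path,
    }
    manifest = {
        "seed": int(seed),
        "generator": {
            "life_table": {"makeham_a": 2e-4, "gompertz_b": 1.2e-5, "gompertz_c": 1.105, "max_age": 110},
            "utility_table": {"u_ref": 0.81, "slope": 0.03, "age_range": [0, 110]},
        },
        "sha256": {
            k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in files.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path
    return files
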