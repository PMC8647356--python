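"""Age-indexed all-cause mortality for the cohort model.

The model needs, for every cohort age, the annual probability of dying of
any cause, and its conversion to the 4-week cycle used by the Markov
engine.  Tables can be loaded from a two/three-column CSV (``age,qx[,sex]``)
or generated from a Gompertz-Makeham hazard when no national life table is
at hand.  The generated table and the loader share one file format, so the
two round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import DAYS_PER_YEAR

__all__ = [
    "LifeTable",
    "LifeTableError",
    "load_life_table",
    "synthetic_life_table",
    "annual_to_cycle_probability",
    "cycle_to_annual_probability",
    "DEFAULT_MAKEHAM_A",
    "DEFAULT_GOMPERTZ_B",
    "DEFAULT_GOMPERTZ_C",
]

# Gompertz-Makeham constants giving a life expectancy of roughly 77 years
# from birth: hazard(age) = a + b * exp(c * age).
DEFAULT_MAKEHAM_A = 5e-4     # age-independent background hazard, per year
DEFAULT_GOMPERTZ_B = 3e-5    # senescent hazard at age 0, per year
DEFAULT_GOMPERTZ_C = 0.09    # exponential growth of senescent hazard, per year


class LifeTableError(ValueError):
    """A life-table file or construction violates the table contract."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities on a contiguous integer age grid.

    ``qx[i]`` is the probability of dying within the year for a person of
    exact age ``ages[i]``.  Ages are strictly increasing and contiguous and
    the final age carries ``qx = 1`` so the horizon is absorbing.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or qx.shape != ages.shape or ages.size == 0:
            raise LifeTableError("life table must be two equal-length 1-d columns")
        diffs = np.diff(ages)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise LifeTableError(
                f"ages must be strictly increasing; offending row {i + 1} "
                f"(age {ages[i + 1]})")
        if np.any(diffs != 1):
            i = int(np.argmax(diffs != 1))
            raise LifeTableError(
                f"ages must be contiguous; gap after age {ages[i]} (row {i})")
        bad = (qx < 0) | (qx > 1) | ~np.isfinite(qx)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise LifeTableError(
                f"death probability out of [0, 1] at age {ages[i]} (row {i}): {qx[i]}")
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"final age {ages[-1]} must be absorbing (qx = 1), got {qx[-1]}")

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def end_age(self) -> int:
        return int(self.ages[-1])

    def q_annual(self, age: float | np.ndarray) -> np.ndarray:
        """Annual death probability at (possibly fractional) age, clamped to the grid."""
        idx = np.clip(np.floor(np.asarray(age, dtype=float)).astype(int) - self.start_age,
                      0, self.ages.size - 1)
        return self.qx[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a life table from CSV with columns ``age,qx`` and optional ``sex``.

    When a ``sex`` column is present the per-age probabilities are averaged
    into a single unisex column (the cohort is not sex-stratified).
    Missing or duplicated ages and probabilities outside [0, 1] are errors.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise LifeTableError(f"cannot read life table {path}: {exc}") from exc
    cols = {c.lower().strip(): c for c in df.columns}
    if "age" not in cols or "qx" not in cols:
        raise LifeTableError(
            f"life table {path} must have columns 'age' and 'qx'; got {list(df.columns)}")
    df = df.rename(columns={cols["age"]: "age", cols["qx"]: "qx"})
    if "sex" in cols:
        df = df.rename(columns={cols["sex"]: "sex"})
        df = df.groupby("age", as_index=False)["qx"].mean()
    else:
        dup = df["age"].duplicated()
        if dup.any():
            i = int(np.argmax(dup.to_numpy()))
            raise LifeTableError(
                f"duplicate age {df['age'].iloc[i]} at row {i} of {path}")
    df = df.sort_values("age")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def synthetic_life_table(
    start_age: int = 0,
    end_age: int = 100,
    makeham_a: float = DEFAULT_MAKEHAM_A,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    gompertz_c: float = DEFAULT_GOMPERTZ_C,
) -> LifeTable:
    """Generate a unisex life table from a Gompertz-Makeham hazard.

    The annual death probability at integer age ``x`` is
    ``q(x) = 1 - exp(-(a + b * exp(c * x)))``, clipped to [0, 1]; the final
    age is forced absorbing.  The defaults approximate a population with
    life expectancy near 77 years at birth.
    """
    if makeham_a < 0 or gompertz_b <= 0 or gompertz_c <= 0:
        raise LifeTableError(
            "require makeham_a >= 0, gompertz_b > 0, gompertz_c > 0; got "
            f"a={makeham_a}, b={gompertz_b}, c={gompertz_c}")
    if end_age <= start_age:
        raise LifeTableError("end_age must exceed start_age")
    ages = np.arange(int(start_age), int(end_age) + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx = np.clip(-np.expm1(-hazard), 0.0, 1.0)
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def annual_to_cycle_probability(q_annual, cycle_length_days: int):
    """Convert an annual death probability to a per-cycle probability.

    Assumes a constant hazard within the year:
    ``q_cycle = 1 - (1 - q_annual) ** (cycle_length_days / 365.25)``.
    Accepts scalars or arrays.
    """
    q = np.asarray(q_annual, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"annual probability outside [0, 1]: {q_annual}")
    if cycle_length_days <= 0:
        raise ValueError("cycle_length_days must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(np.log1p(-q) * (cycle_length_days / DAYS_PER_YEAR))
        out = np.where(q >= 1.0, 1.0, out)  # log1p(-1) = -inf; pin exactly
    return out if out.ndim else float(out)


def cycle_to_annual_probability(q_cycle, cycle_length_days: int):
    """Inverse of :func:`annual_to_cycle_probability`."""
    q = np.asarray(q_cycle, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"cycle probability outside [0, 1]: {q_cycle}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(np.log1p(-q) * (DAYS_PER_YEAR / cycle_length_days))
        out = np.where(q >= 1.0, 1.0, out)
    return out if out.ndim else float(out)
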