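"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full model twice per ranged input (at its low and
high bound, everything else at base) and records the incremental net
monetary benefit, yielding a tornado table sorted by swing.  The PSA
draws every uncertain input from a parametric distribution — beta for
utilities and (range-rescaled) for the treatment-effect ratios, gamma for
costs, Dirichlet for each transition-probability row — and reruns both
strategies per draw, producing the cost-effectiveness-plane quadrant
shares and the acceptability curve.

Range-to-distribution conventions, applied uniformly:

* utilities: beta with mean equal to the base value and the (low, high)
  range read as a central 95% interval (SD = range / 3.92), parameters by
  moment matching;
* costs: gamma with mean pinned at the base value and shape fitted so the
  2.5th/97.5th percentiles track the (low, high) interval;
* effect ratios: beta rescaled to the [low, high] support with mean at
  the base value and SD equal to a quarter of the range;
* transition rows: Dirichlet with mean equal to the base row and
  concentration chosen so the leading probability's SD is a quarter of
  its range.

Adherence, dosing intensity and the discount rate are held fixed in the
PSA (they are varied in the one-way analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats

from .economics import incremental_analysis
from .markov import InfeasibleParameterError, run_strategy
from .mortality import LifeTable
from .parameters import (
    FIELD_REGISTRY,
    ParameterSet,
    Strategy,
    get_ranged,
    set_ranged_base,
    validate_parameters,
)

__all__ = [
    "DistributionSpecError",
    "TornadoEntry",
    "one_way_dsa",
    "make_psa_distributions",
    "PSAResult",
    "run_psa",
    "classify_quadrants",
    "quadrant_labels",
    "ceac",
    "default_wtp_grid",
]


class DistributionSpecError(ValueError):
    """A sensitivity range is incompatible with its assigned distribution."""


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis (tornado)


@dataclass(frozen=True)
class TornadoEntry:
    parameter_name: str
    outcome_at_low: float
    outcome_at_high: float
    swing: float
    icer_at_low: float | None = None
    icer_at_high: float | None = None
    note: str = ""


def _incremental(params: ParameterSet, life_table: LifeTable, wtp: float):
    _, an = run_strategy(params, life_table, Strategy.AS_NEEDED_ICS_FORMOTEROL)
    _, maint = run_strategy(params, life_table, Strategy.MAINTENANCE_ICS)
    return incremental_analysis(an, maint, wtp)


def one_way_dsa(
    params: ParameterSet,
    life_table: LifeTable,
    wtp: float | None = None,
) -> list[TornadoEntry]:
    """Tornado analysis: incremental NMB at each input's low and high bound.

    The outcome metric is incremental net monetary benefit at the
    configured willingness-to-pay (the ICER is additionally recorded for
    excursions where it is defined).  Entries are sorted by swing,
    largest first.  A model infeasibility at an extreme is recorded in the
    entry's note rather than dropped.
    """
    if wtp is None:
        wtp = params.settings.wtp_per_qaly
    entries = []
    for spec in FIELD_REGISTRY:
        rv = get_ranged(params, spec.name)
        outcomes: dict[str, float] = {}
        icers: dict[str, float | None] = {}
        notes = []
        for bound, value in (("low", rv.low), ("high", rv.high)):
            try:
                res = _incremental(
                    set_ranged_base(params, spec.name, value), life_table, wtp)
                outcomes[bound] = res.nmb_at_wtp
                icers[bound] = res.icer
            except InfeasibleParameterError as exc:
                outcomes[bound] = float("nan")
                icers[bound] = None
                notes.append(f"infeasible at {bound}: {exc}")
        entries.append(TornadoEntry(
            parameter_name=spec.name,
            outcome_at_low=outcomes["low"],
            outcome_at_high=outcomes["high"],
            swing=abs(outcomes["high"] - outcomes["low"]),
            icer_at_low=icers["low"],
            icer_at_high=icers["high"],
            note="; ".join(notes),
        ))
    entries.sort(key=lambda e: (-(e.swing if np.isfinite(e.swing) else np.inf),
                                e.parameter_name))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {"parameter": e.parameter_name, "low_outcome": e.outcome_at_low,
         "high_outcome": e.outcome_at_high, "swing": e.swing,
         "icer_low": e.icer_at_low, "icer_high": e.icer_at_high, "note": e.note}
        for e in entries
    ])


# ---------------------------------------------------------------------------
# PSA distributions

_CI_WIDTH_SD = 2.0 * 1.959963984540054  # central 95% interval in SD units


@dataclass(frozen=True)
class PointMass:
    value: float
    kind: str = "point"

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator) -> float:
        return self.value


@dataclass(frozen=True)
class BetaMeanCI:
    """Beta on [0, 1] with given mean and SD (moment matched)."""

    alpha: float
    beta: float
    kind: str = "beta"

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, name: str) -> "BetaMeanCI":
        var = sd * sd
        if not 0.0 < mean < 1.0:
            raise DistributionSpecError(
                f"{name}: beta mean must be in (0, 1), got {mean}")
        if var >= mean * (1.0 - mean):
            raise DistributionSpecError(
                f"{name}: variance {var:.4g} too large for a beta with mean {mean}")
        nu = mean * (1.0 - mean) / var - 1.0
        return cls(alpha=mean * nu, beta=(1.0 - mean) * nu)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class RescaledBeta:
    """Beta rescaled to [low, high], mean at base, SD a quarter of the range."""

    low: float
    high: float
    alpha: float
    beta: float
    kind: str = "beta_rescaled"

    @classmethod
    def from_range(cls, base: float, low: float, high: float, name: str) -> "RescaledBeta":
        width = high - low
        m = (base - low) / width
        inner = BetaMeanCI.from_mean_sd(m, 0.25, name)  # SD = width/4 on unit scale
        return cls(low=low, high=high, alpha=inner.alpha, beta=inner.beta)

    @property
    def mean(self) -> float:
        return self.low + (self.high - self.low) * self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.low + (self.high - self.low)
                     * rng.beta(self.alpha, self.beta))


@dataclass(frozen=True)
class GammaMeanCI:
    """Gamma with given mean and SD (moment matched)."""

    shape: float
    scale: float
    kind: str = "gamma"

    @classmethod
    def from_mean_sd(cls, mean: float, sd: float, name: str) -> "GammaMeanCI":
        if mean <= 0 or sd <= 0:
            raise DistributionSpecError(
                f"{name}: gamma needs positive mean and SD, got {mean}, {sd}")
        return cls(shape=(mean / sd) ** 2, scale=sd * sd / mean)

    @classmethod
    def from_mean_ci(cls, mean: float, low: float, high: float,
                     name: str) -> "GammaMeanCI":
        """Mean pinned at ``mean``; shape fitted so the 2.5th/97.5th
        percentiles track the (low, high) interval (least squares on the
        relative percentile errors, refining the moment-matched start)."""
        if not 0 <= low < mean < high:
            raise DistributionSpecError(
                f"{name}: need low < mean < high, got ({low}, {mean}, {high})")
        start = cls.from_mean_sd(mean, (high - low) / _CI_WIDTH_SD, name)

        def objective(log_shape: float) -> float:
            k = np.exp(log_shape)
            p_lo, p_hi = sp_stats.gamma.ppf([0.025, 0.975], k, scale=mean / k)
            return ((p_lo - low) / low) ** 2 + ((p_hi - high) / high) ** 2

        res = sp_optimize.minimize_scalar(
            objective, bounds=(np.log(start.shape / 16), np.log(start.shape * 16)),
            method="bounded")
        shape = float(np.exp(res.x))
        return cls(shape=shape, scale=mean / shape)

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.gamma(self.shape, self.scale))


@dataclass(frozen=True)
class DirichletRow:
    """Two-component Dirichlet over (event, residual) of one transition row."""

    alpha: tuple[float, float]
    kind: str = "dirichlet"

    @classmethod
    def from_mean_sd(cls, p: float, sd: float, name: str) -> "DirichletRow":
        var = sd * sd
        if not 0.0 < p < 1.0:
            raise DistributionSpecError(
                f"{name}: row probability must be in (0, 1), got {p}")
        if var >= p * (1.0 - p):
            raise DistributionSpecError(
                f"{name}: variance {var:.4g} too large for Dirichlet with mean {p}")
        conc = p * (1.0 - p) / var - 1.0
        return cls(alpha=(p * conc, (1.0 - p) * conc))

    @property
    def mean(self) -> float:
        return self.alpha[0] / sum(self.alpha)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.dirichlet(self.alpha)[0])


def make_psa_distributions(params: ParameterSet) -> dict[str, object]:
    """Assign a sampling distribution to every ranged input, in registry order.

    Degenerate ranges (low = high) become point masses; inputs outside the
    published distribution families (adherence, dosing, discounting) are
    held at their base value.
    """
    out: dict[str, object] = {}
    for spec in FIELD_REGISTRY:
        rv = get_ranged(params, spec.name)
        if spec.psa_family == "fixed" or rv.high == rv.low:
            out[spec.name] = PointMass(rv.base)
            continue
        sd_ci = (rv.high - rv.low) / _CI_WIDTH_SD
        sd_quarter = (rv.high - rv.low) / 4.0
        if spec.psa_family == "beta_ci":
            out[spec.name] = BetaMeanCI.from_mean_sd(rv.base, sd_ci, spec.name)
        elif spec.psa_family == "gamma_ci":
            out[spec.name] = GammaMeanCI.from_mean_ci(
                rv.base, rv.low, rv.high, spec.name)
        elif spec.psa_family == "beta_rescaled":
            out[spec.name] = RescaledBeta.from_range(
                rv.base, rv.low, rv.high, spec.name)
        elif spec.psa_family == "dirichlet_row":
            out[spec.name] = DirichletRow.from_mean_sd(
                rv.base, sd_quarter, spec.name)
        else:  # pragma: no cover - registry is closed
            raise DistributionSpecError(
                f"{spec.name}: unknown PSA family {spec.psa_family}")
    return out


# ---------------------------------------------------------------------------
# CE-plane classification and acceptability curve


def quadrant_labels(delta_cost: np.ndarray, delta_qalys: np.ndarray) -> np.ndarray:
    """Quadrant (1-4) of each (delta cost, delta QALY) pair.

    Q1: costlier & more effective; Q2: cheaper & more effective;
    Q3: cheaper & less effective; Q4: costlier & less effective.
    Zero deltas are assigned to the non-negative side.
    """
    dc = np.asarray(delta_cost, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    cost_up = dc >= 0
    qaly_up = dq >= 0
    labels = np.empty(dc.shape, dtype=int)
    labels[cost_up & qaly_up] = 1
    labels[~cost_up & qaly_up] = 2
    labels[~cost_up & ~qaly_up] = 3
    labels[cost_up & ~qaly_up] = 4
    return labels


def classify_quadrants(delta_cost, delta_qalys) -> np.ndarray:
    """Fractions of draws in CE-plane quadrants 1-4 (sums to 1 exactly)."""
    dc = np.atleast_1d(np.asarray(delta_cost, dtype=float))
    if dc.size == 0:
        raise ValueError("cannot classify an empty draw set")
    labels = quadrant_labels(dc, np.atleast_1d(np.asarray(delta_qalys, dtype=float)))
    return np.bincount(labels, minlength=5)[1:] / labels.size


def ceac(delta_cost, delta_qalys, wtp_grid) -> pd.DataFrame:
    """Acceptability curve: P(NMB >= 0) at each willingness-to-pay value."""
    dc = np.atleast_1d(np.asarray(delta_cost, dtype=float))
    dq = np.atleast_1d(np.asarray(delta_qalys, dtype=float))
    if dc.size == 0:
        raise ValueError("cannot compute a CEAC from an empty draw set")
    grid = np.asarray(wtp_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("willingness-to-pay values must be >= 0")
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    return pd.DataFrame({"wtp": grid, "probability": (nmb >= 0).mean(axis=1)})


def default_wtp_grid(wtp: float, n: int = 39) -> np.ndarray:
    """Grid from 0 to twice the threshold (39 points: steps of 1,000 at 19,000)."""
    return np.linspace(0.0, 2.0 * wtp, n)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Paired Monte-Carlo draws and derived CE-plane / CEAC summaries."""

    draws: pd.DataFrame
    quadrant_proportions: np.ndarray
    mean_delta_cost: float
    mean_delta_qalys: float
    mean_delta_cost_per_person_year: float
    mean_delta_qalys_per_person_year: float
    ceac: pd.DataFrame
    seed: int
    iterations: int
    redraw_count: int = 0
    sampled_parameters: pd.DataFrame | None = field(default=None, repr=False)


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Counter-based substream: one child stream per PSA iteration.

    Derived from the root seed and the iteration index only, so adding
    parameters or iterations never reshuffles existing draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(iteration,)))


def sample_parameter_set(
    params: ParameterSet,
    distributions: dict[str, object],
    rng: np.random.Generator,
) -> ParameterSet:
    """Draw one parameter set, replacing each input's base value."""
    sampled = params
    for name, dist in distributions.items():
        sampled = set_ranged_base(sampled, name, dist.sample(rng))
    return sampled


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    iterations: int | None = None,
    seed: int | None = None,
    wtp_grid=None,
    keep_sampled: bool = False,
    max_redraw_factor: int = 10,
) -> PSAResult:
    """Second-order Monte-Carlo simulation of the full model.

    Each iteration draws one parameter set from
    :func:`make_psa_distributions`, runs both strategies through the
    cohort engine and records the paired cost and QALY differences
    (as-needed minus maintenance).  A draw that fails validation is
    redrawn from the same substream; total redraws are capped at
    ``max_redraw_factor`` times the iteration count.  Results are fully
    reproducible from the seed.
    """
    settings = params.settings
    if iterations is None:
        iterations = settings.psa_iterations
    if seed is None:
        seed = settings.rng_seed
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(settings.wtp_per_qaly)

    distributions = make_psa_distributions(params)
    records = []
    sampled_rows = []
    redraws = 0
    for i in range(iterations):
        rng = _iteration_rng(seed, i)
        while True:
            drawn = sample_parameter_set(params, distributions, rng)
            if not validate_parameters(drawn):
                break
            redraws += 1
            if redraws > max_redraw_factor * iterations:
                raise RuntimeError(
                    f"PSA redraw cap exceeded ({redraws} invalid draws)")
        _, an = run_strategy(drawn, life_table, Strategy.AS_NEEDED_ICS_FORMOTEROL)
        _, maint = run_strategy(drawn, life_table, Strategy.MAINTENANCE_ICS)
        records.append((
            i,
            an.total_discounted_cost - maint.total_discounted_cost,
            an.total_discounted_qalys - maint.total_discounted_qalys,
            an.cost_per_person_year - maint.cost_per_person_year,
            an.qalys_per_person_year - maint.qalys_per_person_year,
            an.total_discounted_cost, maint.total_discounted_cost,
            an.total_discounted_qalys, maint.total_discounted_qalys,
        ))
        if keep_sampled:
            sampled_rows.append(
                {name: get_ranged(drawn, name).base for name in distributions})

    draws = pd.DataFrame(records, columns=[
        "iteration", "delta_cost", "delta_qalys",
        "delta_cost_per_person_year", "delta_qalys_per_person_year",
        "cost_as_needed", "cost_maintenance",
        "qalys_as_needed", "qalys_maintenance",
    ])
    draws["quadrant"] = quadrant_labels(
        draws["delta_cost"].to_numpy(), draws["delta_qalys"].to_numpy())
    proportions = classify_quadrants(
        draws["delta_cost"].to_numpy(), draws["delta_qalys"].to_numpy())
    curve = ceac(draws["delta_cost"].to_numpy(),
                 draws["delta_qalys"].to_numpy(), wtp_grid)
    return PSAResult(
        draws=draws,
        quadrant_proportions=proportions,
        mean_delta_cost=float(draws["delta_cost"].mean()),
        mean_delta_qalys=float(draws["delta_qalys"].mean()),
        mean_delta_cost_per_person_year=float(
            draws["delta_cost_per_person_year"].mean()),
        mean_delta_qalys_per_person_year=float(
            draws["delta_qalys_per_person_year"].mean()),
        ceac=curve,
        seed=seed,
        iterations=iterations,
        redraw_count=redraws,
        sampled_parameters=pd.DataFrame(sampled_rows) if keep_sampled else None,
    )
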