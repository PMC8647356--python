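"""Markov cohort engine for the asthma cost-utility model.

Six health states are tracked: CONTROLLED, three one-cycle exacerbation
states of increasing severity (OCS_BURST, ED_VISIT, HOSPITALIZATION) and
two absorbing death states (ASTHMA_DEATH, OTHER_DEATH).  Asthma death is
reachable only from hospitalization; all-cause death can occur from any
alive state.  The cohort starts fully controlled, advances in 4-week
cycles over a lifetime horizon, and accumulates discounted, half-cycle-
corrected costs and quality-adjusted life-years.

Structure of one cycle, per alive state:

1. other-cause death is applied first (competing risk, from the life
   table converted to a per-cycle probability);
2. survivors take the disease transition for their state — controlled
   patients may enter an OCS burst, an OCS burst may escalate to an ED
   visit, an ED visit to a hospitalization, and a hospitalization to
   asthma death;
3. survivors of an exacerbation state who do not escalate return to
   CONTROLLED, which also receives any residual row probability.

For the as-needed ICS-formoterol arm, the exacerbation-entry probability
is scaled by a rate ratio (constant-hazard transform) and the OCS-burst →
ED transition by an odds ratio (or a rate ratio, configurable).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import LifeTable, annual_to_cycle_probability
from .parameters import (
    DAYS_PER_YEAR,
    ModelSettings,
    ParameterSet,
    Strategy,
)

__all__ = [
    "HealthState",
    "CohortTrace",
    "OutcomeSummary",
    "InfeasibleParameterError",
    "prob_to_rate",
    "rate_to_prob",
    "apply_relative_risk",
    "apply_odds_ratio",
    "effective_transition_probs",
    "build_transition_matrix",
    "run_cohort",
    "drug_cost_per_cycle",
    "accumulate_outcomes",
    "run_strategy",
]

N_STATES = 6


class HealthState(enum.IntEnum):
    CONTROLLED = 0
    OCS_BURST = 1
    ED_VISIT = 2
    HOSPITALIZATION = 3
    ASTHMA_DEATH = 4
    OTHER_DEATH = 5


ALIVE = slice(0, 4)


class InfeasibleParameterError(ValueError):
    """A transition-matrix row cannot be completed to a probability row."""


# ---------------------------------------------------------------------------
# elementary probability transforms


def prob_to_rate(p: float, t: float = 1.0) -> float:
    """Constant-hazard rate underlying probability ``p`` over ``t`` cycles."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1) (p = 1 gives an infinite rate): {p}")
    if t <= 0:
        raise ValueError("duration must be positive")
    return -math.log1p(-p) / t


def rate_to_prob(r: float, t: float = 1.0) -> float:
    """Probability of at least one event at constant rate ``r`` over ``t`` cycles."""
    if r < 0 or t <= 0:
        raise ValueError("rate must be >= 0 and duration > 0")
    return -math.expm1(-r * t)


def apply_relative_risk(p: float, rr: float) -> float:
    """Scale probability ``p`` by rate ratio ``rr`` on the hazard scale.

    ``p' = 1 - (1 - p) ** rr``, i.e. the underlying constant rate is
    multiplied by ``rr``.  Identity at ``rr = 1``; decreasing in ``rr < 1``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1): {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be > 0: {rr}")
    return -math.expm1(rr * math.log1p(-p))


def apply_odds_ratio(p: float, odds_ratio: float) -> float:
    """Apply odds ratio ``odds_ratio`` to probability ``p`` on the odds scale."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1): {p}")
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be > 0: {odds_ratio}")
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# transition structure


def effective_transition_probs(
    params: ParameterSet, strategy: Strategy
) -> tuple[float, float, float, float]:
    """Per-cycle disease transition probabilities after treatment effects.

    Returns ``(p_exac, p_ed, p_hosp, p_asthma_death)`` — entry into an OCS
    burst from controlled, escalation OCS burst → ED, ED → hospitalization,
    and hospitalization → asthma death.  The maintenance arm uses the raw
    base-case probabilities; the as-needed arm applies the exacerbation
    rate ratio and the ED-visit effect (odds or risk scale per settings).
    """
    t = params.transitions
    p_exac = t.p_controlled_to_ocs_burst.base
    p_ed = t.p_ocs_burst_to_ed.base
    p_hosp = t.p_ed_to_hospitalization.base
    p_ad = t.p_hospitalization_to_asthma_death.base
    if strategy is Strategy.AS_NEEDED_ICS_FORMOTEROL:
        rr = params.effects.rr_exacerbation.base
        ed_effect = params.effects.or_ed_visit.base
        if params.settings.adherence_scales_effect:
            adh = params.effects.adherence_as_needed.base
            rr = 1.0 + adh * (rr - 1.0)
            ed_effect = 1.0 + adh * (ed_effect - 1.0)
        p_exac = apply_relative_risk(p_exac, rr)
        if params.settings.ed_effect_scale == "odds":
            p_ed = apply_odds_ratio(p_ed, ed_effect)
        else:
            p_ed = apply_relative_risk(p_ed, ed_effect)
    return p_exac, p_ed, p_hosp, p_ad


def _matrix_from_probs(
    p_exac: float, p_ed: float, p_hosp: float, p_ad: float, q_other: float
) -> np.ndarray:
    """Assemble one 6x6 cycle matrix given disease and mortality probabilities."""
    m = np.zeros((N_STATES, N_STATES))
    rows = {
        HealthState.CONTROLLED: ((HealthState.OCS_BURST, p_exac),),
        HealthState.OCS_BURST: ((HealthState.ED_VISIT, p_ed),),
        HealthState.ED_VISIT: ((HealthState.HOSPITALIZATION, p_hosp),),
        HealthState.HOSPITALIZATION: ((HealthState.ASTHMA_DEATH, p_ad),),
    }
    for state, branches in rows.items():
        survive = 1.0 - q_other
        m[state, HealthState.OTHER_DEATH] = q_other
        used = q_other
        for dest, p in branches:
            m[state, dest] = survive * p
            used += survive * p
        if used > 1.0 + 1e-12:
            raise InfeasibleParameterError(
                f"row {state.name}: transition probabilities sum to {used:.6g} > 1")
        # residual probability returns to (or stays in) CONTROLLED
        m[state, HealthState.CONTROLLED] += 1.0 - used
    m[HealthState.ASTHMA_DEATH, HealthState.ASTHMA_DEATH] = 1.0
    m[HealthState.OTHER_DEATH, HealthState.OTHER_DEATH] = 1.0
    return m


def build_transition_matrix(
    params: ParameterSet,
    life_table: LifeTable,
    age: float,
    strategy: Strategy,
) -> np.ndarray:
    """One-cycle transition matrix for a cohort of the given age and strategy."""
    q_cycle = annual_to_cycle_probability(
        float(life_table.q_annual(age)), params.settings.cycle_length_days)
    return _matrix_from_probs(*effective_transition_probs(params, strategy), q_cycle)


# ---------------------------------------------------------------------------
# cohort recursion


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy for one strategy.

    ``occupancy`` has one row per cycle boundary (``n_cycles + 1`` rows);
    ``cycle_ages`` is the cohort age at each boundary and
    ``cycle_death_prob`` the per-cycle other-cause death probability used
    for each of the ``n_cycles`` transitions.
    """

    occupancy: np.ndarray
    cycle_ages: np.ndarray
    cycle_death_prob: np.ndarray
    strategy: Strategy

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.occupancy,
            columns=[s.name.lower() for s in HealthState],
        )
        df.insert(0, "age", self.cycle_ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def cycle_mortality(
    life_table: LifeTable, settings: ModelSettings
) -> tuple[np.ndarray, np.ndarray]:
    """Cohort ages at each cycle boundary and per-cycle death probabilities.

    The run covers the span from the starting age to the horizon age plus
    one extra cycle; the life table's absorbing final age then empties the
    cohort once it passes the horizon.
    """
    cyc_years = settings.cycle_length_days / DAYS_PER_YEAR
    span = settings.horizon_age_years - settings.starting_age_years
    n_cycles = int(math.ceil(span / cyc_years)) + 1
    ages = settings.starting_age_years + np.arange(n_cycles + 1) * cyc_years
    q_annual = life_table.q_annual(ages[:n_cycles])
    q_cycle = annual_to_cycle_probability(q_annual, settings.cycle_length_days)
    return ages, np.asarray(q_cycle, dtype=float)


def run_cohort(
    params: ParameterSet,
    life_table: LifeTable,
    strategy: Strategy,
) -> CohortTrace:
    """Run the cohort recursion for one strategy over the lifetime horizon.

    The cohort starts entirely in CONTROLLED at the starting age; each
    cycle applies the age-appropriate transition matrix.  Matrices are
    rebuilt only when the annual death probability changes (once per year
    of age), which keeps long horizons cheap.
    """
    ages, q_cycle = cycle_mortality(life_table, params.settings)
    probs = effective_transition_probs(params, strategy)
    n = q_cycle.size
    occ = np.zeros((n + 1, N_STATES))
    occ[0, HealthState.CONTROLLED] = 1.0
    matrix = None
    current_q = None
    state = occ[0]
    for t in range(n):
        q = q_cycle[t]
        if q != current_q:
            matrix = _matrix_from_probs(*probs, q)
            current_q = q
        state = state @ matrix
        occ[t + 1] = state
    return CohortTrace(occupancy=occ, cycle_ages=ages,
                       cycle_death_prob=q_cycle, strategy=strategy)


# ---------------------------------------------------------------------------
# payoffs


def drug_cost_per_cycle(params: ParameterSet, strategy: Strategy) -> float:
    """Inhaler cost per 4-week cycle for one strategy.

    Maintenance: two scheduled doses per day, scaled by maintenance
    adherence.  As-needed: the observed reliever use in doses per day,
    scaled by as-needed adherence.
    """
    per_dose = params.costs.drug_cost_per_120_doses.base / 120.0
    if strategy is Strategy.MAINTENANCE_ICS:
        doses_per_day = 2.0 * params.effects.adherence_maintenance.base
    else:
        doses_per_day = (params.effects.as_needed_doses_per_day.base
                         * params.effects.adherence_as_needed.base)
    return per_dose * doses_per_day * params.settings.cycle_length_days


@dataclass(frozen=True)
class OutcomeSummary:
    """Discounted totals and per-person-year outcomes for one strategy."""

    strategy: Strategy
    total_discounted_cost: float
    total_discounted_qalys: float
    person_years_alive: float
    cost_per_person_year: float
    qalys_per_person_year: float
    exacerbation_free_survival: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "strategy": self.strategy.value,
            "total_discounted_cost": self.total_discounted_cost,
            "total_discounted_qalys": self.total_discounted_qalys,
            "person_years_alive": self.person_years_alive,
            "cost_per_person_year": self.cost_per_person_year,
            "qalys_per_person_year": self.qalys_per_person_year,
            "exacerbation_free_survival": self.exacerbation_free_survival,
        }


def _total(per_cycle_discounted: np.ndarray, half_cycle: bool) -> float:
    """Sum a discounted boundary payoff stream over cycles.

    With half-cycle correction the stream is integrated by the trapezoid
    rule across consecutive boundaries; otherwise the cycle-start value is
    taken for each cycle.
    """
    v = per_cycle_discounted
    if half_cycle:
        return float(0.5 * (v[:-1] + v[1:]).sum())
    return float(v[:-1].sum())


def exacerbation_free_survival(
    trace: CohortTrace, params: ParameterSet, strategy: Strategy
) -> float:
    """Probability of never leaving CONTROLLED by the landmark time.

    A first-passage companion recursion in which any exacerbation entry
    (and death) is absorbing; evaluated at ``efs_landmark_years`` after
    model start (default one year, 13 cycles of 28 days).
    """
    settings = params.settings
    p_exac = effective_transition_probs(params, strategy)[0]
    landmark_cycles = round(settings.efs_landmark_years * DAYS_PER_YEAR
                            / settings.cycle_length_days)
    landmark_cycles = min(landmark_cycles, trace.n_cycles)
    s = 1.0
    for t in range(landmark_cycles):
        s *= (1.0 - trace.cycle_death_prob[t]) * (1.0 - p_exac)
    return float(s)


def accumulate_outcomes(
    trace: CohortTrace,
    params: ParameterSet,
    strategy: Strategy | None = None,
) -> OutcomeSummary:
    """Accumulate discounted costs, QALYs and person-years from a trace.

    Per cycle boundary, the QALY payoff is occupancy-weighted annual
    utility prorated to the cycle length; the cost payoff is drug cost
    plus prorated background management cost over alive states, plus
    per-episode exacerbation costs (mild for an OCS burst, moderate for an
    ED visit, severe for a hospitalization) applied to the incident
    occupancy of the one-cycle exacerbation states.  Discounting is
    continuous-equivalent per-cycle at the annual rate; half-cycle
    correction integrates the discounted stream by the trapezoid rule.
    """
    if strategy is None:
        strategy = trace.strategy
    settings = params.settings
    occ = trace.occupancy
    if occ.shape[1] != N_STATES:
        raise ValueError(
            f"trace has {occ.shape[1]} states, expected {N_STATES}")
    cyc_years = settings.cycle_length_days / DAYS_PER_YEAR
    n_rows = occ.shape[0]

    u = params.utilities
    utility = np.array([u.u_controlled.base, u.u_ocs_burst.base,
                        u.u_ed_visit.base, u.u_hospitalization.base, 0.0, 0.0])
    qaly_payoff = occ @ utility * cyc_years

    alive = occ[:, ALIVE].sum(axis=1)
    c = params.costs
    membership_cost = (drug_cost_per_cycle(params, strategy)
                       + c.annual_cost_controlled.base * cyc_years)
    episode_cost = (occ[:, HealthState.OCS_BURST] * c.cost_mild_exacerbation.base
                    + occ[:, HealthState.ED_VISIT] * c.cost_moderate_exacerbation.base
                    + occ[:, HealthState.HOSPITALIZATION] * c.cost_severe_exacerbation.base)
    cost_payoff = alive * membership_cost + episode_cost

    rate = settings.annual_discount_rate.base
    discount = (1.0 + rate) ** (-np.arange(n_rows) * cyc_years)

    hc = settings.half_cycle_correction
    total_cost = _total(cost_payoff * discount, hc)
    total_qalys = _total(qaly_payoff * discount, hc)
    person_years = _total(alive * cyc_years * discount, hc)

    efs = exacerbation_free_survival(trace, params, strategy)
    return OutcomeSummary(
        strategy=strategy,
        total_discounted_cost=total_cost,
        total_discounted_qalys=total_qalys,
        person_years_alive=person_years,
        cost_per_person_year=total_cost / person_years,
        qalys_per_person_year=total_qalys / person_years,
        exacerbation_free_survival=efs,
    )


def run_strategy(
    params: ParameterSet, life_table: LifeTable, strategy: Strategy
) -> tuple[CohortTrace, OutcomeSummary]:
    """Convenience: run the cohort and accumulate outcomes for one strategy."""
    trace = run_cohort(params, life_table, strategy)
    return trace, accumulate_outcomes(trace, params, strategy)
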