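"""Synthetic inputs and independently-computed reference expectations.

Everything the pipeline consumes can be generated here without any
download: the base-case parameter file, a Gompertz-Makeham life table
standing in for unpublished national tables, a short reference cohort
trace whose expectation is computed by an explicit matrix-power recursion
written in plain Python (kept deliberately independent of the vectorized
engine so it can serve as an oracle), and planted cost-effectiveness-
plane draws with known quadrant labels and a known acceptability-curve
crossover for testing the classifier and CEAC code.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mortality import LifeTable, synthetic_life_table
from .parameters import (
    DAYS_PER_YEAR,
    ParameterSet,
    Strategy,
    base_case_parameters,
    save_parameters,
)

__all__ = [
    "reference_transition_matrix",
    "reference_trace",
    "reference_cycle_death_probs",
    "planted_psa_draws",
    "FixtureBundle",
    "generate_fixtures",
]

# Planted CE-plane draws default to a cheaper-and-more-effective cloud:
# mean cost difference -US$30 and mean QALY difference +0.21 with spreads
# wide enough that all four quadrants are populated.
PLANTED_MEAN = (-30.0, 0.21)
PLANTED_SD = (20.0, 0.15)


# ---------------------------------------------------------------------------
# independent matrix-power oracle (pure Python, no numpy linear algebra)


def reference_transition_matrix(
    p_exac: float, p_ed: float, p_hosp: float, p_ad: float, q_other: float
) -> list[list[float]]:
    """6x6 cycle matrix as nested lists, assembled entry by entry.

    State order: controlled, OCS burst, ED visit, hospitalization,
    asthma death, other-cause death.  Other-cause death competes first;
    survivors of an exacerbation state return to controlled unless they
    escalate.
    """
    s = 1.0 - q_other
    return [
        [s * (1 - p_exac), s * p_exac, 0.0, 0.0, 0.0, q_other],
        [s * (1 - p_ed), 0.0, s * p_ed, 0.0, 0.0, q_other],
        [s * (1 - p_hosp), 0.0, 0.0, s * p_hosp, 0.0, q_other],
        [s * (1 - p_ad), 0.0, 0.0, 0.0, s * p_ad, q_other],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
    ]


def reference_cycle_death_probs(
    life_table: LifeTable,
    start_age: float,
    n_cycles: int,
    cycle_length_days: int,
) -> list[float]:
    """Per-cycle other-cause death probabilities, scalar arithmetic only."""
    out = []
    for t in range(n_cycles):
        age = start_age + t * cycle_length_days / DAYS_PER_YEAR
        q_annual = float(life_table.q_annual(age))
        if q_annual >= 1.0:
            out.append(1.0)
        else:
            out.append(1.0 - (1.0 - q_annual) ** (cycle_length_days / DAYS_PER_YEAR))
    return out


def reference_trace(
    params: ParameterSet,
    life_table: LifeTable,
    strategy: Strategy,
    n_cycles: int,
) -> list[list[float]]:
    """Cohort occupancy over ``n_cycles`` via explicit loops (the oracle).

    Re-derives the treatment-effect application with scalar formulas and
    iterates the occupancy vector with nested Python loops — no shared
    code with the engine's vectorized recursion beyond the parameter set.
    """
    t_in = params.transitions
    p_exac = t_in.p_controlled_to_ocs_burst.base
    p_ed = t_in.p_ocs_burst_to_ed.base
    if strategy is Strategy.AS_NEEDED_ICS_FORMOTEROL:
        rr = params.effects.rr_exacerbation.base
        eff = params.effects.or_ed_visit.base
        if params.settings.adherence_scales_effect:
            adh = params.effects.adherence_as_needed.base
            rr = 1.0 + adh * (rr - 1.0)
            eff = 1.0 + adh * (eff - 1.0)
        p_exac = 1.0 - (1.0 - p_exac) ** rr
        if params.settings.ed_effect_scale == "odds":
            odds = eff * p_ed / (1.0 - p_ed)
            p_ed = odds / (1.0 + odds)
        else:
            p_ed = 1.0 - (1.0 - p_ed) ** eff
    p_hosp = t_in.p_ed_to_hospitalization.base
    p_ad = t_in.p_hospitalization_to_asthma_death.base

    q_cycle = reference_cycle_death_probs(
        life_table, params.settings.starting_age_years, n_cycles,
        params.settings.cycle_length_days)

    occ = [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
    trace = [list(occ)]
    for t in range(n_cycles):
        m = reference_transition_matrix(p_exac, p_ed, p_hosp, p_ad, q_cycle[t])
        nxt = [0.0] * 6
        for j in range(6):
            acc = 0.0
            for i in range(6):
                acc += occ[i] * m[i][j]
            nxt[j] = acc
        occ = nxt
        trace.append(list(occ))
    return trace


# ---------------------------------------------------------------------------
# planted CE-plane draws


def planted_psa_draws(
    n: int,
    rng: np.random.Generator,
    mean: tuple[float, float] = PLANTED_MEAN,
    sd: tuple[float, float] = PLANTED_SD,
) -> pd.DataFrame:
    """Gaussian (delta cost, delta QALY) cloud with recorded quadrant labels.

    Labels follow the CE-plane convention (Q2 = cheaper and more
    effective, ties to the non-negative side) and are written at
    generation time so classifier tests have a planted truth.
    """
    dc = rng.normal(mean[0], sd[0], size=n)
    dq = rng.normal(mean[1], sd[1], size=n)
    labels = np.empty(n, dtype=int)
    for i in range(n):
        if dc[i] >= 0:
            labels[i] = 1 if dq[i] >= 0 else 4
        else:
            labels[i] = 2 if dq[i] >= 0 else 3
    return pd.DataFrame({
        "iteration": np.arange(n),
        "delta_cost": dc,
        "delta_qalys": dq,
        "quadrant": labels,
    })


# ---------------------------------------------------------------------------
# fixture bundle


@dataclass(frozen=True)
class FixtureBundle:
    parameter_file: Path
    life_table_file: Path
    reference_trace_file: Path
    planted_psa_file: Path
    reference_expectation: list[list[float]]
    checksums: dict[str, str]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixtures(
    output_dir: str | Path,
    seed: int,
    n_reference_cycles: int = 20,
    n_planted_draws: int = 2_000,
) -> FixtureBundle:
    """Write the full fixture set; bit-identical for identical seeds.

    Produces the base-case parameter YAML, the default synthetic life
    table, a 20-cycle maintenance-arm reference trace computed by the
    pure-Python oracle, and a planted PSA draw file.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    params = base_case_parameters()
    param_file = out / "base_case.yaml"
    save_parameters(params, param_file)

    table = synthetic_life_table(0, params.settings.horizon_age_years)
    table_file = out / "life_table.csv"
    table.to_csv(table_file)

    expectation = reference_trace(
        params, table, Strategy.MAINTENANCE_ICS, n_reference_cycles)
    cyc_years = params.settings.cycle_length_days / DAYS_PER_YEAR
    trace_df = pd.DataFrame(
        expectation,
        columns=["controlled", "ocs_burst", "ed_visit", "hospitalization",
                 "asthma_death", "other_death"])
    trace_df.insert(0, "age", params.settings.starting_age_years
                    + np.arange(len(expectation)) * cyc_years)
    trace_df.insert(0, "cycle", np.arange(len(expectation)))
    trace_file = out / "reference_trace.csv"
    trace_df.to_csv(trace_file, index=False)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    psa_file = out / "planted_psa.csv"
    planted_psa_draws(n_planted_draws, rng).to_csv(psa_file, index=False)

    files = {
        "base_case.yaml": param_file,
        "life_table.csv": table_file,
        "reference_trace.csv": trace_file,
        "planted_psa.csv": psa_file,
    }
    return FixtureBundle(
        parameter_file=param_file,
        life_table_file=table_file,
        reference_trace_file=trace_file,
        planted_psa_file=psa_file,
        reference_expectation=expectation,
        checksums={name: _sha256(p) for name, p in files.items()},
    )
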