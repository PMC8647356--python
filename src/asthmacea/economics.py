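"""Incremental cost-effectiveness comparison of the two strategies.

Conventions: the *intervention* is the as-needed ICS-formoterol arm, the
*comparator* maintenance ICS.  An ICER is only reported when neither arm
dominates; a dominant intervention (cheaper and more effective) makes the
ratio meaningless, which is flagged instead.  Net monetary benefit at a
willingness-to-pay threshold is always reported and is the outcome metric
used by the sensitivity analyses.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

from .markov import OutcomeSummary

__all__ = ["Dominance", "IncrementalResult", "incremental_analysis"]


class Dominance(enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison (intervention minus comparator)."""

    delta_cost: float
    delta_qalys: float
    delta_cost_per_person_year: float
    delta_qalys_per_person_year: float
    dominance: Dominance
    icer: float | None
    icer_note: str
    nmb_at_wtp: float
    wtp: float

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "delta_cost_per_person_year": self.delta_cost_per_person_year,
            "delta_qalys_per_person_year": self.delta_qalys_per_person_year,
            "dominance": self.dominance.value,
            "icer": self.icer,
            "icer_note": self.icer_note,
            "nmb_at_wtp": self.nmb_at_wtp,
            "wtp": self.wtp,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    def summary_text(self) -> str:
        lines = [
            f"incremental cost (USD):        {self.delta_cost:+.2f}",
            f"incremental QALYs:             {self.delta_qalys:+.5f}",
            f"incremental cost / person-yr:  {self.delta_cost_per_person_year:+.2f}",
            f"incremental QALYs / person-yr: {self.delta_qalys_per_person_year:+.5f}",
            f"dominance:                     {self.dominance.value}",
            f"ICER (USD/QALY):               "
            + (f"{self.icer:.2f}" if self.icer is not None else self.icer_note),
            f"NMB at WTP {self.wtp:,.0f}:         {self.nmb_at_wtp:+.2f}",
        ]
        return "\n".join(lines)


def incremental_analysis(
    intervention: OutcomeSummary,
    comparator: OutcomeSummary,
    wtp: float,
) -> IncrementalResult:
    """Compare two strategy outcomes at a willingness-to-pay threshold.

    Dominance is classified from the signs of the deltas; the ICER
    (delta cost / delta QALYs) is reported as a number only when both
    deltas share a sign, and flagged as undefined when the QALY delta is
    zero.
    """
    d_cost = intervention.total_discounted_cost - comparator.total_discounted_cost
    d_qaly = intervention.total_discounted_qalys - comparator.total_discounted_qalys
    d_cost_ppy = (intervention.cost_per_person_year
                  - comparator.cost_per_person_year)
    d_qaly_ppy = (intervention.qalys_per_person_year
                  - comparator.qalys_per_person_year)

    if d_cost < 0 and d_qaly > 0:
        dominance = Dominance.INTERVENTION_DOMINANT
        icer, note = None, "not reported: intervention dominates"
    elif d_cost > 0 and d_qaly < 0:
        dominance = Dominance.INTERVENTION_DOMINATED
        icer, note = None, "not reported: intervention is dominated"
    else:
        dominance = Dominance.NONE
        if d_qaly == 0.0:
            icer = None
            note = ("undefined: zero QALY difference"
                    if d_cost != 0.0 else "undefined: identical outcomes")
        else:
            icer, note = d_cost / d_qaly, ""

    return IncrementalResult(
        delta_cost=d_cost,
        delta_qalys=d_qaly,
        delta_cost_per_person_year=d_cost_ppy,
        delta_qalys_per_person_year=d_qaly_ppy,
        dominance=dominance,
        icer=icer,
        icer_note=note,
        nmb_at_wtp=wtp * d_qaly - d_cost,
        wtp=wtp,
    )
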