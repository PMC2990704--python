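"""Discounted cost and QALY accounting.

Costs accrue per event: direct test costs plus per-test nonmedical (patient
time and travel) costs and an optional administrative cost per primary
screening test; colonoscopy costs split diagnostic vs therapeutic;
complication costs per bleed or perforation; and the full stage-specific
cancer-management cost charged once, in the year of diagnosis.  Utilities
are state-based: 0.91 without cancer, 0.74 (stages I-II) or 0.46 (stages
III-IV) during the five years following diagnosis, and 0.91 again for
survivors beyond the five-year window.  Costs and utilities are discounted
to the cohort entry year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

from .natural_history import HealthState, PersonState
from .parameters import CostParams, ParameterSet, UtilityParams
from .screening import ScreeningEvent

__all__ = [
    "LedgerEntry",
    "PersonOutcome",
    "discount",
    "cost_of_events",
    "annual_utility",
    "summarize_person",
]


@dataclass(frozen=True)
class LedgerEntry:
    year: int
    category: str  # test_direct | test_nonmedical | admin | complication | crc_management
    amount: float

    def __post_init__(self):
        if self.year < 0:
            raise ValueError("ledger year must be >= 0")
        if self.amount < 0:
            raise ValueError("ledger amount must be >= 0")


@dataclass
class PersonOutcome:
    discounted_cost: float = 0.0
    discounted_qaly: float = 0.0
    life_years: float = 0.0
    cancer: bool = False
    cancer_death: bool = False
    tests_by_modality: Dict[str, int] = field(default_factory=dict)
    colonoscopies: int = 0
    complications: int = 0


def discount(amount: float, year: int, rate: float) -> float:
    """Present value of ``amount`` accruing ``year`` cycles after entry."""
    if year < 0:
        raise ValueError("year must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return amount / (1.0 + rate) ** year


def _colonoscopy_entries(event: ScreeningEvent, costs: CostParams) -> List[LedgerEntry]:
    key = ("colonoscopy_therapeutic" if event.therapeutic
           else "colonoscopy_diagnostic")
    return [
        LedgerEntry(event.year, "test_direct", costs.direct_test_cost[key]),
        LedgerEntry(event.year, "test_nonmedical", costs.nonmedical_cost["colonoscopy"]),
    ]


def cost_of_events(events: Iterable[ScreeningEvent],
                   costs: CostParams) -> List[LedgerEntry]:
    """Translate screening/diagnosis events into ledger entries."""
    ledger: List[LedgerEntry] = []
    for ev in events:
        if ev.kind == "primary_test":
            if ev.modality == "colonoscopy":
                ledger.extend(_colonoscopy_entries(ev, costs))
            else:
                cost_key = ev.modality.split("-")[0]
                if cost_key not in costs.direct_test_cost:
                    raise ValueError(f"no direct cost for modality {ev.modality!r}")
                ledger.append(LedgerEntry(ev.year, "test_direct",
                                          costs.direct_test_cost[cost_key]))
                ledger.append(LedgerEntry(ev.year, "test_nonmedical",
                                          costs.nonmedical_cost[cost_key]))
            if costs.admin_cost_per_test > 0:
                ledger.append(LedgerEntry(ev.year, "admin", costs.admin_cost_per_test))
        elif ev.kind in ("followup_colonoscopy", "surveillance_colonoscopy"):
            ledger.extend(_colonoscopy_entries(ev, costs))
        elif ev.kind == "complication_bleed":
            ledger.append(LedgerEntry(ev.year, "complication",
                                      costs.complication_cost["bleed"]))
        elif ev.kind == "complication_perforation":
            ledger.append(LedgerEntry(ev.year, "complication",
                                      costs.complication_cost["perforation"]))
        elif ev.kind == "crc_detected":
            ledger.append(LedgerEntry(ev.year, "crc_management",
                                      costs.crc_management_cost[ev.stage - 1]))
        elif ev.kind in ("polypectomy", "perforation_death"):
            pass  # costed via the therapeutic colonoscopy / perforation entries
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return ledger


def annual_utility(utilities: UtilityParams, state: HealthState,
                   stage: Optional[int] = None,
                   years_since_diagnosis: Optional[int] = None,
                   survival_window: int = 5) -> float:
    """Utility weight for one lived year."""
    if state is HealthState.DEAD:
        raise ValueError("dead state accrues no utility")
    if state is not HealthState.CRC_DIAGNOSED:
        return utilities.u_no_crc
    if years_since_diagnosis is not None and years_since_diagnosis >= survival_window:
        return utilities.u_no_crc  # cured survivor
    return utilities.u_early_crc if stage in (1, 2) else utilities.u_advanced_crc


def utility_for_person(utilities: UtilityParams, person: PersonState,
                       survival_window: int = 5) -> float:
    return annual_utility(utilities, person.state, person.stage,
                          person.years_since_diagnosis, survival_window)


def summarize_person(ledger: Iterable[LedgerEntry],
                     utility_stream: Iterable[float],
                     rate: float) -> PersonOutcome:
    """Discount a cost ledger and a per-year utility stream.

    ``utility_stream[t]`` is the utility weight of the year beginning at
    cycle ``t`` (0 for years not lived).
    """
    outcome = PersonOutcome()
    for entry in ledger:
        outcome.discounted_cost += discount(entry.amount, entry.year, rate)
    for year, u in enumerate(utility_stream):
        outcome.discounted_qaly += discount(u, year, rate)
        if u > 0:
            outcome.life_years += 1.0
    return outcome
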