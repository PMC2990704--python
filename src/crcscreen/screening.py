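"""Screening strategies, test application and the colonoscopy cascade.

A strategy couples a modality (stool test, CTC, flexible sigmoidoscopy or
colonoscopy) with an offer interval between ages 50 and 75.  A positive
non-colonoscopy test leads to a follow-up colonoscopy with the follow-up
adherence probability; any adenoma found at colonoscopy is removed
(polypectomy), which moves the person to the post-polypectomy state and
schedules surveillance colonoscopy at 3 years (advanced adenoma or resected
cancer) or 5 years (nonadvanced adenoma).  A clean colonoscopy restarts the
screening clock: the person is exempt from routine offers for a
configurable number of years (default 10, the colonoscopy screening
interval).

Flexible sigmoidoscopy's printed sensitivities already include the lesions
found at the completion colonoscopy of referred patients, so its referral
colonoscopy detects the flagged lesion with certainty.  CTC positives are
referred to a colonoscopy with the dedicated higher-sensitivity performance
row; a false-positive CTC leads to a therapeutic colonoscopy in which the
removed polyp is adenomatous with the <10 mm histology fraction, which
decides whether surveillance begins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .natural_history import (
    LESION_FREE_STATES,
    HealthState,
    PersonState,
    diagnose_crc,
)
from .parameters import ParameterSet, TestPerformance

__all__ = [
    "StrategyDefinition",
    "ScreeningEvent",
    "default_strategies",
    "get_strategy",
    "is_screening_due",
    "offer_screen",
    "offer_surveillance",
    "apply_test",
    "colonoscopy_procedure",
    "surveillance_interval",
    "test_positive_probability",
]


@dataclass(frozen=True)
class StrategyDefinition:
    """A screening modality with its schedule and optional adherence overrides."""

    label: str
    interval_years: int
    start_age: int = 50
    stop_age: int = 75
    first_adherence: Optional[float] = None      # None -> ParameterSet value
    subsequent_adherence: Optional[float] = None

    def __post_init__(self):
        if self.label != "none":
            if self.interval_years < 1:
                raise ValueError("interval must be >= 1 year")
            if self.start_age >= self.stop_age:
                raise ValueError("start age must be < stop age")

    @property
    def modality_class(self) -> str:
        if self.label == "none":
            return "none"
        if self.label.startswith(("FOBT", "FIT", "FDNA")):
            return "stool"
        if self.label == "colonoscopy":
            return "colonoscopy"
        if self.label == "flex_sig":
            return "flex_sig"
        if self.label == "CTC":
            return "ctc"
        raise ValueError(f"unknown modality {self.label!r}")

    @property
    def cost_key(self) -> str:
        # FIT-mid -> FIT, FDNA-SDT1 -> FDNA, etc.
        return self.label.split("-")[0]

    def with_interval(self, years: int) -> "StrategyDefinition":
        return replace(self, interval_years=years)


_BASE_INTERVALS = {
    "FOBT-low": 1, "FOBT-high": 1,
    "FIT-low": 1, "FIT-mid": 1, "FIT-high": 1,
    "FDNA-SDT1": 3, "FDNA-SDT2": 3,
    "colonoscopy": 10,
    "flex_sig": 5,
    "CTC": 5,
}


def default_strategies() -> Dict[str, StrategyDefinition]:
    out = {label: StrategyDefinition(label=label, interval_years=iv)
           for label, iv in _BASE_INTERVALS.items()}
    out["none"] = StrategyDefinition(label="none", interval_years=1)
    return out


def get_strategy(label: str) -> StrategyDefinition:
    strategies = default_strategies()
    if label not in strategies:
        raise KeyError(f"unknown strategy {label!r}; known: {sorted(strategies)}")
    return strategies[label]


@dataclass(frozen=True)
class ScreeningEvent:
    kind: str  # primary_test | followup_colonoscopy | surveillance_colonoscopy |
    #           polypectomy | complication_bleed | complication_perforation |
    #           perforation_death | crc_detected
    modality: str
    year: int
    therapeutic: bool = False
    stage: Optional[int] = None
    context: Optional[str] = None


def is_screening_due(person: PersonState, strategy: StrategyDefinition,
                     current_year: int) -> str:
    """Return ``"surveillance"``, ``"primary"`` or ``"none"``.

    Surveillance takes precedence over a routine offer.  Diagnosed cancer
    patients leave the screening programme (their follow-up is part of
    cancer care, not modelled as screening).  Both screening and
    surveillance stop after the stop age.
    """
    if not person.alive:
        raise ValueError("screening offered to a dead person")
    if person.state is HealthState.CRC_DIAGNOSED:
        return "none"
    if person.age > strategy.stop_age:
        return "none"
    if (person.surveillance_due_year is not None
            and current_year >= person.surveillance_due_year):
        return "surveillance"
    if strategy.modality_class == "none":
        return "none"
    if person.age < strategy.start_age:
        return "none"
    if (person.screening_exempt_until is not None
            and current_year < person.screening_exempt_until):
        return "none"
    if (person.last_offer_year is not None
            and current_year - person.last_offer_year < strategy.interval_years):
        return "none"
    return "primary"


def test_positive_probability(state: HealthState, perf: TestPerformance) -> float:
    """P(positive result) for a person in ``state`` under one test."""
    if state is HealthState.NONADVANCED_ADENOMA:
        return perf.sens_nonadvanced
    if state is HealthState.ADVANCED_ADENOMA:
        return perf.sens_advanced
    if state is HealthState.CRC_UNDIAGNOSED:
        return perf.sens_cancer
    if state in LESION_FREE_STATES:
        return 1.0 - perf.specificity_per_person
    raise ValueError(f"test applied in state {state}")


def apply_test(true_state: HealthState, perf: TestPerformance,
               rng: np.random.Generator) -> bool:
    return rng.random() < test_positive_probability(true_state, perf)


def surveillance_interval(finding: str) -> int:
    """Years until the next surveillance colonoscopy after a finding.

    Advanced adenomas and resected cancers get the intensive 3-year
    interval; nonadvanced adenomas the 5-year interval.
    """
    if finding in ("advanced_adenoma", "crc_resected"):
        return 3
    if finding == "nonadvanced_adenoma":
        return 5
    raise ValueError(f"unknown finding {finding!r}")


_COLO_EVENT_KIND = {
    "primary": "primary_test",
    "followup_after_positive": "followup_colonoscopy",
    "surveillance": "surveillance_colonoscopy",
}


def _record_negative_colonoscopy(person: PersonState, params: ParameterSet,
                                 year: int, reason: str) -> None:
    person.surveillance_due_year = None
    # a clean primary or follow-up colonoscopy restarts the screening clock;
    # a clean surveillance colonoscopy simply returns the person to the
    # routine schedule
    exempt = params.structural.clean_colonoscopy_exemption_years
    if exempt > 0 and reason != "surveillance":
        person.screening_exempt_until = year + exempt
    person.last_offer_year = year


def _schedule_surveillance(person: PersonState, year: int, finding: str) -> None:
    person.surveillance_due_year = year + surveillance_interval(finding)
    person.screening_exempt_until = None
    person.last_offer_year = year


def colonoscopy_procedure(person: PersonState, reason: str, params: ParameterSet,
                          rng: np.random.Generator, year: int,
                          origin: Optional[str] = None,
                          certain_detection: bool = False) -> List[ScreeningEvent]:
    """Perform a colonoscopy, removing any detected adenoma.

    ``origin`` names the test that triggered a follow-up ("stool", "CTC",
    "flex_sig") and selects the performance row and the stage distribution
    used if a cancer is found.  ``certain_detection`` models the flexible
    sigmoidoscopy referral, whose printed sensitivity already includes the
    completion colonoscopy.
    """
    if reason not in _COLO_EVENT_KIND:
        raise ValueError(f"unknown colonoscopy reason {reason!r}")
    perf = params.tests["colonoscopy-after-CTC" if origin == "CTC" else "colonoscopy"]
    events: List[ScreeningEvent] = []
    state = person.state
    therapeutic = False
    polypectomy = False
    detected_crc_stage: Optional[int] = None
    context: Optional[str] = None

    if state in (HealthState.NONADVANCED_ADENOMA, HealthState.ADVANCED_ADENOMA):
        sens = (perf.sens_nonadvanced if state is HealthState.NONADVANCED_ADENOMA
                else perf.sens_advanced)
        if certain_detection or rng.random() < sens:
            therapeutic = polypectomy = True
            finding = ("nonadvanced_adenoma" if state is HealthState.NONADVANCED_ADENOMA
                       else "advanced_adenoma")
            person.state = HealthState.POST_POLYPECTOMY
            person.history_adenoma_or_crc = True
            _schedule_surveillance(person, year, finding)
        else:
            _record_negative_colonoscopy(person, params, year, reason)
    elif state is HealthState.CRC_UNDIAGNOSED:
        if certain_detection or rng.random() < perf.sens_cancer:
            context = "stool_detected" if origin == "stool" else "structural_detected"
            diagnose_crc(person, context, params.stage_distributions, rng)
            detected_crc_stage = person.stage
        else:
            _record_negative_colonoscopy(person, params, year, reason)
    elif state in LESION_FREE_STATES:
        if origin == "CTC":
            # CTC flagged a polyp that is not an adenoma in the model's
            # worst-lesion bookkeeping; it is removed anyway, and histology
            # decides whether surveillance begins.
            therapeutic = polypectomy = True
            if rng.random() < params.histology.adenomatous_lt10mm:
                person.state = HealthState.POST_POLYPECTOMY
                person.history_adenoma_or_crc = True
                _schedule_surveillance(person, year, "nonadvanced_adenoma")
            else:
                _record_negative_colonoscopy(person, params, year, reason)
        else:
            _record_negative_colonoscopy(person, params, year, reason)
    else:
        raise ValueError(f"colonoscopy in state {state}")

    events.append(ScreeningEvent(
        kind=_COLO_EVENT_KIND[reason], modality="colonoscopy", year=year,
        therapeutic=therapeutic))
    if polypectomy:
        events.append(ScreeningEvent(kind="polypectomy", modality="colonoscopy",
                                     year=year, therapeutic=True))
    if detected_crc_stage is not None:
        events.append(ScreeningEvent(kind="crc_detected", modality="colonoscopy",
                                     year=year, stage=detected_crc_stage,
                                     context=context))

    comp = params.complications
    p_bleed = comp.bleed_tx_colo if therapeutic else comp.bleed_dx_colo
    p_perf = comp.perf_tx_colo if therapeutic else comp.perf_dx_colo
    if rng.random() < p_bleed:
        events.append(ScreeningEvent(kind="complication_bleed",
                                     modality="colonoscopy", year=year,
                                     therapeutic=therapeutic))
    if rng.random() < p_perf:
        events.append(ScreeningEvent(kind="complication_perforation",
                                     modality="colonoscopy", year=year,
                                     therapeutic=therapeutic))
        if rng.random() < comp.death_after_perforation:
            events.append(ScreeningEvent(kind="perforation_death",
                                         modality="colonoscopy", year=year))
            person.die("perforation")
    return events


def offer_screen(person: PersonState, strategy: StrategyDefinition,
                 params: ParameterSet, rng: np.random.Generator,
                 year: int) -> List[ScreeningEvent]:
    """One routine screening offer: adherence, test, follow-up cascade."""
    first = not person.first_offer_made
    person.first_offer_made = True
    person.last_offer_year = year
    if first:
        p_adhere = (strategy.first_adherence if strategy.first_adherence is not None
                    else params.adherence.first_screen)
    else:
        p_adhere = (strategy.subsequent_adherence
                    if strategy.subsequent_adherence is not None
                    else params.adherence.subsequent_screen)
    if rng.random() >= p_adhere:
        return []

    cls = strategy.modality_class
    if cls == "colonoscopy":
        return colonoscopy_procedure(person, "primary", params, rng, year)

    events = [ScreeningEvent(kind="primary_test", modality=strategy.label, year=year)]
    perf = params.tests[strategy.label]
    positive = apply_test(person.state, perf, rng)

    if cls == "flex_sig":
        comp = params.complications
        if rng.random() < comp.perf_flexsig:
            events.append(ScreeningEvent(kind="complication_perforation",
                                         modality="flex_sig", year=year))
            if rng.random() < comp.death_after_perforation:
                events.append(ScreeningEvent(kind="perforation_death",
                                             modality="flex_sig", year=year))
                person.die("perforation")
                return events
    # CTC perforation risk is zero in the base case and never fatal; a
    # nonzero configured risk contributes cost only.
    if cls == "ctc" and params.complications.perf_ctc > 0:
        if rng.random() < params.complications.perf_ctc:
            events.append(ScreeningEvent(kind="complication_perforation",
                                         modality="CTC", year=year))

    if positive and rng.random() < params.adherence.colonoscopy_after_positive:
        origin = {"stool": "stool", "ctc": "CTC", "flex_sig": "flex_sig"}[cls]
        events.extend(colonoscopy_procedure(
            person, "followup_after_positive", params, rng, year,
            origin=origin, certain_detection=(cls == "flex_sig")))
    return events


def offer_surveillance(person: PersonState, params: ParameterSet,
                       rng: np.random.Generator, year: int) -> List[ScreeningEvent]:
    """One surveillance colonoscopy offer.

    Adherence reuses the follow-up colonoscopy probability.  A missed
    surveillance colonoscopy stays due and is re-offered the next year.
    """
    if rng.random() >= params.adherence.colonoscopy_after_positive:
        return []
    return colonoscopy_procedure(person, "surveillance", params, rng, year)
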