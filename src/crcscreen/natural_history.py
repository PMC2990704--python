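"""Disease natural history: the adenoma-carcinoma sequence.

Each simulated person occupies one of a small set of health states and is
advanced in one-year cycles.  All cancers arise through
normal colon -> nonadvanced adenoma -> advanced adenoma -> CRC; the model
tracks the person's worst lesion only.  Stage is assigned at diagnosis from
a detection-route-specific distribution, after which a constant annual
cancer mortality hazard (derived from stage-specific five-year case
fatality) applies for exactly five years; survivors beyond that window
revert to background mortality and full utility.

Event order within a cycle is fixed: mortality first (background, then
cancer-specific), then any screening activity (driven by the engine), then
disease progression and symptomatic presentation, then ageing.  Putting
mortality first means a person cannot be diagnosed and die of that cancer
in the same cycle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np

from .parameters import AgeStratumParams, ParameterSet, StageDistributions

__all__ = [
    "HealthState",
    "PersonState",
    "initialize_person",
    "advance_one_year",
    "apply_mortality",
    "progress_disease",
    "age_one_year",
    "convert_five_year_mortality",
    "background_mortality",
    "diagnose_crc",
]


class HealthState(enum.Enum):
    NO_LESION = "no_lesion"
    NONADVANCED_ADENOMA = "nonadvanced_adenoma"
    ADVANCED_ADENOMA = "advanced_adenoma"
    CRC_UNDIAGNOSED = "crc_undiagnosed"
    CRC_DIAGNOSED = "crc_diagnosed"
    POST_POLYPECTOMY = "post_polypectomy"
    DEAD = "dead"


#: States in which a person carries no lesion (test positivity is governed by
#: specificity rather than sensitivity).
LESION_FREE_STATES = (HealthState.NO_LESION, HealthState.POST_POLYPECTOMY)


@dataclass
class PersonState:
    """One simulated individual.

    ``years_since_diagnosis`` counts completed model years since the cancer
    was found; the diagnosis year itself is year 0.  ``history_adenoma_or_crc``
    is monotone: once set it never reverts.
    """

    age: int
    state: HealthState
    stage: Optional[int] = None  # 1..4 once diagnosed
    years_since_diagnosis: Optional[int] = None
    detection_context: Optional[str] = None
    history_adenoma_or_crc: bool = False
    surveillance_due_year: Optional[int] = None
    screening_exempt_until: Optional[int] = None
    last_offer_year: Optional[int] = None
    first_offer_made: bool = False
    cause_of_death: Optional[str] = None
    _diagnosed_this_cycle: bool = field(default=False, repr=False)

    @property
    def alive(self) -> bool:
        return self.state is not HealthState.DEAD

    def die(self, cause: str) -> None:
        self.state = HealthState.DEAD
        self.cause_of_death = cause


@lru_cache(maxsize=32)
def _gompertz_coeffs(m_50_64: float, m_65_75: float) -> tuple:
    """Anchor mu(age) = A*exp(B*(age-50)) to the two stratum means.

    The unweighted mean of the curve over ages 50-64 equals the younger
    stratum's annual death risk and the mean over 65-75 equals the older
    stratum's, so the printed inputs are reproduced exactly while the curve
    keeps rising over the lifetime as population mortality does.
    """
    k1 = np.arange(0, 15)   # ages 50..64
    k2 = np.arange(15, 26)  # ages 65..75

    def ratio_gap(b: float) -> float:
        return (np.exp(b * k2).mean() / np.exp(b * k1).mean()
                - m_65_75 / m_50_64)

    from scipy.optimize import brentq
    b = brentq(ratio_gap, 1e-6, 1.0)
    a = m_50_64 / np.exp(b * k1).mean()
    return float(a), float(b)


def background_mortality(params: ParameterSet, age: int) -> float:
    """Annual background (non-CRC) death probability at ``age``."""
    m1 = params.stratum_50_64.annual_background_death
    m2 = params.stratum_65_75.annual_background_death
    # the anchored curve needs 0 < m1 < m2; degenerate inputs fall back to
    # the flat two-band schedule
    if params.structural.mortality_model == "stratum" or not 0.0 < m1 < m2:
        return params.stratum_for_age(age).annual_background_death
    a, b = _gompertz_coeffs(m1, m2)
    return min(1.0, a * float(np.exp(b * (age - 50))))


def convert_five_year_mortality(m5: float) -> float:
    """Annual death probability whose five-fold compounding reproduces ``m5``."""
    if not 0.0 <= m5 <= 1.0:
        raise ValueError(f"five-year mortality must be in [0,1], got {m5}")
    return 1.0 - (1.0 - m5) ** 0.2


def initialize_person(age: int, stratum: AgeStratumParams,
                      rng: np.random.Generator) -> PersonState:
    """Draw a person's entry state from the stratum prevalences."""
    p_na = stratum.prev_nonadvanced
    p_adv = stratum.prev_advanced
    p_crc = stratum.prev_crc
    total = p_na + p_adv + p_crc
    if total > 1.0:
        raise ValueError(f"prevalences sum to {total} > 1")
    u = rng.random()
    if u < p_na:
        state = HealthState.NONADVANCED_ADENOMA
    elif u < p_na + p_adv:
        state = HealthState.ADVANCED_ADENOMA
    elif u < total:
        state = HealthState.CRC_UNDIAGNOSED
    else:
        state = HealthState.NO_LESION
    return PersonState(age=age, state=state)


def diagnose_crc(person: PersonState, detection_context: str,
                 stage_dists: StageDistributions, rng: np.random.Generator) -> PersonState:
    """Assign a stage and move the person to the diagnosed state."""
    if person.state is not HealthState.CRC_UNDIAGNOSED:
        raise ValueError(f"cannot diagnose from state {person.state}")
    dist = stage_dists.for_context(detection_context)
    u = rng.random()
    cum = 0.0
    stage = 4
    for i, p in enumerate(dist.p_stage):
        cum += p
        if u < cum:
            stage = i + 1
            break
    person.state = HealthState.CRC_DIAGNOSED
    person.stage = stage
    person.years_since_diagnosis = 0
    person.detection_context = detection_context
    person.history_adenoma_or_crc = True
    person.surveillance_due_year = None
    person._diagnosed_this_cycle = True
    return person


def apply_mortality(person: PersonState, params: ParameterSet,
                    rng: np.random.Generator) -> None:
    """Background death, then cancer death within the five-year window."""
    if not person.alive:
        return
    if rng.random() < background_mortality(params, person.age):
        person.die("background")
        return
    if (person.state is HealthState.CRC_DIAGNOSED
            and person.years_since_diagnosis is not None
            and person.years_since_diagnosis < params.structural.crc_survival_window):
        m5 = params.stage_mortality.five_year_mortality[person.stage - 1]
        if rng.random() < convert_five_year_mortality(m5):
            person.die("crc")


def progress_disease(person: PersonState, params: ParameterSet,
                     rng: np.random.Generator) -> None:
    """One year of lesion onset/progression and symptomatic presentation."""
    if not person.alive:
        return
    tr = params.transition
    state = person.state
    if state is HealthState.NO_LESION:
        if rng.random() < tr.normal_to_nonadv_no_history:
            person.state = HealthState.NONADVANCED_ADENOMA
    elif state is HealthState.POST_POLYPECTOMY:
        if rng.random() < tr.normal_to_nonadv_history:
            person.state = HealthState.NONADVANCED_ADENOMA
    elif state is HealthState.NONADVANCED_ADENOMA:
        if rng.random() < tr.nonadv_to_adv:
            person.state = HealthState.ADVANCED_ADENOMA
    elif state is HealthState.ADVANCED_ADENOMA:
        if rng.random() < tr.adv_to_crc:
            person.state = HealthState.CRC_UNDIAGNOSED
    elif state is HealthState.CRC_UNDIAGNOSED:
        if rng.random() < params.structural.symptomatic_presentation_annual_prob:
            diagnose_crc(person, "unscreened", params.stage_distributions, rng)


def age_one_year(person: PersonState) -> None:
    person.age += 1
    if person.state is HealthState.CRC_DIAGNOSED:
        if person._diagnosed_this_cycle:
            person._diagnosed_this_cycle = False
        elif person.years_since_diagnosis is not None:
            person.years_since_diagnosis += 1


def advance_one_year(person: PersonState, params: ParameterSet,
                     rng: np.random.Generator) -> PersonState:
    """Advance a person one cycle with no screening interaction.

    Order: mortality, disease progression (a newly advanced lesion cannot
    progress twice in one cycle), symptomatic presentation, ageing.
    """
    if not person.alive:
        raise ValueError("cannot advance a dead person")
    apply_mortality(person, params, rng)
    progress_disease(person, params, rng)
    if person.alive:
        age_one_year(person)
    return person
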