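"""Simulation engines and natural-history calibration.

Two engines share one set of behavioural rules:

* :func:`run_microsim` -- first-order Monte Carlo: individuals are sampled
  one at a time through the per-person functions of ``natural_history`` and
  ``screening``.  It produces lifetime counts (cancers, deaths, tests,
  colonoscopies, complications) with sampling noise, as a screening
  programme would observe them in a cohort of ``n`` people.

* :func:`run_cohort_expectation` -- a deterministic cohort engine that
  propagates the full state-occupancy distribution year by year, treating
  every screening-cascade branch (adherence x test result x follow-up x
  detection x complications) analytically by probability mass.  Its outputs
  are the exact expectations the microsimulation converges to as n grows,
  and are used for cost/QALY comparisons where first-order noise would
  swamp small between-strategy differences.

The two engines are deliberately implemented as separate code paths (branch
enumeration vs sequential sampling); their agreement within Monte-Carlo
error is the model's core internal consistency check.

:func:`calibrate` adjusts the adenoma-carcinoma transition probabilities
and the symptomatic-presentation probability, within their plausible
ranges, so that the no-screening arm reproduces reference lifetime cancer
and cancer-death counts.  The published natural-history rates are known to
overpredict lifetime incidence when applied unadjusted over a lifetime
horizon, which is why the reference burden is matched by small bounded
adjustments rather than taken directly from the rate inputs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .economics import cost_of_events, discount, utility_for_person
from .natural_history import (
    HealthState,
    age_one_year,
    apply_mortality,
    background_mortality,
    convert_five_year_mortality,
    initialize_person,
    progress_disease,
)
from .parameters import PARAMETER_RANGES, ParameterSet
from .screening import (
    ScreeningEvent,
    StrategyDefinition,
    get_strategy,
    is_screening_due,
    offer_screen,
    offer_surveillance,
    test_positive_probability,
)

__all__ = [
    "OutcomeTally",
    "CalibrationResult",
    "run_microsim",
    "run_cohort_expectation",
    "calibrate",
    "DEFAULT_CALIBRATION_TARGETS",
    "DEFAULT_FREE_PARAMETERS",
]


@dataclass
class OutcomeTally:
    """Per-strategy lifetime outcome totals.

    For the microsimulation, totals are counts over ``n`` persons; for the
    cohort engine ``n`` is 1.0 and totals are per-person expectations.
    """

    strategy: str
    n: float
    cancers: float = 0.0
    cancers_screen_detected: float = 0.0
    cancers_symptomatic: float = 0.0
    cancer_deaths: float = 0.0
    perforation_deaths: float = 0.0
    background_deaths: float = 0.0
    primary_tests: float = 0.0
    primary_tests_by_modality: Dict[str, float] = field(default_factory=dict)
    colonoscopies: float = 0.0  # follow-up + surveillance (primary colonoscopies are tests)
    polypectomies: float = 0.0
    bleeds: float = 0.0
    perforations: float = 0.0
    total_cost: float = 0.0
    total_qaly: float = 0.0
    total_life_years: float = 0.0
    survivors: float = 0.0  # alive at the horizon cap

    @property
    def mean_cost(self) -> float:
        return self.total_cost / self.n

    @property
    def mean_qaly(self) -> float:
        return self.total_qaly / self.n

    @property
    def mean_life_years(self) -> float:
        return self.total_life_years / self.n

    def per_100k(self, attr: str) -> float:
        return getattr(self, attr) * 1e5 / self.n


# ---------------------------------------------------------------------------
# First-order Monte Carlo microsimulation


def _tally_events(tally: OutcomeTally, events: Sequence[ScreeningEvent]) -> None:
    for ev in events:
        if ev.kind == "primary_test":
            tally.primary_tests += 1
            by = tally.primary_tests_by_modality
            by[ev.modality] = by.get(ev.modality, 0) + 1
        elif ev.kind in ("followup_colonoscopy", "surveillance_colonoscopy"):
            tally.colonoscopies += 1
        elif ev.kind == "polypectomy":
            tally.polypectomies += 1
        elif ev.kind == "complication_bleed":
            tally.bleeds += 1
        elif ev.kind == "complication_perforation":
            tally.perforations += 1
        elif ev.kind == "crc_detected":
            tally.cancers += 1
            if ev.context == "unscreened":
                tally.cancers_symptomatic += 1
            else:
                tally.cancers_screen_detected += 1


def run_microsim(strategy: StrategyDefinition | str, params: ParameterSet,
                 n_persons: int, seed: int,
                 event_log: Optional[list] = None) -> OutcomeTally:
    """Simulate ``n_persons`` independent lifetimes under one strategy.

    Each person draws from two private random streams (natural history and
    screening) derived from the master seed, so results are reproducible,
    independent of iteration order, and paired across strategies under a
    common seed.
    """
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    s = params.structural
    rate = s.discount_rate
    horizon = s.max_age - s.screen_start_age
    tally = OutcomeTally(strategy=strategy.label, n=float(n_persons))
    costs = params.costs

    for i in range(n_persons):
        ss = np.random.SeedSequence(entropy=(int(seed), i))
        child_nh, child_sc = ss.spawn(2)
        rng_nh = np.random.default_rng(child_nh)
        rng_sc = np.random.default_rng(child_sc)
        person = initialize_person(s.screen_start_age, params.stratum_50_64, rng_nh)
        for t in range(horizon):
            apply_mortality(person, params, rng_nh)
            if not person.alive:
                tally.background_deaths += person.cause_of_death == "background"
                tally.cancer_deaths += person.cause_of_death == "crc"
                break
            events: List[ScreeningEvent] = []
            due = is_screening_due(person, strategy, t)
            if due == "surveillance":
                events = offer_surveillance(person, params, rng_sc, t)
            elif due == "primary":
                events = offer_screen(person, strategy, params, rng_sc, t)
            was_undiagnosed = person.state is not HealthState.CRC_DIAGNOSED
            if person.alive:
                progress_disease(person, params, rng_nh)
                if (was_undiagnosed and person.state is HealthState.CRC_DIAGNOSED
                        and person.detection_context == "unscreened"):
                    events.append(ScreeningEvent(
                        kind="crc_detected", modality="symptomatic", year=t,
                        stage=person.stage, context="unscreened"))
            _tally_events(tally, events)
            for entry in cost_of_events(events, costs):
                tally.total_cost += discount(entry.amount, entry.year, rate)
            if event_log is not None:
                event_log.extend((i, ev) for ev in events)
            if not person.alive:  # perforation death during screening
                tally.perforation_deaths += 1
                break
            age_one_year(person)
            u = utility_for_person(params.utilities, person,
                                   s.crc_survival_window)
            tally.total_qaly += discount(u, t, rate)
            tally.total_life_years += 1.0
        if person.alive:
            tally.survivors += 1
    return tally


# ---------------------------------------------------------------------------
# Deterministic cohort-expectation engine
#
# Schedule state carries two clocks: ``sk`` (years until the pending
# surveillance colonoscopy, None when no surveillance is scheduled) and
# ``rk`` (years until the next routine offer).  Routine screening continues
# between surveillance dates; a due surveillance colonoscopy takes
# precedence over a routine offer in the same year.

class _Branch(NamedTuple):
    p: float
    disease: Optional[HealthState]  # None when the branch ends in death
    sched: Tuple[str, int]          # ("R", k) or ("S", k); see replace_sched
    cost: float
    n_test: float = 0.0
    n_colo: float = 0.0
    n_polyp: float = 0.0
    e_bleed: float = 0.0
    e_perf: float = 0.0
    dx_stage: Optional[int] = None
    dx_context: Optional[str] = None
    dead: bool = False
    # True when the encounter included a colonoscopy, whose outcome
    # supersedes any pending surveillance date; False for branches that only
    # advance the routine clock
    replace_sched: bool = True


def _colo_branches(disease: HealthState, origin: Optional[str],
                   params: ParameterSet, strategy: StrategyDefinition,
                   count_as_colo: bool, certain: bool = False,
                   extra_cost: float = 0.0,
                   surveillance: bool = False) -> List[_Branch]:
    """Analytic expansion of one colonoscopy on a person in ``disease``."""
    perf = params.tests["colonoscopy-after-CTC" if origin == "CTC" else "colonoscopy"]
    costs = params.costs
    comp = params.complications
    # a clean primary/follow-up colonoscopy restarts the clock; a clean
    # surveillance colonoscopy only resumes the routine schedule
    if surveillance:
        exempt = strategy.interval_years
    else:
        exempt = max(strategy.interval_years,
                     params.structural.clean_colonoscopy_exemption_years)
    c_dx = costs.direct_test_cost["colonoscopy_diagnostic"] + costs.nonmedical_cost["colonoscopy"]
    c_tx = costs.direct_test_cost["colonoscopy_therapeutic"] + costs.nonmedical_cost["colonoscopy"]
    nc = 1.0 if count_as_colo else 0.0

    def comp_load(therapeutic: bool) -> Tuple[float, float, float]:
        pb = comp.bleed_tx_colo if therapeutic else comp.bleed_dx_colo
        pp = comp.perf_tx_colo if therapeutic else comp.perf_dx_colo
        cost = (pb * costs.complication_cost["bleed"]
                + pp * costs.complication_cost["perforation"])
        return pb, pp, cost

    raw: List[_Branch] = []
    if disease in (HealthState.NONADVANCED_ADENOMA, HealthState.ADVANCED_ADENOMA):
        nonadv = disease is HealthState.NONADVANCED_ADENOMA
        p_det = 1.0 if certain else (perf.sens_nonadvanced if nonadv else perf.sens_advanced)
        surv = 5 if nonadv else 3
        pb, pp, ccost = comp_load(True)
        raw.append(_Branch(p_det, HealthState.POST_POLYPECTOMY, ("S", surv),
                           c_tx + ccost, 0, nc, 1.0, pb, pp))
        if p_det < 1.0:
            pb, pp, ccost = comp_load(False)
            raw.append(_Branch(1 - p_det, disease, ("R", exempt),
                               c_dx + ccost, 0, nc, 0.0, pb, pp))
    elif disease is HealthState.CRC_UNDIAGNOSED:
        p_det = 1.0 if certain else perf.sens_cancer
        context = "stool_detected" if origin == "stool" else "structural_detected"
        dist = params.stage_distributions.for_context(context)
        pb, pp, ccost = comp_load(False)
        for stage, p_stage in enumerate(dist.p_stage, start=1):
            raw.append(_Branch(p_det * p_stage, HealthState.CRC_DIAGNOSED,
                               ("R", 0),
                               c_dx + ccost + costs.crc_management_cost[stage - 1],
                               0, nc, 0.0, pb, pp,
                               dx_stage=stage, dx_context=context))
        if p_det < 1.0:
            raw.append(_Branch(1 - p_det, disease, ("R", exempt),
                               c_dx + ccost, 0, nc, 0.0, pb, pp))
    elif disease in (HealthState.NO_LESION, HealthState.POST_POLYPECTOMY):
        if origin == "CTC":
            # CTC flagged a polyp that is not an adenoma in the model's
            # worst-lesion bookkeeping; it is removed anyway, and histology
            # decides whether surveillance begins.
            f = params.histology.adenomatous_lt10mm
            pb, pp, ccost = comp_load(True)
            raw.append(_Branch(f, HealthState.POST_POLYPECTOMY, ("S", 5),
                               c_tx + ccost, 0, nc, 1.0, pb, pp))
            raw.append(_Branch(1 - f, disease, ("R", exempt),
                               c_tx + ccost, 0, nc, 1.0, pb, pp))
        else:
            pb, pp, ccost = comp_load(False)
            raw.append(_Branch(1.0, disease, ("R", exempt),
                               c_dx + ccost, 0, nc, 0.0, pb, pp))
    else:
        raise ValueError(f"colonoscopy branch for state {disease}")

    # split each branch on perforation death; expected complication cost is
    # carried unconditionally so totals match the sampling engine exactly
    out: List[_Branch] = []
    for br in raw:
        pdead = br.e_perf * comp.death_after_perforation
        cost = br.cost + extra_cost
        if pdead > 0:
            out.append(br._replace(p=br.p * (1 - pdead), cost=cost))
            out.append(br._replace(p=br.p * pdead, cost=cost, dead=True))
        else:
            out.append(br._replace(cost=cost))
    return out


def _primary_branches(disease: HealthState, first: bool,
                      strategy: StrategyDefinition,
                      params: ParameterSet) -> List[_Branch]:
    adh = params.adherence
    if first:
        p_adh = (strategy.first_adherence if strategy.first_adherence is not None
                 else adh.first_screen)
    else:
        p_adh = (strategy.subsequent_adherence
                 if strategy.subsequent_adherence is not None
                 else adh.subsequent_screen)
    interval = strategy.interval_years
    routine = ("R", interval)
    branches = [_Branch(1 - p_adh, disease, routine, 0.0, replace_sched=False)]
    if p_adh == 0:
        return branches

    cls = strategy.modality_class
    costs = params.costs
    admin = costs.admin_cost_per_test

    if cls == "colonoscopy":
        for br in _colo_branches(disease, None, params, strategy,
                                 count_as_colo=False, extra_cost=admin):
            branches.append(br._replace(p=p_adh * br.p, n_test=1.0))
        return branches

    key = strategy.cost_key
    c_test = costs.direct_test_cost[key] + costs.nonmedical_cost[key] + admin
    perf = params.tests[strategy.label]
    p_pos = test_positive_probability(disease, perf)
    p_fu = adh.colonoscopy_after_positive
    comp = params.complications

    p_alive = p_adh
    if cls == "flex_sig":
        # perforation risk of the sigmoidoscopy itself precedes any referral
        c_test += comp.perf_flexsig * costs.complication_cost["perforation"]
        p_dead = comp.perf_flexsig * comp.death_after_perforation
        if p_dead > 0:
            branches.append(_Branch(p_adh * p_dead, None, routine, c_test,
                                    n_test=1.0, e_perf=comp.perf_flexsig,
                                    dead=True))
        p_alive = p_adh * (1 - p_dead)
    elif cls == "ctc" and comp.perf_ctc > 0:
        c_test += comp.perf_ctc * costs.complication_cost["perforation"]

    e_perf_test = (comp.perf_flexsig if cls == "flex_sig"
                   else comp.perf_ctc if cls == "ctc" else 0.0)
    # negative, or positive without follow-up: routine schedule continues
    p_no_cascade = (1 - p_pos) + p_pos * (1 - p_fu)
    if p_no_cascade > 0:
        branches.append(_Branch(p_alive * p_no_cascade, disease, routine, c_test,
                                n_test=1.0, e_perf=e_perf_test,
                                replace_sched=False))
    if p_pos * p_fu > 0:
        origin = {"stool": "stool", "ctc": "CTC", "flex_sig": "flex_sig"}[cls]
        for br in _colo_branches(disease, origin, params, strategy,
                                 count_as_colo=True,
                                 certain=(cls == "flex_sig"),
                                 extra_cost=c_test):
            branches.append(br._replace(p=p_alive * p_pos * p_fu * br.p,
                                        n_test=1.0,
                                        e_perf=br.e_perf + e_perf_test))
    return branches


def _surveillance_branches(disease: HealthState, strategy: StrategyDefinition,
                           params: ParameterSet) -> List[_Branch]:
    p_adh = params.adherence.colonoscopy_after_positive
    # a missed surveillance colonoscopy stays due and is re-offered next year
    branches = [_Branch(1 - p_adh, disease, ("S", 0), 0.0, replace_sched=False)]
    for br in _colo_branches(disease, None, params, strategy,
                             count_as_colo=True, surveillance=True):
        branches.append(br._replace(p=p_adh * br.p))
    return branches


_PRE_DISEASES = (HealthState.NO_LESION, HealthState.POST_POLYPECTOMY,
                 HealthState.NONADVANCED_ADENOMA, HealthState.ADVANCED_ADENOMA,
                 HealthState.CRC_UNDIAGNOSED)


def run_cohort_expectation(strategy: StrategyDefinition | str,
                           params: ParameterSet) -> OutcomeTally:
    """Deterministic expectation over one unit cohort entering at the start age."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    s = params.structural
    rate = s.discount_rate
    u = params.utilities
    horizon = s.max_age - s.screen_start_age
    tally = OutcomeTally(strategy=strategy.label, n=1.0)

    hazard = [convert_five_year_mortality(m)
              for m in params.stage_mortality.five_year_mortality]
    stage_u = [u.u_early_crc, u.u_early_crc, u.u_advanced_crc, u.u_advanced_crc]
    tr = params.transition
    q_sympt = s.symptomatic_presentation_annual_prob
    p_stage_sympt = params.stage_distributions.unscreened.p_stage
    mgmt = params.costs.crc_management_cost
    window = s.crc_survival_window
    interval = strategy.interval_years

    screening_on = strategy.modality_class != "none"
    branch_cache: Dict[Tuple, List[_Branch]] = {}
    if screening_on:
        for d in _PRE_DISEASES:
            for first in (True, False):
                branch_cache[(d, first, "primary")] = _primary_branches(
                    d, first, strategy, params)
    for d in _PRE_DISEASES:
        branch_cache[(d, "surv")] = _surveillance_branches(d, strategy, params)

    stratum0 = params.stratum_50_64
    # pre-diagnosis state key: (disease, sk, rk, first) where sk is the
    # surveillance countdown (None if unscheduled) and rk the routine one
    pre: Dict[Tuple, float] = defaultdict(float)
    base = 1.0 - (stratum0.prev_nonadvanced + stratum0.prev_advanced
                  + stratum0.prev_crc)
    pre[(HealthState.NO_LESION, None, 0, False)] = base
    pre[(HealthState.NONADVANCED_ADENOMA, None, 0, False)] = stratum0.prev_nonadvanced
    pre[(HealthState.ADVANCED_ADENOMA, None, 0, False)] = stratum0.prev_advanced
    pre[(HealthState.CRC_UNDIAGNOSED, None, 0, False)] = stratum0.prev_crc
    dx: Dict[Tuple[int, int], float] = defaultdict(float)

    tests_by = tally.primary_tests_by_modality

    def apply_branch_sched(br: _Branch, sk, rk):
        """Map a branch's schedule outcome onto the two-clock state."""
        kind, k = br.sched
        if not br.replace_sched:
            if kind == "S":          # missed surveillance: clocks unchanged
                return sk, rk
            return sk, k             # routine offer made, surveillance kept
        if kind == "S":
            return k, interval
        return None, k               # colonoscopy outcome supersedes surveillance

    def settle_progression(d: HealthState, mass: float, sk, rk: int,
                           first: bool, disc: float, new_pre, new_dx) -> None:
        """Apply one year of progression/symptomatic presentation, credit
        utility, and deposit end-of-cycle mass (clocks tick down here)."""
        sk2 = sk if sk is None or sk == 0 else sk - 1
        rk2 = max(rk - 1, 0)
        key_base = (sk2, rk2, first)
        if d is HealthState.CRC_UNDIAGNOSED:
            m_dx = mass * q_sympt
            if m_dx > 0:
                tally.cancers += m_dx
                tally.cancers_symptomatic += m_dx
                for stage, ps in enumerate(p_stage_sympt, start=1):
                    bm = m_dx * ps
                    tally.total_cost += disc * bm * mgmt[stage - 1]
                    tally.total_qaly += disc * bm * stage_u[stage - 1]
                    new_dx[(stage, 0)] += bm
            m_stay = mass - m_dx
            tally.total_qaly += disc * m_stay * u.u_no_crc
            new_pre[(d,) + key_base] += m_stay
            tally.total_life_years += mass
            return
        if d is HealthState.NO_LESION:
            p_move, target = tr.normal_to_nonadv_no_history, HealthState.NONADVANCED_ADENOMA
        elif d is HealthState.POST_POLYPECTOMY:
            p_move, target = tr.normal_to_nonadv_history, HealthState.NONADVANCED_ADENOMA
        elif d is HealthState.NONADVANCED_ADENOMA:
            p_move, target = tr.nonadv_to_adv, HealthState.ADVANCED_ADENOMA
        else:  # advanced adenoma
            p_move, target = tr.adv_to_crc, HealthState.CRC_UNDIAGNOSED
        moved = mass * p_move
        new_pre[(d,) + key_base] += mass - moved
        new_pre[(target,) + key_base] += moved
        tally.total_qaly += disc * mass * u.u_no_crc
        tally.total_life_years += mass

    for t in range(horizon):
        age = s.screen_start_age + t
        mu = background_mortality(params, age)
        disc = 1.0 / (1.0 + rate) ** t
        new_pre: Dict[Tuple, float] = defaultdict(float)
        new_dx: Dict[Tuple[int, int], float] = defaultdict(float)

        for (stage, ysd), mass in dx.items():
            tally.background_deaths += mass * mu
            m = mass * (1 - mu)
            if ysd < window:
                died = m * hazard[stage - 1]
                tally.cancer_deaths += died
                m -= died
            ysd2 = min(ysd + 1, window)
            uw = stage_u[stage - 1] if ysd2 < window else u.u_no_crc
            tally.total_qaly += disc * m * uw
            tally.total_life_years += m
            new_dx[(stage, ysd2)] += m

        offers_open = age <= strategy.stop_age
        for (d, sk, rk, first), mass in pre.items():
            if mass <= 0:
                continue
            tally.background_deaths += mass * mu
            m = mass * (1 - mu)
            if m <= 0:
                continue
            due = None
            if offers_open and sk == 0:
                due = "surv"
            elif (screening_on and offers_open and rk == 0
                  and age >= strategy.start_age):
                due = "primary"
            if due is None:
                settle_progression(d, m, sk, rk, first, disc, new_pre, new_dx)
                continue
            # the state flag records whether an offer was ever made, so the
            # upcoming offer is "first" when the flag is still False
            branches = (branch_cache[(d, "surv")] if due == "surv"
                        else branch_cache[(d, not first, "primary")])
            first2 = True if due == "primary" else first
            for br in branches:
                bm = m * br.p
                if bm <= 0:
                    continue
                tally.total_cost += disc * bm * br.cost
                tally.primary_tests += bm * br.n_test
                if br.n_test:
                    tests_by[strategy.label] = (tests_by.get(strategy.label, 0.0)
                                                + bm * br.n_test)
                tally.colonoscopies += bm * br.n_colo
                tally.polypectomies += bm * br.n_polyp
                tally.bleeds += bm * br.e_bleed
                tally.perforations += bm * br.e_perf
                if br.dead:
                    tally.perforation_deaths += bm
                    continue
                if br.dx_stage is not None:
                    tally.cancers += bm
                    tally.cancers_screen_detected += bm
                    tally.total_qaly += disc * bm * stage_u[br.dx_stage - 1]
                    tally.total_life_years += bm
                    new_dx[(br.dx_stage, 0)] += bm
                    continue
                sk2, rk2 = apply_branch_sched(br, sk, rk)
                settle_progression(br.disease, bm, sk2, rk2, first2, disc,
                                   new_pre, new_dx)
        pre = new_pre
        dx = new_dx
    tally.survivors = sum(pre.values()) + sum(dx.values())
    return tally


# ---------------------------------------------------------------------------
# Calibration

DEFAULT_CALIBRATION_TARGETS: Dict[str, float] = {
    "cancers_per_100k": 4857.0,
    "deaths_per_100k": 1782.0,
}

DEFAULT_FREE_PARAMETERS: Tuple[str, ...] = (
    "transition.normal_to_nonadv_no_history",
    "transition.normal_to_nonadv_history",
    "transition.nonadv_to_adv",
    "transition.adv_to_crc",
    "structural.symptomatic_presentation_annual_prob",
)

#: Bound for the one free parameter without a printed range.
_SYMPTOMATIC_BOUNDS = (0.05, 0.95)


@dataclass
class CalibrationResult:
    params: ParameterSet
    adjusted: Dict[str, float]
    achieved: Dict[str, float]
    targets: Dict[str, float]
    converged: bool
    n_evaluations: int


def _no_screening_counts(params: ParameterSet) -> Tuple[float, float]:
    tally = run_cohort_expectation("none", params)
    return tally.per_100k("cancers"), tally.per_100k("cancer_deaths")


def calibrate(params: ParameterSet,
              targets: Optional[Dict[str, float]] = None,
              free_parameters: Optional[Sequence[str]] = None,
              bounds: Optional[Dict[str, Tuple[float, float]]] = None,
              seed: int = 0,
              rel_tol: float = 0.02) -> CalibrationResult:
    """Fit natural-history rates to reference no-screening cancer burden.

    Minimizes the summed squared relative error of lifetime cancers and
    cancer deaths per 100,000 (deterministic cohort engine, so the
    objective is noise-free) over the bounded free parameters, using
    Powell's derivative-free direction-set search.  ``seed`` is accepted
    for interface stability; the default objective is deterministic.
    """
    targets = dict(targets or DEFAULT_CALIBRATION_TARGETS)
    free = list(free_parameters or DEFAULT_FREE_PARAMETERS)
    allowed = set(DEFAULT_FREE_PARAMETERS)
    for path in free:
        if path not in allowed:
            raise ValueError(f"{path!r} is not a calibratable parameter; "
                             f"allowed: {sorted(allowed)}")
    bnds = []
    for path in free:
        if bounds and path in bounds:
            bnds.append(tuple(bounds[path]))
        elif path in PARAMETER_RANGES:
            bnds.append(PARAMETER_RANGES[path])
        else:
            bnds.append(_SYMPTOMATIC_BOUNDS)

    ct = targets["cancers_per_100k"]
    dt = targets["deaths_per_100k"]
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        trial = params.with_overrides(dict(zip(free, x)))
        c, d = _no_screening_counts(trial)
        return ((c - ct) / ct) ** 2 + ((d - dt) / dt) ** 2

    from .parameters import get_by_path
    x0 = np.array([np.clip(get_by_path(params, p), lo, hi)
                   for p, (lo, hi) in zip(free, bnds)])
    if objective(x0) < 1e-8:  # already on target
        c, d = _no_screening_counts(params)
        return CalibrationResult(params, {}, {"cancers_per_100k": c,
                                              "deaths_per_100k": d},
                                 targets, True, n_eval)

    result = optimize.minimize(objective, x0, method="Powell", bounds=bnds,
                               options={"xtol": 1e-4, "ftol": 1e-8,
                                        "maxiter": 40})
    best = params.with_overrides(dict(zip(free, result.x)))
    c, d = _no_screening_counts(best)
    converged = (abs(c - ct) / ct <= rel_tol) and (abs(d - dt) / dt <= rel_tol)
    return CalibrationResult(
        params=best,
        adjusted={p: float(v) for p, v in zip(free, result.x)},
        achieved={"cancers_per_100k": c, "deaths_per_100k": d},
        targets=targets,
        converged=converged,
        n_evaluations=n_eval,
    )
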