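"""Screening schedules, adherence, the colonoscopy cascade and surveillance."""

import math

import numpy as np
import pytest

from crcscreen.engine import run_microsim
from crcscreen.natural_history import HealthState, PersonState
from crcscreen.screening import (
    StrategyDefinition,
    apply_test,
    colonoscopy_procedure,
    default_strategies,
    get_strategy,
    is_screening_due,
    offer_screen,
    surveillance_interval,
)
from crcscreen.screening import test_positive_probability as positive_probability


@pytest.fixture
def fit_mid():
    return get_strategy("FIT-mid")


def _person(state=HealthState.NO_LESION, age=60, **kw):
    return PersonState(age=age, state=state, **kw)


class TestSchedules:
    def test_base_case_intervals(self):
        strategies = default_strategies()
        assert strategies["FOBT-low"].interval_years == 1
        assert strategies["FIT-mid"].interval_years == 1
        assert strategies["FDNA-SDT1"].interval_years == 3
        assert strategies["flex_sig"].interval_years == 5
        assert strategies["CTC"].interval_years == 5
        assert strategies["colonoscopy"].interval_years == 10

    def test_no_offers_beyond_stop_age(self):
        person = _person(age=76)
        assert is_screening_due(person, get_strategy("colonoscopy"), 26) == "none"

    def test_surveillance_takes_precedence(self, fit_mid):
        person = _person(age=60, surveillance_due_year=10, last_offer_year=5)
        assert is_screening_due(person, fit_mid, 10) == "surveillance"

    def test_annual_fit_due_after_one_year(self, fit_mid):
        person = _person(age=60, last_offer_year=9)
        assert is_screening_due(person, fit_mid, 10) == "primary"
        assert is_screening_due(person, fit_mid, 9) == "none"

    def test_exemption_suppresses_offers(self, fit_mid):
        person = _person(age=60, last_offer_year=5, screening_exempt_until=15)
        assert is_screening_due(person, fit_mid, 10) == "none"
        assert is_screening_due(person, fit_mid, 15) == "primary"

    def test_diagnosed_patients_leave_programme(self, fit_mid):
        person = _person(state=HealthState.CRC_DIAGNOSED)
        person.stage = 2
        assert is_screening_due(person, fit_mid, 10) == "none"

    def test_surveillance_intervals(self):
        assert surveillance_interval("advanced_adenoma") == 3
        assert surveillance_interval("crc_resected") == 3
        assert surveillance_interval("nonadvanced_adenoma") == 5
        with pytest.raises(ValueError):
            surveillance_interval("hyperplastic")


class TestTestApplication:
    def test_positive_probabilities_by_state(self, base_params):
        colo = base_params.tests["colonoscopy"]
        assert positive_probability(HealthState.CRC_UNDIAGNOSED, colo) == 0.966
        after_ctc = base_params.tests["colonoscopy-after-CTC"]
        assert positive_probability(HealthState.ADVANCED_ADENOMA, after_ctc) == 0.970
        fit = base_params.tests["FIT-mid"]
        assert positive_probability(HealthState.NO_LESION, fit) == pytest.approx(0.04)
        assert positive_probability(HealthState.POST_POLYPECTOMY, fit) == pytest.approx(0.04)

    def test_perfect_test_is_deterministic(self, base_params):
        perfect = base_params.tests["FIT-mid"].model_copy(update={
            "sens_nonadvanced": 1.0, "sens_advanced": 1.0, "sens_cancer": 1.0,
            "specificity_per_person": 1.0})
        rng = np.random.default_rng(0)
        assert all(apply_test(HealthState.ADVANCED_ADENOMA, perfect, rng)
                   for _ in range(20))
        assert not any(apply_test(HealthState.NO_LESION, perfect, rng)
                       for _ in range(20))


class TestOfferCascade:
    def test_nonadherent_offer_only_updates_clock(self, base_params, fit_mid):
        params = base_params.with_overrides({"adherence.first_screen": 0.0})
        person = _person(state=HealthState.ADVANCED_ADENOMA)
        events = offer_screen(person, fit_mid, params, np.random.default_rng(0), 4)
        assert events == []
        assert person.last_offer_year == 4
        assert person.state is HealthState.ADVANCED_ADENOMA

    def test_fit_positive_cascade_removes_advanced_adenoma(self, base_params, fit_mid):
        # force every branch: adherent, positive, follow-up, detected
        params = base_params.with_overrides({
            "adherence.first_screen": 1.0,
            "adherence.colonoscopy_after_positive": 1.0,
        })
        params = params.model_copy(update={"tests": {
            **params.tests,
            "FIT-mid": params.tests["FIT-mid"].model_copy(
                update={"sens_advanced": 1.0}),
            "colonoscopy": params.tests["colonoscopy"].model_copy(
                update={"sens_advanced": 1.0}),
        }})
        person = _person(state=HealthState.ADVANCED_ADENOMA)
        events = offer_screen(person, fit_mid, params, np.random.default_rng(1), 0)
        kinds = [e.kind for e in events]
        assert kinds[:3] == ["primary_test", "followup_colonoscopy", "polypectomy"]
        assert person.state is HealthState.POST_POLYPECTOMY
        assert person.surveillance_due_year == 3  # advanced finding -> 3 years

    def test_false_positive_followup_rate(self, base_params, fit_mid):
        # lesion-free person, FIT-mid: P(follow-up colonoscopy) =
        # (1 - 0.960) * 0.81; checked over many offers
        params = base_params.with_overrides({"adherence.first_screen": 1.0})
        rng = np.random.default_rng(12)
        n = 100_000
        followups = 0
        for _ in range(n):
            person = _person()
            events = offer_screen(person, fit_mid, params, rng, 0)
            followups += any(e.kind == "followup_colonoscopy" for e in events)
        p = 0.04 * 0.81
        sd = math.sqrt(n * p * (1 - p))
        assert abs(followups - n * p) < 3 * sd

    def test_negative_colonoscopy_grants_ten_year_exemption(self, base_params):
        person = _person()
        events = colonoscopy_procedure(person, "followup_after_positive",
                                       base_params, np.random.default_rng(0),
                                       year=6, origin="stool")
        assert [e.kind for e in events][0] == "followup_colonoscopy"
        assert not events[0].therapeutic
        assert person.screening_exempt_until == 16

    def test_ctc_false_positive_histology_routes(self, base_params):
        # therapeutic colonoscopy either starts surveillance (adenomatous
        # fraction 0.41) or grants an exemption
        rng = np.random.default_rng(3)
        surveilled = exempted = 0
        for _ in range(3000):
            person = _person()
            events = colonoscopy_procedure(person, "followup_after_positive",
                                           base_params, rng, year=0, origin="CTC")
            assert events[0].therapeutic
            if person.surveillance_due_year is not None:
                surveilled += 1
                assert person.state is HealthState.POST_POLYPECTOMY
            elif person.alive:
                exempted += 1
        frac = surveilled / (surveilled + exempted)
        assert abs(frac - 0.41) < 3 * math.sqrt(0.41 * 0.59 / 3000)

    def test_flexsig_referral_detects_with_certainty(self, base_params):
        params = base_params.with_overrides({
            "adherence.first_screen": 1.0,
            "adherence.colonoscopy_after_positive": 1.0,
        })
        strategy = get_strategy("flex_sig")
        rng = np.random.default_rng(8)
        removed = positives = 0
        for _ in range(2000):
            person = _person(state=HealthState.ADVANCED_ADENOMA)
            events = offer_screen(person, strategy, params, rng, 0)
            if any(e.kind == "followup_colonoscopy" for e in events):
                positives += 1
                removed += person.state is HealthState.POST_POLYPECTOMY
        assert positives > 0
        assert removed == positives  # referral colonoscopy never misses

    def test_unknown_colonoscopy_reason_rejected(self, base_params):
        with pytest.raises(ValueError, match="reason"):
            colonoscopy_procedure(_person(), "curiosity", base_params,
                                  np.random.default_rng(0), year=0)


class TestComplications:
    def test_zero_risk_means_no_complication_events(self, base_params):
        params = base_params.with_overrides({
            "complications.bleed_dx_colo": 0.0,
            "complications.bleed_tx_colo": 0.0,
            "complications.perf_dx_colo": 0.0,
            "complications.perf_tx_colo": 0.0,
        })
        rng = np.random.default_rng(0)
        for _ in range(200):
            events = colonoscopy_procedure(_person(), "surveillance", params,
                                           rng, year=0)
            assert not any(e.kind.startswith("complication") for e in events)

    def test_therapeutic_perforation_and_death_rates(self, base_params):
        # polypectomy perforation risk 0.0024, then death risk 0.049
        params = base_params.model_copy(update={"tests": {
            **base_params.tests,
            "colonoscopy": base_params.tests["colonoscopy"].model_copy(
                update={"sens_advanced": 1.0})}})
        rng = np.random.default_rng(99)
        n = 200_000
        perfs = 0
        for _ in range(n):
            person = _person(state=HealthState.ADVANCED_ADENOMA)
            events = colonoscopy_procedure(person, "surveillance", params,
                                           rng, year=0)
            perfs += any(e.kind == "complication_perforation" for e in events)
        sd = math.sqrt(n * 0.0024 * (1 - 0.0024))
        assert abs(perfs - n * 0.0024) < 3 * sd


class TestStrategyValidation:
    def test_interval_must_be_positive(self):
        with pytest.raises(ValueError):
            StrategyDefinition(label="FIT-mid", interval_years=0)

    def test_unknown_strategy(self):
        with pytest.raises(KeyError):
            get_strategy("barium-enema")


class TestWholeProgrammeInvariants:
    def test_zero_adherence_equals_no_screening_under_common_seeds(self, base_params):
        params = base_params.with_overrides({
            "adherence.first_screen": 0.0,
            "adherence.subsequent_screen": 0.0,
        })
        screened = run_microsim("FIT-mid", params, 2000, seed=77)
        unscreened = run_microsim("none", params, 2000, seed=77)
        assert screened.cancers == unscreened.cancers
        assert screened.cancer_deaths == unscreened.cancer_deaths
        assert screened.total_cost == unscreened.total_cost
        assert screened.total_qaly == unscreened.total_qaly
        assert screened.survivors == unscreened.survivors

    def test_perfect_annual_screening_eliminates_symptomatic_cancer(self, base_params):
        perfect_row = {"sens_nonadvanced": 1.0, "sens_advanced": 1.0,
                       "sens_cancer": 1.0, "specificity_per_person": 1.0}
        params = base_params.with_overrides({
            "adherence.first_screen": 1.0,
            "adherence.subsequent_screen": 1.0,
            "adherence.colonoscopy_after_positive": 1.0,
        })
        params = params.model_copy(update={"tests": {
            **params.tests,
            "FIT-mid": params.tests["FIT-mid"].model_copy(update=perfect_row),
            "colonoscopy": params.tests["colonoscopy"].model_copy(update=perfect_row),
        }})
        # screening offered until the end of life: the invariant concerns
        # the screened span (cancers can still arise after a stop age)
        from dataclasses import replace as dc_replace
        strategy = dc_replace(get_strategy("FIT-mid"), stop_age=99)
        tally = run_microsim(strategy, params, 1500, seed=5)
        assert tally.cancers_symptomatic == 0
        assert tally.cancers == tally.cancers_screen_detected

    def test_event_log_reconciles_with_tally(self, base_params):
        log = []
        tally = run_microsim("FIT-mid", base_params, 500, seed=21, event_log=log)
        kinds = [ev.kind for _, ev in log]
        assert kinds.count("primary_test") == tally.primary_tests
        n_colo = (kinds.count("followup_colonoscopy")
                  + kinds.count("surveillance_colonoscopy"))
        assert n_colo == tally.colonoscopies
        assert kinds.count("crc_detected") == tally.cancers
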