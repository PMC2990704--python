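"""Model inputs for the colorectal-cancer screening cost-utility model.

Every input of the model lives in a single validated :class:`ParameterSet`:
age-stratified adenoma/cancer prevalence and background mortality, annual
transition probabilities of the adenoma-carcinoma sequence, stage
distributions at diagnosis by detection route, stage-specific five-year
mortality, per-person test performance of each screening modality,
adherence, endoscopic complication risks, direct and nonmedical costs
(2008 Canadian dollars), health-state utilities, polyp histology fractions
and structural settings (discounting, ages, cycle length).

The module also implements the probabilistic-sensitivity-analysis layer:
:class:`DistributionSpec` describes a second-order distribution attached to
one parameter path and :func:`sample_psa_parameters` draws a perturbed
parameter set.  Test sensitivities and specificities are deliberately not
samplable: sensitivity and specificity are linked through an ROC curve and
cannot be varied independently, so uncertainty in test performance is
explored through discrete scenarios instead.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Annotated, Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

log = logging.getLogger(__name__)

__all__ = [
    "AgeStratumParams",
    "TransitionRates",
    "StageDistribution",
    "StageDistributions",
    "StageMortality",
    "TestPerformance",
    "AdherenceParams",
    "ComplicationRisks",
    "CostParams",
    "UtilityParams",
    "HistologyFractions",
    "StructuralSettings",
    "DistributionSpec",
    "ParameterSet",
    "ConfigError",
    "base_case",
    "default_psa_specs",
    "load_parameters",
    "load_config",
    "dump_config",
    "emit_fixture",
    "sample_psa_parameters",
    "get_by_path",
    "PARAMETER_RANGES",
]

Probability = Annotated[float, Field(ge=0.0, le=1.0)]
NonNegative = Annotated[float, Field(ge=0.0)]


class ConfigError(ValueError):
    """Raised when a configuration file violates the schema or a range."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class AgeStratumParams(_Model):
    """Prevalence at cohort entry and background mortality for one age band."""

    stratum_label: Literal["50-64", "65-75"]
    prev_nonadvanced: Probability
    prev_advanced: Probability
    prev_crc: Probability
    annual_background_death: Probability

    @model_validator(mode="after")
    def _check_prevalence_budget(self) -> "AgeStratumParams":
        total = self.prev_nonadvanced + self.prev_advanced + self.prev_crc
        if total >= 1.0:
            raise ValueError(
                f"prevalences sum to {total:.3f}; must leave room for the lesion-free state"
            )
        return self


class TransitionRates(_Model):
    """Annual transition probabilities of the adenoma-carcinoma sequence."""

    normal_to_nonadv_no_history: Probability
    normal_to_nonadv_history: Probability
    nonadv_to_adv: Probability
    adv_to_crc: Probability

    @model_validator(mode="after")
    def _history_at_least_naive(self) -> "TransitionRates":
        if self.normal_to_nonadv_history < self.normal_to_nonadv_no_history:
            raise ValueError(
                "new-adenoma probability with an adenoma/CRC history must be >= "
                "the probability without a history"
            )
        return self


DetectionContext = Literal["unscreened", "stool_detected", "structural_detected"]


class StageDistribution(_Model):
    """Stage I-IV probabilities at diagnosis for one detection route.

    Rows are renormalized to sum exactly to one (stochastic stage assignment
    requires a proper distribution); any adjustment is logged.
    """

    detection_context: DetectionContext
    p_stage: Tuple[Probability, Probability, Probability, Probability]

    @model_validator(mode="before")
    @classmethod
    def _renormalize(cls, data):
        if isinstance(data, dict) and "p_stage" in data:
            p = [float(x) for x in data["p_stage"]]
            total = sum(p)
            if total <= 0:
                raise ValueError("stage probabilities must have a positive sum")
            if abs(total - 1.0) > 1e-9:
                log.info(
                    "renormalizing stage distribution %s: printed row sums to %.6f",
                    data.get("detection_context"), total,
                )
                data = dict(data, p_stage=tuple(x / total for x in p))
        return data


class StageDistributions(_Model):
    unscreened: StageDistribution
    stool_detected: StageDistribution
    structural_detected: StageDistribution

    def for_context(self, context: str) -> StageDistribution:
        try:
            return getattr(self, context)
        except AttributeError:
            raise ConfigError(f"unknown detection context {context!r}") from None


class StageMortality(_Model):
    """Five-year case fatality by stage at diagnosis."""

    five_year_mortality: Tuple[Probability, Probability, Probability, Probability]

    @model_validator(mode="after")
    def _nondecreasing(self) -> "StageMortality":
        m = self.five_year_mortality
        if any(m[i] > m[i + 1] for i in range(3)):
            raise ValueError("five-year mortality must be nondecreasing across stages")
        return self


class TestPerformance(_Model):
    """Per-person sensitivity by lesion class and per-person specificity."""

    modality_label: str
    sens_nonadvanced: Probability
    sens_advanced: Probability
    sens_cancer: Probability
    specificity_per_person: Probability


class AdherenceParams(_Model):
    first_screen: Probability
    subsequent_screen: Probability
    colonoscopy_after_positive: Probability


class ComplicationRisks(_Model):
    bleed_dx_colo: Probability
    bleed_tx_colo: Probability
    perf_dx_colo: Probability
    perf_tx_colo: Probability
    perf_flexsig: Probability
    perf_ctc: Probability
    death_after_perforation: Probability

    @model_validator(mode="after")
    def _therapeutic_riskier(self) -> "ComplicationRisks":
        if self.bleed_tx_colo < self.bleed_dx_colo:
            raise ValueError("therapeutic bleed risk must be >= diagnostic")
        if self.perf_tx_colo < self.perf_dx_colo:
            raise ValueError("therapeutic perforation risk must be >= diagnostic")
        return self


class CostParams(_Model):
    """Direct, nonmedical, complication and cancer-management costs (2008 CAN$)."""

    direct_test_cost: Dict[str, NonNegative]
    nonmedical_cost: Dict[str, NonNegative]
    complication_cost: Dict[str, NonNegative]
    crc_management_cost: Tuple[NonNegative, NonNegative, NonNegative, NonNegative]
    admin_cost_per_test: NonNegative = 0.0

    @model_validator(mode="after")
    def _check(self) -> "CostParams":
        c = self.crc_management_cost
        if any(c[i] > c[i + 1] for i in range(3)):
            raise ValueError("CRC management cost must be nondecreasing across stages")
        for key in ("FOBT", "FIT", "FDNA", "flex_sig", "CTC",
                    "colonoscopy_diagnostic", "colonoscopy_therapeutic"):
            if key not in self.direct_test_cost:
                raise ValueError(f"direct_test_cost missing entry for {key!r}")
        for key in ("FOBT", "FIT", "FDNA", "colonoscopy", "CTC", "flex_sig"):
            if key not in self.nonmedical_cost:
                raise ValueError(f"nonmedical_cost missing entry for {key!r}")
        for key in ("bleed", "perforation"):
            if key not in self.complication_cost:
                raise ValueError(f"complication_cost missing entry for {key!r}")
        return self


class UtilityParams(_Model):
    u_no_crc: Probability
    u_early_crc: Probability
    u_advanced_crc: Probability

    @model_validator(mode="after")
    def _ordered(self) -> "UtilityParams":
        if not (self.u_no_crc >= self.u_early_crc >= self.u_advanced_crc):
            raise ValueError("utilities must satisfy no-CRC >= early >= advanced")
        return self


class HistologyFractions(_Model):
    """Fraction of polyps that are adenomatous, by size class."""

    adenomatous_lt10mm: Probability
    adenomatous_ge10mm: Probability


class StructuralSettings(_Model):
    discount_rate: NonNegative = 0.05
    cycle_length: Literal[1] = 1
    screen_start_age: int = 50
    screen_stop_age: int = 75
    max_age: int = 100
    crc_survival_window: int = 5
    # Annual probability that an undiagnosed cancer presents symptomatically.
    # Not directly observable; it is the sojourn-time knob exposed to
    # calibration (see engine.calibrate).
    symptomatic_presentation_annual_prob: Probability = 0.4
    # Years of routine-screening exemption after a clean colonoscopy (0 disables).
    clean_colonoscopy_exemption_years: int = 10
    # Background mortality schedule: "gompertz" anchors an exponential
    # age-specific curve to the two printed stratum means and extrapolates
    # it over the lifetime; "stratum" applies the two means as flat bands
    # (ages above 75 reuse the 65-75 value).
    mortality_model: Literal["gompertz", "stratum"] = "gompertz"

    @model_validator(mode="after")
    def _ages_increasing(self) -> "StructuralSettings":
        if not (self.screen_start_age < self.screen_stop_age < self.max_age):
            raise ValueError("ages must satisfy start < stop < max")
        if self.clean_colonoscopy_exemption_years < 0:
            raise ValueError("exemption years must be >= 0")
        return self


class DistributionSpec(_Model):
    """Second-order distribution attached to one parameter path.

    ``params`` carries the family parameters: ``alpha``/``beta`` or
    ``mean``/``sd`` for beta, ``mean``/``sd`` for normal and log-normal
    (arithmetic moments), ``low``/``mode``/``high`` for triangular.  Sampled
    values are truncated to ``[low, high]`` when given.
    """

    parameter_path: str
    family: Literal["beta", "normal", "log-normal", "triangular"]
    params: Dict[str, float]
    low: Optional[float] = None
    high: Optional[float] = None

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "beta":
            if "alpha" in p and "beta" in p:
                a, b = p["alpha"], p["beta"]
            else:
                a, b = _beta_from_moments(p["mean"], p["sd"])
            value = rng.beta(a, b)
        elif self.family == "normal":
            value = rng.normal(p["mean"], p["sd"])
        elif self.family == "log-normal":
            mu, sigma = _lognormal_from_moments(p["mean"], p["sd"])
            value = rng.lognormal(mu, sigma)
        else:  # triangular (degenerate ranges collapse to a point mass)
            if p["low"] == p["high"]:
                value = p["low"]
            else:
                value = rng.triangular(p["low"], p["mode"], p["high"])
        lo = self.low if self.low is not None else (0.0 if self.family == "beta" else None)
        hi = self.high if self.high is not None else (1.0 if self.family == "beta" else None)
        if lo is not None:
            value = max(lo, value)
        if hi is not None:
            value = min(hi, value)
        return float(value)

    def analytic_mean(self) -> float:
        """Mean of the untruncated family (used by sampling diagnostics)."""
        p = self.params
        if self.family == "beta":
            if "alpha" in p and "beta" in p:
                return p["alpha"] / (p["alpha"] + p["beta"])
            return p["mean"]
        if self.family in ("normal", "log-normal"):
            return p["mean"]
        return (p["low"] + p["mode"] + p["high"]) / 3.0


def _beta_from_moments(mean: float, sd: float) -> Tuple[float, float]:
    if not 0.0 < mean < 1.0:
        raise ConfigError(f"beta mean must be in (0,1), got {mean}")
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise ConfigError(f"beta sd {sd} too large for mean {mean}")
    nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def _lognormal_from_moments(mean: float, sd: float) -> Tuple[float, float]:
    if mean <= 0:
        raise ConfigError(f"log-normal mean must be positive, got {mean}")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


class ParameterSet(_Model):
    """Complete, validated input bundle for the model."""

    stratum_50_64: AgeStratumParams
    stratum_65_75: AgeStratumParams
    transition: TransitionRates
    stage_distributions: StageDistributions
    stage_mortality: StageMortality
    tests: Dict[str, TestPerformance]
    adherence: AdherenceParams
    complications: ComplicationRisks
    costs: CostParams
    utilities: UtilityParams
    histology: HistologyFractions
    structural: StructuralSettings

    @model_validator(mode="after")
    def _required_tests_present(self) -> "ParameterSet":
        for key in ("colonoscopy", "colonoscopy-after-CTC"):
            if key not in self.tests:
                raise ValueError(f"tests must include the {key!r} performance row")
        return self

    def stratum_for_age(self, age: int) -> AgeStratumParams:
        return self.stratum_50_64 if age < 65 else self.stratum_65_75

    def with_overrides(self, overrides: Dict[str, object]) -> "ParameterSet":
        """Return a new set with dotted-path overrides applied and revalidated."""
        data = _to_mutable(self.model_dump())
        for path, value in overrides.items():
            _set_by_path(data, path, value)
        try:
            return ParameterSet.model_validate(data)
        except ValidationError as exc:
            raise ConfigError(_format_validation_error(exc)) from exc


def _to_mutable(obj):
    """Recursively convert tuples from a model dump into lists."""
    if isinstance(obj, (list, tuple)):
        return [_to_mutable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_mutable(v) for k, v in obj.items()}
    return obj


def _set_by_path(data, path: str, value) -> None:
    keys = path.split(".")
    node = data
    for key in keys[:-1]:
        if isinstance(node, (list, tuple)):
            node = node[int(key)]
        elif isinstance(node, dict) and key in node:
            node = node[key]
        else:
            raise ConfigError(f"unknown parameter path {path!r} (at {key!r})")
    last = keys[-1]
    if isinstance(node, dict):
        if last not in node:
            raise ConfigError(f"unknown parameter path {path!r} (at {last!r})")
        node[last] = value
    elif isinstance(node, list):
        node[int(last)] = value
    else:
        # tuples inside a model_dump arrive as lists, so reaching here means
        # the path addressed a scalar's child
        raise ConfigError(f"parameter path {path!r} does not address a field")


def get_by_path(params: ParameterSet, path: str):
    node = params.model_dump()
    for key in path.split("."):
        if isinstance(node, (list, tuple)):
            node = node[int(key)]
        elif isinstance(node, dict) and key in node:
            node = node[key]
        else:
            raise ConfigError(f"unknown parameter path {path!r} (at {key!r})")
    return node


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "invalid parameter configuration: " + "; ".join(lines)


# --------------------------------------------------------------------------
# Base case

_TEST_ROWS = {
    # label: (sens nonadvanced, sens advanced, sens cancer, specificity)
    "FOBT-low": (0.052, 0.107, 0.129, 0.952),
    "FOBT-high": (0.030, 0.074, 0.500, 0.980),
    "FIT-low": (0.070, 0.224, 0.660, 0.950),
    "FIT-mid": (0.180, 0.540, 0.810, 0.960),
    "FIT-high": (0.180, 0.610, 0.940, 0.910),
    "colonoscopy": (0.850, 0.875, 0.966, 1.000),
    "colonoscopy-after-CTC": (0.900, 0.970, 0.990, 1.000),
    "CTC": (0.760, 0.900, 0.966, 0.890),
    "flex_sig": (0.650, 0.750, 0.750, 1.000),
    "FDNA-SDT2": (0.040, 0.447, 0.580, 0.840),
    "FDNA-SDT1": (0.076, 0.151, 0.516, 0.944),
}


@lru_cache(maxsize=1)
def base_case() -> ParameterSet:
    """The base-case parameter set (all values in 2008 CAN$ where monetary)."""
    return ParameterSet(
        stratum_50_64=AgeStratumParams(
            stratum_label="50-64",
            prev_nonadvanced=0.171,
            prev_advanced=0.038,
            prev_crc=0.001,
            annual_background_death=0.005,
        ),
        stratum_65_75=AgeStratumParams(
            stratum_label="65-75",
            prev_nonadvanced=0.173,
            prev_advanced=0.082,
            prev_crc=0.007,
            annual_background_death=0.018,
        ),
        transition=TransitionRates(
            normal_to_nonadv_no_history=0.02,
            normal_to_nonadv_history=0.038,
            nonadv_to_adv=0.019,
            adv_to_crc=0.048,
        ),
        stage_distributions=StageDistributions(
            unscreened=StageDistribution(
                detection_context="unscreened",
                p_stage=(0.145, 0.356, 0.280, 0.219),
            ),
            stool_detected=StageDistribution(
                detection_context="stool_detected",
                p_stage=(0.305, 0.318, 0.243, 0.134),
            ),
            structural_detected=StageDistribution(
                detection_context="structural_detected",
                p_stage=(0.425, 0.226, 0.267, 0.082),
            ),
        ),
        stage_mortality=StageMortality(
            five_year_mortality=(0.068, 0.175, 0.405, 0.919),
        ),
        tests={
            label: TestPerformance(
                modality_label=label,
                sens_nonadvanced=row[0],
                sens_advanced=row[1],
                sens_cancer=row[2],
                specificity_per_person=row[3],
            )
            for label, row in _TEST_ROWS.items()
        },
        adherence=AdherenceParams(
            first_screen=0.68,
            subsequent_screen=0.63,
            colonoscopy_after_positive=0.81,
        ),
        complications=ComplicationRisks(
            bleed_dx_colo=0.0003,
            bleed_tx_colo=0.005,
            perf_dx_colo=0.0009,
            perf_tx_colo=0.0024,
            perf_flexsig=0.0002,
            perf_ctc=0.0,
            death_after_perforation=0.049,
        ),
        costs=CostParams(
            direct_test_cost={
                "FOBT": 12.0,
                "FIT": 19.0,
                "FDNA": 336.0,
                "flex_sig": 650.0,
                "CTC": 582.0,
                "colonoscopy_diagnostic": 857.0,
                "colonoscopy_therapeutic": 999.0,
            },
            nonmedical_cost={
                "FOBT": 36.0,
                "FIT": 36.0,
                "FDNA": 36.0,
                "colonoscopy": 308.0,
                "CTC": 105.0,
                "flex_sig": 105.0,
            },
            complication_cost={"bleed": 3194.0, "perforation": 31223.0},
            crc_management_cost=(25049.0, 36143.0, 96768.0, 134014.0),
            admin_cost_per_test=0.0,
        ),
        utilities=UtilityParams(u_no_crc=0.91, u_early_crc=0.74, u_advanced_crc=0.46),
        histology=HistologyFractions(adenomatous_lt10mm=0.41, adenomatous_ge10mm=0.82),
        structural=StructuralSettings(),
    )


#: Printed plausible ranges for ranged inputs (used to bound calibration and
#: to build the default second-order distributions).
PARAMETER_RANGES: Dict[str, Tuple[float, float]] = {
    "stratum_50_64.prev_nonadvanced": (0.10, 0.25),
    "stratum_50_64.prev_advanced": (0.02, 0.05),
    "stratum_50_64.prev_crc": (0.0005, 0.002),
    "stratum_65_75.prev_nonadvanced": (0.10, 0.25),
    "stratum_65_75.prev_advanced": (0.05, 0.10),
    "stratum_65_75.prev_crc": (0.002, 0.01),
    "transition.normal_to_nonadv_no_history": (0.01, 0.03),
    "transition.normal_to_nonadv_history": (0.03, 0.05),
    "transition.nonadv_to_adv": (0.01, 0.03),
    "transition.adv_to_crc": (0.03, 0.07),
    "stage_distributions.unscreened.p_stage.0": (0.12, 0.25),
    "stage_distributions.unscreened.p_stage.1": (0.34, 0.39),
    "stage_distributions.unscreened.p_stage.2": (0.23, 0.32),
    "stage_distributions.unscreened.p_stage.3": (0.18, 0.25),
    "stage_distributions.stool_detected.p_stage.0": (0.29, 0.33),
    "stage_distributions.stool_detected.p_stage.1": (0.30, 0.35),
    "stage_distributions.stool_detected.p_stage.2": (0.20, 0.26),
    "stage_distributions.stool_detected.p_stage.3": (0.10, 0.15),
    "stage_distributions.structural_detected.p_stage.0": (0.41, 0.50),
    "stage_distributions.structural_detected.p_stage.1": (0.22, 0.26),
    "stage_distributions.structural_detected.p_stage.2": (0.20, 0.27),
    "stage_distributions.structural_detected.p_stage.3": (0.0, 0.09),
    "adherence.first_screen": (0.30, 0.80),
    "adherence.subsequent_screen": (0.10, 0.80),
    "adherence.colonoscopy_after_positive": (0.60, 0.90),
    "complications.bleed_dx_colo": (0.0, 0.009),
    "complications.bleed_tx_colo": (0.003, 0.015),
    "complications.perf_dx_colo": (0.0005, 0.002),
    "complications.perf_tx_colo": (0.001, 0.005),
    "complications.perf_flexsig": (0.0001, 0.0004),
    "complications.death_after_perforation": (0.01, 0.15),
    "costs.direct_test_cost.FOBT": (6.0, 18.0),
    "costs.direct_test_cost.FIT": (10.0, 30.0),
    "costs.direct_test_cost.colonoscopy_diagnostic": (500.0, 1200.0),
    "costs.direct_test_cost.colonoscopy_therapeutic": (700.0, 1700.0),
    "costs.direct_test_cost.CTC": (440.0, 730.0),
    "costs.direct_test_cost.FDNA": (200.0, 500.0),
    "costs.direct_test_cost.flex_sig": (400.0, 900.0),
    "costs.complication_cost.bleed": (2400.0, 4000.0),
    "costs.complication_cost.perforation": (23500.0, 39000.0),
    "costs.nonmedical_cost.FOBT": (25.0, 50.0),
    "costs.nonmedical_cost.FIT": (25.0, 50.0),
    "costs.nonmedical_cost.FDNA": (25.0, 50.0),
    "costs.nonmedical_cost.colonoscopy": (200.0, 450.0),
    "costs.nonmedical_cost.CTC": (100.0, 200.0),
    "costs.nonmedical_cost.flex_sig": (100.0, 200.0),
}

_FORBIDDEN_PSA_PREFIX = "tests."

# Proportions with a printed range but an asymmetric base value get a beta
# distribution (moment-matched, sd = quarter of the printed range); ranged
# rates and adherence get a triangular distribution with the base value as
# the mode; costs get a log-normal with the same quarter-range sd.
_TRIANGULAR_PATHS = {
    "transition.normal_to_nonadv_no_history",
    "transition.normal_to_nonadv_history",
    "transition.nonadv_to_adv",
    "transition.adv_to_crc",
    "adherence.first_screen",
    "adherence.subsequent_screen",
    "adherence.colonoscopy_after_positive",
}


def default_psa_specs(params: Optional[ParameterSet] = None) -> List[DistributionSpec]:
    """Second-order distributions for every ranged probability and cost input.

    Test performance is excluded by construction.  Utilities (no printed
    range) get a normal distribution with sd 0.05; stage management costs
    (no printed range) a log-normal with a 10% coefficient of variation.
    """
    params = params or base_case()
    specs: List[DistributionSpec] = []
    for path, (lo, hi) in PARAMETER_RANGES.items():
        base = float(get_by_path(params, path))
        if path in _TRIANGULAR_PATHS:
            specs.append(DistributionSpec(
                parameter_path=path, family="triangular",
                params={"low": lo, "mode": base, "high": hi}, low=lo, high=hi,
            ))
        elif path.startswith("costs."):
            specs.append(DistributionSpec(
                parameter_path=path, family="log-normal",
                params={"mean": base, "sd": (hi - lo) / 4.0}, low=lo, high=hi,
            ))
        else:
            if not 0.0 < base < 1.0:
                continue  # e.g. a zero lower bound with a zero base value
            sd = (hi - lo) / 4.0
            sd = min(sd, 0.9 * np.sqrt(base * (1 - base)))
            specs.append(DistributionSpec(
                parameter_path=path, family="beta",
                params={"mean": base, "sd": float(sd)}, low=lo, high=hi,
            ))
    for i, m5 in enumerate(params.stage_mortality.five_year_mortality):
        specs.append(DistributionSpec(
            parameter_path=f"stage_mortality.five_year_mortality.{i}",
            family="beta", params={"mean": m5, "sd": 0.1 * m5},
        ))
    for field in ("u_no_crc", "u_early_crc", "u_advanced_crc"):
        specs.append(DistributionSpec(
            parameter_path=f"utilities.{field}", family="normal",
            params={"mean": float(getattr(params.utilities, field)), "sd": 0.05},
            low=0.0, high=1.0,
        ))
    for i, c in enumerate(params.costs.crc_management_cost):
        specs.append(DistributionSpec(
            parameter_path=f"costs.crc_management_cost.{i}",
            family="log-normal", params={"mean": c, "sd": 0.1 * c}, low=0.0,
        ))
    return specs


def sample_psa_parameters(
    base: ParameterSet,
    specs: List[DistributionSpec],
    seed: int | np.random.Generator,
) -> ParameterSet:
    """Draw one second-order parameter set.

    Stage distributions are renormalized after sampling, and the ordering
    invariants (utilities, stage costs, history transition) are restored by
    clipping against neighbouring sampled values, so that every draw is a
    valid :class:`ParameterSet`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    overrides: Dict[str, float] = {}
    for spec in specs:
        if spec.parameter_path.startswith(_FORBIDDEN_PSA_PREFIX):
            raise ConfigError(
                f"{spec.parameter_path!r}: test sensitivity/specificity cannot be "
                "sampled (linked via ROC; vary them through scenarios instead)"
            )
        overrides[spec.parameter_path] = spec.sample(rng)
    if not overrides:
        return base
    data = _to_mutable(base.model_dump())
    for path, value in overrides.items():
        _set_by_path(data, path, value)
    _restore_order_invariants(data)
    try:
        return ParameterSet.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def _restore_order_invariants(data: dict) -> None:
    tr = data["transition"]
    tr["normal_to_nonadv_history"] = max(
        tr["normal_to_nonadv_history"], tr["normal_to_nonadv_no_history"])
    u = data["utilities"]
    u["u_early_crc"] = min(u["u_early_crc"], u["u_no_crc"])
    u["u_advanced_crc"] = min(u["u_advanced_crc"], u["u_early_crc"])
    m = sorted(data["stage_mortality"]["five_year_mortality"])
    data["stage_mortality"]["five_year_mortality"] = m
    data["costs"]["crc_management_cost"] = sorted(data["costs"]["crc_management_cost"])
    comp = data["complications"]
    comp["bleed_tx_colo"] = max(comp["bleed_tx_colo"], comp["bleed_dx_colo"])
    comp["perf_tx_colo"] = max(comp["perf_tx_colo"], comp["perf_dx_colo"])


# --------------------------------------------------------------------------
# Configuration file I/O

_SCHEMA_TAG = "crcscreen-parameters/1"


def dump_config(params: ParameterSet, specs: Optional[List[DistributionSpec]] = None) -> str:
    doc = {
        "schema": _SCHEMA_TAG,
        "inherit_base_case": False,
        "parameters": params.model_dump(),
        "distributions": [s.model_dump() for s in (specs or [])],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def load_config(text: str) -> Tuple[ParameterSet, List[DistributionSpec]]:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(doc) - {"schema", "inherit_base_case", "parameters", "distributions"}
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if doc.get("schema", _SCHEMA_TAG) != _SCHEMA_TAG:
        raise ConfigError(f"unsupported schema {doc.get('schema')!r}")
    payload = doc.get("parameters") or {}
    if doc.get("inherit_base_case", False):
        merged = base_case().model_dump()
        _deep_merge(merged, payload)
        payload = merged
    try:
        params = ParameterSet.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc
    specs = [DistributionSpec.model_validate(s) for s in doc.get("distributions") or []]
    return params, specs


def load_parameters(text: str) -> ParameterSet:
    return load_config(text)[0]


def _deep_merge(target: dict, overlay: dict) -> None:
    for key, value in overlay.items():
        if key in target and isinstance(target[key], dict) and isinstance(value, dict):
            _deep_merge(target[key], value)
        else:
            target[key] = value


def emit_fixture(path, params: Optional[ParameterSet] = None,
                 specs: Optional[List[DistributionSpec]] = None) -> None:
    """Write the base-case configuration with the default second-order specs."""
    params = params or base_case()
    specs = specs if specs is not None else default_psa_specs(params)
    text = dump_config(params, specs)
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise ConfigError(f"cannot write fixture to {path!r}: {exc}") from exc
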