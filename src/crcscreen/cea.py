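"""Incremental cost-effectiveness analysis and probabilistic sensitivity analysis.

Strategies are ranked by increasing mean discounted cost.  A strategy is
*strongly dominated* when another strategy costs no more and yields at
least as many QALYs (one strictly); it is *extendedly dominated* when a
blend of two other strategies dominates it, which manifests as a
non-increasing ICER sequence along the cost-ordered frontier.  Both flags
are reported separately so either elimination convention can be read off.
ICERs are computed between adjacent members of the efficient frontier.

The PSA draws whole parameter sets from the second-order distributions
(test performance excluded), evaluates every strategy on the *same* draw
(common random numbers, so incremental quantities are paired), and reports
empirical 2.5th/97.5th percentile intervals (linear interpolation between
closest ranks) plus the incremental cost/QALY scatter for a designated
comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .engine import run_cohort_expectation
from .parameters import (
    DistributionSpec,
    ParameterSet,
    default_psa_specs,
    sample_psa_parameters,
)
from .screening import StrategyDefinition, default_strategies

__all__ = [
    "StrategyResult",
    "percentile_interval",
    "CEARow",
    "CEAResult",
    "PSAOutput",
    "incremental_analysis",
    "run_psa",
    "scenario_run",
    "evaluate_strategies",
    "SCENARIOS",
]


@dataclass
class StrategyResult:
    label: str
    cost: float
    qaly: float
    cost_ci: Optional[Tuple[float, float]] = None
    qaly_ci: Optional[Tuple[float, float]] = None


@dataclass
class CEARow:
    label: str
    cost: float
    qaly: float
    strongly_dominated: bool = False
    extendedly_dominated: bool = False
    icer: Optional[float] = None  # vs next cheaper frontier member; inf flagged
    comparator: Optional[str] = None
    icer_flag: Optional[str] = None


@dataclass
class CEAResult:
    rows: List[CEARow]
    frontier: List[str]

    def row(self, label: str) -> CEARow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def incremental_analysis(results: Sequence[StrategyResult]) -> CEAResult:
    """Rank strategies, flag dominance and compute frontier ICERs."""
    if len(results) < 2:
        raise ValueError("need at least two strategies")
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")

    rows = [CEARow(r.label, r.cost, r.qaly)
            for r in sorted(results, key=lambda r: (r.cost, -r.qaly, r.label))]

    for row in rows:
        for other in rows:
            if other is row:
                continue
            if (other.cost <= row.cost and other.qaly >= row.qaly
                    and (other.cost < row.cost or other.qaly > row.qaly)):
                row.strongly_dominated = True
                break

    candidates = [r for r in rows if not r.strongly_dominated]
    # peel extendedly dominated strategies until the ICER chain is increasing
    changed = True
    while changed and len(candidates) > 2:
        changed = False
        for i in range(1, len(candidates) - 1):
            prev, cur, nxt = candidates[i - 1], candidates[i], candidates[i + 1]
            icer_cur = _safe_icer(cur, prev)
            icer_nxt = _safe_icer(nxt, cur)
            if (icer_cur is not None and icer_nxt is not None
                    and icer_cur >= icer_nxt):
                cur.extendedly_dominated = True
                candidates.pop(i)
                changed = True
                break

    frontier = [r.label for r in candidates]
    for prev, cur in zip(candidates, candidates[1:]):
        dq = cur.qaly - prev.qaly
        dc = cur.cost - prev.cost
        cur.comparator = prev.label
        if dq == 0:
            if dc == 0:
                cur.icer = None
                cur.icer_flag = "identical cost and effect"
            else:
                cur.icer = math.inf
                cur.icer_flag = "zero QALY gain"
        else:
            cur.icer = dc / dq
    return CEAResult(rows=rows, frontier=frontier)


def _safe_icer(cur: CEARow, prev: CEARow) -> Optional[float]:
    dq = cur.qaly - prev.qaly
    if dq == 0:
        return math.inf if cur.cost > prev.cost else None
    return (cur.cost - prev.cost) / dq


def percentile_interval(values, lo: float = 2.5, hi: float = 97.5) -> Tuple[float, float]:
    """Empirical percentile interval, linear interpolation between closest ranks."""
    return (float(np.percentile(values, lo)), float(np.percentile(values, hi)))


# ---------------------------------------------------------------------------
# Strategy evaluation helpers


def evaluate_strategies(strategies: Dict[str, StrategyDefinition],
                        params: ParameterSet) -> List[StrategyResult]:
    """Deterministic cohort evaluation of each strategy on one parameter set."""
    out = []
    for label, strat in strategies.items():
        tally = run_cohort_expectation(strat, params)
        out.append(StrategyResult(label=label, cost=tally.mean_cost,
                                  qaly=tally.mean_qaly))
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PSAOutput:
    comparison: Tuple[str, str]  # (strategy, reference)
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    quadrant_fractions: Dict[str, float] = field(default_factory=dict)
    draws: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def run_psa(strategies: Dict[str, StrategyDefinition],
            base_params: ParameterSet,
            specs: Optional[List[DistributionSpec]] = None,
            n_draws: int = 100,
            seed: int = 0,
            comparison: Tuple[str, str] = ("FIT-mid", "none"),
            ) -> Tuple[PSAOutput, List[StrategyResult]]:
    """Second-order uncertainty analysis.

    Returns the incremental scatter for ``comparison`` and per-strategy
    results whose point estimates come from the base-case parameter set and
    whose intervals are the 2.5/97.5 empirical percentiles over draws.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    for label in comparison:
        if label not in strategies:
            raise ValueError(f"comparison strategy {label!r} not evaluated")
    specs = default_psa_specs(base_params) if specs is None else specs
    rng = np.random.default_rng(seed)
    labels = list(strategies)
    costs = {lab: np.empty(n_draws) for lab in labels}
    qalys = {lab: np.empty(n_draws) for lab in labels}
    for i in range(n_draws):
        draw_params = sample_psa_parameters(base_params, specs, rng)
        for lab in labels:
            tally = run_cohort_expectation(strategies[lab], draw_params)
            costs[lab][i] = tally.mean_cost
            qalys[lab][i] = tally.mean_qaly

    results = []
    for res in evaluate_strategies(strategies, base_params):
        res.cost_ci = percentile_interval(costs[res.label])
        res.qaly_ci = percentile_interval(qalys[res.label])
        results.append(res)

    target, ref = comparison
    dc = costs[target] - costs[ref]
    dq = qalys[target] - qalys[ref]
    more_eff = dq > 0
    cheaper = dc < 0
    quadrants = {
        "cheaper_more_effective": float(np.mean(more_eff & cheaper)),
        "costlier_more_effective": float(np.mean(more_eff & ~cheaper)),
        "cheaper_less_effective": float(np.mean(~more_eff & cheaper)),
        "costlier_less_effective": float(np.mean(~more_eff & ~cheaper)),
    }
    psa = PSAOutput(comparison=comparison, delta_cost=dc, delta_qaly=dq,
                    quadrant_fractions=quadrants,
                    draws={lab: (costs[lab], qalys[lab]) for lab in labels})
    return psa, results


# ---------------------------------------------------------------------------
# Scenario analyses

_TABLE6_STRATEGIES = ("none", "FIT-mid", "FIT-high", "colonoscopy")


def _strat_subset(labels: Sequence[str]) -> Dict[str, StrategyDefinition]:
    all_s = default_strategies()
    return {lab: all_s[lab] for lab in labels}


def _identity(params, strategies):
    return params, strategies


def _no_biologics(params, strategies):
    params = params.with_overrides({
        "costs.crc_management_cost.1": 35844.0,
        "costs.crc_management_cost.2": 80345.0,
        "costs.crc_management_cost.3": 99574.0,
    })
    return params, strategies


def _fit_cost_plus_50pct(params, strategies):
    base = params.costs.direct_test_cost["FIT"]
    return params.with_overrides({"costs.direct_test_cost.FIT": base * 1.5}), strategies


def _biennial_fit(params, strategies):
    strategies = {lab: (s.with_interval(2) if lab.startswith("FIT") else s)
                  for lab, s in strategies.items()}
    return params, strategies


_DIFFERENTIAL_FIRST = {"FIT": 0.60, "FDNA": 0.60, "FOBT": 0.50,
                       "CTC": 0.40, "colonoscopy": 0.30, "flex_sig": 0.30}


def _differential_first_adherence(params, strategies):
    out = {}
    for lab, s in strategies.items():
        if lab == "none":
            out[lab] = s
            continue
        out[lab] = replace(s, first_adherence=_DIFFERENTIAL_FIRST[s.cost_key])
    return params, out


def _subsequent_adherence(value: float):
    def apply(params, strategies):
        out = {lab: (replace(s, subsequent_adherence=value)
                     if lab.startswith(("FIT", "FOBT")) else s)
               for lab, s in strategies.items()}
        return params, out
    return apply


def _admin_cost(value: float):
    def apply(params, strategies):
        return params.with_overrides({"costs.admin_cost_per_test": value}), strategies
    return apply


def _no_nonmedical(params, strategies):
    overrides = {f"costs.nonmedical_cost.{k}": 0.0
                 for k in params.costs.nonmedical_cost}
    return params.with_overrides(overrides), strategies


SCENARIOS: Dict[str, Callable] = {
    "base_case": _identity,
    "no_biologics": _no_biologics,
    "fit_cost_plus_50pct": _fit_cost_plus_50pct,
    "biennial_fit": _biennial_fit,
    "differential_first_adherence": _differential_first_adherence,
    "subsequent_adherence_40": _subsequent_adherence(0.40),
    "subsequent_adherence_20": _subsequent_adherence(0.20),
    "admin_cost_10": _admin_cost(10.0),
    "admin_cost_30": _admin_cost(30.0),
    "admin_cost_50": _admin_cost(50.0),
    "no_nonmedical": _no_nonmedical,
}


def scenario_run(scenario_name: str,
                 base_params: ParameterSet,
                 strategies: Optional[Dict[str, StrategyDefinition]] = None,
                 overrides: Optional[Dict[str, object]] = None) -> CEAResult:
    """Apply a registered scenario (plus optional ad-hoc parameter overrides)
    and rerun the incremental analysis."""
    if scenario_name not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario_name!r}; registered: "
                       f"{sorted(SCENARIOS)}")
    strategies = strategies or _strat_subset(_TABLE6_STRATEGIES)
    params, strategies = SCENARIOS[scenario_name](base_params, strategies)
    if overrides:
        params = params.with_overrides(overrides)
    return incremental_analysis(evaluate_strategies(strategies, params))
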