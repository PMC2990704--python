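"""Delimited-text report writers mirroring the headline result tables.

Monetary display values are rounded to the nearest dollar with thousands
separators and QALYs to three decimals; the unrounded values are always
emitted alongside so downstream comparisons never operate on rounded
numbers.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence

import pandas as pd

from .cea import CEAResult, PSAOutput, StrategyResult
from .engine import OutcomeTally

__all__ = ["cea_table", "tally_table", "write_table4", "write_table5",
           "write_scatter"]


def _money(x: float) -> str:
    return f"{x:,.0f}"


def cea_table(result: CEAResult,
              psa_results: Optional[Sequence[StrategyResult]] = None) -> pd.DataFrame:
    """Cost/QALY ranking with dominance flags and frontier ICERs."""
    ci = {r.label: r for r in psa_results or []}
    rows = []
    for r in result.rows:
        status = ("strongly dominated" if r.strongly_dominated
                  else "extendedly dominated" if r.extendedly_dominated
                  else "")
        rec = {
            "strategy": r.label,
            "cost_display": _money(r.cost),
            "qaly_display": f"{r.qaly:.3f}",
            "status": status,
            "icer_vs_next_cheaper": "" if r.icer is None else _money(r.icer),
            "comparator": r.comparator or "",
            "cost_raw": r.cost,
            "qaly_raw": r.qaly,
        }
        p = ci.get(r.label)
        if p is not None and p.cost_ci is not None:
            rec["cost_95ci"] = f"({_money(p.cost_ci[0])}-{_money(p.cost_ci[1])})"
            rec["qaly_95ci"] = f"({p.qaly_ci[0]:.2f}-{p.qaly_ci[1]:.2f})"
        rows.append(rec)
    return pd.DataFrame(rows)


def write_table4(result: CEAResult, path,
                 psa_results: Optional[Sequence[StrategyResult]] = None) -> None:
    cea_table(result, psa_results).to_csv(path, index=False)


def tally_table(tallies: Iterable[OutcomeTally]) -> pd.DataFrame:
    """Lifetime outcome counts per 100,000, ordered by cancer deaths."""
    rows = []
    for t in tallies:
        rows.append({
            "strategy": t.strategy,
            "n_cancers_overall": t.per_100k("cancers"),
            "n_cancer_deaths": t.per_100k("cancer_deaths"),
            "n_primary_tests": t.per_100k("primary_tests"),
            "n_colonoscopies": t.per_100k("colonoscopies"),
            "mean_cost": t.mean_cost,
            "mean_qaly": t.mean_qaly,
        })
    columns = ["strategy", "n_cancers_overall", "n_cancer_deaths",
               "n_primary_tests", "n_colonoscopies", "mean_cost", "mean_qaly"]
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows).sort_values("n_cancer_deaths").reset_index(drop=True)
    for col in ("n_cancers_overall", "n_cancer_deaths", "n_primary_tests",
                "n_colonoscopies"):
        df[col + "_display"] = df[col].map(_money)
    df["mean_cost_display"] = df["mean_cost"].map(_money)
    return df


def write_table5(tallies: Iterable[OutcomeTally], path) -> None:
    tally_table(tallies).to_csv(path, index=False)


def write_scatter(psa: PSAOutput, path) -> None:
    """Incremental (cost, QALY) scatter, one row per PSA draw."""
    df = pd.DataFrame({"delta_qaly": psa.delta_qaly,
                       "delta_cost": psa.delta_cost})
    df.to_csv(path, index=False)
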