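"""Additive cumulative lifetime cancer risk.

The model is deliberately simple and linear: each carcinogen's lifetime
excess risk is its mean concentration divided by the concentration that
yields a one-in-a-million risk, times 10⁻⁶, and a system's cumulative risk
is the plain sum of those per-contaminant risks. This mirrors the additive
approach used in the EPA National Air Toxics Assessment: it ignores
chemical interactions (synergistic or antagonistic) and so characterises
the overall burden rather than a precise probability.

Expected lifetime cases for a system are cumulative risk × population
served; statewide counts are sums over systems, annualised by dividing by
the typical lifetime (70 years).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .ingestion import SystemProfile
from .registry import ContaminantSpec, Registry

#: Risk-tier labels in decreasing order of risk, as reported.
TIER_LABELS = (">1e-3", "1e-4–1e-3", "1e-5–1e-4", "<1e-5")

#: Tier boundaries are upper-inclusive: a risk of exactly 1e-3 falls in the
#: second tier because the top tier is defined strictly as "> 1e-3".
_TIER_BOUNDS = (1e-3, 1e-4, 1e-5)

ONE_IN_A_MILLION = 1e-6


class UnitMismatchError(ValueError):
    """A concentration was supplied in a unit other than the benchmark's."""


@dataclass(frozen=True)
class RiskResult:
    """Per-system cumulative cancer risk and case accounting."""

    system_id: str
    per_contaminant_risk: Mapping[str, float]
    cumulative_risk: float
    lifetime_cases: float
    population: int


@dataclass(frozen=True)
class TierSummary:
    """One row of the risk-tier table: system count, exposed population,
    expected lifetime cases and share of total cases for one tier."""

    tier: str
    n_systems: int
    exposed_population: int
    lifetime_cases: float
    percent_of_total_cases: float


def lifetime_risk(
    conc: float,
    c_one_in_million: float,
    unit: str | None = None,
    benchmark_unit: str | None = None,
) -> float:
    """Lifetime excess cancer risk at a mean concentration.

    risk = (conc / c_one_in_million) × 10⁻⁶, capped at 1 (it is a
    probability; the cap never binds for realistic drinking-water inputs).
    When both ``unit`` and ``benchmark_unit`` are given they must agree —
    concentrations are never converted implicitly.
    """
    if unit is not None and benchmark_unit is not None and unit != benchmark_unit:
        raise UnitMismatchError(
            f"concentration unit {unit!r} != benchmark unit {benchmark_unit!r}"
        )
    if not c_one_in_million > 0:
        raise ValueError(f"c_one_in_million must be > 0, got {c_one_in_million}")
    if conc < 0:
        raise ValueError(f"negative concentration {conc}")
    return min((conc / c_one_in_million) * ONE_IN_A_MILLION, 1.0)


def cumulative_risk(profile: SystemProfile, registry: Registry) -> RiskResult:
    """Additive cumulative risk for one system.

    Only carcinogens contribute; the cumulative risk is the sum of
    per-contaminant risks (capped at 1) and expected lifetime cases are
    cumulative risk × population served.
    """
    per_contaminant: dict[str, float] = {}
    for cid, conc in profile.mean_conc.items():
        spec = registry[cid]
        if spec.is_carcinogen:
            per_contaminant[cid] = lifetime_risk(conc, spec.c_one_in_million)
    total = min(sum(per_contaminant.values()), 1.0)
    return RiskResult(
        system_id=profile.system_id,
        per_contaminant_risk=per_contaminant,
        cumulative_risk=total,
        lifetime_cases=total * profile.population,
        population=profile.population,
    )


def classify_tier(risk: float) -> str:
    """Tier label for a cumulative risk in [0, 1]."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk {risk} outside [0, 1]")
    if risk > _TIER_BOUNDS[0]:
        return TIER_LABELS[0]
    if risk > _TIER_BOUNDS[1]:
        return TIER_LABELS[1]
    if risk > _TIER_BOUNDS[2]:
        return TIER_LABELS[2]
    return TIER_LABELS[3]


def tier_table(results: Sequence[RiskResult]) -> list[TierSummary]:
    """Risk-tier summary: four rows always, zeros allowed.

    Percent contribution is each tier's expected cases over the total; when
    total cases are zero the percents are reported as zero with a logged
    note.
    """
    if not results:
        raise ValueError("tier_table requires at least one RiskResult")
    acc = {t: {"n": 0, "pop": 0, "cases": 0.0} for t in TIER_LABELS}
    for r in results:
        tier = classify_tier(r.cumulative_risk)
        acc[tier]["n"] += 1
        acc[tier]["pop"] += r.population
        acc[tier]["cases"] += r.lifetime_cases
    total_cases = sum(a["cases"] for a in acc.values())
    if total_cases == 0:
        import logging
        logging.getLogger("aquarisk").info(
            "total expected cases are zero; tier percents reported as 0")
    return [
        TierSummary(
            tier=t,
            n_systems=acc[t]["n"],
            exposed_population=acc[t]["pop"],
            lifetime_cases=acc[t]["cases"],
            percent_of_total_cases=(
                100.0 * acc[t]["cases"] / total_cases if total_cases > 0 else 0.0
            ),
        )
        for t in TIER_LABELS
    ]


def tier_table_frame(summaries: Sequence[TierSummary]) -> pd.DataFrame:
    """Tier table as a DataFrame with a totals row, columns mirroring the
    standard report layout."""
    rows = [{
        "cumulative_cancer_risk": s.tier,
        "n_systems": s.n_systems,
        "exposed_population": s.exposed_population,
        "lifetime_cancer_cases": round(s.lifetime_cases),
        "percent_of_total_cases": round(s.percent_of_total_cases),
    } for s in summaries]
    rows.append({
        "cumulative_cancer_risk": "Total",
        "n_systems": sum(s.n_systems for s in summaries),
        "exposed_population": sum(s.exposed_population for s in summaries),
        "lifetime_cancer_cases": round(sum(s.lifetime_cases for s in summaries)),
        "percent_of_total_cases": round(sum(s.percent_of_total_cases for s in summaries)),
    })
    return pd.DataFrame(rows)


def annual_cases(total_lifetime_cases: float, lifetime_years: float) -> float:
    """Annualise a lifetime case count by the typical lifetime in years."""
    if not lifetime_years > 0:
        raise ValueError(f"lifetime_years must be > 0, got {lifetime_years}")
    return total_lifetime_cases / lifetime_years


def contribution_by_group(
    results: Sequence[RiskResult], registry: Registry
) -> dict[str, float]:
    """Percent of total expected lifetime cases by contaminant group.

    Cases are attributed proportionally to per-contaminant risk within each
    system (exact when the cumulative cap is inactive). Shares sum to 100
    when any cases exist; groups with no cases report 0.
    """
    group_cases: dict[str, float] = {}
    total = 0.0
    for r in results:
        uncapped = sum(r.per_contaminant_risk.values())
        if uncapped == 0:
            continue
        # Rescale so attributed cases sum to the (possibly capped) total.
        scale = r.lifetime_cases / uncapped
        for cid, risk in r.per_contaminant_risk.items():
            group = registry[cid].group
            group_cases[group] = group_cases.get(group, 0.0) + risk * scale
            total += risk * scale
    if total == 0:
        return {}
    return {g: 100.0 * c / total for g, c in sorted(group_cases.items())}


def per_system_table(
    results: Sequence[RiskResult], registry: Registry
) -> pd.DataFrame:
    """Per-system risk table, highest cumulative risk first, with a stacked
    per-group case decomposition for plotting."""
    groups = sorted({registry[cid].group
                     for r in results for cid in r.per_contaminant_risk})
    rows = []
    for r in sorted(results, key=lambda x: -x.cumulative_risk):
        row = {
            "system_id": r.system_id,
            "population": r.population,
            "cumulative_risk": r.cumulative_risk,
            "tier": classify_tier(r.cumulative_risk),
            "lifetime_cases": r.lifetime_cases,
        }
        for g in groups:
            row[f"risk_{g}"] = sum(
                risk for cid, risk in r.per_contaminant_risk.items()
                if registry[cid].group == g
            )
        rows.append(row)
    return pd.DataFrame(rows)
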