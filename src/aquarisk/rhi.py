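"""Relative Health Indicator (RHI) scoring.

The RHI metric puts cancer and non-cancer endpoints on a single severity-
weighted scale so co-occurring contaminants can be compared and summed:

* cancer score  = lifetime risk × severity × scale
* non-cancer score = hazard quotient × severity × incidence × scale

where the hazard quotient is exposure over the non-cancer reference
concentration, severity is a Global Burden of Disease disability weight in
[0, 1] for the contaminant's critical health effect, the incidence factor
is the assumed fraction of the exposed population experiencing that effect
(default 1%), and the scale (10⁶ by default) places scores on a convenient
integer range. Scores are relative rankings, not probabilities of disease.

The incidence factor is the model's dominant uncertainty, so this module
also provides the severity × incidence sensitivity grid used to bracket a
score, and the conversion from an epidemiological mortality rate to an
incidence factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cancer import UnitMismatchError, lifetime_risk
from .ingestion import SystemProfile
from .registry import ContaminantSpec, Registry


@dataclass(frozen=True)
class RhiResult:
    """Per-system cancer / non-cancer / total RHI scores.

    ``per_contaminant`` maps contaminant id → (cancer_score,
    noncancer_score); contaminants with both endpoint types contribute to
    both sums. ``noncancer_fraction`` is the non-cancer share of the total
    (0 when the total is 0).
    """

    system_id: str
    cancer_score: float
    noncancer_score: float
    total_score: float
    noncancer_fraction: float
    per_contaminant: Mapping[str, tuple[float, float]]


@dataclass(frozen=True)
class SensitivityCell:
    """One (severity, incidence) cell of the sensitivity grid."""

    severity: float
    incidence: float
    cancer_score: float
    noncancer_score: float
    total_score: float
    noncancer_fraction: float


def hazard_quotient(
    conc: float,
    reference_conc: float,
    unit: str | None = None,
    benchmark_unit: str | None = None,
) -> float:
    """Exposure concentration over the non-cancer reference concentration.

    A quotient above 1 means the health benchmark is exceeded; the quotient
    alone says nothing about the probability of an adverse effect.
    """
    if unit is not None and benchmark_unit is not None and unit != benchmark_unit:
        raise UnitMismatchError(
            f"concentration unit {unit!r} != benchmark unit {benchmark_unit!r}"
        )
    if not reference_conc > 0:
        raise ValueError(f"reference_conc must be > 0, got {reference_conc}")
    if conc < 0:
        raise ValueError(f"negative concentration {conc}")
    return conc / reference_conc


def cancer_rhi(lifetime_risk: float, cancer_severity: float, rhi_scale: float) -> float:
    """Cancer RHI score: lifetime risk × severity × scale.

    No incidence factor applies — the lifetime risk already is the
    probability of the outcome.
    """
    if lifetime_risk < 0 or cancer_severity < 0 or rhi_scale <= 0:
        raise ValueError("cancer_rhi inputs must be non-negative (scale positive)")
    return lifetime_risk * cancer_severity * rhi_scale


def noncancer_rhi(hq: float, severity: float, incidence: float, rhi_scale: float) -> float:
    """Non-cancer RHI score: hazard quotient × severity × incidence × scale."""
    if hq < 0 or severity < 0 or rhi_scale <= 0:
        raise ValueError("noncancer_rhi inputs must be non-negative (scale positive)")
    if not 0.0 < incidence <= 1.0:
        raise ValueError(f"incidence factor {incidence} outside (0, 1]")
    return hq * severity * incidence * rhi_scale


def _combine(cancer: float, noncancer: float) -> tuple[float, float]:
    total = cancer + noncancer
    fraction = noncancer / total if total > 0 else 0.0
    return total, fraction


def system_rhi(
    profile: SystemProfile,
    registry: Registry,
    incidence_override: float | None = None,
    severity_choice: Mapping[str, float] | None = None,
) -> RhiResult:
    """Cumulative RHI scores for one system.

    For each contaminant in the profile, computes the cancer score (if it
    is a carcinogen) and the non-cancer score (if it has a non-cancer
    endpoint); contaminants with both endpoint types, such as arsenic and
    hexavalent chromium, contribute to both sums.

    Parameters
    ----------
    incidence_override
        Incidence factor applied to every non-cancer score in place of each
        contaminant's default.
    severity_choice
        Optional map contaminant id → non-cancer severity. The chosen value
        must be one of the contaminant's listed options; anything else
        raises ``ValueError``. Contaminants not in the map use their first
        (most conservative by convention) listed option.
    """
    per_contaminant: dict[str, tuple[float, float]] = {}
    cancer_total = 0.0
    noncancer_total = 0.0
    for cid, conc in profile.mean_conc.items():
        spec = registry[cid]
        c_score = 0.0
        nc_score = 0.0
        if spec.is_carcinogen:
            c_score = cancer_rhi(
                lifetime_risk(conc, spec.c_one_in_million),
                spec.cancer_severity,
                registry.rhi_scale,
            )
        if spec.has_noncancer_endpoint:
            if severity_choice is not None and cid in severity_choice:
                severity = severity_choice[cid]
                if severity not in spec.noncancer_severity_options:
                    raise ValueError(
                        f"{cid}: severity {severity} is not one of the listed "
                        f"options {spec.noncancer_severity_options}"
                    )
            else:
                severity = spec.default_noncancer_severity
            incidence = (incidence_override if incidence_override is not None
                         else spec.incidence_factor_default)
            nc_score = noncancer_rhi(
                hazard_quotient(conc, spec.reference_conc),
                severity, incidence, registry.rhi_scale,
            )
        per_contaminant[cid] = (c_score, nc_score)
        cancer_total += c_score
        noncancer_total += nc_score
    total, fraction = _combine(cancer_total, noncancer_total)
    return RhiResult(
        system_id=profile.system_id,
        cancer_score=cancer_total,
        noncancer_score=noncancer_total,
        total_score=total,
        noncancer_fraction=fraction,
        per_contaminant=per_contaminant,
    )


def sensitivity_grid(
    conc: float,
    contaminant: ContaminantSpec,
    severities: Sequence[float],
    incidences: Sequence[float],
    registry: Registry,
) -> list[SensitivityCell]:
    """Severity × incidence sensitivity grid for one contaminant at one
    concentration.

    One cell per (severity, incidence) pair, row-major in the given order.
    The cancer score is constant across cells: it depends only on the
    concentration and the published risk benchmark, not on the non-cancer
    factors being varied.
    """
    if not severities or not incidences:
        raise ValueError("severities and incidences must be non-empty")
    c_score = 0.0
    if contaminant.is_carcinogen:
        c_score = cancer_rhi(
            lifetime_risk(conc, contaminant.c_one_in_million),
            contaminant.cancer_severity,
            registry.rhi_scale,
        )
    hq = (hazard_quotient(conc, contaminant.reference_conc)
          if contaminant.has_noncancer_endpoint else 0.0)
    cells = []
    for severity in severities:
        for incidence in incidences:
            nc = (noncancer_rhi(hq, severity, incidence, registry.rhi_scale)
                  if severity > 0 else 0.0)
            total, fraction = _combine(c_score, nc)
            cells.append(SensitivityCell(
                severity=severity, incidence=incidence,
                cancer_score=c_score, noncancer_score=nc,
                total_score=total, noncancer_fraction=fraction,
            ))
    return cells


def incidence_from_mortality(rate_per_100k_person_years: float) -> float:
    """Convert an epidemiological mortality/morbidity rate per 100,000
    person-years into an incidence-factor fraction (report as a percent
    rounded to 2 decimals)."""
    if rate_per_100k_person_years < 0:
        raise ValueError(f"negative rate {rate_per_100k_person_years}")
    return rate_per_100k_person_years / 100000.0


def rhi_table(results: Sequence[RhiResult]) -> pd.DataFrame:
    """Per-system RHI table, highest total first. Scores are rounded to the
    nearest integer and fractions to the nearest percent at report time."""
    rows = [{
        "system_id": r.system_id,
        "cancer_score": round(r.cancer_score),
        "noncancer_score": round(r.noncancer_score),
        "total_score": round(r.total_score),
        "noncancer_percent": round(100.0 * r.noncancer_fraction),
    } for r in sorted(results, key=lambda x: -x.total_score)]
    return pd.DataFrame(rows)


def grid_table(cells: Sequence[SensitivityCell]) -> pd.DataFrame:
    """Sensitivity grid as a long-form table keyed by severity and
    incidence, with report-time rounding."""
    return pd.DataFrame([{
        "severity": c.severity,
        "incidence": c.incidence,
        "cancer_score": round(c.cancer_score),
        "noncancer_score": round(c.noncancer_score),
        "total_score": round(c.total_score),
        "noncancer_percent": round(100.0 * c.noncancer_fraction),
    } for c in cells])
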