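"""Monitoring-record ingestion and system-level aggregation.

Reads delimited-text monitoring records (one row per sample) and reduces
them to per-system arithmetic-mean concentration profiles, with explicit
handling of non-detects: samples below the reporting limit arrive with no
numeric value and are imputed per a stated policy before averaging.

The default policy treats non-detects as zero, which makes the resulting
risk estimates conservative lower bounds — for several common carcinogens
the one-in-a-million concentration sits below the official reporting limit,
so mass reported as "non-detect" may still carry risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .registry import Registry

logger = logging.getLogger("aquarisk")

#: Recognised non-detect imputation policies, in increasing order of the
#: value substituted for a censored sample.
NONDETECT_POLICIES = ("zero", "half_limit", "full_limit")

#: Policy used when none is specified.
DEFAULT_NONDETECT_POLICY = "zero"

RECORD_COLUMNS = ("system_id", "contaminant_id", "value", "reporting_limit",
                  "detected", "sample_date")


class IngestionError(ValueError):
    """Malformed monitoring input (bad row, missing population, ...)."""


@dataclass(frozen=True)
class MonitoringRecord:
    """One water-quality sample result.

    ``value`` is present exactly when ``detected`` is true; a non-detect
    carries only its ``reporting_limit`` (the concentration below which the
    laboratory does not report a number).
    """

    system_id: str
    contaminant_id: str
    value: float | None
    reporting_limit: float
    detected: bool
    sample_date: str | None = None

    def __post_init__(self) -> None:
        if self.detected != (self.value is not None):
            raise IngestionError(
                f"{self.system_id}/{self.contaminant_id}: value must be present "
                f"iff detected (detected={self.detected}, value={self.value})"
            )
        if self.value is not None and self.value < 0:
            raise IngestionError(
                f"{self.system_id}/{self.contaminant_id}: negative value {self.value}"
            )
        if self.reporting_limit < 0:
            raise IngestionError(
                f"{self.system_id}/{self.contaminant_id}: negative reporting "
                f"limit {self.reporting_limit}"
            )


@dataclass(frozen=True)
class SystemProfile:
    """One water system: population served and mean concentration per
    contaminant (arithmetic mean over that system's samples)."""

    system_id: str
    population: int
    mean_conc: Mapping[str, float]
    n_samples: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.population < 0:
            raise IngestionError(f"{self.system_id}: negative population")
        for cid, conc in self.mean_conc.items():
            if conc < 0:
                raise IngestionError(f"{self.system_id}/{cid}: negative mean {conc}")


def _parse_bool(raw: object) -> bool:
    text = str(raw).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise IngestionError(f"cannot parse detected flag {raw!r}")


def read_records(path: str | Path, registry: Registry) -> list[MonitoringRecord]:
    """Read monitoring records from a delimited-text file.

    Expects a header with the columns in :data:`RECORD_COLUMNS`
    (``sample_date`` optional, ``unit`` optional). Rows naming a contaminant
    absent from the registry are skipped and counted in the log; a row whose
    declared unit disagrees with the registry's unit for that contaminant,
    or whose value is negative or unparseable, raises :class:`IngestionError`
    with its line number.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"system_id", "contaminant_id", "value", "reporting_limit", "detected"}
    missing = required - set(frame.columns)
    if missing:
        raise IngestionError(f"{path}: missing columns {sorted(missing)}")

    records: list[MonitoringRecord] = []
    skipped = 0
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        cid = row.contaminant_id
        if cid not in registry:
            skipped += 1
            continue
        if "unit" in frame.columns:
            declared = getattr(row, "unit").strip()
            if declared and declared != registry[cid].unit:
                raise IngestionError(
                    f"{path}:{idx}: unit {declared!r} for {cid} does not match "
                    f"registry unit {registry[cid].unit!r}"
                )
        try:
            detected = _parse_bool(row.detected)
            value = float(row.value) if str(row.value).strip() != "" else None
            limit = float(row.reporting_limit)
            date = getattr(row, "sample_date", "") or None
            records.append(MonitoringRecord(
                system_id=row.system_id, contaminant_id=cid, value=value,
                reporting_limit=limit, detected=detected, sample_date=date,
            ))
        except (ValueError, IngestionError) as exc:
            raise IngestionError(f"{path}:{idx}: {exc}") from exc
    if skipped:
        logger.warning("%s: skipped %d rows with unknown contaminants", path, skipped)
    return records


def write_records(
    records: Iterable[MonitoringRecord],
    populations: Mapping[str, int],
    records_path: str | Path,
    populations_path: str | Path,
) -> None:
    """Write records and populations in the delimited format
    :func:`read_records` / :func:`read_populations` consume."""
    rows = [{
        "system_id": r.system_id,
        "contaminant_id": r.contaminant_id,
        "value": "" if r.value is None else repr(r.value),
        "reporting_limit": repr(r.reporting_limit),
        "detected": str(r.detected).lower(),
        "sample_date": r.sample_date or "",
    } for r in records]
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS)).to_csv(records_path, index=False)
    pd.DataFrame(
        {"system_id": list(populations), "population": list(populations.values())}
    ).to_csv(populations_path, index=False)


def read_populations(path: str | Path) -> dict[str, int]:
    """Read the two-column ``system_id, population`` table."""
    frame = pd.read_csv(path, dtype={"system_id": str, "population": int})
    missing = {"system_id", "population"} - set(frame.columns)
    if missing:
        raise IngestionError(f"{path}: missing columns {sorted(missing)}")
    return dict(zip(frame["system_id"], frame["population"].astype(int)))


def imputed_value(record: MonitoringRecord, policy: str) -> float:
    """Numeric value a record contributes to the mean under a policy."""
    if record.detected:
        return float(record.value)  # type: ignore[arg-type]
    if policy == "zero":
        return 0.0
    if policy == "half_limit":
        return 0.5 * record.reporting_limit
    if policy == "full_limit":
        return float(record.reporting_limit)
    raise IngestionError(
        f"unknown nondetect policy {policy!r}; expected one of {NONDETECT_POLICIES}"
    )


def aggregate_profiles(
    records: Sequence[MonitoringRecord],
    populations: Mapping[str, int],
    registry: Registry,
    nondetect_policy: str = DEFAULT_NONDETECT_POLICY,
) -> list[SystemProfile]:
    """Aggregate records to per-system arithmetic-mean profiles.

    All samples for a (system, contaminant) pair are pooled with equal
    weight; non-detects contribute the policy-imputed value. Every system
    appearing in ``records`` must have a population entry.

    Returns profiles sorted by ``system_id``.
    """
    if nondetect_policy not in NONDETECT_POLICIES:
        raise IngestionError(
            f"unknown nondetect policy {nondetect_policy!r}; "
            f"expected one of {NONDETECT_POLICIES}"
        )
    sums: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.contaminant_id not in registry:
            raise IngestionError(f"record names unknown contaminant {rec.contaminant_id!r}")
        s = sums.setdefault(rec.system_id, {})
        n = counts.setdefault(rec.system_id, {})
        s[rec.contaminant_id] = s.get(rec.contaminant_id, 0.0) + imputed_value(rec, nondetect_policy)
        n[rec.contaminant_id] = n.get(rec.contaminant_id, 0) + 1

    profiles = []
    for system_id in sorted(sums):
        if system_id not in populations:
            raise IngestionError(f"no population entry for system {system_id!r}")
        mean = {cid: sums[system_id][cid] / counts[system_id][cid]
                for cid in sums[system_id]}
        profiles.append(SystemProfile(
            system_id=system_id,
            population=int(populations[system_id]),
            mean_conc=mean,
            n_samples=dict(counts[system_id]),
        ))
    return profiles


def profiles_to_table(profiles: Sequence[SystemProfile]) -> pd.DataFrame:
    """One row per (system, contaminant) with mean concentration and n."""
    rows = []
    for p in profiles:
        for cid in sorted(p.mean_conc):
            rows.append({
                "system_id": p.system_id,
                "population": p.population,
                "contaminant_id": cid,
                "mean_conc": p.mean_conc[cid],
                "n_samples": p.n_samples[cid],
            })
    return pd.DataFrame(
        rows, columns=["system_id", "population", "contaminant_id",
                       "mean_conc", "n_samples"]
    )
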