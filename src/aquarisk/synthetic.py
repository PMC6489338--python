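"""Seeded synthetic monitoring-data generator.

Emulates the statistical structure of state-level community-water-system
monitoring data so the whole pipeline is testable without downloading the
real regulatory datasets:

* many small systems and few large ones (lognormal population served);
* per-contaminant lognormal concentrations with Bernoulli occurrence;
* left-censoring at the reporting limit — draws below the limit are
  emitted as non-detects with the value discarded, mirroring how utilities
  report;
* optionally, elevated concentration medians in small systems (population
  below a cutoff), reproducing the qualitative pattern that the highest
  risks concentrate in systems serving under 10,000 people.

The generator does NOT emulate the real data's joint contaminant
correlations, temporal trends or spatial clustering; see the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cancer import ONE_IN_A_MILLION, TIER_LABELS
from .ingestion import MonitoringRecord
from .registry import Registry


@dataclass(frozen=True)
class ContaminantSim:
    """Generation parameters for one contaminant (registry units).

    ``conc_log_mean`` / ``conc_log_sd`` parameterise the natural-log
    lognormal of sample concentrations; the median is
    ``exp(conc_log_mean)``.
    """

    occurrence_prob: float
    conc_log_mean: float
    conc_log_sd: float
    reporting_limit: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence_prob <= 1.0:
            raise ValueError(f"occurrence_prob {self.occurrence_prob} outside [0, 1]")
        if self.conc_log_sd < 0:
            raise ValueError(f"conc_log_sd {self.conc_log_sd} < 0")
        if self.reporting_limit < 0:
            raise ValueError(f"reporting_limit {self.reporting_limit} < 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Scenario description for :func:`generate`.

    Populations are lognormal (natural-log parameters); systems with
    population below ``small_system_cutoff`` have every concentration
    median multiplied by ``small_system_risk_multiplier`` (≥ 1), which
    makes smaller systems systematically riskier when the multiplier
    exceeds 1.
    """

    n_systems: int = 200
    seed: int = 0
    population_log_mean: float = math.log(1000.0)
    population_log_sd: float = 1.8
    samples_per_system: int = 4
    small_system_risk_multiplier: float = 3.0
    small_system_cutoff: int = 10_000
    contaminants: Mapping[str, ContaminantSim] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_systems <= 0:
            raise ValueError("n_systems must be positive")
        if self.samples_per_system <= 0:
            raise ValueError("samples_per_system must be positive")
        if self.small_system_risk_multiplier < 1.0:
            raise ValueError("small_system_risk_multiplier must be >= 1")
        if self.population_log_sd < 0:
            raise ValueError("population_log_sd must be >= 0")


def default_synthetic_config(
    registry: Registry, n_systems: int = 200, seed: int = 0
) -> SyntheticConfig:
    """Default scenario over a registry's contaminants.

    Carcinogen medians sit at 100 × their one-in-a-million concentration
    (per-contaminant risk ~1e-4, the bulk of observed systems); non-cancer
    medians at one fifth of the reference concentration. Reporting limits
    equal the medians, so roughly half of all draws are censored and the
    non-detect machinery is exercised throughout.
    """
    sims = {}
    for spec in registry:
        if spec.is_carcinogen:
            median = 100.0 * spec.c_one_in_million
        else:
            median = spec.reference_conc / 5.0
        sims[spec.id] = ContaminantSim(
            occurrence_prob=0.5,
            conc_log_mean=math.log(median),
            conc_log_sd=1.0,
            reporting_limit=median,
        )
    return SyntheticConfig(n_systems=n_systems, seed=seed, contaminants=sims)


def _draw_population(rng: np.random.Generator, config: SyntheticConfig) -> int:
    pop = rng.lognormal(config.population_log_mean, config.population_log_sd)
    return max(1, int(round(pop)))


def generate(
    config: SyntheticConfig, registry: Registry
) -> tuple[list[MonitoringRecord], dict[str, int]]:
    """Generate a seeded monitoring dataset.

    For each of ``n_systems`` systems: draw the population served; for each
    contaminant present (independent Bernoulli occurrence), draw
    ``samples_per_system`` lognormal concentrations, emitting draws below
    the reporting limit as non-detects. Identical config (including seed)
    gives identical output.
    """
    for cid in config.contaminants:
        if cid not in registry:
            raise ValueError(f"synthetic config names unknown contaminant {cid!r}")
    rng = np.random.default_rng(config.seed)
    records: list[MonitoringRecord] = []
    populations: dict[str, int] = {}
    for i in range(config.n_systems):
        system_id = f"SYS{i:05d}"
        population = _draw_population(rng, config)
        populations[system_id] = population
        small = population < config.small_system_cutoff
        for cid, sim in config.contaminants.items():
            if rng.random() >= sim.occurrence_prob:
                continue
            log_mean = sim.conc_log_mean
            if small and config.small_system_risk_multiplier > 1.0:
                log_mean += math.log(config.small_system_risk_multiplier)
            draws = rng.lognormal(log_mean, sim.conc_log_sd,
                                  size=config.samples_per_system) \
                if sim.conc_log_sd > 0 else np.full(config.samples_per_system,
                                                    math.exp(log_mean))
            for value in draws:
                detected = value >= sim.reporting_limit
                records.append(MonitoringRecord(
                    system_id=system_id,
                    contaminant_id=cid,
                    value=float(value) if detected else None,
                    reporting_limit=sim.reporting_limit,
                    detected=bool(detected),
                ))
    return records, populations


#: Sampling interior for each tier when back-solving scenario risks; the
#: open top end of the highest tier is capped at 1e-2 (well below the
#: probability cap) and the bottom tier at 1e-7.
_TIER_RISK_RANGES = {
    ">1e-3": (1e-3, 1e-2),
    "1e-4–1e-3": (1e-4, 1e-3),
    "1e-5–1e-4": (1e-5, 1e-4),
    "<1e-5": (1e-7, 1e-5),
}


def generate_tiered_scenario(
    config: SyntheticConfig,
    registry: Registry,
    target_tiers: Mapping[str, int],
) -> tuple[list[MonitoringRecord], dict[str, int]]:
    """Construct a dataset whose tier table matches ``target_tiers`` exactly.

    For each requested tier, cumulative risks are sampled log-uniformly
    strictly inside the tier's bounds and back-solved to a single-carcinogen
    concentration (the registry's first carcinogen); each system then emits
    ``samples_per_system`` identical detected records, so the aggregated
    mean — and hence the tier classification — is exact by construction
    under any non-detect policy.
    """
    carcinogens = registry.carcinogens
    if not carcinogens:
        raise ValueError("registry has no carcinogen to back-solve against")
    spec = carcinogens[0]
    for tier in target_tiers:
        if tier not in _TIER_RISK_RANGES:
            raise ValueError(f"unknown tier {tier!r}; expected one of {TIER_LABELS}")
    rng = np.random.default_rng(config.seed)
    records: list[MonitoringRecord] = []
    populations: dict[str, int] = {}
    i = 0
    for tier in TIER_LABELS:
        n = target_tiers.get(tier, 0)
        lo, hi = _TIER_RISK_RANGES[tier]
        if hi > 1.0:
            raise ValueError(f"tier {tier!r} upper risk bound {hi} exceeds 1")
        for _ in range(n):
            system_id = f"SYS{i:05d}"
            i += 1
            populations[system_id] = _draw_population(rng, config)
            # log-uniform jitter strictly inside the tier bounds
            u = rng.uniform(0.001, 0.999)
            risk = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
            conc = risk / ONE_IN_A_MILLION * spec.c_one_in_million
            for _ in range(config.samples_per_system):
                records.append(MonitoringRecord(
                    system_id=system_id,
                    contaminant_id=spec.id,
                    value=conc,
                    reporting_limit=0.0,
                    detected=True,
                ))
    return records, populations
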