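"""Contaminant benchmark registry.

Holds, for every contaminant the pipeline knows about, the health-benchmark
constants consumed by the two scoring engines:

* ``c_one_in_million`` — the concentration that, over a lifetime of exposure,
  yields a 10⁻⁶ excess cancer risk (the risk-model anchor; absent for
  non-carcinogens);
* ``reference_conc`` — the non-cancer health benchmark below which adverse
  effects are assumed unlikely (absent when no non-cancer endpoint is
  mapped);
* severity factors — Global Burden of Disease disability weights in [0, 1]
  mapped to the contaminant's critical health effect;
* a default incidence factor — the assumed fraction of the exposed
  population experiencing that effect (1% by default).

Registries are plain data: they load from a YAML document or a delimited
table and carry no behaviour beyond validation, so that every benchmark a
run used is inspectable and swappable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("aquarisk")

#: Contaminant groups used for the contribution decomposition.
GROUPS = (
    "arsenic",
    "disinfection_byproduct",
    "hexavalent_chromium",
    "radioactive",
    "voc",
    "other_noncancer",
)

#: Default lifetime used to annualize lifetime case counts, in years.
DEFAULT_LIFETIME_YEARS = 70.0

#: Default multiplicative scale applied to both RHI score components so the
#: scores land on a convenient integer range (a risk of 10^-6 with severity 1
#: maps to a score of 1).
DEFAULT_RHI_SCALE = 1e6


class RegistryError(ValueError):
    """A registry document or contaminant entry violates an invariant."""


@dataclass(frozen=True)
class ContaminantSpec:
    """Identity, unit and benchmark constants for one contaminant.

    Parameters
    ----------
    id
        Short stable key used in monitoring records.
    display_name
        Human-readable name for reports.
    group
        One of :data:`GROUPS`; drives the group-level contribution table.
    unit
        Concentration unit for every benchmark and every sample of this
        contaminant (mass/volume such as ``ug/L`` or activity/volume such as
        ``pCi/L``). Units are never converted implicitly.
    c_one_in_million
        Concentration giving a 10⁻⁶ lifetime excess cancer risk, in `unit`;
        ``None`` for non-carcinogens.
    reference_conc
        Non-cancer reference concentration in `unit`; ``None`` when the
        contaminant has no mapped non-cancer endpoint.
    cancer_severity
        Disability weight in [0, 1] for the cancer endpoint (diagnosis and
        initial-treatment stage).
    noncancer_severity_options
        One or more candidate disability weights in [0, 1] for the
        non-cancer endpoint; the first entry is the default choice.
    incidence_factor_default
        Fraction in (0, 1] of the exposed population assumed to experience
        the non-cancer effect.
    """

    id: str
    display_name: str
    group: str
    unit: str
    c_one_in_million: float | None = None
    reference_conc: float | None = None
    cancer_severity: float | None = None
    noncancer_severity_options: tuple[float, ...] = ()
    incidence_factor_default: float = 0.01

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise RegistryError(
                f"{self.id}: unknown group {self.group!r} (expected one of {GROUPS})"
            )
        if self.c_one_in_million is None and self.reference_conc is None:
            raise RegistryError(
                f"{self.id}: needs at least one of c_one_in_million, reference_conc"
            )
        for name in ("c_one_in_million", "reference_conc"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise RegistryError(f"{self.id}: {name} must be > 0, got {v}")
        if self.c_one_in_million is not None and self.cancer_severity is None:
            raise RegistryError(f"{self.id}: carcinogen lacks cancer_severity")
        if self.reference_conc is not None and not self.noncancer_severity_options:
            raise RegistryError(
                f"{self.id}: non-cancer endpoint lacks noncancer_severity_options"
            )
        sevs = list(self.noncancer_severity_options)
        if self.cancer_severity is not None:
            sevs.append(self.cancer_severity)
        for s in sevs:
            if not 0.0 <= s <= 1.0:
                raise RegistryError(f"{self.id}: severity {s} outside [0, 1]")
        if not 0.0 < self.incidence_factor_default <= 1.0:
            raise RegistryError(
                f"{self.id}: incidence_factor_default {self.incidence_factor_default}"
                " outside (0, 1]"
            )

    @property
    def is_carcinogen(self) -> bool:
        return self.c_one_in_million is not None

    @property
    def has_noncancer_endpoint(self) -> bool:
        return self.reference_conc is not None

    @property
    def default_noncancer_severity(self) -> float | None:
        if not self.noncancer_severity_options:
            return None
        return self.noncancer_severity_options[0]


@dataclass(frozen=True)
class Registry:
    """Validated collection of :class:`ContaminantSpec` plus run constants."""

    contaminants: Mapping[str, ContaminantSpec]
    lifetime_years: float = DEFAULT_LIFETIME_YEARS
    rhi_scale: float = DEFAULT_RHI_SCALE

    def __post_init__(self) -> None:
        if not self.lifetime_years > 0:
            raise RegistryError(f"lifetime_years must be > 0, got {self.lifetime_years}")
        if not self.rhi_scale > 0:
            raise RegistryError(f"rhi_scale must be > 0, got {self.rhi_scale}")
        for key, spec in self.contaminants.items():
            if key != spec.id:
                raise RegistryError(f"registry key {key!r} != spec id {spec.id!r}")

    def __getitem__(self, contaminant_id: str) -> ContaminantSpec:
        return self.contaminants[contaminant_id]

    def __contains__(self, contaminant_id: str) -> bool:
        return contaminant_id in self.contaminants

    def __iter__(self):
        return iter(self.contaminants.values())

    @property
    def carcinogens(self) -> tuple[ContaminantSpec, ...]:
        return tuple(c for c in self if c.is_carcinogen)

    @property
    def noncancer_contaminants(self) -> tuple[ContaminantSpec, ...]:
        return tuple(c for c in self if c.has_noncancer_endpoint)


# ---------------------------------------------------------------------------
# Built-in defaults
# ---------------------------------------------------------------------------

# Arsenic constants are calibrated jointly so the standard worked example
# holds: 1 ug/L -> lifetime risk 2.5e-4 -> cancer score 180, and the 3x3
# severity/incidence grid spans cumulative scores 276-2169. That pins
# c_one_in_million = 1e-6/2.5e-4 = 0.004 ug/L, cancer severity = 180/250
# = 0.72, reference_conc = 0.9 ug/L. The three heart-failure disability
# weights 0.041/0.072/0.179 are the GBD mild/moderate/severe states.
_ARSENIC = ContaminantSpec(
    id="arsenic",
    display_name="Arsenic",
    group="arsenic",
    unit="ug/L",
    c_one_in_million=0.004,
    reference_conc=0.9,
    cancer_severity=0.72,
    noncancer_severity_options=(0.041, 0.072, 0.179),
)

# Every benchmark below other than arsenic's is a placeholder loosely based
# on California public health goals / notification levels; swap in a vetted
# table via load_registry for real analyses.
_DEFAULT_SPECS: tuple[ContaminantSpec, ...] = (
    _ARSENIC,
    # Nine carcinogenic disinfection byproducts.
    ContaminantSpec("chloroform", "Chloroform", "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.4, cancer_severity=0.288),
    ContaminantSpec("bromodichloromethane", "Bromodichloromethane",
                    "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.06, cancer_severity=0.288),
    ContaminantSpec("dibromochloromethane", "Dibromochloromethane",
                    "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.1, cancer_severity=0.288),
    ContaminantSpec("bromoform", "Bromoform", "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.5, cancer_severity=0.288),
    ContaminantSpec("bromate", "Bromate", "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.1, cancer_severity=0.288),
    ContaminantSpec("dichloroacetic_acid", "Dichloroacetic acid",
                    "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.7, cancer_severity=0.288),
    ContaminantSpec("trichloroacetic_acid", "Trichloroacetic acid",
                    "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.1, cancer_severity=0.288),
    ContaminantSpec("ndma", "N-Nitrosodimethylamine", "disinfection_byproduct",
                    "ug/L", c_one_in_million=0.003, cancer_severity=0.288),
    ContaminantSpec("mx", "3-Chloro-4-(dichloromethyl)-5-hydroxy-2(5H)-furanone",
                    "disinfection_byproduct", "ug/L",
                    c_one_in_million=0.02, cancer_severity=0.288),
    # Hexavalent chromium carries both endpoint types, like arsenic.
    ContaminantSpec("hexavalent_chromium", "Hexavalent chromium",
                    "hexavalent_chromium", "ug/L",
                    c_one_in_million=0.02, reference_conc=20.0,
                    cancer_severity=0.288, noncancer_severity_options=(0.123,)),
    # Radioactive element (activity units).
    ContaminantSpec("uranium", "Uranium", "radioactive", "pCi/L",
                    c_one_in_million=0.43, cancer_severity=0.288),
    # Carcinogenic volatile organic chemical.
    ContaminantSpec("tetrachloroethylene", "Tetrachloroethylene", "voc", "ug/L",
                    c_one_in_million=0.06, cancer_severity=0.288),
    # The four most common non-cancer drinking-water contaminants.
    ContaminantSpec("chlorate", "Chlorate", "other_noncancer", "ug/L",
                    reference_conc=210.0, noncancer_severity_options=(0.052,)),
    ContaminantSpec("manganese", "Manganese", "other_noncancer", "ug/L",
                    reference_conc=500.0, noncancer_severity_options=(0.133,)),
    ContaminantSpec("nitrate", "Nitrate (as N)", "other_noncancer", "ug/L",
                    reference_conc=10000.0, noncancer_severity_options=(0.052,)),
    ContaminantSpec("vanadium", "Vanadium", "other_noncancer", "ug/L",
                    reference_conc=50.0, noncancer_severity_options=(0.051,)),
)


def builtin_default_registry() -> Registry:
    """Registry shipped with the package.

    Contains arsenic (dual cancer / non-cancer endpoints, calibrated to the
    standard 1 ug/L worked example), nine carcinogenic disinfection
    byproducts, hexavalent chromium, uranium, tetrachloroethylene, and the
    four non-cancer contaminants chlorate, manganese, nitrate and vanadium.
    """
    return Registry(contaminants={c.id: c for c in _DEFAULT_SPECS})


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_SPEC_FIELDS = {
    "id", "display_name", "group", "unit", "c_one_in_million",
    "reference_conc", "cancer_severity", "noncancer_severity_options",
    "incidence_factor_default",
}


def _spec_from_mapping(raw: Mapping) -> ContaminantSpec:
    unknown = set(raw) - _SPEC_FIELDS
    if unknown:
        logger.warning("contaminant %s: ignoring unknown fields %s",
                       raw.get("id", "?"), sorted(unknown))
    kwargs = {k: raw[k] for k in _SPEC_FIELDS & set(raw)}
    missing = {"id", "display_name", "group", "unit"} - set(kwargs)
    if missing:
        raise RegistryError(
            f"contaminant entry {raw.get('id', '?')!r} missing fields {sorted(missing)}"
        )
    sevs = kwargs.get("noncancer_severity_options")
    if sevs is not None:
        if isinstance(sevs, (int, float)):
            sevs = (float(sevs),)
        kwargs["noncancer_severity_options"] = tuple(float(s) for s in sevs)
    for key in ("c_one_in_million", "reference_conc", "cancer_severity"):
        if kwargs.get(key) is not None:
            kwargs[key] = float(kwargs[key])
    return ContaminantSpec(**kwargs)


def load_registry(path: str | Path) -> Registry:
    """Load and validate a registry from a YAML config document.

    The document has top-level keys ``lifetime_years``, ``rhi_scale`` and a
    ``contaminants`` list of per-contaminant mappings. Unknown fields are
    ignored with a logged warning; any invariant violation raises
    :class:`RegistryError` naming the contaminant and field.
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "contaminants" not in doc:
        raise RegistryError(f"{path}: expected a mapping with a 'contaminants' list")
    specs = [_spec_from_mapping(entry) for entry in doc["contaminants"]]
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise RegistryError(f"{path}: duplicate contaminant ids {dupes}")
    return Registry(
        contaminants={s.id: s for s in specs},
        lifetime_years=float(doc.get("lifetime_years", DEFAULT_LIFETIME_YEARS)),
        rhi_scale=float(doc.get("rhi_scale", DEFAULT_RHI_SCALE)),
    )


def write_registry(registry: Registry, path: str | Path) -> None:
    """Serialize a registry to YAML such that :func:`load_registry` round-trips
    every numeric field exactly."""
    doc = {
        "lifetime_years": registry.lifetime_years,
        "rhi_scale": registry.rhi_scale,
        "contaminants": [
            {
                "id": c.id,
                "display_name": c.display_name,
                "group": c.group,
                "unit": c.unit,
                "c_one_in_million": c.c_one_in_million,
                "reference_conc": c.reference_conc,
                "cancer_severity": c.cancer_severity,
                "noncancer_severity_options": list(c.noncancer_severity_options),
                "incidence_factor_default": c.incidence_factor_default,
            }
            for c in registry
        ],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def registry_to_table(registry: Registry) -> pd.DataFrame:
    """Flatten a registry to one row per contaminant (delimited-text export).

    Multi-valued severity options are pipe-joined in a single column.
    """
    rows = []
    for c in registry:
        rows.append({
            "id": c.id,
            "display_name": c.display_name,
            "group": c.group,
            "unit": c.unit,
            "c_one_in_million": c.c_one_in_million,
            "reference_conc": c.reference_conc,
            "cancer_severity": c.cancer_severity,
            "noncancer_severity_options": "|".join(
                repr(s) for s in c.noncancer_severity_options
            ),
            "incidence_factor_default": c.incidence_factor_default,
        })
    return pd.DataFrame(rows)


def registry_from_table(
    table: pd.DataFrame,
    lifetime_years: float = DEFAULT_LIFETIME_YEARS,
    rhi_scale: float = DEFAULT_RHI_SCALE,
) -> Registry:
    """Inverse of :func:`registry_to_table` (run constants are not part of the
    per-contaminant table and are passed separately)."""
    specs = {}
    for raw in table.to_dict("records"):
        entry = {k: v for k, v in raw.items() if not pd.isna(v)}
        sevs = entry.get("noncancer_severity_options", "")
        entry["noncancer_severity_options"] = tuple(
            float(s) for s in str(sevs).split("|") if s
        )
        spec = _spec_from_mapping(entry)
        specs[spec.id] = spec
    return Registry(contaminants=specs, lifetime_years=lifetime_years,
                    rhi_scale=rhi_scale)
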