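"""Central registry of emission factors and uncertainty specifications.

Every multiplier the accounting uses lives here as an :class:`EFSpec` —
a named factor with mean, sd, bounds and a distribution family — so the
deterministic engine and the Monte Carlo propagation draw on one source.

The registry covers:

* three direct soil N2O-N EF schemes — the IPCC global default (Tier 1:
  0.010, range 0.001-0.018), the IPCC wet/dry disaggregation (wet 0.016,
  dry 0.005), and empirical estimates from paired-plot data at country,
  regional or global level with a country -> region -> global fallback;
* indirect-emission factors per climate class: the volatilised fraction
  (FRACGASF) with its N2O yield (EF4), and the leached fraction
  (FRACLEACH) with its yield (EF5);
* the urea-hydrolysis factor (0.2 +/- 0.1 t CO2-C per tonne urea product);
* manufacturing EFs per (region of production, product), t CO2e per tonne
  product at factory gate, lognormal with 25% relative sd by convention;
* transport EFs per (origin region, destination region, product), normal
  with 50% relative sd by convention.

Manufacturing and transport EF values from commercial LCA databases are
licence-restricted; the registry only defines their slots and accepts
user-supplied (or synthetic) tables.

Defaults carry provenance labels: "paper" for values fixed by the method,
"IPCC-2019-default" for IPCC-sourced substitutes, "user" for overrides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .activity import PRODUCTS, N_CONTENT, UAN_UREA_FRACTION
from .efdirect import DirectEFEstimate, EFStore
from .regions import check_region

log = logging.getLogger(__name__)

SCHEMES = (
    "ipcc_tier1",
    "ipcc_wetdry",
    "empirical_global",
    "empirical_regional",
    "empirical_country",
)

#: Mass-ratio constants (not configurable): N2O-N -> N2O and CO2-C -> CO2.
N2O_MASS_RATIO = 44.0 / 28.0
CO2_C_MASS_RATIO = 44.0 / 12.0


class ConfigError(ValueError):
    """Raised when the registry configuration is inconsistent."""


@dataclass(frozen=True)
class EFSpec:
    """A named emission factor with its uncertainty specification.

    Units depend on context: dimensionless fraction for field EFs,
    t CO2e per tonne product for manufacturing/transport, t CO2-C per
    tonne urea product for the hydrolysis factor. ``min``/``max`` bound
    Monte Carlo draws (rejection sampling); ``None`` means unbounded.
    """

    name: str
    mean: float
    sd: float
    min: float | None = None
    max: float | None = None
    pdf: str = "normal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")
        if self.min is not None and self.min > self.mean:
            raise ValueError(f"{self.name}: min > mean")
        if self.max is not None and self.max < self.mean:
            raise ValueError(f"{self.name}: max < mean")
        if self.pdf not in ("normal", "lognormal"):
            raise ValueError(f"{self.name}: pdf must be normal or lognormal")

    @property
    def cv(self) -> float:
        return self.sd / self.mean if self.mean else float("nan")


# ---------------------------------------------------------------------------
# Shipped defaults

def _default_direct_schemes() -> dict[str, EFSpec]:
    return {
        "ipcc_tier1": EFSpec("direct/ipcc_tier1", 0.010, 0.009, 0.001, 0.018, "normal"),
        "ipcc_wetdry:wet": EFSpec("direct/ipcc_wetdry/wet", 0.016, 0.003, 0.013, 0.019, "normal"),
        "ipcc_wetdry:dry": EFSpec("direct/ipcc_wetdry/dry", 0.005, 0.006, -0.001, 0.011, "normal"),
    }


def _default_indirect() -> dict[str, EFSpec]:
    # FRAC terms: sd 0.05, normal. Dry-climate FRACLEACH is identically
    # zero (no leaching pathway), so its sd is 0 rather than 0.05: a
    # truncated normal around 0 would manufacture a positive mean.
    # EF4/EF5 means and ranges follow the IPCC 2019 wet/dry disaggregation.
    return {
        "fracgasf:wet": EFSpec("fracgasf/wet", 0.11, 0.05, 0.0, 1.0, "normal"),
        "fracgasf:dry": EFSpec("fracgasf/dry", 0.11, 0.05, 0.0, 1.0, "normal"),
        "ef4:wet": EFSpec("ef4/wet", 0.014, 0.003, 0.011, 0.017, "normal"),
        "ef4:dry": EFSpec("ef4/dry", 0.005, 0.003, 0.000, 0.011, "normal"),
        "fracleach:wet": EFSpec("fracleach/wet", 0.24, 0.05, 0.0, 1.0, "normal"),
        "fracleach:dry": EFSpec("fracleach/dry", 0.0, 0.0, 0.0, 0.0, "normal"),
        "ef5:wet": EFSpec("ef5/wet", 0.011, 0.005, 0.000, 0.020, "normal"),
        "ef5:dry": EFSpec("ef5/dry", 0.011, 0.005, 0.000, 0.020, "normal"),
    }


def _default_urea() -> EFSpec:
    return EFSpec("urea_hydrolysis", 0.2, 0.1, 0.0, None, "normal")


DEFAULT_CONSTANTS: dict[str, float] = {
    "gwp": 265.0,  # N2O 100-year GWP used throughout
    "urea_n_content": N_CONTENT["urea"],
    "uan_n_content": N_CONTENT["uan"],
    "uan_urea_fraction": UAN_UREA_FRACTION,
}


# ---------------------------------------------------------------------------
# EF tables

_MANUF_COLS = ["region", "product", "mean_tco2e_per_t", "sd", "min", "max", "pdf"]
_TRANSPORT_COLS = ["region", "region_to", "product", "mean_tco2e_per_t", "sd", "min", "max", "pdf"]


def _spec_from_row(row, name: str) -> EFSpec:
    def _opt(v):
        return None if pd.isna(v) else float(v)

    return EFSpec(
        name=name,
        mean=float(row["mean_tco2e_per_t"]),
        sd=float(row["sd"]),
        min=_opt(row.get("min")),
        max=_opt(row.get("max")),
        pdf=str(row.get("pdf", "normal")),
    )


class ManufacturingEFTable:
    """(region of production, product) -> EFSpec, t CO2e per tonne product."""

    def __init__(self, specs: Mapping[tuple[str, str], EFSpec]):
        self._specs = dict(specs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ManufacturingEFTable":
        missing = [c for c in _MANUF_COLS[:4] if c not in df.columns]
        if missing:
            raise ConfigError(f"manufacturing EF table missing columns: {missing}")
        specs = {}
        for row in df.to_dict("records"):
            key = (check_region(str(row["region"])), str(row["product"]))
            specs[key] = _spec_from_row(row, f"manuf/{key[0]}/{key[1]}")
        return cls(specs)

    def get(self, region: str, product: str) -> EFSpec:
        try:
            return self._specs[(region, product)]
        except KeyError:
            raise ConfigError(
                f"no manufacturing EF for (region={region!r}, product={product!r})"
            ) from None

    def items(self):
        return self._specs.items()

    def __len__(self) -> int:
        return len(self._specs)


class TransportEFTable:
    """(origin region, destination region, product) -> EFSpec."""

    def __init__(self, specs: Mapping[tuple[str, str, str], EFSpec]):
        self._specs = dict(specs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransportEFTable":
        missing = [c for c in _TRANSPORT_COLS[:5] if c not in df.columns]
        if missing:
            raise ConfigError(f"transport EF table missing columns: {missing}")
        specs = {}
        for row in df.to_dict("records"):
            key = (
                check_region(str(row["region"])),
                check_region(str(row["region_to"])),
                str(row["product"]),
            )
            specs[key] = _spec_from_row(row, f"transport/{key[0]}->{key[1]}/{key[2]}")
        return cls(specs)

    def get(self, origin: str, dest: str, product: str) -> EFSpec:
        try:
            return self._specs[(origin, dest, product)]
        except KeyError:
            raise ConfigError(
                f"no transport EF for (origin={origin!r}, dest={dest!r}, "
                f"product={product!r})"
            ) from None

    def items(self):
        return self._specs.items()

    def __len__(self) -> int:
        return len(self._specs)


# ---------------------------------------------------------------------------
# Registry

@dataclass
class Registry:
    """Fully resolved emission-factor registry."""

    constants: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))
    direct_schemes: dict[str, EFSpec] = field(default_factory=_default_direct_schemes)
    indirect: dict[str, EFSpec] = field(default_factory=_default_indirect)
    urea: EFSpec = field(default_factory=_default_urea)
    manufacturing: ManufacturingEFTable | None = None
    transport: TransportEFTable | None = None
    empirical: EFStore | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def gwp(self) -> float:
        return self.constants["gwp"]

    def indirect_factor(self, which: str, climate: str) -> EFSpec:
        """Look up fracgasf / ef4 / fracleach / ef5 for a climate class.

        Countries lacking a climate class fall back to wet with a warning.
        """
        if climate not in ("wet", "dry"):
            log.warning("unknown climate %r; falling back to wet", climate)
            climate = "wet"
        return self.indirect[f"{which}:{climate}"]

    def get_direct_ef(self, scheme: str, country: str, climate: str) -> EFSpec:
        """Resolve the direct soil EF for one country under a scheme.

        Empirical schemes fall back country -> region -> global when the
        requested scope is missing. An empirical country estimate with a
        single underlying plot (sd 0) borrows its region's sd so the
        Monte Carlo does not treat it as certain.
        """
        if scheme not in SCHEMES:
            raise ConfigError(f"unknown direct-EF scheme {scheme!r}")
        if scheme == "ipcc_tier1":
            return self.direct_schemes["ipcc_tier1"]
        if scheme == "ipcc_wetdry":
            if climate not in ("wet", "dry"):
                log.warning("unknown climate %r for %s; falling back to wet", climate, country)
                climate = "wet"
            return self.direct_schemes[f"ipcc_wetdry:{climate}"]

        if self.empirical is None:
            raise ConfigError(
                f"scheme {scheme!r} requires empirical EF estimates, none loaded"
            )
        est = self._resolve_empirical(scheme, country)
        sd = est.sd
        if est.level == "country" and sd == 0.0:
            region = self.empirical.country_region.get(country)
            if region and region in self.empirical.region:
                sd = self.empirical.region[region].sd
                log.warning(
                    "country %s empirical EF has sd 0 (single plot); using "
                    "regional sd %.4g", country, sd,
                )
        return EFSpec(f"direct/empirical/{est.level}/{est.scope}", est.mean, sd, None, None, "lognormal")

    def _resolve_empirical(self, scheme: str, country: str) -> DirectEFEstimate:
        store = self.empirical
        assert store is not None
        if scheme == "empirical_country" and country in store.country:
            return store.country[country]
        if scheme in ("empirical_country", "empirical_regional"):
            region = store.country_region.get(country)
            if region in store.region:
                return store.region[region]
        if store.global_ is not None:
            return store.global_
        raise ConfigError(f"no empirical EF available for {country!r} at any level")

    def validate_against(self, activity: pd.DataFrame, sourcing: pd.DataFrame | None = None) -> None:
        """Check every (region, product) the activity data needs resolves."""
        if self.manufacturing is None or self.transport is None:
            raise ConfigError("manufacturing and transport EF tables are required")
        for region in activity["region"].unique():
            for product in PRODUCTS:
                self.manufacturing.get(region, product)
                self.transport.get(region, region, product)
        if sourcing is not None:
            for row in sourcing.itertuples():
                self.transport.get(row.origin_region, row.region, row.product)


def get_direct_ef(
    scheme: str,
    country: str = "",
    climate: str = "wet",
    empirical: EFStore | None = None,
) -> EFSpec:
    """Functional wrapper around :meth:`Registry.get_direct_ef`."""
    reg = Registry(empirical=empirical)
    return reg.get_direct_ef(scheme, country, climate)


# ---------------------------------------------------------------------------
# Config loading

def _override_spec(spec: EFSpec, cfg: Mapping) -> EFSpec:
    kwargs = {}
    for k in ("mean", "sd", "min", "max", "pdf"):
        if k in cfg:
            kwargs[k] = cfg[k]
    return replace(spec, **kwargs)


def load_registry(
    config: Mapping | str | Path | None = None,
    *,
    base_dir: Path | None = None,
    empirical: EFStore | None = None,
) -> Registry:
    """Build a registry from a YAML config document (or mapping).

    Recognised sections: ``constants`` (gwp, urea_n_content,
    uan_n_content, uan_urea_fraction, n_content per product),
    ``direct_ef_schemes``, ``indirect_factors``, ``urea_ef``,
    ``manufacturing_ef`` and ``transport_ef`` (CSV paths, resolved
    relative to the config file). An empty config yields all shipped
    defaults. Every resolved value is logged with its provenance.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        base_dir = base_dir or path.parent
        with open(path) as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})
    base_dir = base_dir or Path(".")

    reg = Registry(empirical=empirical)
    reg.provenance = {
        "gwp": "paper",
        "direct_ef_schemes": "paper",
        "urea_ef": "paper",
        "indirect_factors": "IPCC-2019-default",
    }

    for key, val in (config.get("constants") or {}).items():
        if key not in DEFAULT_CONSTANTS and key != "n_content":
            raise ConfigError(f"unknown constant {key!r}")
        if key == "n_content":
            continue  # consumed by callers via activity.N_CONTENT overrides
        reg.constants[key] = float(val)
        reg.provenance[key] = "user"
        log.info("constant %s = %s (user)", key, val)

    for key, cfg in (config.get("direct_ef_schemes") or {}).items():
        if key not in reg.direct_schemes:
            raise ConfigError(f"unknown direct EF scheme entry {key!r}")
        reg.direct_schemes[key] = _override_spec(reg.direct_schemes[key], cfg)
        reg.provenance[f"direct:{key}"] = "user"

    for key, cfg in (config.get("indirect_factors") or {}).items():
        if key not in reg.indirect:
            raise ConfigError(f"unknown indirect factor entry {key!r}")
        reg.indirect[key] = _override_spec(reg.indirect[key], cfg)
        reg.provenance[f"indirect:{key}"] = "user"

    if "urea_ef" in config:
        reg.urea = _override_spec(reg.urea, config["urea_ef"])
        reg.provenance["urea_ef"] = "user"

    if "manufacturing_ef" in config:
        reg.manufacturing = ManufacturingEFTable.from_frame(
            pd.read_csv(base_dir / config["manufacturing_ef"])
        )
        reg.provenance["manufacturing_ef"] = "user"
    if "transport_ef" in config:
        reg.transport = TransportEFTable.from_frame(
            pd.read_csv(base_dir / config["transport_ef"])
        )
        reg.provenance["transport_ef"] = "user"
    return reg


def registry_to_config(reg: Registry) -> dict:
    """Serialise the registry's scalar parts back to a config mapping.

    EFSpec round-trip: ``load_registry(registry_to_config(r))`` preserves
    every scheme, indirect factor and constant.
    """
    def _spec(s: EFSpec) -> dict:
        return {"mean": s.mean, "sd": s.sd, "min": s.min, "max": s.max, "pdf": s.pdf}

    return {
        "constants": {k: v for k, v in reg.constants.items()},
        "direct_ef_schemes": {k: _spec(s) for k, s in reg.direct_schemes.items()},
        "indirect_factors": {k: _spec(s) for k, s in reg.indirect.items()},
        "urea_ef": _spec(reg.urea),
    }
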