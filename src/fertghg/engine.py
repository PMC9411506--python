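"""Deterministic emissions accounting for the fertiliser supply chain.

Per country, six components are evaluated and summed:

* manufacturing: sum over products of product tonnage x factory-gate EF of
  the region of production (t CO2e per t product);
* transport: sum over products and origin regions of tonnage x sourcing
  share x transport EF (t CO2e per t product);
* direct soil N2O: N applied x direct EF, converted t N2O-N -> t N2O by
  44/28 and to CO2e by the N2O GWP;
* indirect N2O from volatilisation/redeposition: N applied x volatilised
  fraction x EF4, same conversion;
* indirect N2O from leaching/runoff: N applied x leached fraction x EF5,
  same conversion;
* urea hydrolysis: urea-equivalent product tonnage x hydrolysis factor
  (t CO2-C per t product), converted to CO2 by 44/12.

The national total is the exact sum of the six; regional and global
figures are component-wise sums of the national ones. Field components
use total national N consumption (including the N not covered by the
eight product groups); manufacturing and transport cover only the
allocated products.

All component functions broadcast over numpy arrays, so the Monte Carlo
layer can push vectors of EF draws through the identical arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import (
    PRODUCTS,
    ProductConsumption,
    allocate_products,
    urea_equivalent_tonnage,
    validate_activity,
)
from .registry import (
    CO2_C_MASS_RATIO,
    N2O_MASS_RATIO,
    ManufacturingEFTable,
    Registry,
    TransportEFTable,
)

log = logging.getLogger(__name__)

_SHARE_TOL = 1e-9

Value = "float | np.ndarray"


@dataclass
class EmissionsBreakdown:
    """GHG emissions of one scope (country, region or global), t CO2e.

    ``ghg_m/t/d/v/l/u`` are manufacturing, transport, direct soil N2O,
    indirect volatilisation, indirect leaching and urea hydrolysis; the
    intermediates hold the underlying t N2O-N / t CO2-C quantities.
    Fields are floats in deterministic runs and draw vectors under MC.
    """

    scope: str
    ghg_m: Value
    ghg_t: Value
    ghg_d: Value
    ghg_v: Value
    ghg_l: Value
    ghg_u: Value
    n2o_n_direct: Value = 0.0
    n2o_n_volat: Value = 0.0
    n2o_n_leach: Value = 0.0
    co2_c_urea: Value = 0.0

    @property
    def total(self):
        return self.ghg_m + self.ghg_t + self.ghg_d + self.ghg_v + self.ghg_l + self.ghg_u

    def components(self) -> dict:
        return {
            "manufacturing": self.ghg_m,
            "transport": self.ghg_t,
            "direct": self.ghg_d,
            "volatilisation": self.ghg_v,
            "leaching": self.ghg_l,
            "urea": self.ghg_u,
        }


# ---------------------------------------------------------------------------
# Component operations

def manufacturing_emissions(
    products: Iterable[ProductConsumption],
    table: ManufacturingEFTable,
    region_of_production: Mapping[str, str],
    ef_values: Mapping[str, "Value"] | None = None,
):
    """Sum of product tonnage x factory-gate EF over the product mix.

    ``region_of_production`` maps each country to the region whose
    manufacturing EFs apply (by default the country's own region, i.e.
    regional EFs taken as national)."""
    total = 0.0
    for p in products:
        if p.product_tonnes == 0:
            continue
        spec = table.get(region_of_production[p.country], p.product)
        ef = spec.mean if ef_values is None else ef_values.get(spec.name, spec.mean)
        total = total + p.product_tonnes * ef
    return total


def transport_emissions(
    products: Iterable[ProductConsumption],
    table: TransportEFTable,
    sourcing_mix: Mapping[str, Mapping[str, float]],
    dest_region: str,
    ef_values: Mapping[str, "Value"] | None = None,
):
    """Sum over products and origins of tonnage x share x transport EF.

    ``sourcing_mix`` maps product -> {origin region: share}; shares must
    sum to 1 per product (a missing product means 100% intra-regional).
    """
    total = 0.0
    for p in products:
        if p.product_tonnes == 0:
            continue
        origins = sourcing_mix.get(p.product, {dest_region: 1.0})
        ssum = sum(origins.values())
        if abs(ssum - 1.0) > _SHARE_TOL:
            raise ValueError(
                f"sourcing shares for {p.country}/{p.product} sum to {ssum}, not 1"
            )
        for origin, share in origins.items():
            if share == 0:
                continue
            spec = table.get(origin, dest_region, p.product)
            ef = spec.mean if ef_values is None else ef_values.get(spec.name, spec.mean)
            total = total + p.product_tonnes * share * ef
    return total


def direct_field_emissions(n_applied, ef, gwp: float):
    """Direct soil N2O from N applied: returns (t N2O-N, t CO2e)."""
    n2o_n = n_applied * ef
    return n2o_n, n2o_n * N2O_MASS_RATIO * gwp


def indirect_volatilisation_emissions(n_applied, vf, ef, gwp: float):
    """Indirect N2O after volatilisation/redeposition: (t N2O-N, t CO2e)."""
    n2o_n = n_applied * vf * ef
    return n2o_n, n2o_n * N2O_MASS_RATIO * gwp


def indirect_leaching_emissions(n_applied, vf_leach, ef5, gwp: float):
    """Indirect N2O after leaching/runoff: (t N2O-N, t CO2e)."""
    n2o_n = n_applied * vf_leach * ef5
    return n2o_n, n2o_n * N2O_MASS_RATIO * gwp


def urea_field_emissions(urea_product_tonnes, ef_u):
    """CO2 released by urea hydrolysis: returns (t CO2-C, t CO2)."""
    co2_c = urea_product_tonnes * ef_u
    return co2_c, co2_c * CO2_C_MASS_RATIO


def assemble_country(
    scope: str, ghg_m, ghg_t, ghg_d, ghg_v, ghg_l, ghg_u, **intermediates
) -> EmissionsBreakdown:
    return EmissionsBreakdown(scope, ghg_m, ghg_t, ghg_d, ghg_v, ghg_l, ghg_u, **intermediates)


def aggregate(breakdowns: Sequence[EmissionsBreakdown], scope: str) -> EmissionsBreakdown:
    """Component-wise sum of national breakdowns (regional/global totals)."""
    seen = set()
    for b in breakdowns:
        if b.scope in seen:
            raise ValueError(f"duplicate scope {b.scope!r} in aggregation")
        seen.add(b.scope)
    if not breakdowns:
        raise ValueError("nothing to aggregate")
    return EmissionsBreakdown(
        scope,
        sum(b.ghg_m for b in breakdowns),
        sum(b.ghg_t for b in breakdowns),
        sum(b.ghg_d for b in breakdowns),
        sum(b.ghg_v for b in breakdowns),
        sum(b.ghg_l for b in breakdowns),
        sum(b.ghg_u for b in breakdowns),
        n2o_n_direct=sum(b.n2o_n_direct for b in breakdowns),
        n2o_n_volat=sum(b.n2o_n_volat for b in breakdowns),
        n2o_n_leach=sum(b.n2o_n_leach for b in breakdowns),
        co2_c_urea=sum(b.co2_c_urea for b in breakdowns),
    )


# ---------------------------------------------------------------------------
# Whole-inventory evaluation

def _sourcing_lookup(sourcing: pd.DataFrame | None) -> dict:
    """Index a tidy sourcing table (region, product, origin_region, share)."""
    lookup: dict[tuple[str, str], dict[str, float]] = {}
    if sourcing is None:
        return lookup
    for row in sourcing.itertuples():
        lookup.setdefault((row.region, row.product), {})[row.origin_region] = float(row.share)
    return lookup


def account(
    activity: pd.DataFrame,
    registry: Registry,
    scheme: str = "ipcc_tier1",
    sourcing: pd.DataFrame | None = None,
    ef_values: Mapping[str, "Value"] | None = None,
) -> list[EmissionsBreakdown]:
    """Evaluate the full chain for every country in an activity table.

    Returns one national breakdown per row, in tonnes CO2e. Pass
    ``ef_values`` (EF name -> scalar or draw vector) to substitute
    sampled EFs for the registry means.
    """
    validate_activity(activity)
    if registry.manufacturing is None or registry.transport is None:
        raise ValueError("registry lacks manufacturing/transport EF tables")
    gwp = registry.gwp
    sourcing_by_key = _sourcing_lookup(sourcing)

    def val(spec):
        return spec.mean if ef_values is None else ef_values.get(spec.name, spec.mean)

    out = []
    for row in activity.to_dict("records"):
        country, region, climate = row["country"], row["region"], row["climate"]
        products, _remainder = allocate_products(row)
        n_total = float(row["n_consumption_t"])

        ghg_m = manufacturing_emissions(
            products, registry.manufacturing, {country: region}, ef_values
        )
        mix = {
            p: sourcing_by_key[(region, p)]
            for p in PRODUCTS
            if (region, p) in sourcing_by_key
        }
        ghg_t = transport_emissions(
            products, registry.transport, mix, region, ef_values
        )

        direct_spec = registry.get_direct_ef(scheme, country, climate)
        n2o_d, ghg_d = direct_field_emissions(n_total, val(direct_spec), gwp)
        n2o_v, ghg_v = indirect_volatilisation_emissions(
            n_total,
            val(registry.indirect_factor("fracgasf", climate)),
            val(registry.indirect_factor("ef4", climate)),
            gwp,
        )
        n2o_l, ghg_l = indirect_leaching_emissions(
            n_total,
            val(registry.indirect_factor("fracleach", climate)),
            val(registry.indirect_factor("ef5", climate)),
            gwp,
        )
        by_product = {p.product: p.n_tonnes for p in products}
        urea_equiv = urea_equivalent_tonnage(
            by_product.get("urea", 0.0),
            by_product.get("uan", 0.0),
            urea_n_content=registry.constants["urea_n_content"],
            uan_n_content=registry.constants["uan_n_content"],
            uan_urea_fraction=registry.constants["uan_urea_fraction"],
        )
        co2_c, ghg_u = urea_field_emissions(urea_equiv, val(registry.urea))

        out.append(
            EmissionsBreakdown(
                scope=country,
                ghg_m=ghg_m,
                ghg_t=ghg_t,
                ghg_d=ghg_d,
                ghg_v=ghg_v,
                ghg_l=ghg_l,
                ghg_u=ghg_u,
                n2o_n_direct=n2o_d,
                n2o_n_volat=n2o_v,
                n2o_n_leach=n2o_l,
                co2_c_urea=co2_c,
            )
        )
    return out


def aggregate_by_region(
    breakdowns: Sequence[EmissionsBreakdown], country_region: Mapping[str, str]
) -> dict[str, EmissionsBreakdown]:
    by_region: dict[str, list[EmissionsBreakdown]] = {}
    for b in breakdowns:
        by_region.setdefault(country_region[b.scope], []).append(b)
    return {r: aggregate(bs, r) for r, bs in sorted(by_region.items())}


def breakdowns_to_frame(
    breakdowns: Sequence[EmissionsBreakdown],
    activity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-country results in Mt CO2e with share of the global total."""
    rows = []
    total_global = sum(float(b.total) for b in breakdowns)
    n_by_country = (
        activity.set_index("country")["n_consumption_t"] if activity is not None else None
    )
    for b in breakdowns:
        rows.append(
            {
                "country": b.scope,
                "n_consumption_mt": (
                    float(n_by_country[b.scope]) / 1e6
                    if n_by_country is not None and b.scope in n_by_country.index
                    else np.nan
                ),
                "ghg_m": float(b.ghg_m) / 1e6,
                "ghg_t": float(b.ghg_t) / 1e6,
                "ghg_u": float(b.ghg_u) / 1e6,
                "ghg_d": float(b.ghg_d) / 1e6,
                "ghg_v": float(b.ghg_v) / 1e6,
                "ghg_l": float(b.ghg_l) / 1e6,
                "total": float(b.total) / 1e6,
                "share_of_global": 100.0 * float(b.total) / total_global if total_global else np.nan,
            }
        )
    return pd.DataFrame(rows)
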