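"""Country-level synthetic-nitrogen activity data.

The activity table holds, per country and year, total agricultural
consumption of nitrogen in synthetic fertilisers (tonnes N), the country's
predominant climate class (wet/dry, by cropland area), and the market-mix
shares over the eight fertiliser product groups that carry manufacturing
and transport emission factors. Shares may sum to less than one: the
uncovered remainder (about 4% of world N in practice) is tracked
separately, included in field-emission accounting but excluded from
manufacturing and transport accounting.

The internal canonical unit is tonnes (of N or of product); reporting
layers convert to Mt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)

#: The eight fertiliser product groups, in canonical order: anhydrous
#: ammonia, ammonium nitrate, ammonium sulphate, calcium ammonium nitrate,
#: urea, urea-ammonium-nitrate solutions, ammonium phosphates, NPK compounds.
PRODUCTS: tuple[str, ...] = (
    "ammonia",
    "an",
    "as",
    "can",
    "urea",
    "uan",
    "ap",
    "npk",
)

SHARE_COLUMNS = [f"share_{p}" for p in PRODUCTS]

#: CSV schema for activity tables.
ACTIVITY_COLUMNS = (
    ["country", "region", "year", "n_consumption_t", "climate"]
    + SHARE_COLUMNS
    + ["population", "cropland_ha"]
)

#: Nitrogen mass fraction of one tonne of product, per product group.
#: Urea (0.466) and UAN (0.30) fix the urea-hydrolysis arithmetic; the
#: others are typical industry nutrient contents and are configurable
#: through the EF registry constants.
N_CONTENT: dict[str, float] = {
    "ammonia": 0.82,
    "an": 0.335,
    "as": 0.21,
    "can": 0.27,
    "urea": 0.466,
    "uan": 0.30,
    "ap": 0.11,
    "npk": 0.15,
}

#: Average tonnes of urea contained in one tonne of UAN solution.
UAN_UREA_FRACTION = 0.35

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class ProductConsumption:
    """Consumption of one product group in one country, on both nutrient
    (tonnes N) and product (tonnes of fertiliser product) bases."""

    country: str
    product: str
    n_tonnes: float
    product_tonnes: float

    def __post_init__(self) -> None:
        if self.product not in PRODUCTS:
            raise ValueError(f"unknown product group {self.product!r}")
        if self.n_tonnes < 0:
            raise ValueError("n_tonnes must be >= 0")
        if self.product_tonnes < self.n_tonnes - _SHARE_TOL:
            raise ValueError("product_tonnes must be >= n_tonnes (N content < 1)")


def allocate_products(
    row: Mapping[str, float],
    n_content: Mapping[str, float] | None = None,
) -> tuple[list[ProductConsumption], float]:
    """Split a country's N consumption over the eight product groups.

    *row* is an activity-table row (mapping with ``country``,
    ``n_consumption_t`` and the ``share_*`` columns). Returns the
    per-product consumptions and the unallocated N remainder (tonnes N).
    Nitrogen is conserved exactly: allocated + remainder = consumption.
    """
    n_content = dict(N_CONTENT, **(n_content or {}))
    total = float(row["n_consumption_t"])
    if total < 0:
        raise ValueError("n_consumption_t must be >= 0")
    shares = {p: float(row.get(f"share_{p}", 0.0) or 0.0) for p in PRODUCTS}
    for p, s in shares.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"share_{p} = {s} outside [0, 1]")
    ssum = sum(shares.values())
    if ssum > 1.0 + _SHARE_TOL:
        raise ValueError(f"product shares sum to {ssum} > 1")

    out = []
    for p in PRODUCTS:
        n_t = total * shares[p]
        out.append(
            ProductConsumption(
                country=str(row["country"]),
                product=p,
                n_tonnes=n_t,
                product_tonnes=n_t / n_content[p] if n_t else 0.0,
            )
        )
    remainder = total - sum(c.n_tonnes for c in out)
    return out, remainder


def urea_equivalent_tonnage(
    urea_n: float,
    uan_n: float,
    urea_n_content: float = N_CONTENT["urea"],
    uan_n_content: float = N_CONTENT["uan"],
    uan_urea_fraction: float = UAN_UREA_FRACTION,
) -> float:
    """Total urea product tonnage from urea and UAN nutrient tonnages.

    Urea N is converted to product by its N content; UAN N is converted to
    UAN product and then to its contained urea via the average urea
    fraction of UAN. The result feeds the urea-hydrolysis CO2 term.
    """
    if urea_n < 0 or uan_n < 0:
        raise ValueError("nutrient tonnages must be >= 0")
    return urea_n / urea_n_content + uan_urea_fraction * (uan_n / uan_n_content)


def assign_climate(country: str, cropland_by_zone: Mapping[str, float]) -> str:
    """Predominant climate class of a country by cropland area.

    Returns ``"wet"`` or ``"dry"``, whichever zone holds more cropland.
    Ties resolve to wet (the conservative, higher-EF class) with a warning.
    """
    wet = float(cropland_by_zone.get("wet", 0.0))
    dry = float(cropland_by_zone.get("dry", 0.0))
    if wet <= 0 and dry <= 0:
        raise ValueError(f"{country}: no cropland in either climate zone")
    if wet == dry:
        log.warning("%s: wet/dry cropland tie; assigning wet", country)
        return "wet"
    return "wet" if wet > dry else "dry"


def validate_activity(df: pd.DataFrame) -> pd.DataFrame:
    """Check an activity table against the schema and invariants."""
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {', '.join(missing)}")
    if (df["n_consumption_t"] < 0).any():
        raise ValueError("n_consumption_t must be >= 0")
    bad_climate = ~df["climate"].isin(["wet", "dry"])
    if bad_climate.any():
        raise ValueError(
            f"invalid climate class in rows {list(df.index[bad_climate])}"
        )
    share_sum = df[SHARE_COLUMNS].sum(axis=1)
    if ((df[SHARE_COLUMNS] < -_SHARE_TOL) | (df[SHARE_COLUMNS] > 1 + _SHARE_TOL)).any().any():
        raise ValueError("product shares must lie in [0, 1]")
    if (share_sum > 1 + _SHARE_TOL).any():
        raise ValueError("product shares must sum to <= 1 per row")
    dup = df.duplicated(subset=["country", "year"])
    if dup.any():
        raise ValueError("duplicate (country, year) rows in activity table")
    return df


def read_activity(path) -> pd.DataFrame:
    """Read and validate an activity CSV."""
    return validate_activity(pd.read_csv(path))


def products_to_frame(products: list[ProductConsumption]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "country": p.country,
                "product": p.product,
                "n_tonnes": p.n_tonnes,
                "product_tonnes": p.product_tonnes,
            }
            for p in products
        ]
    )
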