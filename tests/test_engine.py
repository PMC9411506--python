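"""Accounting engine: component formulas, aggregation, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from oracle import oracle_country_emissions

from fertghg.activity import PRODUCTS, N_CONTENT, ProductConsumption
from fertghg.engine import (
    EmissionsBreakdown,
    account,
    aggregate,
    aggregate_by_region,
    direct_field_emissions,
    indirect_leaching_emissions,
    indirect_volatilisation_emissions,
    manufacturing_emissions,
    transport_emissions,
    urea_field_emissions,
)
from fertghg.registry import (
    EFSpec,
    ManufacturingEFTable,
    Registry,
    TransportEFTable,
)

CO2E_PER_N2O_N = 44.0 / 28.0 * 265.0  # 416.42857...


def _manuf_table(ef_by_product, region="Europe"):
    return ManufacturingEFTable(
        {
            (region, p): EFSpec(f"manuf/{region}/{p}", ef, 0.0)
            for p, ef in ef_by_product.items()
        }
    )


class TestComponentFormulas:
    def test_manufacturing_sums_tonnage_times_ef(self):
        products = [
            ProductConsumption("X1", "urea", 4.66, 10.0),
            ProductConsumption("X1", "an", 1.675, 5.0),
        ]
        table = _manuf_table({"urea": 2.0, "an": 3.0})
        total = manufacturing_emissions(products, table, {"X1": "Europe"})
        assert total == pytest.approx(35.0)  # 10*2 + 5*3

    def test_manufacturing_empty_product_list(self):
        assert manufacturing_emissions([], _manuf_table({}), {}) == 0.0

    def test_transport_origin_split(self):
        products = [ProductConsumption("X1", "urea", 46.6, 100.0)]
        table = TransportEFTable(
            {
                ("Europe", "Europe", "urea"): EFSpec("t1", 0.05, 0.0),
                ("East Asia", "Europe", "urea"): EFSpec("t2", 0.20, 0.0),
            }
        )
        total = transport_emissions(
            products, table, {"urea": {"Europe": 0.6, "East Asia": 0.4}}, "Europe"
        )
        assert total == pytest.approx(11.0)  # 100*(0.6*0.05 + 0.4*0.2)

    def test_transport_shares_must_sum_to_one(self):
        products = [ProductConsumption("X1", "urea", 46.6, 100.0)]
        table = TransportEFTable({("Europe", "Europe", "urea"): EFSpec("t", 0.05, 0.0)})
        with pytest.raises(ValueError, match="sum"):
            transport_emissions(products, table, {"urea": {"Europe": 0.9}}, "Europe")

    @pytest.mark.parametrize(
        "n, ef, n2o_expected, co2e_expected",
        [(100.0, 0.01, 1.0, 416.4285714), (0.0, 0.01, 0.0, 0.0)],
    )
    def test_direct_field(self, n, ef, n2o_expected, co2e_expected):
        n2o, co2e = direct_field_emissions(n, ef, 265.0)
        assert n2o == pytest.approx(n2o_expected)
        assert co2e == pytest.approx(co2e_expected)

    def test_volatilisation(self):
        n2o, co2e = indirect_volatilisation_emissions(100.0, 0.11, 0.010, 265.0)
        assert n2o == pytest.approx(0.11)
        assert co2e == pytest.approx(45.807, rel=1e-4)

    def test_volatilisation_upper_bound(self):
        n2o, _ = indirect_volatilisation_emissions(100.0, 1.0, 1.0, 265.0)
        assert n2o == pytest.approx(100.0)

    def test_leaching(self):
        n2o, co2e = indirect_leaching_emissions(100.0, 0.24, 0.011, 265.0)
        assert n2o == pytest.approx(0.264)
        assert co2e == pytest.approx(109.937, rel=1e-4)

    def test_dry_climate_zero_leaching(self):
        assert indirect_leaching_emissions(100.0, 0.0, 0.011, 265.0) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "tonnes, ef_u, co2c_expected, co2_expected",
        [(100.0, 0.2, 20.0, 73.3333333), (0.0, 0.2, 0.0, 0.0), (100.0, 0.3, 30.0, 110.0)],
    )
    def test_urea_hydrolysis(self, tonnes, ef_u, co2c_expected, co2_expected):
        co2_c, co2 = urea_field_emissions(tonnes, ef_u)
        assert co2_c == pytest.approx(co2c_expected)
        assert co2 == pytest.approx(co2_expected)


class TestAssemblyAndAggregation:
    def test_total_is_exact_component_sum(self):
        b = EmissionsBreakdown("X1", 1, 2, 3, 4, 5, 6)
        assert b.total == 21

    def test_aggregate_sums_componentwise(self):
        a = EmissionsBreakdown("X1", 1, 1, 1, 1, 1, 5)
        b = EmissionsBreakdown("X2", 2, 2, 2, 2, 2, 10)
        g = aggregate([a, b], "global")
        assert g.total == a.total + b.total == 30
        assert g.ghg_u == 15

    def test_single_country_aggregate_is_identity(self):
        a = EmissionsBreakdown("X1", 1, 2, 3, 4, 5, 6)
        g = aggregate([a], "global")
        assert g.components() == a.components()

    def test_duplicate_country_rejected(self):
        a = EmissionsBreakdown("X1", 1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError, match="duplicate"):
            aggregate([a, a], "global")


def _random_inventory(rng, n_countries, regions=("Europe", "East Asia")):
    rows = []
    for i in range(n_countries):
        shares = rng.dirichlet(np.ones(len(PRODUCTS))) * rng.uniform(0.7, 1.0)
        row = {
            "country": f"C{i}",
            "region": regions[i % len(regions)],
            "year": 2018,
            "n_consumption_t": float(rng.uniform(1e4, 1e6)),
            "climate": "wet" if rng.random() < 0.5 else "dry",
            "population": 1e6,
            "cropland_ha": 1e6,
        }
        row.update({f"share_{p}": float(s) for p, s in zip(PRODUCTS, shares)})
        rows.append(row)
    activity = pd.DataFrame(rows)

    manuf = {}
    transport = {}
    for r in regions:
        for p in PRODUCTS:
            manuf[(r, p)] = float(rng.uniform(0.5, 3.5))
            for r2 in regions:
                transport[(r, r2, p)] = float(rng.uniform(0.02, 0.3))
    sourcing = {}
    for r in regions:
        for p in PRODUCTS:
            d = float(rng.uniform(0.5, 1.0))
            other = [x for x in regions if x != r][0]
            sourcing[(r, p)] = {r: d, other: 1.0 - d}
    return activity, manuf, transport, sourcing


def _registry_from_dicts(manuf, transport):
    return Registry(
        manufacturing=ManufacturingEFTable(
            {k: EFSpec(f"manuf/{k[0]}/{k[1]}", v, 0.25 * v, pdf="lognormal") for k, v in manuf.items()}
        ),
        transport=TransportEFTable(
            {k: EFSpec(f"transport/{k[0]}->{k[1]}/{k[2]}", v, 0.5 * v) for k, v in transport.items()}
        ),
    )


def _sourcing_frame(sourcing):
    rows = []
    for (region, product), origins in sourcing.items():
        for origin, share in origins.items():
            rows.append(
                {"region": region, "product": product, "origin_region": origin, "share": share}
            )
    return pd.DataFrame(rows)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_single_expression(self, seed):
        """Engine output equals a literal formula translation to 1e-9
        relative, on random <=5-country inventories."""
        rng = np.random.default_rng(1000 + seed)
        activity, manuf, transport, sourcing = _random_inventory(rng, int(rng.integers(1, 6)))
        registry = _registry_from_dicts(manuf, transport)
        breakdowns = account(activity, registry, "ipcc_tier1", _sourcing_frame(sourcing))
        for row, b in zip(activity.to_dict("records"), breakdowns):
            climate = row["climate"]
            expected = oracle_country_emissions(
                row,
                manuf,
                transport,
                sourcing,
                direct_ef=0.010,
                fracgasf=0.11,
                ef4=0.014 if climate == "wet" else 0.005,
                fracleach=0.24 if climate == "wet" else 0.0,
                ef5=0.011,
                urea_ef=0.2,
                gwp=265.0,
            )
            got = dict(b.components())
            got["total"] = b.total
            for comp, val in expected.items():
                assert got[comp] == pytest.approx(val, rel=1e-9, abs=1e-9), comp


class TestInventoryProperties:
    def test_linearity_in_activity(self):
        rng = np.random.default_rng(5)
        activity, manuf, transport, sourcing = _random_inventory(rng, 3)
        registry = _registry_from_dicts(manuf, transport)
        src = _sourcing_frame(sourcing)
        base = account(activity, registry, "ipcc_tier1", src)
        scaled_activity = activity.copy()
        scaled_activity["n_consumption_t"] *= 3.0
        scaled = account(scaled_activity, registry, "ipcc_tier1", src)
        for a, b in zip(base, scaled):
            assert b.total == pytest.approx(3.0 * a.total, rel=1e-12)

    def test_region_then_global_equals_direct_sum(self, activity, registry, sourcing):
        breakdowns = account(activity, registry, "ipcc_tier1", sourcing)
        country_region = dict(zip(activity["country"], activity["region"]))
        regional = aggregate_by_region(breakdowns, country_region)
        via_regions = aggregate(list(regional.values()), "global")
        direct = aggregate(breakdowns, "global")
        assert via_regions.total == pytest.approx(direct.total, rel=1e-12)
        assert via_regions.ghg_d == pytest.approx(direct.ghg_d, rel=1e-12)

    def test_constant_co2e_per_n2o_ratio(self, activity, registry, sourcing):
        breakdowns = account(activity, registry, "ipcc_wetdry", sourcing)
        for b in breakdowns:
            for co2e, n2o in [(b.ghg_d, b.n2o_n_direct), (b.ghg_v, b.n2o_n_volat)]:
                if n2o:
                    assert co2e / n2o == pytest.approx(CO2E_PER_N2O_N, rel=1e-12)
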