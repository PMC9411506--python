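"""Independent single-expression reference implementation of the accounting.

Deliberately written as one literal formula translation over plain dicts,
sharing no code with the engine, so agreement between the two is a
meaningful cross-check on toy inventories.
"""

from fertghg.activity import N_CONTENT, PRODUCTS, UAN_UREA_FRACTION


def oracle_country_emissions(row, manuf_ef, transport_ef, sourcing, direct_ef,
                             fracgasf, ef4, fracleach, ef5, urea_ef, gwp):
    """Reference totals for one country.

    ``row``: dict with country, region, climate, n_consumption_t and
    share_<product> entries. ``manuf_ef``: (region, product) -> t CO2e/t
    product; ``transport_ef``: (origin, dest, product) -> same;
    ``sourcing``: (region, product) -> {origin: share}. Field factors are
    plain fractions. Returns a dict of the six components in t CO2e.
    """
    n = row["n_consumption_t"]
    region = row["region"]
    tonnes_product = {
        p: n * row.get(f"share_{p}", 0.0) / N_CONTENT[p] for p in PRODUCTS
    }
    ghg_m = sum(
        tonnes_product[p] * manuf_ef[(region, p)]
        for p in PRODUCTS
        if tonnes_product[p] > 0
    )
    ghg_t = sum(
        tonnes_product[p] * share * transport_ef[(origin, region, p)]
        for p in PRODUCTS
        if tonnes_product[p] > 0
        for origin, share in sourcing.get((region, p), {region: 1.0}).items()
    )
    ghg_d = n * direct_ef * (44.0 / 28.0) * gwp
    ghg_v = n * fracgasf * ef4 * (44.0 / 28.0) * gwp
    ghg_l = n * fracleach * ef5 * (44.0 / 28.0) * gwp
    urea_equiv = (
        n * row.get("share_urea", 0.0) / 0.466
        + UAN_UREA_FRACTION * (n * row.get("share_uan", 0.0) / 0.30)
    )
    ghg_u = urea_equiv * urea_ef * (44.0 / 12.0)
    return {
        "manufacturing": ghg_m,
        "transport": ghg_t,
        "direct": ghg_d,
        "volatilisation": ghg_v,
        "leaching": ghg_l,
        "urea": ghg_u,
        "total": ghg_m + ghg_t + ghg_d + ghg_v + ghg_l + ghg_u,
    }
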