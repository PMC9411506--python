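"""Synthetic world generator: every input the pipeline needs.

Real inputs to the accounting — national fertiliser-consumption
statistics, market-mix breakdowns, commercial manufacturing/transport EF
tables, and the compiled paired-plot flux dataset — are either
licence-restricted or large external downloads. This module generates
structurally faithful stand-ins with known ground truth so the full
analysis runs end-to-end and estimator behaviour can be verified against
the truth that generated the data.

What is emulated: a nine-region world with per-country N consumption
summing to a configurable world total (default 100 Mt N); wet/dry
climate classes; Dirichlet market-mix shares over the eight product
groups covering ~96% of N; paired-plot datasets (default 1,602 records)
with deliberately uneven country coverage over-representing North
America and Europe, and lognormal multiplicative plot-level EF
dispersion around known country truths; manufacturing EF tables with 25%
relative sd (lognormal) and transport tables with 50% relative sd
(normal); and smooth exponential-growth-with-slowdown historical series
(growth decaying from ~15%/yr early to ~2.5%/yr late).

What is not emulated: real FAO country values, crop composition, or any
statistical realism beyond structure.

All draws flow from a single master seed through named substreams, so
changing one generator's parameters does not perturb another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .activity import PRODUCTS, SHARE_COLUMNS, ACTIVITY_COLUMNS
from .efdirect import PAIRED_PLOT_COLUMNS
from .regions import REGIONS

#: Substream ids: one independent stream per generator.
_STREAMS = {"activity": 0, "plots": 1, "eftables": 2, "sourcing": 3, "trends": 4}

#: Regional medians for the true direct EF (fraction of N applied),
#: echoing the reported spread: low in Africa/Russian Commonwealth,
#: high in the Americas.
DEFAULT_EF_MEDIANS: dict[str, float] = {
    "East Asia": 0.005,
    "South Asia": 0.007,
    "Europe": 0.007,
    "North America": 0.011,
    "Latin America": 0.024,
    "Africa": 0.003,
    "Middle East": 0.004,
    "Oceania": 0.005,
    "Russian Commonwealth": 0.003,
}

#: Probability that a country of the region is classed wet.
DEFAULT_WET_PROB: dict[str, float] = {
    "East Asia": 0.7,
    "South Asia": 0.6,
    "Europe": 0.8,
    "North America": 0.7,
    "Latin America": 0.9,
    "Africa": 0.5,
    "Middle East": 0.1,
    "Oceania": 0.5,
    "Russian Commonwealth": 0.4,
}

#: Paired-plot sampling weights per region: North America and Europe are
#: over-represented, mirroring the documented bias of field studies.
DEFAULT_PLOT_WEIGHTS: dict[str, float] = {
    "North America": 0.30,
    "Europe": 0.28,
    "East Asia": 0.15,
    "South Asia": 0.08,
    "Latin America": 0.08,
    "Oceania": 0.04,
    "Africa": 0.03,
    "Middle East": 0.02,
    "Russian Commonwealth": 0.02,
}

#: Baseline factory-gate EF per product, t CO2e per tonne product (the
#: urea value excludes the CO2 later released by hydrolysis, which is
#: accounted separately).
BASE_MANUF_EF: dict[str, float] = {
    "ammonia": 2.4,
    "an": 2.8,
    "as": 1.6,
    "can": 2.5,
    "urea": 1.5,
    "uan": 2.0,
    "ap": 1.2,
    "npk": 1.4,
}


@dataclass
class WorldSpec:
    """Parameters of the synthetic world.

    Defaults size the world so the full pipeline plus a 5,000-draw Monte
    Carlo runs in seconds: 9 regions x 5 countries, ~100 Mt N world
    consumption, 1,602 paired plots.
    """

    seed: int = 0
    countries_per_region: int = 5
    regions: tuple[str, ...] = REGIONS
    world_n_mt: float = 100.0
    coverage: float = 0.96  # share of N covered by the 8 product groups
    mix_alpha: float = 2.0  # Dirichlet concentration for market mixes
    ef_medians: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EF_MEDIANS))
    ef_country_log_sd: float = 0.3  # country spread around the regional median
    wet_prob: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WET_PROB))
    n_plots_total: int = 1602
    plot_region_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLOT_WEIGHTS)
    )
    plot_noise_sigma: float = 0.8  # log-scale sd of plot-level EF dispersion
    n_applied_range: tuple[float, float] = (50.0, 250.0)
    control_flux_median: float = 0.5  # kg N2O-N/ha baseline, lognormal
    control_flux_log_sd: float = 0.5
    domestic_share: float = 0.79  # intra-regional sourcing fraction
    years: tuple[int, int] = (1961, 2018)

    def country_codes(self) -> dict[str, str]:
        """country code -> region, deterministic naming."""
        abbr = {r: "".join(w[0] for w in r.split()).upper() for r in self.regions}
        return {
            f"{abbr[r]}{i + 1}": r
            for r in self.regions
            for i in range(self.countries_per_region)
        }


def _rng(spec_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([spec_seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Activity data

def gen_true_efs(spec: WorldSpec) -> dict[str, float]:
    """Known per-country true direct EFs (the recovery target)."""
    rng = _rng(spec.seed, "activity")
    out = {}
    for country, region in spec.country_codes().items():
        median = spec.ef_medians[region]
        out[country] = float(median * rng.lognormal(0.0, spec.ef_country_log_sd))
    return out


def gen_activity_table(spec: WorldSpec) -> pd.DataFrame:
    """Country-level activity table satisfying every consumer invariant."""
    rng = _rng(spec.seed, "activity")
    codes = spec.country_codes()
    # consume the EF draws first so gen_true_efs and this function agree
    true_efs = {}
    for country, region in codes.items():
        true_efs[country] = spec.ef_medians[region] * rng.lognormal(0.0, spec.ef_country_log_sd)

    raw_n = rng.lognormal(mean=0.0, sigma=1.0, size=len(codes))
    n_t = raw_n / raw_n.sum() * spec.world_n_mt * 1e6

    mix_by_region = {
        r: rng.dirichlet(np.full(len(PRODUCTS), spec.mix_alpha)) * spec.coverage
        for r in spec.regions
    }

    rows = []
    for (country, region), n in zip(codes.items(), n_t):
        climate = "wet" if rng.random() < spec.wet_prob[region] else "dry"
        mix = mix_by_region[region]
        population = float(rng.lognormal(math.log(2e7), 1.0))
        cropland = float(n / rng.uniform(0.05, 0.15))  # implies 50-150 kgN/ha
        row = {
            "country": country,
            "region": region,
            "year": spec.years[1],
            "n_consumption_t": float(n),
            "climate": climate,
        }
        row.update({c: float(s) for c, s in zip(SHARE_COLUMNS, mix)})
        row["population"] = population
        row["cropland_ha"] = cropland
        rows.append(row)
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)


# ---------------------------------------------------------------------------
# Paired plots

def gen_paired_plots(
    true_efs: Mapping[str, float],
    n_per_country: "int | Mapping[str, int]",
    country_region: Mapping[str, str],
    noise_sigma: float = 0.8,
    n_applied_range: tuple[float, float] = (50.0, 250.0),
    control_flux_median: float = 0.5,
    control_flux_log_sd: float = 0.5,
    seed: int = 0,
    climates: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Paired-plot records with known ground-truth country EFs.

    Each record draws a plot-level EF lognormally around the country
    truth (mean-preserving: the multiplicative noise has mean 1), an N
    rate uniform in ``n_applied_range`` and an independent positive
    control flux; the treated flux is control + rate x plot EF, so the
    paired-plot subtraction is genuinely exercised. With
    ``noise_sigma = 0`` every plot EF equals the truth and the estimator
    recovers it exactly.
    """
    rng = np.random.default_rng([seed, _STREAMS["plots"]])
    rows = []
    for country in sorted(true_efs):
        truth = float(true_efs[country])
        n = n_per_country if isinstance(n_per_country, int) else n_per_country.get(country, 0)
        if n < 1:
            continue
        if noise_sigma > 0:
            noise = rng.lognormal(-noise_sigma**2 / 2.0, noise_sigma, n)
        else:
            noise = np.ones(n)
        ef_plot = truth * noise
        n_applied = rng.uniform(*n_applied_range, n)
        control = rng.lognormal(math.log(control_flux_median), control_flux_log_sd, n)
        treated = control + n_applied * ef_plot
        for i in range(n):
            rows.append(
                {
                    "record_id": f"{country}-{i + 1}",
                    "country": country,
                    "region": country_region[country],
                    "crop": "synthetic-crop",
                    "n_applied_kg_ha": float(n_applied[i]),
                    "n2o_treated_kg_ha": float(treated[i]),
                    "n2o_control_kg_ha": float(control[i]),
                    "climate": climates.get(country, "unknown") if climates else "unknown",
                    "fertiliser_type": "synthetic",
                }
            )
    return pd.DataFrame(rows, columns=PAIRED_PLOT_COLUMNS)


def plot_counts(spec: WorldSpec) -> dict[str, int]:
    """Allocate the total plot budget unevenly across countries.

    Regions get shares per ``plot_region_weights`` (North America and
    Europe dominating); within a region the budget splits evenly, each
    country keeping at least one plot.
    """
    codes = spec.country_codes()
    counts: dict[str, int] = {}
    for region in spec.regions:
        members = [c for c, r in codes.items() if r == region]
        budget = spec.plot_region_weights.get(region, 0.0) * spec.n_plots_total
        per = max(1, round(budget / len(members)))
        for c in members:
            counts[c] = per
    return counts


def gen_world_plots(spec: WorldSpec, true_efs: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Default-world paired-plot dataset (~1,602 uneven records)."""
    if true_efs is None:
        true_efs = gen_true_efs(spec)
    return gen_paired_plots(
        true_efs,
        plot_counts(spec),
        spec.country_codes(),
        noise_sigma=spec.plot_noise_sigma,
        n_applied_range=spec.n_applied_range,
        control_flux_median=spec.control_flux_median,
        control_flux_log_sd=spec.control_flux_log_sd,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# EF tables and sourcing

def gen_ef_tables(spec: WorldSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic manufacturing and transport EF tables.

    Manufacturing: per (region, product), baseline product EF times a
    regional lognormal factor; sd = 25% of the mean, lognormal pdf,
    bounds at 0.4x and 2.5x the mean. Transport: per (origin,
    destination, product); intra-regional lanes are cheap, inter-regional
    lanes distance-like; sd = 50% of the mean, normal pdf, floored at 0.
    """
    rng = _rng(spec.seed, "eftables")
    regional_factor = {r: float(rng.lognormal(0.0, 0.2)) for r in spec.regions}

    manuf_rows = []
    for region in spec.regions:
        for product in PRODUCTS:
            mean = BASE_MANUF_EF[product] * regional_factor[region] * float(
                rng.lognormal(0.0, 0.05)
            )
            manuf_rows.append(
                {
                    "region": region,
                    "product": product,
                    "mean_tco2e_per_t": mean,
                    "sd": 0.25 * mean,
                    "min": 0.4 * mean,
                    "max": 2.5 * mean,
                    "pdf": "lognormal",
                }
            )

    transport_rows = []
    for origin in spec.regions:
        for dest in spec.regions:
            base = 0.05 if origin == dest else float(rng.uniform(0.12, 0.25))
            for product in PRODUCTS:
                mean = base * float(rng.lognormal(0.0, 0.1))
                transport_rows.append(
                    {
                        "region": origin,
                        "region_to": dest,
                        "product": product,
                        "mean_tco2e_per_t": mean,
                        "sd": 0.50 * mean,
                        "min": 0.0,
                        "max": None,
                        "pdf": "normal",
                    }
                )
    return pd.DataFrame(manuf_rows), pd.DataFrame(transport_rows)


def gen_sourcing_mix(spec: WorldSpec) -> pd.DataFrame:
    """Origin shares per (consumer region, product).

    Around 79% of product is sourced within the consuming region; the
    remainder splits over two other origin regions.
    """
    rng = _rng(spec.seed, "sourcing")
    rows = []
    for region in spec.regions:
        others = [r for r in spec.regions if r != region]
        for product in PRODUCTS:
            domestic = float(np.clip(rng.normal(spec.domestic_share, 0.05), 0.5, 1.0))
            foreign = rng.choice(len(others), size=2, replace=False)
            split = float(rng.uniform(0.3, 0.7))
            shares = {
                region: domestic,
                others[int(foreign[0])]: (1 - domestic) * split,
                others[int(foreign[1])]: (1 - domestic) * (1 - split),
            }
            for origin, share in shares.items():
                rows.append(
                    {
                        "region": region,
                        "product": product,
                        "origin_region": origin,
                        "share": share,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Historical series

#: (early growth rate, late growth rate, decay time constant in years).
DEFAULT_GROWTH: dict[str, tuple[float, float, float]] = {
    "n_use": (0.15, 0.025, 12.0),
    "population": (0.020, 0.010, 30.0),
    "cropland": (0.010, 0.002, 30.0),
    "crop_production": (0.030, 0.025, 30.0),
}


def gen_trend_series(
    spec: WorldSpec,
    growth: Mapping[str, tuple[float, float, float]] | None = None,
) -> pd.DataFrame:
    """Smooth exponential-growth-with-slowdown series per region.

    The annual growth rate decays exponentially from the early to the
    late value: g(t) = g_late + (g_early - g_late) exp(-(t - t0)/tau).
    With g_early = g_late the series is exactly constant-growth and the
    growth-rate indicator recovers the rate in closed form.
    """
    growth = dict(DEFAULT_GROWTH, **(growth or {}))
    rng = _rng(spec.seed, "trends")
    y0, y1 = spec.years
    rows = []
    for region in spec.regions:
        for variable, (g0, g1, tau) in growth.items():
            level = float(rng.lognormal(math.log(1e6), 0.5))
            for year in range(y0, y1 + 1):
                rows.append(
                    {"scope": region, "variable": variable, "year": year, "value": level}
                )
                g = g1 + (g0 - g1) * math.exp(-(year - y0) / tau)
                level *= 1.0 + g
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle writer

def write_bundle(spec: WorldSpec, out_dir: "str | Path") -> dict[str, Path]:
    """Write the complete input bundle for a pipeline run.

    Produces activity.csv, paired_plots.csv, manufacturing_ef.csv,
    transport_ef.csv, sourcing.csv, trends.csv, true_efs.csv and
    config.yaml in *out_dir*; returns the file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    activity = gen_activity_table(spec)
    plots = gen_world_plots(spec)
    manuf, transport = gen_ef_tables(spec)
    sourcing = gen_sourcing_mix(spec)
    trends = gen_trend_series(spec)
    true_efs = gen_true_efs(spec)

    files = {
        "activity": out / "activity.csv",
        "paired_plots": out / "paired_plots.csv",
        "manufacturing_ef": out / "manufacturing_ef.csv",
        "transport_ef": out / "transport_ef.csv",
        "sourcing": out / "sourcing.csv",
        "trends": out / "trends.csv",
        "true_efs": out / "true_efs.csv",
        "config": out / "config.yaml",
    }
    activity.to_csv(files["activity"], index=False)
    plots.to_csv(files["paired_plots"], index=False)
    manuf.to_csv(files["manufacturing_ef"], index=False)
    transport.to_csv(files["transport_ef"], index=False)
    sourcing.to_csv(files["sourcing"], index=False)
    trends.to_csv(files["trends"], index=False)
    pd.DataFrame(
        [{"country": c, "true_ef": v} for c, v in sorted(true_efs.items())]
    ).to_csv(files["true_efs"], index=False)
    config = {
        "manufacturing_ef": "manufacturing_ef.csv",
        "transport_ef": "transport_ef.csv",
    }
    with open(files["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return files
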