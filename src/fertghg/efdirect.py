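"""Empirical direct soil N2O-N emission factors from paired-plot data.

A paired-plot experiment measures cumulative soil N2O-N flux on a fertilised
plot and on a matched unfertilised control (same site, crop and season).
Subtracting the control isolates the flux attributable to the fertiliser,
and dividing by the nitrogen applied gives a dimensionless plot-level
emission factor (kg N2O-N emitted per kg N applied):

    EF_plot = (N2O_treated - N2O_control) / N_applied

Country estimates are the mean and sample standard deviation of the plot
EFs measured in that country. Regional estimates weight country means by
the number of underlying plots; the regional sd is the sd of the pooled
plot-level EFs of the member countries, reconstructed from the per-country
sufficient statistics. The global estimate weights regional means by the
number of countries contributing data to each region.

Plot-level EFs may be negative (the control can out-emit the treated plot);
negative values are retained so means are not biased upward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .regions import check_region

log = logging.getLogger(__name__)

#: CSV schema for paired-plot input files.
PAIRED_PLOT_COLUMNS = [
    "record_id",
    "country",
    "region",
    "crop",
    "n_applied_kg_ha",
    "n2o_treated_kg_ha",
    "n2o_control_kg_ha",
    "climate",
    "fertiliser_type",
]


@dataclass(frozen=True)
class PairedPlotRecord:
    """One fertilised/control plot pair.

    Fluxes are cumulative kg N2O-N per hectare over the measurement period;
    ``n_applied`` is kg N per hectare on the treated plot.
    """

    record_id: str
    country: str
    region: str
    crop: str
    n_applied: float
    n2o_treated: float
    n2o_control: float
    climate: str = "unknown"

    def __post_init__(self) -> None:
        if not (self.n_applied > 0):
            raise ValueError(
                f"record {self.record_id}: n_applied must be > 0, got {self.n_applied}"
            )
        for name in ("n2o_treated", "n2o_control"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"record {self.record_id}: {name} is not finite")
        check_region(self.region)


@dataclass(frozen=True)
class DirectEFEstimate:
    """A direct soil EF at country, regional or global level.

    ``mean`` and ``sd`` are dimensionless fractions (kg N2O-N per kg N);
    ``n_points`` counts the paired plots underlying the estimate. The
    dispersion of empirical EFs is treated as lognormal downstream.
    """

    level: str  # country | region | global
    scope: str
    mean: float
    sd: float
    n_points: int
    pdf: str = "lognormal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass
class EFStore:
    """Country, regional and global empirical EF estimates plus the
    country-to-region map needed for fallback resolution."""

    country: dict[str, DirectEFEstimate]
    region: dict[str, DirectEFEstimate]
    global_: DirectEFEstimate
    country_region: dict[str, str]


# ---------------------------------------------------------------------------
# Filtering

def filter_synthetic_only(
    raw: pd.DataFrame,
) -> tuple[list[PairedPlotRecord], dict[str, int]]:
    """Keep only synthetic-fertiliser records with a valid control pair.

    Drops (in order, with per-reason counts returned): records whose
    fertiliser type is not ``synthetic``; records missing the control flux,
    the treated flux or the N rate; records with a non-positive N rate;
    exact duplicates (same country, crop, rate and fluxes).

    Raises ``ValueError`` if the input or the filtered result is empty.
    """
    missing = [c for c in PAIRED_PLOT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"paired-plot table missing columns: {', '.join(missing)}")
    if len(raw) == 0:
        raise ValueError("paired-plot table is empty: no usable records")

    counts: dict[str, int] = {"input": len(raw)}
    df = raw.copy()

    keep = df["fertiliser_type"].astype(str).str.strip().str.lower() == "synthetic"
    counts["non_synthetic"] = int((~keep).sum())
    df = df[keep]

    numeric = ["n_applied_kg_ha", "n2o_treated_kg_ha", "n2o_control_kg_ha"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    complete = df[numeric].notna().all(axis=1)
    counts["missing_plot_data"] = int((~complete).sum())
    df = df[complete]

    positive = df["n_applied_kg_ha"] > 0
    counts["nonpositive_n_applied"] = int((~positive).sum())
    df = df[positive]

    dup_key = ["country", "crop"] + numeric
    dups = df.duplicated(subset=dup_key, keep="first")
    counts["duplicate"] = int(dups.sum())
    df = df[~dups]

    counts["retained"] = len(df)
    for reason, n in counts.items():
        if reason not in ("input", "retained") and n:
            log.info("filter_synthetic_only: removed %d records (%s)", n, reason)
    if len(df) == 0:
        raise ValueError("no usable records after filtering: dataset is unusable")

    records = [
        PairedPlotRecord(
            record_id=str(r.record_id),
            country=str(r.country),
            region=str(r.region),
            crop=str(r.crop),
            n_applied=float(r.n_applied_kg_ha),
            n2o_treated=float(r.n2o_treated_kg_ha),
            n2o_control=float(r.n2o_control_kg_ha),
            climate=str(r.climate) if pd.notna(r.climate) else "unknown",
        )
        for r in df.itertuples()
    ]
    return records, counts


# ---------------------------------------------------------------------------
# Estimation

def plot_level_ef(record: PairedPlotRecord) -> float:
    """Dimensionless plot-level EF: flux difference over N applied."""
    return (record.n2o_treated - record.n2o_control) / record.n_applied


def estimate_country_efs(
    records: Iterable[PairedPlotRecord],
) -> dict[str, DirectEFEstimate]:
    """Per-country mean and sample sd (ddof=1) of plot-level EFs.

    A country with a single plot gets sd = 0 and a logged warning.
    """
    by_country: dict[str, list[float]] = {}
    for rec in records:
        by_country.setdefault(rec.country, []).append(plot_level_ef(rec))
    if not by_country:
        raise ValueError("no records supplied")

    out: dict[str, DirectEFEstimate] = {}
    for country, efs in sorted(by_country.items()):
        n = len(efs)
        mean = sum(efs) / n
        if n == 1:
            sd = 0.0
            log.warning(
                "country %s has a single paired plot; sd set to 0", country
            )
        else:
            var = sum((e - mean) ** 2 for e in efs) / (n - 1)
            sd = math.sqrt(var)
        out[country] = DirectEFEstimate("country", country, mean, sd, n)
    return out


def _pooled(
    members: list[tuple[float, float, int]],
) -> tuple[float, float, int]:
    """Weighted mean and pooled sd from (mean, sd, n) sufficient statistics.

    The pooled variance reconstructs the variance of the union of the
    underlying observations: sum of within-group sums of squares plus
    between-group deviation, over N-1.
    """
    n_total = sum(n for _, _, n in members)
    mean = sum(m * n for m, _, n in members) / n_total
    if n_total == 1:
        return mean, 0.0, n_total
    ss = sum((n - 1) * s * s + n * (m - mean) ** 2 for m, s, n in members)
    return mean, math.sqrt(ss / (n_total - 1)), n_total


def estimate_regional_efs(
    country_efs: Mapping[str, DirectEFEstimate],
    country_region: Mapping[str, str],
) -> dict[str, DirectEFEstimate]:
    """Regional EFs: country means weighted by plots per country.

    The regional sd is the sd of the pooled plot-level EFs of member
    countries. Regions with no contributing country are absent from the
    result rather than reported as zero.
    """
    by_region: dict[str, list[tuple[float, float, int]]] = {}
    for country, est in country_efs.items():
        region = check_region(country_region[country])
        by_region.setdefault(region, []).append((est.mean, est.sd, est.n_points))

    out: dict[str, DirectEFEstimate] = {}
    for region, members in sorted(by_region.items()):
        mean, sd, n = _pooled(members)
        out[region] = DirectEFEstimate("region", region, mean, sd, n)
    return out


def estimate_global_ef(
    regional_efs: Mapping[str, DirectEFEstimate],
    countries_per_region: Mapping[str, int],
) -> DirectEFEstimate:
    """Global EF: regional means weighted by countries contributing data.

    The sd pools the regional estimates with the same country-count
    weights, so between-region spread dominates when regions disagree.
    """
    if not regional_efs:
        raise ValueError("no regional estimates supplied")
    members = []
    n_points = 0
    for region, est in regional_efs.items():
        c = countries_per_region[region]
        if c < 1:
            raise ValueError(f"region {region} has country count {c} < 1")
        members.append((est.mean, est.sd, c))
        n_points += est.n_points
    mean, sd, _ = _pooled(members)
    return DirectEFEstimate("global", "global", mean, sd, n_points)


def estimate_all(records: Iterable[PairedPlotRecord]) -> EFStore:
    """Run the full country -> region -> global estimation chain."""
    records = list(records)
    country_region = {r.country: r.region for r in records}
    country = estimate_country_efs(records)
    region = estimate_regional_efs(country, country_region)
    countries_per_region: dict[str, int] = {}
    for c in country:
        countries_per_region[country_region[c]] = (
            countries_per_region.get(country_region[c], 0) + 1
        )
    global_ = estimate_global_ef(region, countries_per_region)
    return EFStore(country, region, global_, country_region)


# ---------------------------------------------------------------------------
# I/O

def read_paired_plots(path) -> pd.DataFrame:
    """Read a paired-plot CSV (see ``PAIRED_PLOT_COLUMNS``)."""
    return pd.read_csv(path, dtype={"record_id": str})


def store_from_frame(df: pd.DataFrame, country_region: Mapping[str, str]) -> EFStore:
    """Rebuild an EFStore from a tidy estimates table.

    Inverse of :func:`estimates_to_frame`; ``country_region`` supplies the
    fallback map (typically taken from the activity table).
    """
    required = {"scope_level", "scope", "mean", "sd", "n_points"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"estimates table missing columns: {sorted(missing)}")
    country: dict[str, DirectEFEstimate] = {}
    region: dict[str, DirectEFEstimate] = {}
    global_ = None
    for row in df.itertuples():
        est = DirectEFEstimate(
            str(row.scope_level), str(row.scope), float(row.mean), float(row.sd), int(row.n_points)
        )
        if est.level == "country":
            country[est.scope] = est
        elif est.level == "region":
            region[est.scope] = est
        elif est.level == "global":
            global_ = est
        else:
            raise ValueError(f"unknown scope_level {est.level!r}")
    if global_ is None:
        raise ValueError("estimates table lacks a global row")
    return EFStore(country, region, global_, dict(country_region))


def estimates_to_frame(store: EFStore) -> pd.DataFrame:
    """Flatten an EFStore to a tidy table (scope_level, scope, mean, sd, n_points)."""
    rows = []
    for est in list(store.country.values()) + list(store.region.values()) + [store.global_]:
        rows.append(
            {
                "scope_level": est.level,
                "scope": est.scope,
                "mean": est.mean,
                "sd": est.sd,
                "n_points": est.n_points,
            }
        )
    return pd.DataFrame(rows)
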