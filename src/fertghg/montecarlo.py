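"""Monte Carlo propagation of emission-factor uncertainty.

Each emission factor is an :class:`~fertghg.registry.EFSpec` with a mean,
standard deviation, optional bounds and a distribution family. Per
iteration one value is drawn per EF and shared across every country that
uses that EF (full correlation within an EF, independence across distinct
EFs); the whole accounting chain is then re-evaluated. With 5,000 draws
per EF (the default) the per-component sample mean, sd and coefficient of
variation are reported for every country, region and the world.

Lognormal specs are moment-matched on the natural scale (the draws'
mean and sd equal the spec's); normal specs sample N(mean, sd). Bounds
are enforced by rejection (redraw out-of-range values), never by
clamping, which would pile probability onto the bounds and bias means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import PRODUCTS
from .engine import EmissionsBreakdown, account, aggregate, aggregate_by_region
from .registry import EFSpec, Registry

log = logging.getLogger(__name__)

DEFAULT_DRAWS = 5000
_MAX_REJECTION_ROUNDS = 1000


class NumericalError(RuntimeError):
    """Raised when sampling cannot satisfy the requested constraints."""


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo summary for one scope x component."""

    scope_level: str  # country | region | global
    scope: str
    component: str  # one of the six components or "total"
    mean: float  # t CO2e
    sd: float  # t CO2e
    cv: float  # percent; NaN when mean == 0
    n_draws: int
    seed: int | None


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent, 100 x sd / mean; NaN (missing) when mean is 0."""
    if mean == 0:
        return float("nan")
    return 100.0 * sd / mean


def sample_ef(spec: EFSpec, n: int, seed=None) -> np.ndarray:
    """Draw *n* values from an EF's uncertainty distribution.

    ``seed`` may be an int or a ``numpy.random.Generator``. Draws falling
    outside [spec.min, spec.max] are rejected and redrawn. Deterministic
    given the seed. A lognormal spec with mean <= 0 is an error: use a
    shifted lognormal or override the pdf to normal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if spec.sd == 0:
        return np.full(n, spec.mean, dtype=float)

    if spec.pdf == "lognormal":
        if spec.mean <= 0:
            raise NumericalError(
                f"{spec.name}: lognormal sampling requires mean > 0 "
                f"(got {spec.mean}); configure a shifted lognormal or a "
                "normal pdf for this factor"
            )
        sigma2 = math.log1p((spec.sd / spec.mean) ** 2)
        mu = math.log(spec.mean) - sigma2 / 2.0
        draw = lambda size: rng.lognormal(mu, math.sqrt(sigma2), size)
    else:
        draw = lambda size: rng.normal(spec.mean, spec.sd, size)

    out = draw(n)
    if spec.min is None and spec.max is None:
        return out
    lo = -np.inf if spec.min is None else spec.min
    hi = np.inf if spec.max is None else spec.max
    bad = (out < lo) | (out > hi)
    rounds = 0
    while bad.any():
        rounds += 1
        if rounds > _MAX_REJECTION_ROUNDS:
            raise NumericalError(
                f"{spec.name}: rejection sampling failed to satisfy "
                f"[{spec.min}, {spec.max}] after {rounds} rounds"
            )
        out[bad] = draw(int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# EF enumeration and propagation

def collect_ef_specs(
    activity: pd.DataFrame,
    registry: Registry,
    scheme: str,
    sourcing: pd.DataFrame | None = None,
) -> dict[str, EFSpec]:
    """Every distinct EFSpec the accounting of this inventory touches."""
    specs: dict[str, EFSpec] = {}

    def add(spec: EFSpec) -> None:
        specs[spec.name] = spec

    for row in activity.to_dict("records"):
        region, climate = row["region"], row["climate"]
        for product in PRODUCTS:
            if float(row.get(f"share_{product}", 0) or 0) > 0:
                add(registry.manufacturing.get(region, product))
                add(registry.transport.get(region, region, product))
        add(registry.get_direct_ef(scheme, row["country"], climate))
        for which in ("fracgasf", "ef4", "fracleach", "ef5"):
            add(registry.indirect_factor(which, climate))
    if sourcing is not None:
        for srow in sourcing.itertuples():
            add(registry.transport.get(srow.origin_region, srow.region, srow.product))
    add(registry.urea)
    return specs


def sample_all(
    specs: Mapping[str, EFSpec], n: int, seed: int | None
) -> dict[str, np.ndarray]:
    """One draw vector per EF, in deterministic (sorted-name) order."""
    rng = np.random.default_rng(seed)
    return {name: sample_ef(specs[name], n, rng) for name in sorted(specs)}


def _summarise(b: EmissionsBreakdown, level: str, n: int, seed) -> list[MCResult]:
    rows = []
    comps = dict(b.components())
    comps["total"] = b.total
    for comp, vals in comps.items():
        vals = np.broadcast_to(np.asarray(vals, dtype=float), (n,))
        if vals.size and (vals == vals.flat[0]).all():
            # degenerate (all-sds-zero) case: summarise exactly, no
            # floating-point noise from the pairwise mean
            mean, sd = float(vals.flat[0]), 0.0
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            MCResult(level, b.scope, comp, mean, sd, coefficient_of_variation(mean, sd), n, seed)
        )
    return rows


def propagate(
    activity: pd.DataFrame,
    registry: Registry,
    scheme: str = "ipcc_tier1",
    n: int = DEFAULT_DRAWS,
    seed: int | None = None,
    sourcing: pd.DataFrame | None = None,
) -> list[MCResult]:
    """Push EF uncertainty through the accounting engine.

    Samples every EF once per iteration (shared across countries), then
    evaluates the deterministic chain with the draw vectors in place of
    the EF means. Returns per-country, per-region and global summaries
    for every component and the total. The per-draw total is the exact
    per-draw sum of components by construction.
    """
    if n < 1:
        raise ValueError("number of draws must be >= 1")
    specs = collect_ef_specs(activity, registry, scheme, sourcing)
    draws = sample_all(specs, n, seed)
    breakdowns = account(activity, registry, scheme, sourcing, ef_values=draws)

    country_region = dict(zip(activity["country"], activity["region"]))
    results: list[MCResult] = []
    for b in breakdowns:
        results.extend(_summarise(b, "country", n, seed))
    regional = aggregate_by_region(breakdowns, country_region)
    for b in regional.values():
        results.extend(_summarise(b, "region", n, seed))
    world = aggregate(breakdowns, "global")
    results.extend(_summarise(world, "global", n, seed))
    return results


def mc_to_frame(results: Sequence[MCResult]) -> pd.DataFrame:
    """Tidy summary table in Mt CO2e."""
    return pd.DataFrame(
        [
            {
                "scope_level": r.scope_level,
                "scope": r.scope,
                "component": r.component,
                "mean_mt": r.mean / 1e6,
                "sd_mt": r.sd / 1e6,
                "cv_pct": r.cv,
                "n_draws": r.n_draws,
                "seed": r.seed,
            }
            for r in results
        ]
    )
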