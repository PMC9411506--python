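"""World-region vocabulary used throughout the accounting.

Nine macro-regions partition all countries; every country code maps to
exactly one region. The vocabulary is fixed here but a custom grouping can
be supplied wherever a ``country_region`` mapping is accepted.
"""

from __future__ import annotations

REGIONS: tuple[str, ...] = (
    "East Asia",
    "South Asia",
    "Europe",
    "North America",
    "Latin America",
    "Africa",
    "Middle East",
    "Oceania",
    "Russian Commonwealth",
)


def check_region(region: str) -> str:
    """Return *region* unchanged, raising ``ValueError`` if unknown."""
    if region not in REGIONS:
        raise ValueError(
            f"unknown region {region!r}; expected one of {', '.join(REGIONS)}"
        )
    return region
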