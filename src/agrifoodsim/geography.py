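"""Model regions, commodity groups, and the region hierarchy.

The world is resolved at seven "leaf" model regions — the five African
sub-regions (Northern, Western, Eastern, Central, Southern Africa), an
other-developing aggregate, and a developed aggregate — plus reporting
aggregates (South of the Sahara, Africa, Developing, World) that are sums
of their children.  North-Africa-and-West-Asia appears only as a fixture
reporting label, not a model region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

# Leaf model regions
NAF = "NAF"  # Northern Africa
WAF = "WAF"  # Western Africa
EAF = "EAF"  # Eastern Africa
CAF = "CAF"  # Central Africa
SAF = "SAF"  # Southern Africa
ODV = "ODV"  # Other developing countries
DEV = "DEV"  # Developed countries

# Aggregates
SSA = "SSA"  # Africa South of the Sahara
AFR = "AFR"  # Africa
DVG = "DVG"  # All developing countries
WLD = "WLD"  # World

AFRICAN_SUBREGIONS = (NAF, WAF, EAF, CAF, SAF)
SSA_SUBREGIONS = (WAF, EAF, CAF, SAF)
LEAF_REGIONS = (NAF, WAF, EAF, CAF, SAF, ODV, DEV)
DEVELOPING_LEAVES = (NAF, WAF, EAF, CAF, SAF, ODV)
AGGREGATES = (SSA, AFR, DVG, WLD)

REGION_NAMES = {
    NAF: "Northern Africa",
    WAF: "Western Africa",
    EAF: "Eastern Africa",
    CAF: "Central Africa",
    SAF: "Southern Africa",
    ODV: "Other Developing Countries",
    DEV: "Developed Countries",
    SSA: "Africa South of the Sahara",
    AFR: "Africa",
    DVG: "Developing Countries",
    WLD: "World",
}

# parent of each region in the reporting forest (WLD is the root)
PARENTS = {
    NAF: AFR,
    WAF: SSA,
    EAF: SSA,
    CAF: SSA,
    SAF: SSA,
    SSA: AFR,
    AFR: DVG,
    ODV: DVG,
    DVG: WLD,
    DEV: WLD,
    WLD: None,
}

COMMODITY_GROUPS = (
    "cereals",
    "meats",
    "pulses",
    "roots_tubers",
    "oils",
    "sugar",
    "fruits_veg",
)

# dietary energy density, kcal per kg (stylized FAO food-balance magnitudes)
KCAL_PER_KG = {
    "cereals": 3400.0,
    "meats": 1900.0,
    "pulses": 3450.0,
    "roots_tubers": 1000.0,
    "oils": 8800.0,
    "sugar": 3870.0,
    "fruits_veg": 500.0,
}


@dataclass(frozen=True)
class Geography:
    """One node of the region hierarchy.

    ``food_va_share`` is the fraction of GDP generated by food production,
    used to downscale economy-wide income deviations.
    """

    region_id: str
    name: str
    parent: Optional[str] = None
    food_va_share: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.food_va_share < 0.8):
            raise ValueError(
                f"food_va_share for {self.region_id} must lie in (0, 0.8), "
                f"got {self.food_va_share}"
            )


@dataclass(frozen=True)
class Commodity:
    """A commodity group with its dietary energy density (kcal/kg)."""

    commodity_id: str
    group: str
    kcal_per_kg: float

    def __post_init__(self) -> None:
        if self.kcal_per_kg <= 0:
            raise ValueError(
                f"kcal_per_kg for {self.commodity_id} must be positive"
            )


def children(region_id: str, regions: dict[str, Geography]) -> list[str]:
    return [r for r, g in regions.items() if g.parent == region_id]


def leaves_under(region_id: str, regions: dict[str, Geography]) -> list[str]:
    """Leaf regions beneath (or equal to) ``region_id``, in insertion order."""
    kids = children(region_id, regions)
    if not kids:
        return [region_id]
    out: list[str] = []
    for k in kids:
        out.extend(leaves_under(k, regions))
    return out


def path_to_root(region_id: str, regions: dict[str, Geography]) -> list[str]:
    path = [region_id]
    seen = {region_id}
    while regions[path[-1]].parent is not None:
        nxt = regions[path[-1]].parent
        if nxt in seen:
            raise ValueError(f"cycle in region hierarchy at {nxt}")
        path.append(nxt)
        seen.add(nxt)
    return path


def validate_hierarchy(regions: dict[str, Geography]) -> list[str]:
    """Return a list of hierarchy violations (empty if the forest is valid)."""
    problems = []
    for rid, geo in regions.items():
        if geo.parent is not None and geo.parent not in regions:
            problems.append(f"region {rid} has unknown parent {geo.parent}")
            continue
        try:
            path_to_root(rid, regions)
        except ValueError as exc:
            problems.append(str(exc))
    return problems
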