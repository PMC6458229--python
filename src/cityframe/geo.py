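"""Multilevel geographic data model.

Units live at one of six levels:

``L1Admin``
    a "city" operationalized as a cluster of administrative sub-city units;
``L1Metro``
    an official, country-defined metropolitan area;
``L1UrbExt``
    the satellite-derived built-up urban extent;
``L1Excess``
    the urban extent including area spilling across a national border;
``L2``
    a sub-city administrative unit (municipio, comuna, ...);
``L3``
    a neighborhood proxy (census tract scale) nested within an L2.

The module validates the nesting hierarchy (L3 → L2 → L1Admin, with optional
alternate metro groupings), assigns sub-city units to cities by shared
built-up area, links neighborhoods to urban extents with binary or areal
weights, and aggregates indicators up the hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

LEVELS = ("L1Admin", "L1Metro", "L1UrbExt", "L1Excess", "L2", "L3")

#: parent-link level pairs accepted by :func:`build_hierarchy`
VALID_LINK_LEVELS = {
    ("L3", "L2"),
    ("L2", "L1Admin"),
    ("L2", "L1Metro"),
    ("L3", "L1Metro"),
}


class GeoModelError(ValueError):
    """Structural or input error in the geographic model."""


@dataclass
class GeoUnit:
    """An identified geographic unit at one level of the model.

    Parameters
    ----------
    unit_id:
        Opaque key, unique within a dataset.
    level:
        One of :data:`LEVELS`.
    country:
        ISO-3166 alpha-2 code.
    name:
        Free-text display name.
    geometry:
        Optional shapely (multi)polygon in the CRS named by ``crs``.
    population:
        Optional non-negative count.
    crs:
        Declared coordinate reference system of ``geometry``. All metric
        operations require a projected CRS shared by their inputs.
    """

    unit_id: str
    level: str
    country: str = ""
    name: str = ""
    geometry: BaseGeometry | None = None
    population: float | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise GeoModelError(f"unknown level {self.level!r} for unit {self.unit_id!r}")
        if self.population is not None and self.population < 0:
            raise GeoModelError(f"negative population for unit {self.unit_id!r}")
        if self.geometry is not None and not self.geometry.is_valid:
            raise GeoModelError(f"invalid geometry for unit {self.unit_id!r}")


@dataclass
class LinkWeight:
    """Share of an L3 unit attributable to an urban extent."""

    l3_id: str
    urbext_id: str
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise GeoModelError(
                f"link weight {self.weight} for {self.l3_id}->{self.urbext_id} outside [0, 1]"
            )


@dataclass
class Hierarchy:
    """Validated parent links between unit levels.

    ``parents`` maps child id → parent id per link kind; ``orphans`` lists
    units that have no parent link at their level (retained, not dropped).
    """

    units: dict[str, GeoUnit]
    parents: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)
    orphans: list[str] = field(default_factory=list)

    def parent_of(self, child_id: str, link: tuple[str, str] = ("L3", "L2")) -> str | None:
        return self.parents.get(link, {}).get(child_id)

    def children_of(self, parent_id: str, link: tuple[str, str]) -> list[str]:
        return sorted(c for c, p in self.parents.get(link, {}).items() if p == parent_id)

    def l2_members(self, l1_id: str) -> list[str]:
        """The L2 units composing an L1Admin."""
        return self.children_of(l1_id, ("L2", "L1Admin"))

    def to_edge_list(self) -> pd.DataFrame:
        """Serialize as a CSV-ready edge list (child_id, parent_id, level_child, level_parent)."""
        rows = [
            {"child_id": c, "parent_id": p, "level_child": lc, "level_parent": lp}
            for (lc, lp), links in sorted(self.parents.items())
            for c, p in sorted(links.items())
        ]
        return pd.DataFrame(rows, columns=["child_id", "parent_id", "level_child", "level_parent"])


def build_hierarchy(
    units: Iterable[GeoUnit],
    parent_links: Iterable[tuple[str, str]],
) -> Hierarchy:
    """Validate parent links and assemble a :class:`Hierarchy`.

    Each link is a ``(child_id, parent_id)`` pair whose levels must be one of
    :data:`VALID_LINK_LEVELS`. Every L3 may have at most one L2 parent and
    every L2 at most one L1Admin. Units without a parent are reported as
    orphans but kept.

    Raises
    ------
    GeoModelError
        If an id does not resolve, the levels of a link are not an accepted
        pair, or a child carries two different parents for the same link kind.
    """
    index = {u.unit_id: u for u in units}
    if len(index) == 0:
        raise GeoModelError("no units supplied")
    parents: dict[tuple[str, str], dict[str, str]] = {}
    for child_id, parent_id in parent_links:
        for uid in (child_id, parent_id):
            if uid not in index:
                raise GeoModelError(f"link references unknown unit {uid!r}")
        pair = (index[child_id].level, index[parent_id].level)
        if pair not in VALID_LINK_LEVELS:
            raise GeoModelError(
                f"link {child_id!r}->{parent_id!r} has level pair {pair}, "
                f"expected one of {sorted(VALID_LINK_LEVELS)}"
            )
        links = parents.setdefault(pair, {})
        if child_id in links and links[child_id] != parent_id:
            raise GeoModelError(
                f"duplicate parent for child {child_id!r}: "
                f"{links[child_id]!r} and {parent_id!r}"
            )
        links[child_id] = parent_id

    childful_levels = {"L3": ("L3", "L2"), "L2": ("L2", "L1Admin")}
    orphans = [
        uid
        for uid, u in sorted(index.items())
        if u.level in childful_levels and uid not in parents.get(childful_levels[u.level], {})
    ]
    if orphans:
        logger.info("hierarchy has %d orphan unit(s): %s", len(orphans), orphans[:10])
    return Hierarchy(units=index, parents=parents, orphans=orphans)


def assign_l2_to_l1(
    l2_units: Sequence[GeoUnit],
    candidate_l1s: Sequence[GeoUnit],
    builtup_overlap: pd.DataFrame,
) -> dict[str, str | None]:
    """Assign each L2 unit to the candidate city sharing the most built-up area.

    ``builtup_overlap`` has columns ``l2_id, l1_id, shared_area``. An L2 with
    zero overlap everywhere stays unassigned (``None``). Ties are broken by
    the lexicographically smallest L1 id and logged.
    """
    required = {"l2_id", "l1_id", "shared_area"}
    if not required.issubset(builtup_overlap.columns):
        raise GeoModelError(f"overlap table must have columns {sorted(required)}")
    if (builtup_overlap["shared_area"] < 0).any():
        bad = builtup_overlap.loc[builtup_overlap["shared_area"] < 0, "l2_id"].tolist()
        raise GeoModelError(f"negative shared built-up area for l2 unit(s) {bad}")

    assignment: dict[str, str | None] = {u.unit_id: None for u in l2_units}
    for l2_id, group in builtup_overlap.groupby("l2_id"):
        positive = group[group["shared_area"] > 0]
        if positive.empty:
            continue
        best = positive["shared_area"].max()
        winners = sorted(positive.loc[positive["shared_area"] == best, "l1_id"])
        if len(winners) > 1:
            logger.warning(
                "l2 %s ties on shared built-up area %g among %s; assigning %s",
                l2_id, best, winners, winners[0],
            )
        assignment[str(l2_id)] = winners[0]
    return assignment


def link_l3_to_urbext(
    l3_units: Sequence[GeoUnit],
    urbext: GeoUnit,
    mode: Literal["any_overlap", "area_weight"] = "any_overlap",
) -> list[LinkWeight]:
    """Link neighborhood units to an urban extent.

    ``any_overlap`` gives weight 1 to every L3 whose geometry intersects the
    extent; ``area_weight`` gives the fraction of the L3 area covered by the
    extent (areal interpolation). Disjoint units produce no link.
    """
    if urbext.geometry is None:
        raise GeoModelError(f"urban extent {urbext.unit_id!r} has no geometry")
    links: list[LinkWeight] = []
    for unit in l3_units:
        if unit.geometry is None:
            raise GeoModelError(f"l3 unit {unit.unit_id!r} has no geometry")
        if unit.crs != urbext.crs:
            raise GeoModelError(
                f"CRS mismatch: l3 unit {unit.unit_id!r} has {unit.crs!r}, "
                f"extent has {urbext.crs!r}"
            )
        if not unit.geometry.is_valid:
            raise GeoModelError(f"invalid geometry for unit {unit.unit_id!r}")
        if not unit.geometry.intersects(urbext.geometry):
            continue
        if mode == "any_overlap":
            w = 1.0
        elif mode == "area_weight":
            w = unit.geometry.intersection(urbext.geometry).area / unit.geometry.area
            w = min(max(w, 0.0), 1.0)
        else:
            raise GeoModelError(f"unknown link mode {mode!r}")
        if w > 0:
            links.append(LinkWeight(l3_id=unit.unit_id, urbext_id=urbext.unit_id, weight=w))
    return links


def aggregate_indicator(
    child_values: Mapping[str, float],
    links: Mapping[str, str] | Sequence[LinkWeight] | Hierarchy,
    method: Literal["sum", "weighted_sum", "weighted_mean"] = "sum",
    hierarchy_link: tuple[str, str] = ("L3", "L2"),
) -> dict[str, float]:
    """Aggregate child-level values to their parents.

    ``links`` may be a plain child→parent mapping, a sequence of
    :class:`LinkWeight` (weights used for the weighted methods), or a
    :class:`Hierarchy` (the ``hierarchy_link`` kind is used, weights all 1).
    ``sum``/``weighted_sum`` conserve totals when all weights are 1;
    ``weighted_mean`` normalizes weights within each parent.
    """
    if isinstance(links, Hierarchy):
        pairs = [(c, p, 1.0) for c, p in links.parents.get(hierarchy_link, {}).items()]
    elif isinstance(links, Mapping):
        pairs = [(c, p, 1.0) for c, p in links.items()]
    else:
        pairs = [(lw.l3_id, lw.urbext_id, lw.weight) for lw in links]
    linked = {c for c, _, _ in pairs}
    missing = sorted(set(child_values) - linked)
    if missing:
        raise GeoModelError(f"children with values but no link: {missing}")

    num: dict[str, float] = {}
    den: dict[str, float] = {}
    for child, parent, w in pairs:
        if child not in child_values:
            continue
        v = child_values[child]
        if method == "sum":
            num[parent] = num.get(parent, 0.0) + v
        elif method in ("weighted_sum", "weighted_mean"):
            num[parent] = num.get(parent, 0.0) + w * v
            den[parent] = den.get(parent, 0.0) + w
        else:
            raise GeoModelError(f"unknown aggregation method {method!r}")
    if method == "weighted_mean":
        return {p: num[p] / den[p] for p in num if den[p] > 0}
    return num


_KEY_SEP = "@"


def make_key(unit_id: str, year: int) -> str:
    """Compose a spatio-temporal key from a unit id and a calendar year.

    Stable and order-independent; round-trips through :func:`parse_key`.
    """
    year = int(year)
    if not 1850 <= year <= 2200:
        raise GeoModelError(f"implausible calendar year {year}")
    if _KEY_SEP in unit_id:
        raise GeoModelError(f"unit id {unit_id!r} contains reserved separator {_KEY_SEP!r}")
    return f"{unit_id}{_KEY_SEP}{year}"


def parse_key(key: str) -> tuple[str, int]:
    """Inverse of :func:`make_key`."""
    unit_id, _, year = key.rpartition(_KEY_SEP)
    if not unit_id:
        raise GeoModelError(f"malformed spatio-temporal key {key!r}")
    return unit_id, int(year)
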