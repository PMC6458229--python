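"""Two-source city-list reconciliation.

A universe of cities above a population threshold is built by combining an
extent-based list (cities delineated from built-up area, which may be whole
agglomerations) with a census-based list (administratively defined cities
with official population counts). Records are matched by normalized name,
administrative subdivision, and country; unmatched census cities whose
location falls inside an extent footprint are absorbed into that
agglomeration, the rest stand alone. Contiguous cities sharing built-up area
are merged, which can lift pairs of sub-threshold towns over the population
cutoff.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)


class ReconcileError(ValueError):
    pass


@dataclass
class CityRecord:
    """One city as reported by one source list."""

    source: str  # "extent_list" | "census_list"
    name: str
    admin_subdivision: str
    country: str
    population: float
    record_id: str = ""
    location: BaseGeometry | None = None  # point or polygon
    footprint: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if not self.country:
            raise ReconcileError(f"record {self.name!r} has empty country")
        if self.population < 0:
            raise ReconcileError(f"record {self.name!r} has negative population")
        if not self.record_id:
            self.record_id = f"{self.source}:{self.country}:{normalize_name(self.name)}"


@dataclass
class MatchResult:
    """Outcome of matching the census list against the extent list."""

    matched: list[tuple[CityRecord, CityRecord]] = field(default_factory=list)
    absorbed: dict[str, str] = field(default_factory=dict)  # census record_id -> extent record_id
    standalone: list[CityRecord] = field(default_factory=list)
    review: list[CityRecord] = field(default_factory=list)  # needs manual review
    notes: list[str] = field(default_factory=list)


_BRACKETED = re.compile(r"[\(\[\{][^\)\]\}]*[\)\]\}]")
_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Canonicalize a place name for matching.

    Casefolds, strips diacritics, removes bracketed qualifiers and
    punctuation, and collapses whitespace. Idempotent.
    """
    s = _BRACKETED.sub(" ", raw)
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.casefold()
    s = _PUNCT.sub(" ", s)
    return _WS.sub(" ", s).strip()


def _match_key(rec: CityRecord, with_admin: bool) -> tuple:
    key = (normalize_name(rec.name), rec.country)
    if with_admin:
        key = (normalize_name(rec.name), normalize_name(rec.admin_subdivision), rec.country)
    return key


def _check_duplicates(records: Sequence[CityRecord], label: str) -> None:
    seen: dict[tuple, str] = {}
    dups = []
    for rec in records:
        key = _match_key(rec, with_admin=True)
        if key in seen:
            dups.append((seen[key], rec.record_id))
        seen[key] = rec.record_id
    if dups:
        raise ReconcileError(f"duplicate (name, admin, country) in {label}: {dups}")


def match_lists(
    extent_list: Sequence[CityRecord],
    census_list: Sequence[CityRecord],
) -> MatchResult:
    """Match extent-based cities to census cities.

    Exact matches on (normalized name, normalized admin subdivision, country)
    are taken first; remaining records are matched on (name, country) when
    the candidate is unique. Census records left over are unmatched and go on
    to :func:`resolve_unmatched`. Deterministic given the inputs.
    """
    if not extent_list or not census_list:
        raise ReconcileError("both city lists must be non-empty")
    _check_duplicates(extent_list, "extent_list")
    _check_duplicates(census_list, "census_list")

    result = MatchResult()
    unmatched_census = list(census_list)
    unmatched_extent = list(extent_list)

    # pass 1: name + admin + country
    census_by_key = {_match_key(r, True): r for r in unmatched_census}
    for ext in list(unmatched_extent):
        key = _match_key(ext, True)
        if key in census_by_key:
            cen = census_by_key.pop(key)
            result.matched.append((ext, cen))
            unmatched_extent.remove(ext)
            unmatched_census.remove(cen)

    # pass 2: name + country, unique candidate only
    census_by_loose: dict[tuple, list[CityRecord]] = {}
    for r in unmatched_census:
        census_by_loose.setdefault(_match_key(r, False), []).append(r)
    for ext in list(unmatched_extent):
        candidates = census_by_loose.get(_match_key(ext, False), [])
        if len(candidates) == 1:
            cen = candidates[0]
            result.matched.append((ext, cen))
            unmatched_extent.remove(ext)
            unmatched_census.remove(cen)
            census_by_loose[_match_key(cen, False)] = []
        elif len(candidates) > 1:
            result.notes.append(
                f"extent city {ext.record_id} has {len(candidates)} loose candidates; left unmatched"
            )

    result.standalone = unmatched_census  # provisional until resolve_unmatched
    if unmatched_extent:
        result.notes.append(
            f"{len(unmatched_extent)} extent cities without census match: "
            f"{[r.record_id for r in unmatched_extent]}"
        )
    return result


def resolve_unmatched(
    match: MatchResult,
    extent_footprints: dict[str, BaseGeometry],
) -> MatchResult:
    """Label unmatched census cities as absorbed or standalone.

    A record whose location intersects an extent footprint (boundary
    included — closed-set rule) is absorbed into that agglomeration; records
    lacking a location are queued for manual review, never silently dropped.
    """
    still_standalone: list[CityRecord] = []
    for rec in match.standalone:
        if rec.location is None:
            match.review.append(rec)
            match.notes.append(f"census record {rec.record_id} has no location; flagged for review")
            continue
        host = None
        for ext_id, footprint in sorted(extent_footprints.items()):
            if footprint is not None and rec.location.intersects(footprint):
                host = ext_id
                break
        if host is not None:
            match.absorbed[rec.record_id] = host
        else:
            still_standalone.append(rec)
    match.standalone = still_standalone
    return match


@dataclass
class ConsolidatedCity:
    city_id: str
    name: str
    country: str
    population: float
    provenance: str  # "matched" | "standalone" | "merged"
    members: list[str] = field(default_factory=list)
    footprint: BaseGeometry | None = None


def consolidate(match: MatchResult, threshold: float = 100_000) -> list[ConsolidatedCity]:
    """Build the consolidated city list above a population threshold.

    Matched extent cities take their population from the census source;
    standalone census cities are added as-is. Absorbed records contribute
    provenance only. Inclusion uses ``population >= threshold``.
    """
    if threshold <= 0:
        raise ReconcileError("threshold must be positive")
    cities: list[ConsolidatedCity] = []
    for ext, cen in match.matched:
        cities.append(
            ConsolidatedCity(
                city_id=ext.record_id,
                name=ext.name,
                country=ext.country,
                population=cen.population,  # census population is the source of record
                provenance="matched",
                members=[ext.record_id, cen.record_id],
                footprint=ext.footprint,
            )
        )
    for rec in match.standalone:
        cities.append(
            ConsolidatedCity(
                city_id=rec.record_id,
                name=rec.name,
                country=rec.country,
                population=rec.population,
                provenance="standalone",
                members=[rec.record_id],
                footprint=rec.footprint or rec.location,
            )
        )
    return [c for c in cities if c.population >= threshold]


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def merge_contiguous(
    cities: Sequence[ConsolidatedCity],
    contiguity: Sequence[tuple[str, str]],
    candidates: Sequence[ConsolidatedCity] = (),
    threshold: float = 100_000,
) -> tuple[list[ConsolidatedCity], list[str]]:
    """Merge cities that share contiguous built-up area.

    ``contiguity`` pairs may reference consolidated cities or sub-threshold
    ``candidates``; connected components become single cities with summed
    population, entering the list if the merged total meets ``threshold``.
    Merged ids are the smallest member id plus a ``+merged`` suffix. Returns
    the merged list and a human-readable merge log.
    """
    pool = {c.city_id: c for c in list(cities) + list(candidates)}
    uf = _UnionFind(pool)
    for a, b in contiguity:
        if a not in pool or b not in pool:
            raise ReconcileError(f"contiguity pair ({a!r}, {b!r}) references unknown city")
        uf.union(a, b)

    components: dict[str, list[str]] = {}
    for cid in pool:
        components.setdefault(uf.find(cid), []).append(cid)

    merged: list[ConsolidatedCity] = []
    log: list[str] = []
    for root, members in sorted(components.items()):
        members = sorted(members)
        if len(members) == 1:
            city = pool[members[0]]
            if city.population >= threshold:
                merged.append(city)
            continue
        total = sum(pool[m].population for m in members)
        new_id = f"{members[0]}+merged"
        log.append(f"merged {members} -> {new_id} (population {total:.0f})")
        if total >= threshold:
            merged.append(
                ConsolidatedCity(
                    city_id=new_id,
                    name=" / ".join(pool[m].name for m in members),
                    country=pool[members[0]].country,
                    population=total,
                    provenance="merged",
                    members=members,
                )
            )
        else:
            log.append(f"component {members} below threshold ({total:.0f}); excluded")
    for line in log:
        logger.info(line)
    return merged, log
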