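"""Urban-extent delineation from binary built-up rasters.

A "city" can be delineated quantitatively from a satellite-derived raster
that classifies ~12 m pixels as built-up or not. Each built pixel is
classified as urban, suburban, or rural according to the share of built-up
pixels within a surrounding 1-km² window; non-built pixels sufficiently
surrounded by construction count as urbanized open space. Connected
components over urban + suburban + urbanized-open pixels form urban
clusters, nearby clusters are joined by a hierarchical agglomerative rule
(minimum edge-to-edge distance below a join threshold, closed
transitively), and the largest cluster intersecting an administrative city
is taken as that city's urban extent.

Where the extent spills past the administrative boundary, four cases are
distinguished: small excess (< 20% of the administrative area) is clipped
and ignored; larger within-country excess flags additional sub-city units
for inclusion; excess reaching into a neighboring administrative city is
left for case-by-case review; excess crossing a national border yields a
separate "excess" extent that keeps the cross-border area.

All distances and areas are computed in a projected CRS in meters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

# pixel class codes
OUTSIDE, RURAL, SUBURBAN, URBAN, URBANIZED_OPEN = 0, 1, 2, 3, 4
CLASS_NAMES = {
    OUTSIDE: "outside",
    RURAL: "rural",
    SUBURBAN: "suburban",
    URBAN: "urban",
    URBANIZED_OPEN: "urbanized_open",
}

#: default built-share thresholds (share of built pixels in the 1-km² window)
URBAN_MIN = 0.50
SUBURBAN_MIN = 0.25

DEFAULT_JOIN_DISTANCE = 500.0  # meters


class ExtentError(ValueError):
    pass


@dataclass
class BuiltUpRaster:
    """Binary built/not-built grid with planar georeferencing.

    ``origin`` is the (x, y) of the grid's top-left corner; rows increase
    southward. ``cell_size`` is in meters, so ``crs`` must name a projected
    CRS.
    """

    grid: np.ndarray  # bool, shape (nrows, ncols)
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.size == 0:
            raise ExtentError("empty raster")
        if self.cell_size <= 0:
            raise ExtentError(f"cell size must be positive, got {self.cell_size}")

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_box(self, row: int, col: int) -> BaseGeometry:
        x0, y0 = self.origin
        cs = self.cell_size
        return box(x0 + col * cs, y0 - (row + 1) * cs, x0 + (col + 1) * cs, y0 - row * cs)


@dataclass
class PixelClassRaster:
    classes: np.ndarray  # uint8 codes, same shape as source
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-metric"

    def urbanized_mask(self) -> np.ndarray:
        """Cells that enter urban clusters: urban, suburban, urbanized open."""
        return np.isin(self.classes, (URBAN, SUBURBAN, URBANIZED_OPEN))


@dataclass
class UrbanCluster:
    """One connected urban patch: member cells, area, and footprint polygon."""

    cluster_id: int
    cells: np.ndarray  # (n, 2) array of (row, col)
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    footprint: BaseGeometry | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area(self) -> float:
        return self.n_cells * self.cell_size**2

    def build_footprint(self) -> BaseGeometry:
        if self.footprint is None:
            x0, y0 = self.origin
            cs = self.cell_size
            boxes = [
                box(x0 + c * cs, y0 - (r + 1) * cs, x0 + (c + 1) * cs, y0 - r * cs)
                for r, c in self.cells
            ]
            self.footprint = unary_union(boxes)
        return self.footprint


def circular_window(window_area: float, cell_size: float) -> np.ndarray:
    """Boolean offset mask approximating a circle of the given area on the grid."""
    if window_area < cell_size**2:
        raise ExtentError(
            f"window area {window_area} m² smaller than one {cell_size} m cell"
        )
    radius = np.sqrt(window_area / np.pi)
    r_cells = int(np.floor(radius / cell_size))
    span = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    return (dx**2 + dy**2) * cell_size**2 <= radius**2


def built_share(
    raster: BuiltUpRaster,
    window_area: float = 1e6,
    window_shape: str = "circle",
) -> np.ndarray:
    """Share of built-up cells within the moving window around each cell.

    Raster edges use the truncated window normalized by the in-bounds cell
    count, so the share stays a genuine fraction everywhere.
    """
    if window_shape == "circle":
        mask = circular_window(window_area, raster.cell_size)
    elif window_shape == "square":
        side = max(1, int(round(np.sqrt(window_area) / raster.cell_size)))
        mask = np.ones((2 * (side // 2) + 1, 2 * (side // 2) + 1), dtype=bool)
    else:
        raise ExtentError(f"unknown window shape {window_shape!r}")
    weights = mask.astype(float)
    # both convolutions count whole cells, so rounding removes FFT round-off
    # and keeps threshold comparisons exact
    built = np.rint(signal.fftconvolve(raster.grid.astype(float), weights, mode="same"))
    in_bounds = np.rint(
        signal.fftconvolve(np.ones_like(raster.grid, dtype=float), weights, mode="same")
    )
    return built / in_bounds


def classify_pixels(
    raster: BuiltUpRaster,
    window_area: float = 1e6,
    urban_min: float = URBAN_MIN,
    suburban_min: float = SUBURBAN_MIN,
    window_shape: str = "circle",
) -> PixelClassRaster:
    """Classify pixels as urban / suburban / rural / urbanized open / outside.

    Built cells with built-share ≥ ``urban_min`` are urban, ≥ ``suburban_min``
    suburban, below that rural. Non-built cells are urbanized open space when
    their built-share reaches ``suburban_min`` or when they are holes fully
    enclosed by urban/suburban cells; the rest are outside.
    """
    if not 0 <= suburban_min < urban_min <= 1:
        raise ExtentError(
            f"need 0 <= suburban_min < urban_min <= 1, got {suburban_min}, {urban_min}"
        )
    share = built_share(raster, window_area, window_shape)
    built = raster.grid
    classes = np.full(built.shape, OUTSIDE, dtype=np.uint8)
    classes[built & (share >= urban_min)] = URBAN
    classes[built & (share >= suburban_min) & (share < urban_min)] = SUBURBAN
    classes[built & (share < suburban_min)] = RURAL

    core = (classes == URBAN) | (classes == SUBURBAN)
    open_share = ~built & (share >= suburban_min)
    holes = ndimage.binary_fill_holes(core) & ~core & ~built
    classes[open_share | holes] = URBANIZED_OPEN
    return PixelClassRaster(
        classes=classes, cell_size=raster.cell_size, origin=raster.origin, crs=raster.crs
    )


def _order_clusters(
    components: list[np.ndarray], cell_size: float, origin: tuple[float, float]
) -> list[UrbanCluster]:
    """Deterministic ids: descending area, then scanline position of the first cell."""
    def sort_key(cells: np.ndarray):
        first = min(map(tuple, cells))
        return (-len(cells), first)

    ordered = sorted(components, key=sort_key)
    return [
        UrbanCluster(cluster_id=i + 1, cells=cells, cell_size=cell_size, origin=origin)
        for i, cells in enumerate(ordered)
    ]


def build_clusters(classes: PixelClassRaster, connectivity: int = 8) -> list[UrbanCluster]:
    """Connected components over urban + suburban + urbanized-open cells."""
    if connectivity not in (4, 8):
        raise ExtentError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(classes.urbanized_mask(), structure=structure)
    components = [np.argwhere(labels == k) for k in range(1, n + 1)]
    return _order_clusters(components, classes.cell_size, classes.origin)


def agglomerate(
    clusters: list[UrbanCluster],
    join_distance: float = DEFAULT_JOIN_DISTANCE,
) -> list[UrbanCluster]:
    """Join clusters whose minimum edge-to-edge distance is within the threshold.

    Merging is the transitive closure of the proximity relation, so the
    result is independent of merge order; a zero threshold is the identity.
    """
    if join_distance < 0:
        raise ExtentError("join distance must be non-negative")
    if join_distance == 0 or len(clusters) < 2:
        return clusters
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    footprints = [c.build_footprint() for c in clusters]
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if footprints[i].distance(footprints[j]) <= join_distance:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        groups.setdefault(find(i), []).append(i)
    components = [
        np.vstack([clusters[i].cells for i in members]) for members in groups.values()
    ]
    merged = _order_clusters(components, clusters[0].cell_size, clusters[0].origin)
    return merged


def select_urbext(clusters: list[UrbanCluster], l1admin_geometry: BaseGeometry) -> UrbanCluster:
    """The largest cluster intersecting the administrative city boundary."""
    candidates = [c for c in clusters if c.build_footprint().intersects(l1admin_geometry)]
    if not candidates:
        raise ExtentError("no urban cluster intersects the administrative boundary")
    best_area = max(c.area for c in candidates)
    winners = sorted(
        (c for c in candidates if c.area == best_area), key=lambda c: c.cluster_id
    )
    if len(winners) > 1:
        logger.warning(
            "area tie among clusters %s; selecting id %d",
            [c.cluster_id for c in winners], winners[0].cluster_id,
        )
    return winners[0]


@dataclass
class SpilloverCase:
    """Classification of how an urban extent relates to its administrative city."""

    case: str  # extends_add_l2 | extends_ignore_lt20pct | spills_other_l1 | spills_other_country
    excess_area: float
    fraction_of_l1admin: float
    urbext_footprint: BaseGeometry  # the extent to use (clipped where applicable)
    excess_footprint: BaseGeometry | None = None  # full unclipped extent (border-crossing case)
    crossing_ids: list[str] = field(default_factory=list)


def classify_spillover(
    urbext_footprint: BaseGeometry,
    l1admin_geometry: BaseGeometry,
    other_l1admins: dict[str, BaseGeometry] | None = None,
    country_boundary: BaseGeometry | None = None,
    ignore_fraction: float = 0.20,
    area_tol: float = 1e-9,
) -> SpilloverCase:
    """Classify extent/boundary spillover into the four handled cases.

    Excess = extent area outside the administrative city. Excess crossing the
    national border produces a separate cross-border extent alongside the
    clipped one; excess reaching a neighboring administrative city is flagged
    for review without modification; small excess (< ``ignore_fraction`` of
    the administrative area) is clipped and ignored; anything larger flags
    additional sub-city units for inclusion.
    """
    for name, geom in (("extent", urbext_footprint), ("admin boundary", l1admin_geometry)):
        if geom is None or not geom.is_valid:
            raise ExtentError(f"invalid {name} geometry")
    excess = urbext_footprint.difference(l1admin_geometry)
    excess_area = excess.area
    fraction = excess_area / l1admin_geometry.area
    clipped = urbext_footprint.intersection(l1admin_geometry)

    if excess_area > area_tol and country_boundary is not None:
        outside_country = excess.difference(country_boundary)
        if outside_country.area > area_tol:
            return SpilloverCase(
                case="spills_other_country",
                excess_area=excess_area,
                fraction_of_l1admin=fraction,
                urbext_footprint=clipped,
                excess_footprint=urbext_footprint,
            )
    if excess_area > area_tol and other_l1admins:
        crossing = sorted(
            oid
            for oid, geom in other_l1admins.items()
            if excess.intersection(geom).area > area_tol
        )
        if crossing:
            return SpilloverCase(
                case="spills_other_l1",
                excess_area=excess_area,
                fraction_of_l1admin=fraction,
                urbext_footprint=urbext_footprint,
                crossing_ids=crossing,
            )
    if fraction < ignore_fraction:
        return SpilloverCase(
            case="extends_ignore_lt20pct",
            excess_area=excess_area,
            fraction_of_l1admin=fraction,
            urbext_footprint=clipped,
        )
    return SpilloverCase(
        case="extends_add_l2",
        excess_area=excess_area,
        fraction_of_l1admin=fraction,
        urbext_footprint=urbext_footprint,
    )
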