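"""Landscape fragmentation and inequality metrics.

Urban-form indicators computed from patch mosaics (connected regions of the
urban class within a landscape) and from unit-level population vectors:
patch counts and densities, effective mesh size, area-weighted shape index,
edge densities, area-weighted nearest-neighbor isolation, the aggregation
index, and the Gini coefficient. Definitions follow the standard landscape
ecology formulations (FRAGSTATS-style), with the raster shape index
normalized so a square patch scores exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry.base import BaseGeometry


class MetricsError(ValueError):
    pass


@dataclass
class Patch:
    """One connected region of the focal class."""

    area: float
    perimeter: float
    footprint: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.area <= 0 or self.perimeter <= 0:
            raise MetricsError("patch area and perimeter must be positive")


@dataclass
class PatchSet:
    """A landscape and its patches of the focal class.

    ``landscape_area`` is the total area of the reporting unit in the same
    units as patch areas (m² when built from a raster with metric cells).
    """

    landscape_area: float
    patches: list[Patch] = field(default_factory=list)
    cell_size: float | None = None

    def __post_init__(self) -> None:
        if self.landscape_area <= 0:
            raise MetricsError("landscape area must be positive")

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.patches], dtype=float)

    @property
    def perimeters(self) -> np.ndarray:
        return np.array([p.perimeter for p in self.patches], dtype=float)

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, cell_size: float, landscape_area: float | None = None
    ) -> "PatchSet":
        """Build patches from a labeled raster (0 = background).

        Patch perimeter counts every exposed cell edge — exterior and
        interior (hole) edges — converted to meters via the cell size.
        """
        labels = np.asarray(labels)
        if landscape_area is None:
            landscape_area = labels.size * cell_size**2
        patches = []
        for k in np.unique(labels):
            if k == 0:
                continue
            mask = labels == k
            n = int(mask.sum())
            # shared edges between like cells, counted once per pair
            horiz = int((mask[:, :-1] & mask[:, 1:]).sum())
            vert = int((mask[:-1, :] & mask[1:, :]).sum())
            perimeter = (4 * n - 2 * (horiz + vert)) * cell_size
            patches.append(Patch(area=n * cell_size**2, perimeter=perimeter))
        return cls(landscape_area=landscape_area, patches=patches, cell_size=cell_size)


def patch_stats(patches: PatchSet) -> dict[str, float]:
    """Patch count, density (per landscape area), mean area, and CV of area.

    CV uses the population standard deviation, so a single patch (or equal
    patches) gives 0. An empty patch set reports zeros.
    """
    areas = patches.areas
    n = len(areas)
    if n == 0:
        return {"n_patches": 0, "patch_density": 0.0, "mean_patch_area": 0.0, "cv_patch_area": 0.0}
    mean = areas.mean()
    cv = areas.std(ddof=0) / mean if mean > 0 else 0.0
    return {
        "n_patches": n,
        "patch_density": n / patches.landscape_area,
        "mean_patch_area": mean,
        "cv_patch_area": cv,
    }


def effective_mesh_size(patches: PatchSet) -> float:
    """Σ(patch area²) / landscape area — the expected area of the patch
    containing a randomly placed point (0 when there are no patches)."""
    return float((patches.areas**2).sum() / patches.landscape_area)


def shape_metrics(patches: PatchSet, fragstats_norm: bool = False) -> dict[str, float]:
    """Area-weighted mean shape index.

    Default normalization SIᵢ = 0.25·pᵢ/√aᵢ (a square patch scores 1). With
    ``fragstats_norm`` the denominator is the minimum possible raster
    perimeter for the patch's cell count instead.
    """
    areas, perims = patches.areas, patches.perimeters
    if len(areas) == 0:
        return {"awm_shape_index": 0.0}
    if fragstats_norm:
        if patches.cell_size is None:
            raise MetricsError("fragstats normalization needs a cell size")
        cs = patches.cell_size
        cells = np.round(areas / cs**2).astype(int)
        si = perims / np.array([_min_raster_perimeter(c) * cs for c in cells])
    else:
        si = 0.25 * perims / np.sqrt(areas)
    w = areas / areas.sum()
    return {"awm_shape_index": float((w * si).sum())}


def _min_raster_perimeter(n_cells: int) -> int:
    """Minimum edge count of a raster patch of n cells (most compact arrangement)."""
    side = math.isqrt(n_cells)
    if side * side == n_cells:
        return 4 * side
    if side * (side + 1) >= n_cells:
        return 4 * side + 2
    return 4 * side + 4


def edge_metrics(patches: PatchSet) -> dict[str, float]:
    """Edge density (total perimeter / landscape area) and its area-weighted
    variant (per-patch perimeter-to-area ratio weighted by area share)."""
    areas, perims = patches.areas, patches.perimeters
    if len(areas) == 0:
        return {"edge_density": 0.0, "awm_edge_density": 0.0}
    w = areas / areas.sum()
    return {
        "edge_density": float(perims.sum() / patches.landscape_area),
        "awm_edge_density": float((w * perims / areas).sum()),
    }


def isolation_metric(patches: PatchSet) -> dict[str, float | None]:
    """Area-weighted mean Euclidean nearest-neighbor (edge-to-edge) distance.

    Undefined (reported missing, not 0) with fewer than two patches.
    """
    n = len(patches.patches)
    if n < 2:
        return {"awm_enn": None}
    footprints = [p.footprint for p in patches.patches]
    if any(f is None for f in footprints):
        raise MetricsError("isolation metric needs patch footprints")
    enn = np.array(
        [
            min(footprints[i].distance(footprints[j]) for j in range(n) if j != i)
            for i in range(n)
        ]
    )
    areas = patches.areas
    w = areas / areas.sum()
    return {"awm_enn": float((w * enn).sum())}


def aggregation_index(cells: np.ndarray) -> float | None:
    """Aggregation index: 100 · g / g_max, g the count of like side-adjacencies.

    g_max comes from the largest-integer-square construction for the class
    cell count, so a maximally compact arrangement scores 100 and fully
    scattered cells score 0. A single cell is trivially fully aggregated
    (100); zero class cells → missing (None).
    """
    mask = np.asarray(cells, dtype=bool)
    a = int(mask.sum())
    if a == 0:
        return None
    g = int((mask[:, :-1] & mask[:, 1:]).sum() + (mask[:-1, :] & mask[1:, :]).sum())
    side = math.isqrt(a)
    m = a - side * side
    if m == 0:
        g_max = 2 * side * (side - 1)
    elif m <= side:
        g_max = 2 * side * (side - 1) + 2 * m - 1
    else:
        g_max = 2 * side * (side - 1) + 2 * m - 2
    if g_max == 0:
        return 100.0
    return 100.0 * g / g_max


def gini(values, areas=None) -> float | None:
    """Gini coefficient G = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ) of non-negative quantities.

    Computed via the equivalent sorted form, exact to floating precision;
    equal values give 0, {0, x} gives 0.5. All-zero input is undefined
    (None). Unweighted across units by default; passing ``areas`` switches
    to the density variant (values per unit area).
    """
    x = np.asarray(values, dtype=float)
    if areas is not None:
        a = np.asarray(areas, dtype=float)
        if (a <= 0).any():
            raise MetricsError("areas must be positive for the density variant")
        x = x / a
    if x.size == 0:
        raise MetricsError("gini needs at least one value")
    if (x < 0).any():
        raise MetricsError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        return None
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def metric_report(
    patches: PatchSet, class_grid: np.ndarray | None = None
) -> dict[str, float | None]:
    """All landscape metrics for one reporting unit as a flat dict."""
    report: dict[str, float | None] = {}
    report.update(patch_stats(patches))
    report["effective_mesh_size"] = effective_mesh_size(patches)
    report.update(shape_metrics(patches))
    report.update(edge_metrics(patches))
    has_footprints = patches.patches and all(p.footprint is not None for p in patches.patches)
    report.update(isolation_metric(patches) if has_footprints else {"awm_enn": None})
    if class_grid is not None:
        report["aggregation_index"] = aggregation_index(class_grid)
    return report
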