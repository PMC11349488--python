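"""Survey-site selection on a classified raster.

The workflow mirrors a stratified, remote-sensing-first field design:

1. polygonize the label raster into connected same-class patches and keep
   patches large enough to host a block of five plots (area strictly above
   ``min_patch_area``);
2. lay a regular grid over the raster (anchored at the raster origin) and
   draw a candidate circle at every intersection;
3. keep circles whose class labels are homogeneous — population variance of
   the integer labels of the pixels whose centers fall strictly inside the
   circle below a threshold;
4. give candidates a random priority within each (heap, class) group and
   allocate a total block quota across classes proportionally to each
   class's candidate count (largest-remainder rounding), taking sites in
   priority order within a class;
5. expand each selected center into a block: a central plot plus four
   satellites 50 m due N, S, E and W, each a circle of 3 m radius
   (28.27 m^2, i.e. 28.3 m^2 at one decimal).

"Variance of class number" is computed literally on the integer labels, so
the statistic depends on label ordering; a label-agnostic alternative
(1 - majority proportion) is available via ``statistic="impurity"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, mapping

from .rasters import ClassifiedRaster


@dataclass
class SelectionConfig:
    min_patch_area: float = 14_400.0   # m^2, strict lower bound
    grid_spacing: float = 120.0        # m
    circle_radius: float = 60.0        # m
    homogeneity_var_max: float = 0.2
    block_offset: float = 50.0         # m
    plots_per_block: int = 5
    plot_radius: float = 3.0           # m
    seed: int = 0
    connectivity: int = 4              # 4 (rook) or 8 (queen)
    statistic: str = "variance"        # or "impurity"

    def __post_init__(self) -> None:
        for name in ("min_patch_area", "grid_spacing", "circle_radius",
                     "block_offset", "plot_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.homogeneity_var_max < 0:
            raise ValueError("homogeneity_var_max must be >= 0")


@dataclass
class Patch:
    patch_id: int
    label: int
    pixel_count: int
    area: float  # m^2


@dataclass
class CandidateSite:
    x: float
    y: float
    heap: str
    majority_label: int
    variance: float
    n_pixels: int
    passes_homogeneity: bool
    priority: int | None = None


@dataclass
class PlotBlock:
    center: tuple[float, float]
    plot_centers: list[tuple[float, float]] = field(default_factory=list)
    plot_names: list[str] = field(default_factory=list)
    plot_radius: float = 3.0

    @property
    def plot_area(self) -> float:
        """Single-plot area in m^2, reported to 0.01."""
        return round(math.pi * self.plot_radius ** 2, 2)

    def polygons(self):
        return [Point(x, y).buffer(self.plot_radius, quad_segs=64)
                for x, y in self.plot_centers]


def polygonize(classes: ClassifiedRaster, connectivity: int = 4) -> tuple[list[Patch], np.ndarray]:
    """Connected components of same-label pixels.

    Returns the patch list and a patch-id grid (0 = nodata). Default rook
    (4-)connectivity; ``connectivity=8`` uses queen moves.
    """
    labels = classes.labels
    if not classes.valid.any():
        raise ValueError("raster has no valid pixels")
    if connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    elif connectivity == 8:
        structure = ndimage.generate_binary_structure(2, 2)
    else:
        raise ValueError("connectivity must be 4 or 8")
    px = classes.georef.pixel_size
    patch_grid = np.zeros_like(labels, dtype=int)
    patches: list[Patch] = []
    next_id = 1
    for lab in np.unique(labels[classes.valid]):
        comp, n = ndimage.label(labels == lab, structure=structure)
        for i in range(1, n + 1):
            sel = comp == i
            count = int(sel.sum())
            patch_grid[sel] = next_id
            patches.append(Patch(next_id, int(lab), count, count * px * px))
            next_id += 1
    return patches, patch_grid


def filter_patches(patches: list[Patch], min_area: float) -> list[Patch]:
    """Keep patches with area strictly greater than ``min_area`` m^2."""
    return [p for p in patches if p.area > min_area]


def grid_circle_candidates(
    classes: ClassifiedRaster, config: SelectionConfig
) -> list[tuple[float, float]]:
    """Circle centers at regular grid intersections anchored at the origin.

    Intersections at multiples of ``grid_spacing`` from the raster's
    top-left corner, inclusive of both edges; centers whose circle contains
    no valid pixel center are dropped.
    """
    g = classes.georef
    h, w = classes.labels.shape
    width_m, height_m = w * g.pixel_size, h * g.pixel_size
    nx = int(math.floor(width_m / config.grid_spacing + 1e-9)) + 1
    ny = int(math.floor(height_m / config.grid_spacing + 1e-9)) + 1
    centers = []
    for iy in range(ny):
        for ix in range(nx):
            cx = g.x_origin + ix * config.grid_spacing
            cy = g.y_origin - iy * config.grid_spacing
            if _pixels_in_circle(classes, cx, cy, config.circle_radius).size:
                centers.append((cx, cy))
    return centers


def _pixels_in_circle(
    classes: ClassifiedRaster, cx: float, cy: float, radius: float
) -> np.ndarray:
    """Labels of valid pixels whose centers lie strictly inside the circle."""
    g = classes.georef
    h, w = classes.labels.shape
    col0 = max(int((cx - radius - g.x_origin) / g.pixel_size) - 1, 0)
    col1 = min(int((cx + radius - g.x_origin) / g.pixel_size) + 2, w)
    row0 = max(int((g.y_origin - cy - radius) / g.pixel_size) - 1, 0)
    row1 = min(int((g.y_origin - cy + radius) / g.pixel_size) + 2, h)
    if col0 >= col1 or row0 >= row1:
        return np.array([], dtype=int)
    xs = g.x_origin + (np.arange(col0, col1) + 0.5) * g.pixel_size
    ys = g.y_origin - (np.arange(row0, row1) + 0.5) * g.pixel_size
    xx, yy = np.meshgrid(xs, ys)
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 < radius ** 2
    sub = classes.labels[row0:row1, col0:col1]
    return sub[inside & (sub > 0)]


def homogeneity(
    classes: ClassifiedRaster,
    center: tuple[float, float],
    config: SelectionConfig,
) -> tuple[float, int, int]:
    """(variance, majority label, n pixels) for one candidate circle.

    Variance is the population variance of the integer class labels (or the
    impurity 1 - majority proportion when configured); majority ties break
    to the lower label.
    """
    labs = _pixels_in_circle(classes, center[0], center[1], config.circle_radius)
    if labs.size == 0:
        raise ValueError("no valid pixels inside circle")
    counts = np.bincount(labs)
    majority = int(counts.argmax())          # argmax returns the lowest tied label
    if config.statistic == "impurity":
        stat = 1.0 - counts.max() / labs.size
    else:
        stat = float(np.var(labs))
    return stat, majority, int(labs.size)


def evaluate_candidates(
    classes: ClassifiedRaster,
    config: SelectionConfig,
    heap: str = "h1",
    patch_grid: np.ndarray | None = None,
) -> list[CandidateSite]:
    """Score every grid-circle candidate on one heap's raster.

    If ``patch_grid`` is given (from :func:`polygonize` after filtering),
    candidates whose center pixel lies outside a retained patch are dropped.
    """
    sites = []
    for cx, cy in grid_circle_candidates(classes, config):
        if patch_grid is not None:
            g = classes.georef
            col = int((cx - g.x_origin) / g.pixel_size)
            row = int((g.y_origin - cy) / g.pixel_size)
            if not (0 <= row < patch_grid.shape[0] and 0 <= col < patch_grid.shape[1]
                    and patch_grid[row, col] > 0):
                continue
        var, majority, n = homogeneity(classes, (cx, cy), config)
        sites.append(CandidateSite(
            x=cx, y=cy, heap=heap, majority_label=majority, variance=var,
            n_pixels=n, passes_homogeneity=var < config.homogeneity_var_max,
        ))
    return sites


def assign_priorities(sites: list[CandidateSite], seed: int = 0) -> list[CandidateSite]:
    """Random priority permutation 1..n within each (heap, class) group."""
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, int], list[CandidateSite]] = {}
    for s in sites:
        groups.setdefault((s.heap, s.majority_label), []).append(s)
    for key in sorted(groups):
        members = groups[key]
        perm = rng.permutation(len(members)) + 1
        for s, p in zip(members, perm):
            s.priority = int(p)
    return sites


def layout_block(center: tuple[float, float], config: SelectionConfig) -> PlotBlock:
    """Central plot plus four satellites at ``block_offset`` due N, S, E, W."""
    cx, cy = center
    d = config.block_offset
    centers = [(cx, cy), (cx, cy + d), (cx, cy - d), (cx + d, cy), (cx - d, cy)]
    return PlotBlock(
        center=center, plot_centers=centers,
        plot_names=["C", "N", "S", "E", "W"], plot_radius=config.plot_radius,
    )


def allocate_sites(
    candidates: list[CandidateSite], total_blocks: int
) -> dict[int, list[CandidateSite]]:
    """Allocate a block quota across classes, proportional to candidate counts.

    Only candidates passing the homogeneity filter count. Quotas use
    largest-remainder rounding (ties -> lower class label); within a class,
    sites are taken in priority order. A quota exceeding the available
    candidates is truncated.
    """
    passing = [s for s in candidates if s.passes_homogeneity]
    by_class: dict[int, list[CandidateSite]] = {}
    for s in passing:
        by_class.setdefault(s.majority_label, []).append(s)
    if not by_class:
        return {}
    labels = sorted(by_class)
    counts = np.array([len(by_class[c]) for c in labels], dtype=float)
    exact = total_blocks * counts / counts.sum()
    quota = np.floor(exact).astype(int)
    remainder = exact - quota
    short = total_blocks - quota.sum()
    # ties on fractional part go to the lower class label (stable sort)
    order = np.argsort(-remainder, kind="stable")
    for i in order[:short]:
        quota[i] += 1
    selected: dict[int, list[CandidateSite]] = {}
    for c, q in zip(labels, quota):
        pool = sorted(by_class[c], key=lambda s: (s.priority if s.priority else 0))
        selected[c] = pool[: min(int(q), len(pool))]
    return selected


def sites_to_geojson(sites: list[CandidateSite], blocks: list[PlotBlock] | None = None) -> dict:
    """Candidates (and optionally plot polygons) as a GeoJSON FeatureCollection."""
    features = []
    for s in sites:
        features.append({
            "type": "Feature",
            "geometry": mapping(Point(s.x, s.y)),
            "properties": {
                "heap": s.heap, "class": s.majority_label, "variance": s.variance,
                "n_pixels": s.n_pixels, "passes": s.passes_homogeneity,
                "priority": s.priority,
            },
        })
    for blk in blocks or []:
        for name, poly in zip(blk.plot_names, blk.polygons()):
            features.append({
                "type": "Feature",
                "geometry": mapping(poly),
                "properties": {"plot": name, "area_m2": blk.plot_area},
            })
    return {"type": "FeatureCollection", "features": features}
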