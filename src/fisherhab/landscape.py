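"""Environmental covariates: focal statistics, terrain metrics, patch layer.

Derives everything the selection models consume from the raw raster stack:

* multi-scale circular neighborhood means (canopy, vegetation-class
  proportions) at the 100 / 400 / 4000 m scales used for 10-min, hourly and
  daily movement distances;
* terrain: slope, linearized aspect (heat-load fold at 30 degrees) and the
  topographic position index (cell elevation minus neighborhood mean,
  negative in drainages, positive on ridges);
* the forest-opening patch layer: canopy binned at quartile thresholds
  (<=25 / 26-50 / 51-75 / >75 %), two passes of a 3x3 focal-mode majority
  filter, connected-component patches with a strict 0.4-ha minimum mapping
  unit, and the derived patch covariates (category, size, distance to edge,
  edge density in km/km^2).

Neighborhoods are discs of cells whose centers lie within the radius of the
focal cell's center.  Windowed results agree with per-cell brute-force
computation to floating-point accuracy (FFT convolution).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

CANOPY_BINS = (25.0, 50.0, 75.0)  # quartile class boundaries, strict upper edges
CATEGORY_CODES = {1: "sparse", 2: "open", 3: "moderate", 4: "dense"}
CATEGORY_LABELS = {v: k for k, v in CATEGORY_CODES.items()}


# ---------------------------------------------------------------------------
# focal statistics
# ---------------------------------------------------------------------------

def disc_offsets(radius: float, resolution: float) -> np.ndarray:
    """Boolean disc kernel: cell centers within ``radius`` of the focal center."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r_cells = int(np.floor(radius / resolution + 1e-9))
    di = np.arange(-r_cells, r_cells + 1)
    dd = di[:, None] ** 2 + di[None, :] ** 2
    return (dd * resolution ** 2) <= radius ** 2 + 1e-6


def _disc_sum_count(arr: np.ndarray, kernel: np.ndarray):
    """Windowed sum and in-bounds valid count (NaN-aware), via FFT convolution."""
    a = np.asarray(arr, dtype=float)
    valid = np.isfinite(a)
    a0 = np.where(valid, a, 0.0)
    k = kernel.astype(float)
    s = fftconvolve(a0, k, mode="same")
    n = np.rint(fftconvolve(valid.astype(float), k, mode="same"))
    return s, n


def neighborhood_mean(raster: np.ndarray, radius: float,
                      resolution: float) -> np.ndarray:
    """Mean over cells whose centers lie within ``radius``; NaN cells ignored.

    A radius smaller than the cell size returns each cell's own value; a
    window with no valid cells yields NaN.
    """
    kernel = disc_offsets(radius, resolution)
    s, n = _disc_sum_count(raster, kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / n
    out[n == 0] = np.nan
    return out


def tpi(elevation: np.ndarray, radius: float, resolution: float) -> np.ndarray:
    """Topographic position index: elevation minus disc-mean (center excluded)."""
    if radius < resolution:
        raise ValueError("tpi radius must be >= resolution")
    kernel = disc_offsets(radius, resolution)
    s, n = _disc_sum_count(elevation, kernel)
    elev = np.asarray(elevation, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ring_mean = (s - elev) / (n - 1)
    ring_mean[n <= 1] = np.nan
    return elev - ring_mean


def slope_linear_aspect(elevation: np.ndarray, resolution: float,
                        fold_deg: float = 30.0):
    """Slope (degrees) and linearized aspect from 3x3 finite differences.

    Horn's weighted differences (edge-replicated borders).  Aspect is the
    compass bearing of steepest descent, folded onto [0, 1] by the heat-load
    transform (1 - cos(aspect - fold)) / 2, so ``fold_deg`` (default 30, i.e.
    NNE) maps to 0 and its opposite to 1; flat cells get 0.5.
    """
    e = np.pad(np.asarray(elevation, dtype=float), 1, mode="edge")
    a, b, c = e[2:, :-2], e[2:, 1:-1], e[2:, 2:]       # northern row (high y)
    d, _, f = e[1:-1, :-2], e[1:-1, 1:-1], e[1:-1, 2:]
    g, h, i = e[:-2, :-2], e[:-2, 1:-1], e[:-2, 2:]    # southern row
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * resolution)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * resolution)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0  # bearing of descent
    idx = (1.0 - np.cos(np.radians(aspect - fold_deg))) / 2.0
    idx = np.where((dzdx == 0) & (dzdy == 0), 0.5, idx)
    return slope, idx


# ---------------------------------------------------------------------------
# canopy categories and focal mode
# ---------------------------------------------------------------------------

def categorize_canopy(canopy: np.ndarray) -> np.ndarray:
    """Bin percent canopy at the quartile thresholds into codes 1..4.

    <=25 sparse(1); >25-<=50 open(2); >50-<=75 moderate(3); >75 dense(4).
    """
    c = np.asarray(canopy, dtype=float)
    if np.nanmin(c) < 0 or np.nanmax(c) > 100:
        raise ValueError("canopy values must lie in [0, 100]")
    out = np.digitize(c, CANOPY_BINS, right=True) + 1
    return out.astype(np.int8)


def focal_mode(categorical: np.ndarray, window: int = 3, passes: int = 2) -> np.ndarray:
    """Majority (modal) filter over a square window, applied ``passes`` times.

    Border windows are clipped to the raster.  When the modal class is tied
    the center cell keeps its value.  Two passes of the 3x3 filter remove
    isolated cells and small clusters while leaving uniform regions unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    cat = np.asarray(categorical)
    classes = np.unique(cat)
    half = window // 2
    out = cat.copy()
    for _ in range(passes):
        counts = np.zeros((len(classes),) + out.shape, dtype=np.int32)
        for k, cl in enumerate(classes):
            ind = (out == cl).astype(np.int32)
            padded = np.pad(ind, half, mode="constant")
            # windowed sum by cumulative shifts (exact integer arithmetic)
            acc = np.zeros_like(ind)
            for di in range(window):
                for dj in range(window):
                    acc = acc + padded[di:di + ind.shape[0], dj:dj + ind.shape[1]]
            counts[k] = acc
        best = counts.max(axis=0)
        n_best = (counts == best).sum(axis=0)
        winner = classes[np.argmax(counts, axis=0)]
        out = np.where(n_best > 1, out, winner).astype(cat.dtype)
    return out


# ---------------------------------------------------------------------------
# patch delineation
# ---------------------------------------------------------------------------

@dataclass
class PatchSet:
    """Labeled patch raster with per-patch attributes and boundary geometry.

    ``labels`` assigns every cell to exactly one patch id (1..n); ``table``
    holds per-patch category (sparse/open/moderate/dense), area (ha) and
    perimeter (m).  Boundary lines are the shared edges between cells of
    different patches; edges on the analysis-extent border are excluded from
    the line set (map edges are artifacts, not stand edges) though they do
    count toward patch perimeter.
    """

    labels: np.ndarray
    category: np.ndarray  # per-cell category code 1..4
    table: pd.DataFrame
    resolution: float
    x0: float = 0.0
    y0: float = 0.0
    _segments: np.ndarray | None = field(default=None, repr=False)
    _cell_edge_len: np.ndarray | None = field(default=None, repr=False)

    @property
    def cell_boundary_length(self) -> np.ndarray:
        """Per-cell boundary length (m): half of each internal unlike edge."""
        if self._cell_edge_len is None:
            lab = self.labels
            diff = np.zeros(lab.shape, dtype=float)
            diff[1:, :] += lab[1:, :] != lab[:-1, :]
            diff[:-1, :] += lab[:-1, :] != lab[1:, :]
            diff[:, 1:] += lab[:, 1:] != lab[:, :-1]
            diff[:, :-1] += lab[:, :-1] != lab[:, 1:]
            object.__setattr__(self, "_cell_edge_len", 0.5 * self.resolution * diff)
        return self._cell_edge_len

    @property
    def boundary_segments(self) -> np.ndarray:
        """(n, 4) array of internal boundary segments (x0, y0, x1, y1)."""
        if self._segments is None:
            res, lab = self.resolution, self.labels
            segs = []
            vdiff = lab[1:, :] != lab[:-1, :]   # horizontal edges between rows i-1, i
            for i, j in zip(*np.nonzero(vdiff)):
                y = self.y0 + (i + 1) * res
                x = self.x0 + j * res
                segs.append((x, y, x + res, y))
            hdiff = lab[:, 1:] != lab[:, :-1]   # vertical edges between cols j, j+1
            for i, j in zip(*np.nonzero(hdiff)):
                x = self.x0 + (j + 1) * res
                y = self.y0 + i * res
                segs.append((x, y, x, y + res))
            object.__setattr__(self, "_segments",
                               np.asarray(segs, dtype=float).reshape(-1, 4))
        return self._segments


def _label_by_category(category: np.ndarray) -> np.ndarray:
    """Connected components (4-connectivity) within each category."""
    labels = np.zeros(category.shape, dtype=np.int32)
    nxt = 0
    for cl in np.unique(category):
        lab = cc_label(category == cl, connectivity=1)
        m = lab > 0
        labels[m] = lab[m] + nxt
        nxt = labels.max()
    return labels


def _patch_stats(labels, category, resolution):
    ids, counts = np.unique(labels, return_counts=True)
    cell_ha = resolution ** 2 / 1e4
    cat = np.zeros(ids.max() + 1, dtype=np.int8)
    # category is constant within a patch
    flat_lab, flat_cat = labels.ravel(), category.ravel()
    cat[flat_lab] = flat_cat
    return ids, counts * cell_ha, cat


def delineate_patches(categorical: np.ndarray, resolution: float,
                      min_area_ha: float = 0.4,
                      x0: float = 0.0, y0: float = 0.0) -> PatchSet:
    """Connected-component patches with a strict minimum mapping unit.

    Components (4-connectivity, per category) strictly smaller than
    ``min_area_ha`` are merged into the adjacent patch sharing the longest
    boundary (ties broken toward the lower category code), so that every cell
    keeps a patch category.  Merging repeats until all patches reach the
    minimum area or a single patch remains.
    """
    cat = np.asarray(categorical).copy()
    if cat.size == 0:
        raise ValueError("empty raster")
    min_cells = int(np.ceil(min_area_ha * 1e4 / resolution ** 2 - 1e-9))

    for _pass in range(200):
        labels = _label_by_category(cat)
        ids, counts = np.unique(labels, return_counts=True)
        small = ids[counts < min_cells]
        if small.size == 0 or ids.size == 1:
            break
        sizes = dict(zip(ids, counts))
        # merge smallest first so tiny slivers don't dictate their neighbors
        for p in sorted(small, key=lambda q: sizes[q]):
            mask = labels == p
            if not mask.any():  # already overwritten this pass
                continue
            neigh: dict[int, int] = {}
            for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                shifted = np.roll(labels, shift, axis=(0, 1))
                edge = mask.copy()
                # roll wraps; mask out wrapped borders
                if shift[0] == 1:
                    edge[0, :] = False
                elif shift[0] == -1:
                    edge[-1, :] = False
                elif shift[1] == 1:
                    edge[:, 0] = False
                else:
                    edge[:, -1] = False
                for q in np.unique(shifted[edge]):
                    if q != p:
                        neigh[q] = neigh.get(q, 0) + int((shifted[edge] == q).sum())
            if not neigh:
                continue  # patch spans the whole raster
            qcat = {q: int(cat[labels == q].flat[0]) for q in neigh}
            target = min(neigh, key=lambda q: (-neigh[q], qcat[q]))
            cat[mask] = qcat[target]
            labels[mask] = target
    labels = _label_by_category(cat)
    ids, areas, catmap = _patch_stats(labels, cat, resolution)

    # perimeter: exposed 4-neighbor edges incl. the extent border
    padded = np.pad(labels, 1, mode="constant", constant_values=-1)
    exposed = np.zeros(labels.shape, dtype=np.int32)
    exposed += padded[:-2, 1:-1] != labels
    exposed += padded[2:, 1:-1] != labels
    exposed += padded[1:-1, :-2] != labels
    exposed += padded[1:-1, 2:] != labels
    perim = np.zeros(ids.max() + 1)
    np.add.at(perim, labels.ravel(), exposed.ravel() * resolution)

    table = pd.DataFrame({
        "patch_id": ids,
        "category": [CATEGORY_CODES[int(catmap[i])] for i in ids],
        "area_ha": areas,
        "perimeter_m": perim[ids],
    })
    logger.info("delineated %d patches (min area %.2f ha)", len(ids), min_area_ha)
    return PatchSet(labels=labels, category=cat, table=table,
                    resolution=resolution, x0=x0, y0=y0)


# ---------------------------------------------------------------------------
# patch covariates
# ---------------------------------------------------------------------------

def edge_density(patches: PatchSet, radius: float) -> np.ndarray:
    """Boundary length per unit area (km/km^2) in a circular window.

    The numerator is the total internal patch-boundary length whose owning
    cells fall in the disc (half of each shared edge per side); the
    denominator is the full disc area pi*r^2.  Extent-border edges never
    count.
    """
    if radius < patches.resolution:
        raise ValueError("edge-density radius must be >= resolution")
    kernel = disc_offsets(radius, patches.resolution)
    s, _ = _disc_sum_count(patches.cell_boundary_length, kernel)
    area_m2 = np.pi * radius ** 2
    return s / area_m2 * 1000.0  # m/m^2 -> km/km^2


def _point_segment_distance(px, py, segs):
    x0, y0, x1, y1 = segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3]
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    t = np.clip(((px - x0) * dx + (py - y0) * dy) / np.where(L2 > 0, L2, 1.0), 0, 1)
    qx, qy = x0 + t * dx, y0 + t * dy
    return np.hypot(px - qx, py - qy)


def distance_to_edge(patches: PatchSet, points) -> np.ndarray:
    """Euclidean distance (m) from points to the nearest patch boundary line.

    Points on a boundary get 0.  Raises if a point lies outside the extent.
    If the patch set has no internal boundaries the distance is NaN.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    nr, nc = patches.labels.shape
    res = patches.resolution
    x1, y1 = patches.x0 + nc * res, patches.y0 + nr * res
    if ((pts[:, 0] < patches.x0) | (pts[:, 0] >= x1) |
            (pts[:, 1] < patches.y0) | (pts[:, 1] >= y1)).any():
        raise ValueError("point outside patch-raster extent")
    segs = patches.boundary_segments
    if len(segs) == 0:
        return np.full(len(pts), np.nan)
    import shapely
    lines = shapely.linestrings(segs.reshape(-1, 2, 2))
    tree = shapely.STRtree(lines)
    pt_geoms = shapely.points(pts)
    idx = tree.nearest(pt_geoms)
    return shapely.distance(pt_geoms, lines[idx])


# ---------------------------------------------------------------------------
# covariate extraction
# ---------------------------------------------------------------------------

class CovariateEngine:
    """Precomputes covariate rasters for a landscape and serves point queries.

    Columns produced per point: ``canopy_{r}`` and ``prop_veg{c}_{r}`` for
    each scale r, ``elevation``, ``slope``, ``linear_aspect``, ``tpi_{r}``,
    ``patch_category``, ``patch_size_ha``, ``dist_to_edge`` and
    ``edge_density_{r}``.
    """

    def __init__(self, stack, scales=(100.0, 400.0, 4000.0),
                 patches: PatchSet | None = None, smooth_passes: int = 2):
        self.stack = stack
        self.scales = tuple(scales)
        res = stack.resolution
        if patches is None:
            smoothed = focal_mode(categorize_canopy(stack.canopy), passes=smooth_passes)
            patches = delineate_patches(smoothed, res, x0=stack.x0, y0=stack.y0)
        self.patches = patches
        self.rasters: dict[str, np.ndarray] = {}
        self.rasters["elevation"] = np.asarray(stack.elevation, dtype=float)
        slope, aspect_idx = slope_linear_aspect(stack.elevation, res)
        self.rasters["slope"] = slope
        self.rasters["linear_aspect"] = aspect_idx
        for r in self.scales:
            tag = _scale_tag(r)
            self.rasters[f"canopy_{tag}"] = neighborhood_mean(stack.canopy, r, res)
            self.rasters[f"tpi_{tag}"] = tpi(stack.elevation, r, res)
            self.rasters[f"edge_density_{tag}"] = edge_density(patches, r)
            for code in stack.veg_codes:
                ind = (stack.vegclass == code).astype(float)
                self.rasters[f"prop_veg{code}_{tag}"] = neighborhood_mean(ind, r, res)
        area = dict(zip(self.patches.table["patch_id"], self.patches.table["area_ha"]))
        self._patch_area = np.zeros(int(self.patches.labels.max()) + 1)
        for pid, a in area.items():
            self._patch_area[pid] = a

    def extract(self, points, disturbed_mask: np.ndarray | None = None) -> pd.DataFrame:
        """One covariate row per point; points outside the extent give NaN rows."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        stack = self.stack
        inside = stack.contains(pts[:, 0], pts[:, 1])
        if not inside.all():
            warnings.warn(f"{int((~inside).sum())} points outside the raster extent; "
                          "their rows are missing (NaN)")
        i = np.zeros(len(pts), dtype=int)
        j = np.zeros(len(pts), dtype=int)
        i[inside], j[inside] = stack.cell_of(pts[inside, 0], pts[inside, 1])
        cols: dict[str, np.ndarray] = {"x": pts[:, 0], "y": pts[:, 1]}
        for name, ras in self.rasters.items():
            v = np.full(len(pts), np.nan)
            v[inside] = ras[i[inside], j[inside]]
            cols[name] = v
        lab = np.full(len(pts), -1, dtype=int)
        lab[inside] = self.patches.labels[i[inside], j[inside]]
        catcode = np.full(len(pts), -1, dtype=int)
        catcode[inside] = self.patches.category[i[inside], j[inside]]
        cols["patch_category"] = np.array(
            [CATEGORY_CODES.get(c, "missing") for c in catcode], dtype=object)
        size = np.full(len(pts), np.nan)
        size[inside] = self._patch_area[lab[inside]]
        cols["patch_size_ha"] = size
        d = np.full(len(pts), np.nan)
        if inside.any():
            d[inside] = distance_to_edge(self.patches, pts[inside])
        cols["dist_to_edge"] = d
        df = pd.DataFrame(cols)
        if disturbed_mask is not None:
            flagged = np.zeros(len(pts), dtype=bool)
            flagged[inside] = disturbed_mask[i[inside], j[inside]]
            df = df.loc[~flagged].reset_index(drop=True)
            if flagged.any():
                logger.info("dropped %d points in disturbed-after-measurement areas",
                            int(flagged.sum()))
        return df


def _scale_tag(radius: float) -> str:
    return str(int(radius)) if float(radius).is_integer() else str(radius)


def extract_covariates(points, stack, patches: PatchSet | None = None,
                       scales=(100.0, 400.0, 4000.0),
                       disturbed_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Convenience wrapper: build a :class:`CovariateEngine` and extract rows."""
    eng = CovariateEngine(stack, scales=scales, patches=patches)
    return eng.extract(points, disturbed_mask=disturbed_mask)


# ---------------------------------------------------------------------------
# raster / vector I/O (plain TIFF + JSON sidecar; GeoJSON lines)
# ---------------------------------------------------------------------------

def write_landscape(stack, path_prefix: str) -> None:
    """Write the stack as multi-band TIFF plus a JSON metadata sidecar."""
    import tifffile
    bands = np.stack([stack.canopy.astype(np.float32),
                      stack.elevation.astype(np.float32),
                      stack.vegclass.astype(np.float32)])
    tifffile.imwrite(f"{path_prefix}.tif", bands)
    meta = {"x0": stack.x0, "y0": stack.y0, "resolution": stack.resolution,
            "bands": ["canopy", "elevation", "vegclass"],
            "veg_codes": list(stack.veg_codes)}
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh)


def read_landscape(path_prefix: str):
    import tifffile
    from .synthgen import LandscapeStack
    bands = tifffile.imread(f"{path_prefix}.tif")
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    return LandscapeStack(x0=meta["x0"], y0=meta["y0"],
                          resolution=meta["resolution"],
                          canopy=bands[0].astype(float),
                          elevation=bands[1].astype(float),
                          vegclass=bands[2].astype(np.int32),
                          veg_codes=tuple(meta["veg_codes"]))


def write_patches(patches: PatchSet, path_prefix: str, extra_properties=None) -> None:
    """Labeled raster as TIFF + boundary lines as GeoJSON."""
    import tifffile
    tifffile.imwrite(f"{path_prefix}_labels.tif", patches.labels.astype(np.int32))
    feats = []
    for s in patches.boundary_segments:
        feats.append({"type": "Feature",
                      "properties": dict(extra_properties or {}),
                      "geometry": {"type": "LineString",
                                   "coordinates": [[s[0], s[1]], [s[2], s[3]]]}})
    with open(f"{path_prefix}_boundaries.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    patches.table.to_csv(f"{path_prefix}_table.csv", index=False)
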