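"""Track preprocessing: behavior states, thinning, home ranges, availability.

Implements the collar-data conventions of accelerometer-informed GPS
telemetry: activity counts below a resting threshold (default 6400) mark
resting fixes and counts above a fast threshold (48,000) mark fast movement;
fix schedules are behavior-linked (~5/20-min movement fixes, ~120-min resting
fixes).  Movement data are thinned to a uniform 20-min interval, home ranges
are 100% minimum convex polygons buffered by 5 km, and availability is drawn
uniformly within the buffered range at a 1:20 used:available ratio from one
shared pool per individual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon, mapping

logger = logging.getLogger(__name__)

ACCEL_REST_THRESHOLD = 6400.0
ACCEL_FAST_THRESHOLD = 48000.0


@dataclass
class HomeRange:
    """Convex-hull home range and its buffered availability polygon."""

    individual_id: str
    hull: Polygon
    buffered_hull: Polygon
    buffer_distance: float

    @property
    def area_km2(self) -> float:
        return self.hull.area / 1e6


def _require_sorted(track: pd.DataFrame) -> None:
    for iid, g in track.groupby("individual_id", sort=False):
        ts = pd.to_datetime(g["timestamp"]).to_numpy()
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValueError(f"timestamps not strictly increasing for individual {iid}")


def classify_behavior(track: pd.DataFrame,
                      accel_rest_threshold: float = ACCEL_REST_THRESHOLD,
                      accel_fast_threshold: float = ACCEL_FAST_THRESHOLD,
                      rest_interval: float = 120.0,
                      interval_tolerance: float = 5.0,
                      moving_intervals: tuple[float, ...] = (5.0, 20.0),
                      moving_tolerance: float = 2.0) -> pd.DataFrame:
    """Assign each fix to exactly one behavior state.

    Fixes with an accelerometer activity value use the threshold rule:
    ``activity < accel_rest_threshold`` is resting, anything above (including
    fast movement above ``accel_fast_threshold``) is moving.  Fixes without an
    activity value fall back to the interval rule: an interval to the next fix
    within ``rest_interval +/- interval_tolerance`` minutes marks resting,
    intervals near the movement schedule (5 or 20 min, ``+/- moving_tolerance``)
    mark moving, and anything else is "unknown".

    Returns a copy with ``interval_to_next`` (minutes) and ``behavior`` columns.
    """
    _require_sorted(track)
    out = track.copy()
    ts = pd.to_datetime(out["timestamp"])
    nxt = ts.groupby(out["individual_id"], sort=False).shift(-1)
    out["interval_to_next"] = (nxt - ts).dt.total_seconds() / 60.0

    activity = out["activity"] if "activity" in out else pd.Series(np.nan, index=out.index)
    has_act = activity.notna().to_numpy()
    act = activity.to_numpy(dtype=float)
    iv = out["interval_to_next"].to_numpy(dtype=float)

    behavior = np.full(len(out), "unknown", dtype=object)
    behavior[has_act & (act < accel_rest_threshold)] = "resting"
    behavior[has_act & (act >= accel_rest_threshold)] = "moving"
    rest_iv = np.abs(iv - rest_interval) <= interval_tolerance
    move_iv = np.zeros(len(out), dtype=bool)
    for m in moving_intervals:
        move_iv |= np.abs(iv - m) <= moving_tolerance
    behavior[~has_act & rest_iv] = "resting"
    behavior[~has_act & ~rest_iv & move_iv] = "moving"
    out["behavior"] = behavior
    if len(out) and (behavior == "unknown").all():
        warnings.warn("behavior classification produced only 'unknown' fixes")
    return out


def thin_track(track: pd.DataFrame,
               target_interval: float = 20.0,
               tolerance: float = 2.0) -> pd.DataFrame:
    """Thin to a uniform sampling interval by a greedy forward pass.

    Keeps the first fix of each individual, then the earliest subsequent fix
    whose gap from the last kept fix is at least ``target_interval - tolerance``
    minutes; consecutive kept gaps are therefore >= target - tolerance.
    Idempotent.  After a long gap the pass simply continues from the next fix.
    """
    _require_sorted(track)
    if track.empty:
        return track.copy()
    keep_idx = []
    min_gap = pd.Timedelta(minutes=target_interval - tolerance)
    for _, g in track.groupby("individual_id", sort=False):
        ts = pd.to_datetime(g["timestamp"])
        last = None
        for idx, t in zip(g.index, ts):
            if last is None or t - last >= min_gap:
                keep_idx.append(idx)
                last = t
    return track.loc[keep_idx].copy()


def compute_mcp(locations, percent: float = 100.0) -> Polygon:
    """Minimum convex polygon of a point set.

    ``locations`` is an (n, 2) array or a DataFrame with x/y columns.  For
    ``percent < 100`` the (100 - percent)% of points farthest from the
    centroid are peeled off before hulling.  Requires >= 3 non-collinear
    retained points.
    """
    if isinstance(locations, pd.DataFrame):
        pts = locations[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(locations, dtype=float)
    if not 0 < percent <= 100:
        raise ValueError("percent must lie in (0, 100]")
    if percent < 100 and len(pts):
        centroid = pts.mean(axis=0)
        d = np.hypot(*(pts - centroid).T)
        n_keep = int(np.ceil(len(pts) * percent / 100.0))
        pts = pts[np.argsort(d)[:n_keep]]
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a convex hull")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("points are collinear; convex hull is degenerate")
    return hull


def buffer_home_range(hull: Polygon, distance: float = 5000.0,
                      quad_segs: int = 64) -> Polygon:
    """Outward Euclidean buffer of a home-range polygon (default 5 km)."""
    if distance < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance == 0:
        return hull
    return hull.buffer(distance, quad_segs=quad_segs)


def build_home_range(track: pd.DataFrame, percent: float = 100.0,
                     buffer_distance: float = 5000.0) -> HomeRange:
    iid = str(track["individual_id"].iloc[0])
    hull = compute_mcp(track, percent=percent)
    return HomeRange(individual_id=iid, hull=hull,
                     buffered_hull=buffer_home_range(hull, buffer_distance),
                     buffer_distance=buffer_distance)


def sample_availability(polygon: Polygon, n_used: int, ratio: int = 20,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random points within a polygon: exactly ``ratio * n_used`` of them.

    One call per individual produces the shared availability pool reused by
    both behavior datasets.
    """
    if n_used < 1:
        raise ValueError("n_used must be >= 1")
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("availability polygon is degenerate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(ratio * n_used)
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        from shapely import contains_xy
        ok = contains_xy(polygon, xs, ys)
        take = min(int(ok.sum()), n - got)
        out[got:got + take] = np.column_stack([xs[ok][:take], ys[ok][:take]])
        got += take
    return out


# ---------------------------------------------------------------------------
# fix-success bias screen
# ---------------------------------------------------------------------------

@dataclass
class FixBiasResult:
    """Outcome of the fix-success habitat-bias screen."""

    fitted: bool
    environmentally_biased: bool
    coefficients: pd.DataFrame | None  # term, beta, se, lo95, hi95
    message: str = ""


def assess_fix_bias(attempts: pd.DataFrame,
                    covariate_cols: list[str]) -> FixBiasResult:
    """Screen scheduled fix attempts for habitat-dependent failure.

    Fits a random-intercept logistic model of the binary ``success`` flag on
    the environmental covariates at the attempt locations, with individual as
    the grouping factor.  The screen flags "environmentally biased" when any
    environmental coefficient's 95% CI excludes zero.  This is a simplified
    stand-in for a full fix-success analysis: it asks only whether success
    varies with habitat after allowing collar/individual differences.
    """
    if attempts["individual_id"].nunique() < 2:
        raise ValueError("fix-bias screen needs attempts from >= 2 individuals")
    succ = attempts["success"].astype(int)
    if succ.nunique() < 2:
        warnings.warn("all fix attempts share one outcome; bias screen not fitted")
        return FixBiasResult(False, False, None, "degenerate success column")

    from . import rsf  # local import: rsf is the model layer
    data = attempts.copy()
    data["response"] = succ
    std, _ = rsf.standardize(data, columns=covariate_cols)
    fit = rsf.fit_mixed_logistic("response ~ " + " + ".join(covariate_cols), std)
    coefs = fit.estimates
    env = coefs[coefs["term"] != "Intercept"]
    biased = bool(((env["lo95"] > 0) | (env["hi95"] < 0)).any())
    return FixBiasResult(True, biased, coefs)


# ---------------------------------------------------------------------------
# external interfaces
# ---------------------------------------------------------------------------

def write_home_ranges(home_ranges: list[HomeRange], path, extra_properties=None) -> None:
    """Write hulls and buffered hulls as a GeoJSON FeatureCollection."""
    import json
    feats = []
    for hr in home_ranges:
        for role, geom in (("hull", hr.hull), ("buffered_hull", hr.buffered_hull)):
            props = {"individual_id": hr.individual_id, "role": role,
                     "area_km2": geom.area / 1e6,
                     "buffer_distance_m": hr.buffer_distance}
            if extra_properties:
                props.update(extra_properties)
            feats.append({"type": "Feature", "properties": props,
                          "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_points(used: pd.DataFrame, available: dict[str, np.ndarray], path) -> None:
    """Used and available points as CSV with a role column."""
    rows = [used.assign(role="used")[["individual_id", "x", "y", "role"]]]
    for iid, pts in available.items():
        rows.append(pd.DataFrame({"individual_id": iid, "x": pts[:, 0],
                                  "y": pts[:, 1], "role": "available"}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
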