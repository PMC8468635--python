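"""Image-derived quantification: vessel morphometry and cell velocimetry.

Vessel diameter follows the classical manual rule — the distance between
the two vessel walls measured perpendicular to the local vessel direction —
automated as: skeletonize the lumen mask, extract the main centerline as
the longest geodesic path through the skeleton (which prunes side spurs),
estimate the local direction along the path, and cast a perpendicular chord
through the mask at sub-pixel precision.

Vessel "density" is interpreted as the lumen coverage area fraction within
a region of interest — the simplest measure computable from a mask; see the
methods note for the rationale.

Cell velocimetry reduces time-stamped trajectories to per-cell statistics:
mean speed (path length over elapsed time), net displacement, and the
signed velocity component along the flow axis, so that endothelium-arrested
cells and cells crawling against the flow are distinguishable from cells
advected with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage import measure as skmeasure
from skimage import morphology as skmorph


class MaskError(ValueError):
    """The lumen mask is empty or has no measurable vessel."""


@dataclass
class LumenMask:
    """Binary vessel-lumen image. ``pixels``: bool (rows, cols), 1 = lumen."""

    pixels: np.ndarray
    pixel_size: float  # m per pixel
    flow_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    day: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise MaskError("mask must be 2-D")
        if not self.pixels.any():
            raise MaskError("empty mask: no lumen foreground")
        if self.pixel_size <= 0:
            raise MaskError("pixel_size must be positive")


@dataclass
class VesselMeasurement:
    """Diameters sampled along the centerline, plus coverage density."""

    positions: np.ndarray  # arc length along centerline, m
    diameters: np.ndarray  # m
    density: float = np.nan  # coverage fraction in [0, 1]
    day: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")

    @property
    def mean(self) -> float:
        return float(np.mean(self.diameters))

    @property
    def sd(self) -> float:
        return float(np.std(self.diameters, ddof=1)) if self.diameters.size > 1 else 0.0


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Dominant connected component (keeping it subsumes small-object removal)."""
    lab = skmeasure.label(mask, connectivity=2)
    if lab.max() == 0:
        raise MaskError("no foreground component")
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == np.argmax(counts)


def _skeleton_main_path(mask: np.ndarray) -> np.ndarray:
    """Ordered (row, col) pixels of the longest geodesic through the skeleton.

    Taking the longest path between skeleton extremities acts as spur
    pruning: short side branches at wall irregularities are bypassed, and at
    branch points the longer continuation wins.
    """
    skel = skmorph.skeletonize(mask)
    pts = np.argwhere(skel)
    if len(pts) < 5:
        raise MaskError("mask has no elongated component (skeleton too short)")
    index = -np.ones(mask.shape, dtype=np.int64)
    index[tuple(pts.T)] = np.arange(len(pts))
    rows, cols, w = [], [], []
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        p = pts
        q = pts + (di, dj)
        ok = (
            (q[:, 0] >= 0)
            & (q[:, 0] < mask.shape[0])
            & (q[:, 1] >= 0)
            & (q[:, 1] < mask.shape[1])
        )
        ok[ok] = skel[q[ok, 0], q[ok, 1]]
        a = index[p[ok, 0], p[ok, 1]]
        b = index[q[ok, 0], q[ok, 1]]
        rows.extend([a, b])
        cols.extend([b, a])
        w.extend([np.full(len(a), np.hypot(di, dj))] * 2)
    g = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(pts), len(pts)),
    ).tocsr()
    d0 = dijkstra(g, indices=0)
    start = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    dist, pred = dijkstra(g, indices=start, return_predecessors=True)
    end = int(np.nanargmax(np.where(np.isinf(dist), np.nan, dist)))
    path = [end]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return pts[np.array(path[::-1])]


def _chords(
    float_mask: np.ndarray,
    points: np.ndarray,
    normals: np.ndarray,
    t_max: float,
    step: float = 0.25,
) -> np.ndarray:
    """Sub-pixel chord length through the mask at each point along its normal."""
    t = np.arange(0.0, t_max + step, step)
    out = np.empty(len(points))
    for i, (p, n) in enumerate(zip(points, normals)):
        half = []
        for sign in (1.0, -1.0):
            coords = p[:, None] + sign * n[:, None] * t[None, :]
            v = ndimage.map_coordinates(float_mask, coords, order=1, cval=0.0)
            below = np.nonzero(v < 0.5)[0]
            if len(below) == 0 or below[0] == 0:
                half.append(np.nan)
                continue
            k = below[0]
            # linear root of the interpolated intensity crossing 0.5
            frac = (v[k - 1] - 0.5) / max(v[k - 1] - v[k], 1e-12)
            half.append(t[k - 1] + frac * step)
        out[i] = half[0] + half[1]
    return out


def measure_diameter(
    mask: LumenMask,
    sample_stride: int = 5,
    direction_window: int = 10,
    end_exclusion: float = 0.05,
) -> VesselMeasurement:
    """Perpendicular-chord vessel diameter along the lumen centerline.

    At points sampled every ``sample_stride`` pixels of arc along the main
    centerline, the local direction is the secant over ``direction_window``
    path pixels on each side and the diameter is the through-mask chord
    perpendicular to it. Points on end spurs (where the centerline departs
    from the vessel axis toward mask corners) are rejected by requiring the
    local inscribed radius to stay near the path-median value, then a
    further ``end_exclusion`` fraction is trimmed at each end.
    """
    fg = _largest_component(mask.pixels)
    path = _skeleton_main_path(fg)
    edt = ndimage.distance_transform_edt(fg)
    r_path = edt[path[:, 0], path[:, 1]]
    good = r_path >= 0.7 * np.median(r_path)
    # longest contiguous run of good points
    runs = np.split(np.arange(len(path)), np.nonzero(np.diff(good.astype(int)))[0] + 1)
    runs = [r for r in runs if good[r[0]]]
    if not runs:
        raise MaskError("mask has no elongated component")
    keep = max(runs, key=len)
    path = path[keep]
    trim = int(np.ceil(end_exclusion * len(path)))
    if len(path) - 2 * trim < max(3, 2 * direction_window):
        raise MaskError("mask has no elongated component (centerline too short)")
    path = path[trim : len(path) - trim]

    idx = np.arange(direction_window, len(path) - direction_window, sample_stride)
    w = direction_window
    tang = (path[idx + w] - path[idx - w]).astype(float)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    pts = path[idx].astype(float)

    t_max = 4.0 * float(edt.max()) + 10.0
    chords = _chords(fg.astype(float), pts, normals, t_max)
    ok = np.isfinite(chords)
    if not ok.any():
        raise MaskError("no valid perpendicular chords found")
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    return VesselMeasurement(
        positions=arc[idx[ok]] * mask.pixel_size,
        diameters=chords[ok] * mask.pixel_size,
        density=vessel_density(mask),
        day=mask.day,
    )


def vessel_density(mask: LumenMask, roi=None) -> float:
    """Lumen coverage area fraction within the ROI (whole image by default).

    ``roi`` is (row_slice, col_slice).
    """
    px = mask.pixels if roi is None else mask.pixels[roi]
    if px.size == 0:
        raise ValueError("empty ROI")
    return float(px.mean())


def longitudinal_stability(
    measurements: list[VesselMeasurement],
    value: str = "diameter",
    grouping: str = "device",
) -> tuple[pd.DataFrame, float, float]:
    """Per-day summary and one-way ANOVA across days.

    ``grouping='device'`` uses one value (the per-measurement mean) per
    measurement; ``'pooled'`` pools all sampled positions. Returns
    (summary table with day/n/mean/sd, F statistic, p-value). A degenerate
    series with no between-day variation reports p = 1 (no effect).
    """
    if value not in ("diameter", "density"):
        raise ValueError("value must be 'diameter' or 'density'")
    groups: dict[int, list[float]] = {}
    for m in measurements:
        if value == "density":
            vals = [m.density]
        elif grouping == "device":
            vals = [m.mean]
        elif grouping == "pooled":
            vals = list(m.diameters)
        else:
            raise ValueError("grouping must be 'device' or 'pooled'")
        groups.setdefault(m.day, []).extend(vals)
    if len(groups) < 2:
        raise ValueError("need measurements from at least 2 days")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need at least 2 values per day")
    days = sorted(groups)
    summary = pd.DataFrame(
        {
            "day": days,
            "n": [len(groups[d]) for d in days],
            "mean": [float(np.mean(groups[d])) for d in days],
            "sd": [float(np.std(groups[d], ddof=1)) for d in days],
        }
    )
    means = summary["mean"].to_numpy()
    allvals = np.concatenate([groups[d] for d in days])
    if np.ptp(means) <= 1e-12 * max(1.0, np.abs(allvals).max()):
        return summary, 0.0, 1.0
    F, p = stats.f_oneway(*(groups[d] for d in days))
    return summary, float(F), float(p)


REQUIRED_TRACK_COLUMNS = ("cell_id", "t", "x", "y")


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Check the track table contract: required columns, time strictly
    increasing per cell, >= 2 frames per cell."""
    missing = set(REQUIRED_TRACK_COLUMNS) - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing column(s): {sorted(missing)}")
    for cid, g in tracks.groupby("cell_id"):
        if len(g) < 2:
            raise ValueError(f"cell {cid!r} has a single frame")
        if np.any(np.diff(g["t"].to_numpy()) <= 0):
            raise ValueError(f"cell {cid!r} has non-increasing timestamps")
    return tracks


def track_stats(
    tracks: pd.DataFrame,
    arrest_threshold: float = 1.0e-6,
    flow_axis=(1.0, 0.0),
) -> pd.DataFrame:
    """Per-cell velocimetry from a track table (columns cell_id, t, x, y; SI).

    mean_speed = path length / elapsed time; along_flow_velocity = net
    displacement projected on the flow axis / elapsed time (negative for
    cells moving against the flow); arrested if mean_speed falls below
    ``arrest_threshold`` (m/s).
    """
    validate_tracks(tracks)
    axis = np.asarray(flow_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rows = []
    for cid, g in tracks.groupby("cell_id", sort=False):
        g = g.sort_values("t")
        xy = g[["x", "y"]].to_numpy(dtype=float)
        t = g["t"].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        path = float(steps.sum())
        elapsed = float(t[-1] - t[0])
        net_vec = xy[-1] - xy[0]
        rows.append(
            {
                "cell_id": cid,
                "mean_speed": path / elapsed,
                "net_displacement": float(np.linalg.norm(net_vec)),
                "path_length": path,
                "along_flow_velocity": float(net_vec @ axis) / elapsed,
                "arrested": path / elapsed < arrest_threshold,
            }
        )
    return pd.DataFrame(rows)


def classify_track(
    stats_row,
    arrest_threshold: float = 1.0e-6,
    along_threshold: float = 1.0e-7,
) -> str:
    """Coarse behavioral class: 'flowing', 'arrested', or 'against_flow'."""
    if stats_row["along_flow_velocity"] <= -along_threshold:
        return "against_flow"
    if stats_row["mean_speed"] < arrest_threshold:
        return "arrested"
    return "flowing"
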