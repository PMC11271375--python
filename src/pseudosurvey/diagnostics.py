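"""Spatial-balance and data-representativeness diagnostics.

Spatial balance of a site set against a frame is scored from the Voronoi
tessellation of the sites clipped to the frame: under a perfectly balanced
design every site's Voronoi cell holds an equal share of the resource area.
Two 0-is-best metrics summarize departure from that ideal — an entropy-based
Pielou evenness score and the root-mean-square error of the normalized cell
totals.

Data representativeness is tested by a null mean simulation: bootstrap means
of the pseudo-probabilistically selected values are compared against the 95 %
confidence interval of the observed raw-data mean, and the p-value is the
fraction of simulated means falling inside that interval (high = the reduced
dataset reproduces the observed distribution's centre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point

from .frame_grid import SampleFrame

__all__ = ["BalanceResult", "SimulationResult", "spatial_balance",
           "null_mean_simulation", "voronoi_cell_areas"]


@dataclass(frozen=True)
class BalanceResult:
    metric: str
    value: float
    n_sites: int


@dataclass(frozen=True)
class SimulationResult:
    parameter: str
    p_value: float
    n_sims: int
    seed: int
    observed_mean: float
    ci: tuple


def voronoi_cell_areas(points: np.ndarray, frame: SampleFrame) -> np.ndarray:
    """km² of each point's Voronoi cell clipped to the frame (sums to total area).

    Frame fragments (islands, disjoint lobes) are implicitly assigned to the
    nearest point, which is exactly what the Voronoi partition encodes.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 1:
        raise ValueError("need at least one point")
    if len(np.unique(pts, axis=0)) != n:
        raise ValueError("duplicate points are not supported for balance metrics")
    inside = frame.contains_xy(pts[:, 0], pts[:, 1])
    if not np.all(inside):
        bad = np.where(~inside)[0][0]
        raise ValueError(f"point index {bad} at {tuple(pts[bad])} lies outside the frame")
    if n == 1:
        return np.array([frame.total_area])

    minx, miny, maxx, maxy = frame.bounds
    pad = max(maxx - minx, maxy - miny)
    env = shapely.box(minx - pad, miny - pad, maxx + pad, maxy + pad)
    vor = shapely.voronoi_polygons(MultiPoint([tuple(p) for p in pts]), extend_to=env)
    cells = list(vor.geoms)
    tree = shapely.STRtree(cells)
    areas = np.zeros(n)
    for i, p in enumerate(pts):
        cand = tree.query(Point(p), predicate="intersects")
        # a point lies in exactly one open cell; boundary grazing picks nearest
        j = int(cand[0]) if len(cand) else int(tree.nearest(Point(p)))
        areas[i] = cells[j].intersection(frame.geometry).area
    return areas


def spatial_balance(points, frame: SampleFrame, metric: str = "pielou") -> BalanceResult:
    """Score the spatial balance of a point set against a frame (0 = perfect).

    With ``v_i = n * area_i / total_area`` (expected 1 under perfect balance):
    ``pielou`` is ``1 - H / ln(n)`` with H the entropy of the area shares and
    lies in [0, 1]; ``rmse`` is ``sqrt(mean((v_i - 1)^2))``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if metric not in ("pielou", "rmse"):
        raise ValueError("metric must be 'pielou' or 'rmse'")
    if n == 1:
        return BalanceResult(metric=metric, value=0.0, n_sites=1)
    areas = voronoi_cell_areas(pts, frame)
    total = areas.sum()
    v = n * areas / total
    if metric == "rmse":
        value = float(np.sqrt(np.mean((v - 1.0) ** 2)))
    else:
        p = areas / total
        nz = p[p > 0]
        h = float(-np.sum(nz * np.log(nz)))
        value = 1.0 - h / np.log(n)
        value = float(min(max(value, 0.0), 1.0))
    return BalanceResult(metric=metric, value=value, n_sites=n)


def null_mean_simulation(observed_values, pp_values, n_sims: int = 1000,
                         seed: int = 0, parameter: str = "",
                         replace: bool = True,
                         subset_fraction: float = 1.0) -> SimulationResult:
    """Bootstrap test of whether reduced (pseudo-probabilistic) data reproduce
    the observed mean.

    The 95 % CI of the observed mean is ``mean ± 1.96 sd/sqrt(n)``; each
    simulation draws a random subset of the pseudo-probabilistic values
    (with replacement by default, full size) and the p-value is the fraction
    of simulated means inside the interval.
    """
    obs = np.asarray(observed_values, dtype=float)
    pp = np.asarray(pp_values, dtype=float)
    if obs.size == 0 or pp.size == 0:
        raise ValueError("both inputs must be non-empty")
    m = float(obs.mean())
    half = 1.959963984540054 * float(obs.std(ddof=1)) / np.sqrt(obs.size) if obs.size > 1 else 0.0
    lo, hi = m - half, m + half
    rng = np.random.default_rng(seed)
    k = max(1, int(round(subset_fraction * pp.size)))
    sims = np.array([
        rng.choice(pp, size=k, replace=replace).mean() for _ in range(n_sims)
    ])
    p = float(np.mean((sims >= lo) & (sims <= hi)))
    return SimulationResult(parameter=parameter, p_value=p, n_sims=n_sims,
                            seed=int(seed), observed_mean=m, ci=(lo, hi))
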