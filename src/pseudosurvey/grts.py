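"""Generalized random tessellation stratified (GRTS) sampling of a polygon resource.

GRTS draws spatially balanced, equal-probability samples from a continuous
two-dimensional resource.  The frame is enclosed in a square that is
recursively split into quadrants; each node of the quadrant tree receives an
independent random permutation of its four sub-cell addresses, which maps the
plane to the unit line in a randomized hierarchical (quadrant-recursive)
order.  A systematic sample with a random start along that line — each cell
weighted by its frame-intersection area — selects cells with probability
proportional to area, i.e. with equal inclusion probability over the frame.
One point is then placed uniformly at random inside each selected
cell∩frame.  Finally the sample is put in *reverse hierarchical order*, so
that every prefix of the ordered list is itself a spatially balanced sample.

The quadrant tree geometry is deterministic for a given frame, so a
:class:`GrtsEngine` can be built once and reused across many seeded draws
(only the per-node address permutations, the systematic start and the point
placement are random).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box

from .frame_grid import SampleFrame

__all__ = ["GrtsEngine", "GrtsSample", "grts_sample", "assign_weights"]


@dataclass
class GrtsSample:
    """An ordered GRTS draw. ``points`` columns: order_index, x, y."""

    points: pd.DataFrame
    n_requested: int
    seed: int
    frame_ref: str

    def xy(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy()


class GrtsEngine:
    """Quadrant tree over a frame, reusable across seeded draws.

    Parameters
    ----------
    frame:
        The resource polygon.
    n_max:
        Largest sample size the engine must support; cells are subdivided
        until their selection mass is below ``total_area / (min_cells_per_site
        * n_max)`` so no cell can be hit twice by the systematic sample.
    min_cells_per_site:
        Resolution multiplier (default 4).
    max_depth:
        Hard recursion cap (4**max_depth potential cells).
    """

    def __init__(self, frame: SampleFrame, n_max: int = 64,
                 min_cells_per_site: int = 4, max_depth: int = 11):
        if n_max < 1:
            raise ValueError("n_max must be >= 1")
        self.frame = frame
        self.n_max = n_max
        self.max_depth = max_depth
        geom = frame.geometry
        shapely.prepare(geom)
        minx, miny, maxx, maxy = frame.bounds
        side = max(maxx - minx, maxy - miny)
        self._origin = (minx, miny)
        self._side = side
        total = frame.total_area
        self._threshold = total / (min_cells_per_site * n_max)

        leaves = []       # (path, x0, y0, size, mass)
        internal = set()  # node paths that were subdivided
        stack = [((), minx, miny, side, None)]
        while stack:
            path, x0, y0, size, mass = stack.pop()
            cell = box(x0, y0, x0 + size, y0 + size)
            if mass is None:
                if not shapely.intersects(geom, cell):
                    continue
                if shapely.contains_properly(geom, cell):
                    mass = size * size
                else:
                    mass = cell.intersection(geom).area
            if mass <= 0:
                continue
            if mass <= self._threshold or len(path) >= max_depth:
                leaves.append((path, x0, y0, size, mass))
                continue
            internal.add(path)
            half = size / 2.0
            for digit, (dx, dy) in enumerate(((0, 0), (1, 0), (0, 1), (1, 1))):
                stack.append((path + (digit,), x0 + dx * half, y0 + dy * half, half, None))

        if not leaves:
            raise ValueError("frame has no area; cannot build GRTS engine")
        self._leaves = sorted(leaves, key=lambda t: t[0])
        self._internal = sorted(internal)
        self._mass = np.array([t[4] for t in self._leaves])
        self.total_mass = float(self._mass.sum())

    # -- internal helpers ---------------------------------------------------

    def _random_point_in_leaf(self, leaf, rng) -> tuple:
        _, x0, y0, size, mass = leaf
        geom = self.frame.geometry
        for _ in range(10_000):
            x = rng.uniform(x0, x0 + size)
            y = rng.uniform(y0, y0 + size)
            if shapely.contains_xy(geom, x, y):
                return x, y
        # pathological sliver: fall back to a deterministic interior point
        poly = box(x0, y0, x0 + size, y0 + size).intersection(geom)
        p = poly.representative_point()
        return p.x, p.y

    @staticmethod
    def _reverse_hierarchical(n: int) -> np.ndarray:
        """Ranks assigning order_index: reverse base-4 digits of line position."""
        ndig = max(1, math.ceil(math.log(max(n, 2), 4)))
        rev = np.empty(n, dtype=int)
        for i in range(n):
            digits = [(i >> (2 * d)) & 3 for d in range(ndig)]  # LSD first
            # reversed address: least-significant digit becomes most significant
            val = 0
            for d in digits:
                val = 4 * val + d
            rev[i] = val
        return np.argsort(rev, kind="stable")

    # -- public API ---------------------------------------------------------

    def sample(self, n: int, seed: int) -> GrtsSample:
        """Draw a spatially balanced sample of ``n`` points (bit-identical per seed)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if n > self.n_max:
            raise ValueError(
                f"engine built for n_max={self.n_max}; requested n={n} could place "
                "two sample points in one cell — rebuild with a larger n_max")
        rng = np.random.default_rng(seed)

        # randomized hierarchical addresses: one 4-permutation per internal node
        perms = {p: rng.permutation(4) for p in self._internal}
        keys = []
        for path, *_ in self._leaves:
            keys.append(tuple(int(perms[path[:i]][d]) for i, d in enumerate(path)))
        order = sorted(range(len(self._leaves)), key=lambda i: keys[i])

        mass = self._mass[order]
        cum = np.cumsum(mass)
        k = self.total_mass / n
        start = rng.uniform(0.0, k)
        targets = start + k * np.arange(n)
        idx = np.searchsorted(cum, targets, side="right")
        if len(set(idx.tolist())) != n:
            raise RuntimeError("systematic selection hit a cell twice; increase max_depth")

        pts = [self._random_point_in_leaf(self._leaves[order[i]], rng) for i in idx]
        rho = self._reverse_hierarchical(n)
        ordered = [pts[i] for i in rho]
        df = pd.DataFrame(ordered, columns=["x", "y"])
        df.insert(0, "order_index", np.arange(1, n + 1))
        return GrtsSample(points=df, n_requested=n, seed=int(seed),
                          frame_ref=self.frame.crs_id)


def grts_sample(frame: SampleFrame, n: int, seed: int,
                engine: GrtsEngine | None = None) -> GrtsSample:
    """Convenience wrapper: draw one GRTS sample of ``n`` points over ``frame``.

    Pass a prebuilt :class:`GrtsEngine` when drawing repeatedly from one frame.
    """
    if engine is None:
        engine = GrtsEngine(frame, n_max=n)
    return engine.sample(n, seed)


def assign_weights(sample, frame: SampleFrame, n_effective: int) -> pd.DataFrame:
    """Equal area weights: every site represents total_area / n_effective km².

    Accepts a :class:`GrtsSample` or a point DataFrame; returns the point
    table with a ``weight`` column (weights sum to the frame total area).
    """
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    df = sample.points.copy() if isinstance(sample, GrtsSample) else sample.copy()
    df["weight"] = frame.total_area / n_effective
    return df
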