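"""Synthetic estuaries, parameter surfaces and multi-source monitoring records.

Every stage of the pipeline is testable offline against data generated here:

* :func:`make_estuary` builds a multi-lobed coastal polygon with narrow tidal
  river arms and an upstream→marine gradient coordinate (``axis``: 0 at the
  river heads, 1 at the marine edge), the synthetic stand-in for a panhandle
  estuary complex;
* :class:`SurfaceModel` maps the gradient to parameter values — salinity
  rising seaward, nutrients and chlorophyll falling, lognormal noise for
  concentration-like parameters (matching the strong right skew of real
  summaries, e.g. enterococci means far above medians) and normal noise for
  temperature and pH;
* :func:`sample_records` emulates two record sources: a targeted, clustered,
  revisit-heavy program (1–10 visits per site, per-visit parameter dropout,
  occasional alternate units and non-detects) and a single-visit probabilistic
  program whose sites come from a GRTS draw;
* :func:`known_truth` integrates the noise-free surface over a fine grid to
  provide true category area fractions and true means for estimator
  validation.

All randomness flows from explicit seeds; identical seeds reproduce identical
geometry and records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .frame_grid import SampleFrame
from .grts import GrtsEngine
from .harmonize import PARAMETERS, do_mgL_to_percent, salinity_to_conductance

__all__ = ["SyntheticEstuary", "SurfaceModel", "SamplingScript",
           "make_estuary", "default_surface", "sample_records", "known_truth"]


@dataclass
class SyntheticEstuary:
    """A synthetic estuarine frame with an upstream→marine gradient coordinate."""

    frame: SampleFrame
    y_upstream: float
    y_marine: float
    n_lobes: int
    n_arms: int
    seed: int

    def axis(self, x, y):
        """Gradient coordinate in [0, 1]: 0 at river heads, 1 at the marine edge."""
        a = (self.y_upstream - np.asarray(y, dtype=float)) / (self.y_upstream - self.y_marine)
        return np.clip(a, 0.0, 1.0)


def make_estuary(seed: int = 0, n_lobes: int = 3, n_arms: int = 2,
                 lobe_radius: float = 7.0, strip_height: float = 3.0) -> SyntheticEstuary:
    """Build a multi-lobed coastal polygon with tidal-river arms (km units).

    Lobes (bays) sit on a nearshore lagoon strip whose southern edge is the
    marine boundary; narrow buffered-line arms extend upstream (north) from
    lobe heads.  Deterministic for a given seed.
    """
    if n_lobes < 1:
        raise ValueError("n_lobes must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    centers = []
    for i in range(n_lobes):
        cx = 2.6 * lobe_radius * i + rng.uniform(-1.0, 1.0)
        rx = lobe_radius * rng.uniform(0.85, 1.1)
        ry = lobe_radius * rng.uniform(0.7, 1.0)
        cy = strip_height + 0.7 * ry
        circ = Point(cx, cy).buffer(1.0, quad_segs=48)
        lobe = shapely.transform(circ, lambda c, rx=rx, ry=ry, cx=cx, cy=cy:
                                 np.c_[cx + (c[:, 0] - cx) * rx, cy + (c[:, 1] - cy) * ry])
        parts.append(lobe)
        centers.append((cx, cy, ry))

    # nearshore lagoon strip connecting the lobes; its south edge (y=0) is marine
    xs = [c[0] for c in centers]
    strip = box(min(xs) - 1.5 * lobe_radius, 0.0, max(xs) + 1.5 * lobe_radius, strip_height)
    parts.append(strip)

    # tidal river arms extending upstream from lobe heads
    for j in range(n_arms):
        cx, cy, ry = centers[j % n_lobes]
        x0 = cx + rng.uniform(-0.3, 0.3) * lobe_radius
        y0 = cy + 0.5 * ry
        length = 2.2 * lobe_radius * rng.uniform(0.8, 1.2)
        t = np.linspace(0.0, 1.0, 12)
        wiggle = 1.5 * np.sin(t * np.pi * rng.uniform(1.0, 2.0) + rng.uniform(0, np.pi))
        path = LineString(np.c_[x0 + wiggle, y0 + t * length])
        parts.append(path.buffer(0.6, quad_segs=8))

    geom = unary_union(parts)
    frame = SampleFrame.from_polygons([geom], crs_id=f"synthetic-estuary-km-seed{seed}")
    _, miny, _, maxy = frame.bounds
    return SyntheticEstuary(frame=frame, y_upstream=maxy, y_marine=miny,
                            n_lobes=n_lobes, n_arms=n_arms, seed=int(seed))


# ---------------------------------------------------------------------------
# parameter surfaces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSurface:
    median: object                 # callable axis -> median value
    dist: str                      # "lognormal" | "normal"
    noise_sd: float                # sd of log values / values
    detection_limit: float = 0.0
    month_offset: dict = field(default_factory=dict)


@dataclass
class SurfaceModel:
    """Per-parameter gradient→value model with seasonal offsets and noise."""

    params: dict

    def median_value(self, parameter: str, axis, month: int | None = None):
        ps = self.params[parameter]
        v = np.asarray(ps.median(np.asarray(axis, dtype=float)), dtype=float)
        if month is not None:
            v = v + ps.month_offset.get(month, 0.0)
        return v

    def draw(self, parameter: str, axis, month: int, rng) -> np.ndarray:
        ps = self.params[parameter]
        med = self.median_value(parameter, axis, month)
        a = np.asarray(axis, dtype=float)
        if ps.dist == "lognormal":
            vals = np.exp(np.log(np.clip(med, 1e-9, None))
                          + rng.normal(0.0, ps.noise_sd, size=a.shape))
        else:
            vals = med + rng.normal(0.0, ps.noise_sd, size=a.shape)
        return vals

    def is_nondetect(self, parameter: str, values) -> np.ndarray:
        dl = self.params[parameter].detection_limit
        return np.asarray(values) < dl


def default_surface() -> SurfaceModel:
    """Summer estuarine gradients with realistic magnitudes and skew."""
    return SurfaceModel(params={
        "SAL": ParamSurface(lambda a: 30.0 * a**1.3 + 0.02, "lognormal", 0.25),
        "TEMP": ParamSurface(lambda a: 29.0 + 1.0 * a, "normal", 1.5,
                             month_offset={6: -1.0, 7: 0.3, 8: 0.8, 9: -0.4}),
        "PH": ParamSurface(lambda a: 7.4 + 0.6 * a, "normal", 0.25),
        "DO_MGL": ParamSurface(lambda a: 5.8 + 1.0 * a, "lognormal", 0.15),
        "CHLA": ParamSurface(lambda a: 2.0 + 6.0 * (1.0 - a), "lognormal", 0.6,
                             detection_limit=0.3),
        "TN": ParamSurface(lambda a: 0.55 - 0.25 * a, "lognormal", 0.30,
                           detection_limit=0.01),
        "TP": ParamSurface(lambda a: 0.030 - 0.015 * a, "lognormal", 0.40,
                           detection_limit=0.002),
        "ENTERO": ParamSurface(lambda a: 1.0 + 30.0 * np.exp(-3.0 * a), "lognormal", 1.2,
                               detection_limit=1.0),
    })


# ---------------------------------------------------------------------------
# sampling scripts
# ---------------------------------------------------------------------------

@dataclass
class SamplingScript:
    """How a monitoring source places sites and visits over the estuary."""

    source: str
    mode: str                       # "targeted" | "probabilistic"
    n_sites: int
    years: tuple = (2015,)
    months: tuple = (6, 7, 8, 9)
    visits_range: tuple = (1, 10)   # targeted revisit span (inclusive)
    n_clusters: int = 3
    cluster_sd: float = 1.5         # km spread of targeted clusters
    dropout: float = 0.3            # per-visit probability a parameter is skipped
    alt_unit_fraction: float = 0.0  # fraction of SAL/DO records in raw units
    seed: int = 0


def _rejection_points(n, frame: SampleFrame, rng, propose):
    pts = []
    geom = frame.geometry
    while len(pts) < n:
        x, y = propose()
        if shapely.contains_xy(geom, x, y):
            pts.append((x, y))
    return np.array(pts)


def _targeted_sites(estuary: SyntheticEstuary, script: SamplingScript, rng) -> np.ndarray:
    frame = estuary.frame
    minx, miny, maxx, maxy = frame.bounds
    centers = _rejection_points(
        script.n_clusters, frame, rng,
        lambda: (rng.uniform(minx, maxx), rng.uniform(miny, maxy)))
    sites = []
    for i in range(script.n_sites):
        c = centers[i % len(centers)]
        pt = _rejection_points(1, frame, rng,
                               lambda: tuple(c + rng.normal(0.0, script.cluster_sd, 2)))
        sites.append(pt[0])
    return np.array(sites)


def sample_records(estuary: SyntheticEstuary, surface: SurfaceModel,
                   script: SamplingScript) -> pd.DataFrame:
    """Generate a raw record table in the canonical CSV schema.

    Columns: site_id, source, x, y, datetime, parameter, value, unit,
    qualifiers, mdl, pql, depth_m.  Non-detects carry a blank value and the
    detection limit in ``mdl``.
    """
    rng = np.random.default_rng(script.seed)
    if script.mode == "targeted":
        sites = _targeted_sites(estuary, script, rng)
        visits_per_site = rng.integers(script.visits_range[0],
                                       script.visits_range[1] + 1, size=len(sites))
    elif script.mode == "probabilistic":
        engine = GrtsEngine(estuary.frame, n_max=script.n_sites)
        draw = engine.sample(script.n_sites, seed=int(rng.integers(0, 2**31 - 1)))
        sites = draw.xy()
        visits_per_site = np.ones(len(sites), dtype=int)
    else:
        raise ValueError("mode must be 'targeted' or 'probabilistic'")

    params = list(surface.params)
    rows = []
    for s_idx, (x, y) in enumerate(sites):
        site_id = f"{script.source}-{s_idx:04d}"
        a = float(estuary.axis(x, y))
        # distinct visit dates per site (a site is never sampled twice at once)
        combos = [(yr, mo, d) for yr in script.years for mo in script.months
                  for d in range(1, 29)]
        picks = rng.choice(len(combos), size=min(int(visits_per_site[s_idx]), len(combos)),
                           replace=False)
        for pick in picks:
            year, month, day = combos[pick]
            ts = f"{year:04d}-{month:02d}-{day:02d}T{int(rng.integers(6, 18)):02d}:00:00"
            for p in params:
                if script.mode == "targeted" and rng.uniform() < script.dropout:
                    continue
                val = float(surface.draw(p, np.array([a]), month, rng)[0])
                spec = PARAMETERS[p]
                unit = spec.standard_unit
                dl = surface.params[p].detection_limit
                nd = val < dl
                value: object = "" if nd else val
                mdl = dl if dl > 0 else np.nan
                qual = "U" if nd else ""
                # occasionally report raw field units to exercise conversions
                if not nd and script.alt_unit_fraction > 0 and rng.uniform() < script.alt_unit_fraction:
                    if p == "SAL":
                        value, unit = salinity_to_conductance(val), "uS/cm"
                    elif p == "DO_MGL":
                        t = float(surface.median_value("TEMP", a, month))
                        s = float(surface.median_value("SAL", a))
                        value, unit = do_mgL_to_percent(val, t, s), "%sat"
                rows.append({
                    "site_id": site_id, "source": script.source,
                    "x": x, "y": y, "datetime": ts, "parameter": p,
                    "value": value, "unit": unit, "qualifiers": qual,
                    "mdl": mdl, "pql": np.nan, "depth_m": 0.5,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _frame_grid_points(frame: SampleFrame, resolution: float) -> np.ndarray:
    """Stratified integration points: one jittered point per resolution pixel.

    The deterministic jitter (fixed seed) avoids the quantization bias an
    aligned lattice shows when a category boundary parallels a grid row.
    """
    minx, miny, maxx, maxy = frame.bounds
    xs = np.arange(minx + resolution / 2, maxx, resolution)
    ys = np.arange(miny + resolution / 2, maxy, resolution)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.c_[xx.ravel(), yy.ravel()]
    rng = np.random.default_rng(20_240_101)
    pts = pts + rng.uniform(-resolution / 2, resolution / 2, size=pts.shape)
    inside = shapely.contains_xy(frame.geometry, pts[:, 0], pts[:, 1])
    return pts[inside]


def known_truth(estuary: SyntheticEstuary, surface: SurfaceModel, scheme,
                resolution: float = 0.5) -> dict:
    """True category area fractions (%) and true means on the noise-free surface.

    Numerical integration over a ``resolution``-km point grid inside the
    frame; refining the grid changes the fractions by well under a percent.
    """
    from .estimate import categorize

    pts = _frame_grid_points(estuary.frame, resolution)
    a = estuary.axis(pts[:, 0], pts[:, 1])
    out = {}
    for p in surface.params:
        vals = surface.median_value(p, a)
        entry = {"mean": float(np.mean(vals))}
        if p in scheme.breaks:
            labels = categorize(vals, scheme, p)
            fr = {}
            for lab in scheme.labels:
                fr[lab] = 100.0 * float(np.mean(np.asarray(labels, dtype=object) == lab))
            entry["fractions"] = fr
        out[p] = entry
    return out
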