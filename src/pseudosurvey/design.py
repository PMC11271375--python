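"""Reconcile GRTS design points with the data grid and assemble scenario datasets.

A GRTS draw and the data hexagon grid are constructed independently, so more
than one design point can land in a single data hexagon.  Reconciliation keeps
only the *first chronologically generated* (lowest order_index) point per
hexagon; the survivors form the pseudo-probabilistic design framework.

A *scenario* pairs the design with composite sites for a chosen set of years:
design points whose hexagon has composite data carry those values, design
points in unsampled hexagons are retained with a not-sampled marker (their
area weight is reported as the "Not sampled" category downstream), and
composite hexagons without a design point are excluded.  All sites receive
the equal weight total_area / n_design_rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frame_grid import HexGrid, SampleFrame, assign_hex_ids
from .grts import GrtsSample
from .harmonize import PARAMETERS

__all__ = ["PseudoDesign", "AssessmentDataset", "reconcile", "build_scenario",
           "check_minimum", "MinimumSitesWarning"]

MINIMUM_SITES = 30  # design minimum for 90%-confidence variance estimates


class MinimumSitesWarning(UserWarning):
    pass


@dataclass
class PseudoDesign:
    """Design points deduplicated to one per data hexagon."""

    points: pd.DataFrame          # order_index, x, y, hex_id
    dropped: pd.DataFrame         # points removed by the first-chronological rule

    @property
    def n_unique(self) -> int:
        return len(self.points)


@dataclass
class AssessmentDataset:
    """One scenario's analysis table: one row per design point.

    ``data`` columns: hex_id, x, y, weight, plus one column per parameter
    (NaN = not sampled).  Weights are equal and sum to the frame total area.
    """

    scenario: str
    data: pd.DataFrame
    parameters: list
    total_area: float

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def sampled(self, parameter: str) -> pd.DataFrame:
        return self.data[self.data[parameter].notna()]


def reconcile(sample: GrtsSample, grid: HexGrid) -> PseudoDesign:
    """Keep, per data hexagon, the design point with the smallest order_index."""
    df = sample.points.copy()
    if "hex_id" not in df.columns:
        df["hex_id"] = assign_hex_ids(df[["x", "y"]].to_numpy(), grid)
    df = df.sort_values("order_index", kind="stable")
    keep = ~df.duplicated(subset="hex_id", keep="first")
    points = df[keep].reset_index(drop=True)
    dropped = df[~keep].reset_index(drop=True)
    return PseudoDesign(points=points, dropped=dropped)


def _geo_mean(v: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(v))))


def build_scenario(design: PseudoDesign, composites: pd.DataFrame,
                   years, frame: SampleFrame, *, sources=None,
                   scenario: str | None = None,
                   parameters=None) -> AssessmentDataset:
    """Assemble the per-scenario assessment dataset.

    ``composites`` is the tidy composite table (hex_id, year, x, y, parameter,
    value).  Multi-year scenarios aggregate a hexagon's yearly composites by
    geometric mean across years (arithmetic mean for parameters without
    positive support).  ``sources``, if given, requires a ``source`` column on
    the composite table (source selection normally happens before
    compositing).
    """
    years = sorted(set(int(y) for y in years)) if years is not None else None
    comp = composites.copy()
    if sources is not None:
        if "source" not in comp.columns:
            raise ValueError(
                "composites carry no 'source' column; filter records by source "
                "before compositing instead")
        comp = comp[comp["source"].isin(list(sources))]
    if years is not None:
        comp = comp[comp["year"].isin(years)]

    if parameters is None:
        parameters = sorted(set(comp["parameter"].unique()) or PARAMETERS)
        if not parameters:
            parameters = sorted(PARAMETERS)

    rows = design.points[["order_index", "x", "y", "hex_id"]].copy()
    n_eff = len(rows)
    rows["weight"] = frame.total_area / n_eff

    for p in parameters:
        sub = comp[comp["parameter"] == p]
        if sub.empty:
            rows[p] = np.nan
            continue
        spec = PARAMETERS.get(p)
        if spec is not None and spec.positive_support:
            agg = sub.groupby("hex_id")["value"].apply(lambda v: _geo_mean(v.to_numpy()))
        else:
            agg = sub.groupby("hex_id")["value"].mean()
        rows[p] = rows["hex_id"].map(agg)

    label = scenario or (f"{years[0]}-{years[-1]}" if years else "all-years")
    return AssessmentDataset(scenario=label, data=rows.reset_index(drop=True),
                             parameters=list(parameters), total_area=frame.total_area)


def check_minimum(dataset: AssessmentDataset, minimum: int = MINIMUM_SITES) -> bool:
    """Warn (not fail) when a scenario has fewer design rows than the minimum.

    The minimum of 30 spatially balanced sites is the design rationale for
    90 % confidence in population variance estimates.
    """
    ok = dataset.n_rows >= minimum
    if not ok:
        warnings.warn(
            f"scenario {dataset.scenario!r} has {dataset.n_rows} sites, below the "
            f"design minimum of {minimum} needed for 90%-confidence variance estimates",
            MinimumSitesWarning, stacklevel=2)
    return ok
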