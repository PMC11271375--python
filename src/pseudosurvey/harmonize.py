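"""Screening, standardization and compositing of secondary water-quality records.

Secondary monitoring data arrive from multiple programs with different designs,
units, qualifier vocabularies and visit frequencies.  This module turns a raw
record table into per-hexagon, per-year *composite sites*:

1.  screen records to the summer index window, drop duplicates, unit-less
    values and exclusion-qualified results (every exclusion is logged with a
    machine-readable reason);
2.  average replicate measurements (e.g. upcast/downcast profile pairs);
3.  substitute non-detects with the practical quantitation limit if reported,
    else the method detection limit;
4.  standardize units, including specific conductance (µS/cm at 25 °C) to
    practical salinity via the PSS-78 polynomial and dissolved-oxygen percent
    saturation to mg/L via the Benson–Krause equilibrium solubility;
5.  flag (never auto-drop) values beyond 3 interquartile ranges of Q1/Q3;
6.  flag and by default drop freshwater site-visits (salinity ≤ 0.05 pss);
7.  Winsorize each parameter group at the central 99 % band;
8.  composite by hexagon and year with the geometric mean, locating each
    composite at the mean coordinates of its contributing sites.

The pipeline order is fixed, and identical input + config reproduces identical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frame_grid import HexGrid, assign_hex_ids

__all__ = [
    "ParameterSpec",
    "PARAMETERS",
    "UnitError",
    "screen_records",
    "resolve_replicates",
    "substitute_nondetects",
    "conductance_to_salinity",
    "salinity_to_conductance",
    "oxygen_solubility_mgL",
    "do_percent_to_mgL",
    "do_mgL_to_percent",
    "standardize_units",
    "flag_outliers",
    "flag_freshwater",
    "winsorize",
    "composite",
    "harmonize_records",
    "HarmonizeResult",
]


@dataclass(frozen=True)
class ParameterSpec:
    code: str
    standard_unit: str
    positive_support: bool


#: Registry of assessed parameters and the unit each is standardized to.
PARAMETERS = {
    "CHLA": ParameterSpec("CHLA", "ug/L", True),
    "DO_MGL": ParameterSpec("DO_MGL", "mg/L", True),
    "ENTERO": ParameterSpec("ENTERO", "MPN/100mL", True),
    "PH": ParameterSpec("PH", "su", False),
    "SAL": ParameterSpec("SAL", "pss", True),
    "TEMP": ParameterSpec("TEMP", "degC", False),
    "TN": ParameterSpec("TN", "mg/L", True),
    "TP": ParameterSpec("TP", "mg/L", True),
}

INDEX_MONTHS = (6, 7, 8, 9)  # June–September summer index period

_ND_MARKERS = {"nd", "n.d.", "not detected", "nondetect", "non-detect", "u", ""}

_UNIT_ALIASES = {
    "µg/l": "ug/L", "ug/l": "ug/L", "ppb": "ug/L",
    "mg/l": "mg/L", "ppm": "mg/L",
    "mpn/100ml": "MPN/100mL", "mpn/100 ml": "MPN/100mL", "cfu/100ml": "MPN/100mL",
    "su": "su", "scale": "su", "ph units": "su", "std units": "su",
    "pss": "pss", "psu": "pss", "ppt": "pss",
    "us/cm": "uS/cm", "µs/cm": "uS/cm", "umho/cm": "uS/cm",
    "degc": "degC", "c": "degC", "deg c": "degC", "celsius": "degC",
    "degf": "degF", "f": "degF",
    "%": "%sat", "% sat": "%sat", "%sat": "%sat", "% saturation": "%sat",
}


class UnitError(ValueError):
    """Raised when units within a replicate group or conversion are inconsistent."""


def _norm_unit(u) -> str:
    if u is None or (isinstance(u, float) and np.isnan(u)):
        return ""
    s = str(u).strip()
    return _UNIT_ALIASES.get(s.lower(), s)


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

# PSS-78 practical-salinity polynomial coefficients (sum = 35 at R = 1)
_PSS_A = np.array([0.0080, -0.1692, 25.3851, 14.0941, -7.0261, 2.7081])
_SC_REF = 53_087.0  # µS/cm of the KCl reference solution at 25 °C


def conductance_to_salinity(specific_conductance):
    """Practical salinity (pss) from specific conductance (µS/cm at 25 °C).

    Evaluates the PSS-78 polynomial ``S = sum a_k R^(k/2)`` with
    ``R = SC / 53087``; small negative outputs near zero conductance are
    clamped to 0.  Assumes the conductance is already temperature-compensated
    to 25 °C ("specific" conductance).
    """
    sc = np.asarray(specific_conductance, dtype=float)
    if np.any(sc < 0):
        raise ValueError("specific conductance must be non-negative")
    r = np.sqrt(sc / _SC_REF)
    s = np.polyval(_PSS_A[::-1], r)
    # the polynomial is unreliable below ~2 pss; zero conductance is fresh water
    s = np.where(r == 0.0, 0.0, np.clip(s, 0.0, None))
    return float(s) if np.isscalar(specific_conductance) else s


def salinity_to_conductance(salinity: float) -> float:
    """Numeric inverse of :func:`conductance_to_salinity` (for generators/tests)."""
    from scipy.optimize import brentq

    if salinity <= 0:
        return 0.0
    return brentq(lambda sc: conductance_to_salinity(sc) - salinity, 0.0, 200_000.0)


def oxygen_solubility_mgL(temp_c, salinity=0.0):
    """Benson–Krause equilibrium DO solubility (mg/L) at 1 atm.

    ``ln C*`` polynomial in inverse Kelvin with a salinity correction; valid
    for roughly -2–40 °C.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < -2.0) or np.any(t > 40.0):
        raise ValueError("temperature outside physical range [-2, 40] degC")
    s = np.asarray(salinity, dtype=float)
    tk = t + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.243800e10 / tk**3
        - 8.621949e11 / tk**4
        - s * (0.017674 - 10.754 / tk + 2140.7 / tk**2)
    )
    c = np.exp(ln_c)
    return float(c) if np.isscalar(temp_c) else c


def do_percent_to_mgL(pct_saturation, temp_c, salinity):
    """Dissolved oxygen mg/L from % saturation at a given temperature/salinity."""
    p = np.asarray(pct_saturation, dtype=float)
    if np.any(p < 0):
        raise ValueError("percent saturation must be non-negative")
    out = p / 100.0 * oxygen_solubility_mgL(temp_c, salinity)
    return float(out) if np.isscalar(pct_saturation) else out


def do_mgL_to_percent(mg_l, temp_c, salinity):
    """Inverse of :func:`do_percent_to_mgL` at the same temperature/salinity."""
    m = np.asarray(mg_l, dtype=float)
    out = 100.0 * m / oxygen_solubility_mgL(temp_c, salinity)
    return float(out) if np.isscalar(mg_l) else out


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = ["site_id", "source", "x", "y", "datetime", "parameter",
                      "value", "unit", "qualifiers", "mdl", "pql", "depth_m"]


def _canonicalize(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df = df.rename(columns={"lon": "x", "lat": "y"})
    for col in _CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def _parse_value(v):
    """Return (numeric value or nan, is_nondetect, is_bad)."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan, True, False
    if isinstance(v, (int, float, np.floating, np.integer)):
        return float(v), False, False
    s = str(v).strip()
    if s.lower() in _ND_MARKERS:
        return np.nan, True, False
    try:
        return float(s), False, False
    except ValueError:
        return np.nan, False, True


def screen_records(records: pd.DataFrame,
                   index_months=INDEX_MONTHS,
                   years=None,
                   qualifier_rules: dict | None = None,
                   max_depth_m: float = 0.5):
    """Screen raw records; return ``(kept, exclusion_log)``.

    ``qualifier_rules`` maps qualifier codes to ``"keep"``, ``"exclude"`` or
    ``"review"``; unknown codes default to ``"review"`` (kept, logged).
    Duplicates (same site, datetime, parameter, value, source) collapse to one.
    """
    df = _canonicalize(records).reset_index(drop=True)
    qualifier_rules = qualifier_rules or {}
    reasons = pd.Series("", index=df.index, dtype=object)
    log_rows = []

    def exclude(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    # coordinates / datetime
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    df["x"], df["y"] = x, y
    exclude(x.isna() | y.isna(), "missing-coordinates")
    dt = pd.to_datetime(df["datetime"], errors="coerce", format="mixed")
    df["datetime"] = dt
    exclude(dt.isna(), "bad-datetime")

    # parameter registry
    df["parameter"] = df["parameter"].astype(str).str.upper().str.strip()
    exclude(~df["parameter"].isin(PARAMETERS), "unknown-parameter")

    # index window
    exclude(dt.notna() & ~dt.dt.month.isin(list(index_months)), "outside-index-months")
    if years is not None:
        exclude(dt.notna() & ~dt.dt.year.isin(list(years)), "outside-index-years")

    # surface measurements only
    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    exclude(depth.notna() & (depth > max_depth_m), "below-surface-depth")

    # values
    parsed = df["value"].map(_parse_value)
    df["value"] = [p[0] for p in parsed]
    df["nondetect"] = [p[1] for p in parsed]
    bad = pd.Series([p[2] for p in parsed], index=df.index)
    exclude(bad, "bad-value")

    # units: required except for unitless pH
    df["unit"] = df["unit"].map(_norm_unit)
    needs_unit = df["parameter"] != "PH"
    exclude(needs_unit & (df["unit"] == ""), "no-unit")
    df.loc[(df["parameter"] == "PH") & (df["unit"] == ""), "unit"] = "su"

    # qualifiers
    quals = df["qualifiers"].fillna("").astype(str)
    df["qualifiers"] = quals
    dispositions = []
    for q in quals:
        codes = [c.strip() for c in q.replace(",", ";").split(";") if c.strip()]
        disp = "keep"
        for c in codes:
            rule = qualifier_rules.get(c, "review")
            if rule == "exclude":
                disp = "exclude"
                break
            if rule == "review":
                disp = "review"
        dispositions.append(disp)
    disp = pd.Series(dispositions, index=df.index)
    exclude(disp == "exclude", "exclusion-qualifier")
    for i in df.index[(disp == "review") & (reasons == "")]:
        log_rows.append({"index": i, "reason": "review-qualifier-kept",
                         "detail": df.at[i, "qualifiers"]})

    # duplicates: identical site, datetime, parameter, value, source
    dup = df.duplicated(subset=["site_id", "datetime", "parameter", "value", "source"],
                        keep="first")
    exclude(dup & (reasons == ""), "duplicate")

    excluded = reasons != ""
    for i in df.index[excluded]:
        log_rows.append({"index": i, "reason": reasons[i], "detail": ""})
    log = pd.DataFrame(log_rows, columns=["index", "reason", "detail"])
    kept = df[~excluded].copy()
    kept["year"] = kept["datetime"].dt.year
    kept["month"] = kept["datetime"].dt.month
    return kept, log


# ---------------------------------------------------------------------------
# replicates & non-detects
# ---------------------------------------------------------------------------

def resolve_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate measurements (same site, datetime, parameter) to their mean.

    Detected values are averaged arithmetically; a group that is entirely
    non-detect keeps a single non-detect record (largest reported limits).
    Mixed units within a group raise :class:`UnitError`.
    """
    keys = ["site_id", "datetime", "parameter"]
    out = []
    for key, g in records.groupby(keys, dropna=False, sort=False):
        if g["unit"].nunique() > 1:
            raise UnitError(f"mixed units {sorted(g['unit'].unique())} in replicate group {key}")
        if len(g) == 1:
            out.append(g.iloc[0])
            continue
        row = g.iloc[0].copy()
        det = g[~g["nondetect"]]
        if len(det):
            row["value"] = det["value"].mean()
            row["nondetect"] = False
        else:
            row["mdl"] = g["mdl"].max()
            row["pql"] = g["pql"].max()
        out.append(row)
    return pd.DataFrame(out).reset_index(drop=True)


def substitute_nondetects(records: pd.DataFrame):
    """Replace non-detects with PQL if reported, else MDL; flag substitutions.

    Records with neither limit are excluded and logged.
    Returns ``(records, exclusion_log)``.
    """
    df = records.copy().reset_index(drop=True)
    mdl = pd.to_numeric(df["mdl"], errors="coerce")
    pql = pd.to_numeric(df["pql"], errors="coerce")
    nd = df["nondetect"].astype(bool)
    sub = pql.where(pql.notna(), mdl)
    df["nondetect_substituted"] = False
    use = nd & sub.notna()
    df.loc[use, "value"] = sub[use]
    df.loc[use, "nondetect_substituted"] = True
    drop = nd & sub.isna()
    log = pd.DataFrame({"index": df.index[drop], "reason": "nondetect-no-limit",
                        "detail": ""})
    return df[~drop].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# unit standardization
# ---------------------------------------------------------------------------

def standardize_units(records: pd.DataFrame):
    """Convert every value to its parameter's standard unit.

    Supported conversions: SAL from specific conductance (uS/cm); TEMP from
    degF; DO_MGL from % saturation (needs a same-visit TEMP and SAL value —
    records lacking them are excluded); mg/L↔ug/L scaling for CHLA/TN/TP.
    Unconvertible units are excluded and logged.
    Returns ``(records, exclusion_log)``.
    """
    df = records.copy().reset_index(drop=True)
    log_rows = []
    drop = np.zeros(len(df), dtype=bool)

    scale = {("CHLA", "mg/L"): 1e3, ("TN", "ug/L"): 1e-3, ("TP", "ug/L"): 1e-3}

    for i in df.index:
        p, u = df.at[i, "parameter"], df.at[i, "unit"]
        std = PARAMETERS[p].standard_unit
        if u == std:
            continue
        if (p, u) in scale:
            df.at[i, "value"] = df.at[i, "value"] * scale[(p, u)]
            df.at[i, "unit"] = std
        elif p == "SAL" and u == "uS/cm":
            df.at[i, "value"] = conductance_to_salinity(df.at[i, "value"])
            df.at[i, "unit"] = std
        elif p == "TEMP" and u == "degF":
            df.at[i, "value"] = (df.at[i, "value"] - 32.0) / 1.8
            df.at[i, "unit"] = std
        elif p == "DO_MGL" and u == "%sat":
            continue  # second pass, needs covariates
        else:
            drop[i] = True
            log_rows.append({"index": i, "reason": "unconvertible-unit",
                             "detail": f"{p} [{u}]"})

    # second pass: DO % saturation using same-visit standardized TEMP and SAL
    temp_lu = {k: v for k, v in
               df[(df.parameter == "TEMP") & (df.unit == "degC")]
               .groupby(["site_id", "datetime"])["value"].mean().items()}
    sal_lu = {k: v for k, v in
              df[(df.parameter == "SAL") & (df.unit == "pss")]
              .groupby(["site_id", "datetime"])["value"].mean().items()}
    for i in df.index:
        if drop[i] or not (df.at[i, "parameter"] == "DO_MGL" and df.at[i, "unit"] == "%sat"):
            continue
        key = (df.at[i, "site_id"], df.at[i, "datetime"])
        t, s = temp_lu.get(key), sal_lu.get(key)
        if t is None or s is None:
            drop[i] = True
            log_rows.append({"index": i, "reason": "do-conversion-missing-covariates",
                             "detail": str(key)})
        else:
            df.at[i, "value"] = do_percent_to_mgL(df.at[i, "value"], t, s)
            df.at[i, "unit"] = "mg/L"

    log = pd.DataFrame(log_rows, columns=["index", "reason", "detail"])
    return df[~drop].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# outliers, freshwater screen, winsorization
# ---------------------------------------------------------------------------

def iqr_fences(values) -> tuple:
    """(lower, upper) review fences at Q1 - 3 IQR and Q3 + 3 IQR."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - 3.0 * iqr, q3 + 3.0 * iqr


def flag_outliers(records: pd.DataFrame) -> pd.DataFrame:
    """Flag values beyond 3 IQR of Q1/Q3 within each parameter group (review only)."""
    df = records.copy()
    df["outlier_candidate"] = False
    for p, g in df.groupby("parameter"):
        if len(g) < 4:
            continue
        lo, hi = iqr_fences(g["value"])
        df.loc[g.index, "outlier_candidate"] = (g["value"] < lo) | (g["value"] > hi)
    return df


def flag_freshwater(records: pd.DataFrame) -> pd.DataFrame:
    """Flag every record of a site-visit whose salinity is ≤ 0.05 pss."""
    df = records.copy()
    df["freshwater"] = False
    sal = df[(df.parameter == "SAL")].groupby(["site_id", "datetime"])["value"].mean()
    fresh_visits = set(sal.index[sal <= 0.05])
    if fresh_visits:
        key = list(zip(df["site_id"], df["datetime"]))
        df["freshwater"] = [k in fresh_visits for k in key]
    return df


def winsorize(values, level: float = 0.99):
    """Clamp values outside the central ``level`` percentile band.

    A 99 % Winsorization clamps below the 0.5th and above the 99.5th
    percentile (two tails totalling 1 %); order statistics inside the band
    are untouched.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return v.copy()
    tail = round((1.0 - level) / 2.0, 12)  # e.g. exactly 0.005 for level=0.99
    lo, hi = np.quantile(v, [tail, 1.0 - tail])
    return np.clip(v, lo, hi)


def winsorize_records(records: pd.DataFrame, level: float = 0.99) -> pd.DataFrame:
    df = records.copy()
    df["winsorized"] = False
    for p, g in df.groupby("parameter"):
        if len(g) < 2:
            continue
        clamped = winsorize(g["value"].to_numpy(), level)
        changed = clamped != g["value"].to_numpy()
        df.loc[g.index, "value"] = clamped
        df.loc[g.index, "winsorized"] = changed
    return df


# ---------------------------------------------------------------------------
# compositing
# ---------------------------------------------------------------------------

def _resolve_zeros(g: pd.DataFrame, param: str) -> pd.DataFrame:
    """Substitute non-positive values of positive-support parameters.

    Replacement is the smaller of the reported MDL and half the minimum
    positive observed value in the parameter group (geometric means are
    undefined at zero; this mirrors the non-detect substitution rule).
    """
    v = g["value"].to_numpy(dtype=float)
    bad = v <= 0
    if not bad.any():
        return g
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError(f"all values non-positive for positive-support parameter {param}")
    half_min = 0.5 * pos.min()
    mdl = pd.to_numeric(g["mdl"], errors="coerce").to_numpy()
    repl = np.where(np.isfinite(mdl), np.minimum(mdl, half_min), half_min)
    if np.any(repl[bad] <= 0):
        i = g.index[bad][repl[bad] <= 0][0]
        raise ValueError(f"cannot resolve non-positive value for {param} at record {i}")
    g = g.copy()
    g.loc[g.index[bad], "value"] = repl[bad]
    return g


def composite(records: pd.DataFrame, grid: HexGrid) -> pd.DataFrame:
    """Composite clean records into per-(hexagon, year) geometric-mean sites.

    Returns a tidy frame with columns ``hex_id, year, x, y, parameter, value,
    n_records``; ``x, y`` are the arithmetic mean coordinates of the distinct
    site locations contributing to that hexagon-year.
    """
    df = records.copy()
    if "hex_id" not in df.columns or df["hex_id"].isna().any():
        df["hex_id"] = assign_hex_ids(df[["x", "y"]].to_numpy(), grid)

    pieces = []
    for p in sorted(df["parameter"].unique()):
        gp = df[df["parameter"] == p]
        if PARAMETERS[p].positive_support:
            gp = _resolve_zeros(gp, p)
            if (gp["value"] <= 0).any():
                i = gp.index[gp["value"] <= 0][0]
                raise ValueError(f"non-positive {p} value at record {i} reached compositing")
            agg = gp.groupby(["hex_id", "year"])["value"].agg(
                value=lambda v: float(np.exp(np.mean(np.log(v)))), n_records="size")
        else:
            # geometric mean is inappropriate for pH/temperature scales
            agg = gp.groupby(["hex_id", "year"])["value"].agg(value="mean", n_records="size")
        agg = agg.reset_index()
        agg["parameter"] = p
        pieces.append(agg)
    out = pd.concat(pieces, ignore_index=True)

    loc = (df.drop_duplicates(subset=["hex_id", "year", "site_id", "x", "y"])
             .groupby(["hex_id", "year"])[["x", "y"]].mean().reset_index())
    out = out.merge(loc, on=["hex_id", "year"], how="left")
    return out[["hex_id", "year", "x", "y", "parameter", "value", "n_records"]]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class HarmonizeResult:
    composites: pd.DataFrame
    clean: pd.DataFrame
    exclusions: pd.DataFrame
    counts: dict = field(default_factory=dict)


def harmonize_records(records: pd.DataFrame, grid: HexGrid, *,
                      index_months=INDEX_MONTHS, years=None,
                      qualifier_rules: dict | None = None,
                      drop_freshwater: bool = True,
                      winsor_level: float | None = 0.99,
                      sources=None) -> HarmonizeResult:
    """Run the full harmonization pipeline in its fixed order.

    ``sources`` optionally restricts the record pool (source selection must
    happen before compositing, because composites pool all records in a
    hexagon-year).
    """
    df = _canonicalize(records)
    counts = {"input": len(df)}
    if sources is not None:
        df = df[df["source"].isin(list(sources))].reset_index(drop=True)
    counts["after_source_filter"] = len(df)

    logs = []
    kept, log = screen_records(df, index_months=index_months, years=years,
                               qualifier_rules=qualifier_rules)
    logs.append(log.assign(stage="screen"))
    counts["after_screen"] = len(kept)

    kept = resolve_replicates(kept)
    counts["after_replicates"] = len(kept)

    kept, log = substitute_nondetects(kept)
    logs.append(log.assign(stage="nondetect"))
    kept, log = standardize_units(kept)
    logs.append(log.assign(stage="units"))
    counts["after_units"] = len(kept)

    kept = flag_outliers(kept)
    kept = flag_freshwater(kept)
    if drop_freshwater:
        dropped = kept[kept["freshwater"]]
        logs.append(pd.DataFrame({"index": dropped.index, "reason": "freshwater",
                                  "detail": "", "stage": "freshwater"}))
        kept = kept[~kept["freshwater"]].reset_index(drop=True)
    counts["after_freshwater"] = len(kept)

    if winsor_level is not None:
        kept = winsorize_records(kept, winsor_level)

    composites = composite(kept, grid)
    counts["composites"] = len(composites)

    exclusions = (pd.concat(logs, ignore_index=True)
                  if logs else pd.DataFrame(columns=["index", "reason", "detail", "stage"]))
    return HarmonizeResult(composites=composites, clean=kept,
                           exclusions=exclusions, counts=counts)
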