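"""Design-based estimation: weighted CDF, category, mean and change estimates.

All estimators are Horvitz–Thompson style: each site carries an inclusion
weight in km² and the estimated percent of resource area with some property is
the weighted share of sites with that property.  Standard errors come from the
local-mean (neighbourhood) variance estimator for continuous-resource surveys:
each site's estimator contribution is contrasted against a smoothed local mean
over its ~4 nearest sites, capturing the variance reduction that spatial
balance buys relative to independent random sampling.  Confidence limits are
normal-approximation (z) intervals, clipped to [0, 100] on the percent scale.

Threshold schemes map continuous values to condition categories: a *quartile*
scheme (Low / Moderate / High around the 25th and 75th percentile breaks,
boundary values falling in Moderate) or a *criteria* scheme (Above strictly
exceeding a regulatory threshold, else At/Below).  Missing values map to
"Not sampled", which is a first-class category carrying its area weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .design import AssessmentDataset

__all__ = [
    "NOT_SAMPLED", "ThresholdScheme", "default_quartile_scheme",
    "florida_criteria_scheme", "local_mean_weights", "local_mean_var",
    "ht_mean", "ht_percent", "weighted_cdf", "categorize", "category_estimates",
    "mean_estimate", "MeanEstimate", "change_estimate",
]

NOT_SAMPLED = "Not sampled"

Z95 = 1.959963984540054
Z90 = 1.6448536269514722


# ---------------------------------------------------------------------------
# threshold schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdScheme:
    """Ordered cutpoints and category labels per parameter.

    ``kind`` is ``"quartile"`` (two breaks, labels Low/Moderate/High) or
    ``"criteria"`` (one break, labels At/Below / Above).
    """

    kind: str
    breaks: dict
    labels: tuple

    def __post_init__(self):
        for p, b in self.breaks.items():
            bb = tuple(b)
            if any(bb[i] >= bb[i + 1] for i in range(len(bb) - 1)):
                raise ValueError(f"breaks for {p} must be strictly increasing: {bb}")
            if len(self.labels) != len(bb) + 1:
                raise ValueError("label count must equal interval count")

    @property
    def categories(self) -> tuple:
        return tuple(self.labels) + (NOT_SAMPLED,)


def default_quartile_scheme() -> ThresholdScheme:
    """25th/75th-percentile breaks of the pooled raw demonstration data."""
    return ThresholdScheme(
        kind="quartile",
        breaks={
            "CHLA": (1.80, 6.55),
            "DO_MGL": (5.88, 7.09),
            "ENTERO": (5.0, 20.0),
            "PH": (7.6, 8.1),
            "SAL": (0.12, 1.1),
            "TEMP": (28.7, 31.0),
            "TN": (0.305, 0.492),
            "TP": (0.013, 0.027),
        },
        labels=("Low", "Moderate", "High"),
    )


def florida_criteria_scheme() -> ThresholdScheme:
    """Mean Florida surface-water-quality criteria for the study estuaries."""
    return ThresholdScheme(
        kind="criteria",
        breaks={
            "CHLA": (5.44,),
            "DO_MGL": (5.54,),
            "ENTERO": (35.0,),
            "PH": (6.5,),
            "SAL": (0.5,),
            "TEMP": (28.3,),
        },
        labels=("At/Below", "Above"),
    )


def categorize(value, scheme: ThresholdScheme, parameter: str):
    """Category label(s) for a value; NaN maps to "Not sampled".

    Quartile kind: strictly below the first break ⇒ first label, strictly
    above the last break ⇒ last label, boundary values ⇒ middle.  Criteria
    kind: strictly above the threshold ⇒ "Above".
    """
    if parameter not in scheme.breaks:
        raise KeyError(f"parameter {parameter!r} not in scheme")
    breaks = scheme.breaks[parameter]
    v = np.atleast_1d(np.asarray(value, dtype=float))
    out = np.full(v.shape, NOT_SAMPLED, dtype=object)
    ok = np.isfinite(v)
    if len(breaks) == 1:  # criteria: "Above" requires strict exceedance
        out[ok & (v <= breaks[0])] = scheme.labels[0]
        out[ok & (v > breaks[0])] = scheme.labels[1]
    else:  # quartile: boundary values fall in the middle category
        out[ok] = scheme.labels[1]
        out[ok & (v < breaks[0])] = scheme.labels[0]
        out[ok & (v > breaks[-1])] = scheme.labels[-1]
    if np.isscalar(value) or np.ndim(value) == 0:
        return out.item()
    return out


# ---------------------------------------------------------------------------
# local-mean variance machinery
# ---------------------------------------------------------------------------

def local_mean_weights(coords: np.ndarray, nbh: int = 4, max_iter: int = 100,
                       tol: float = 1e-10) -> np.ndarray:
    """Row/column-normalized neighbourhood smoothing weights.

    Each site's neighbourhood is its ``nbh`` nearest sites (self-inclusive,
    uniform initial weights); iterative proportional fitting then balances row
    and column sums toward 1.  Returns a dense (n, n) matrix with rows summing
    to 1.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 sites")
    k = min(nbh, n)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k)
    idx = np.atleast_2d(idx)
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    w[rows, idx.ravel()] = 1.0 / k
    for _ in range(max_iter):
        rs = w.sum(axis=1, keepdims=True)
        w /= rs
        cs = w.sum(axis=0, keepdims=True)
        w /= np.where(cs > 0, cs, 1.0)
        if (np.abs(w.sum(axis=1) - 1).max() < tol
                and np.abs(w.sum(axis=0) - 1).max() < tol):
            break
    w /= w.sum(axis=1, keepdims=True)
    return w


def local_mean_var(z: np.ndarray, weights: np.ndarray) -> float:
    """Neighbourhood variance: weighted squared deviations from local means.

    Each neighbourhood's contribution is divided by ``1 - sum_j w_ij**2``, the
    weighted-variance analogue of Bessel's correction: a plain weighted sum of
    squared deviations from a mean estimated inside the same small
    neighbourhood shrinks the variance by exactly that factor for exchangeable
    values.
    """
    z = np.asarray(z, dtype=float)
    zbar = weights @ z
    contrib = np.sum(weights * (z[None, :] - zbar[:, None]) ** 2, axis=1)
    denom = 1.0 - np.sum(weights**2, axis=1)
    denom = np.where(denom > 1e-12, denom, 1.0)
    return float(np.sum(contrib / denom))


def _degenerate_coords(coords: np.ndarray) -> bool:
    return len(np.unique(np.asarray(coords, dtype=float), axis=0)) < 4


def _srs_var_of_ratio_mean(y, w, mu) -> float:
    # with-replacement SRS approximation for the ratio mean
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = len(y)
    z = w * (y - mu) / w.sum()
    return float(np.sum(z**2) * n / max(n - 1, 1))


def ht_mean(y, w) -> float:
    """Horvitz–Thompson ratio mean over sampled sites."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(w * y) / np.sum(w))


def ht_mean_variance(y, w, coords, nbh: int = 4) -> float:
    """Variance of the HT ratio mean via the local-mean estimator.

    Falls back (with a warning) to the with-replacement SRS variance when
    fewer than 4 sites or degenerate coordinates make neighbourhoods
    meaningless.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    coords = np.asarray(coords, dtype=float)
    mu = ht_mean(y, w)
    if len(y) < 4 or _degenerate_coords(coords):
        warnings.warn("fewer than 4 distinct site locations; using SRS variance",
                      stacklevel=2)
        return _srs_var_of_ratio_mean(y, w, mu)
    z = w * (y - mu) / w.sum()
    wmat = local_mean_weights(coords, nbh=nbh)
    return local_mean_var(z, wmat)


def ht_percent(indicator, w) -> float:
    """Percent of total weight where ``indicator`` is true (0–100)."""
    return 100.0 * ht_mean(np.asarray(indicator, dtype=float), w)


# ---------------------------------------------------------------------------
# CDF estimation
# ---------------------------------------------------------------------------

def weighted_cdf(values, weights, coords, x_grid=None, nbh: int = 4) -> pd.DataFrame:
    """Estimated percent of area with parameter value ≤ x, with 95 % limits.

    Returns a DataFrame with columns ``x, p_hat, se, ci_low, ci_high``;
    ``p_hat`` is non-decreasing and reaches 100 at the sample maximum, and
    limits are clipped to [0, 100].
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    coords = np.asarray(coords, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need at least 2 sampled observations for a CDF estimate")
    y, w, coords = y[ok], w[ok], coords[ok]
    if x_grid is None:
        x_grid = np.unique(y)
    x_grid = np.asarray(x_grid, dtype=float)

    wsum = w.sum()
    use_local = len(y) >= 4 and not _degenerate_coords(coords)
    wmat = local_mean_weights(coords, nbh=nbh) if use_local else None

    p_hat = np.empty_like(x_grid)
    se = np.empty_like(x_grid)
    for j, x in enumerate(x_grid):
        ind = (y <= x).astype(float)
        p = float(np.sum(w * ind) / wsum)
        p_hat[j] = 100.0 * p
        z = w * (ind - p) / wsum
        if use_local:
            var = local_mean_var(z, wmat)
        else:
            var = float(np.sum(z**2) * len(y) / max(len(y) - 1, 1))
        se[j] = 100.0 * np.sqrt(max(var, 0.0))

    ci_low = np.clip(p_hat - Z95 * se, 0.0, 100.0)
    ci_high = np.clip(p_hat + Z95 * se, 0.0, 100.0)
    return pd.DataFrame({"x": x_grid, "p_hat": p_hat, "se": se,
                         "ci_low": ci_low, "ci_high": ci_high})


# ---------------------------------------------------------------------------
# categorical / continuous / change analyses
# ---------------------------------------------------------------------------

def category_estimates(dataset: AssessmentDataset, scheme: ThresholdScheme,
                       parameter: str, nbh: int = 4) -> pd.DataFrame:
    """Percent-of-area estimate per condition category (incl. "Not sampled").

    Each category's share is the HT-weighted share of total weight; standard
    errors come from the local-mean estimator applied to category indicators
    over all design rows.  Shares sum to exactly 100.
    """
    df = dataset.data
    w = df["weight"].to_numpy(dtype=float)
    coords = df[["x", "y"]].to_numpy(dtype=float)
    labels = categorize(df[parameter].to_numpy(dtype=float), scheme, parameter)
    labels = np.asarray(labels, dtype=object)
    wsum = w.sum()

    use_local = len(df) >= 4 and not _degenerate_coords(coords)
    wmat = local_mean_weights(coords, nbh=nbh) if use_local else None

    rows = []
    for cat in scheme.categories:
        ind = (labels == cat).astype(float)
        p = float(np.sum(w * ind) / wsum)
        z = w * (ind - p) / wsum
        if use_local:
            var = local_mean_var(z, wmat)
        else:
            var = float(np.sum(z**2) * len(df) / max(len(df) - 1, 1))
        se = 100.0 * np.sqrt(max(var, 0.0))
        pct = 100.0 * p
        rows.append({
            "category": cat, "pct_area": pct, "se": se, "moe": Z95 * se,
            "ci_low": max(pct - Z95 * se, 0.0), "ci_high": min(pct + Z95 * se, 100.0),
            "n_sites": int(ind.sum()),
        })
    out = pd.DataFrame(rows)
    assert abs(out["pct_area"].sum() - 100.0) < 1e-9
    return out


@dataclass(frozen=True)
class MeanEstimate:
    mean: float
    moe: float
    n_obs: int
    se: float = 0.0

    @property
    def ci(self) -> tuple:
        return (self.mean - self.moe, self.mean + self.moe)


def mean_estimate(dataset: AssessmentDataset, parameter: str,
                  confidence: float = 0.95, nbh: int = 4) -> MeanEstimate:
    """HT ratio mean of a parameter over sampled sites, with z-interval MOE."""
    sub = dataset.sampled(parameter)
    if len(sub) < 2:
        raise ValueError(f"fewer than 2 sampled values for {parameter}")
    y = sub[parameter].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    coords = sub[["x", "y"]].to_numpy(dtype=float)
    mu = ht_mean(y, w)
    var = ht_mean_variance(y, w, coords, nbh=nbh)
    from scipy.stats import norm
    z = norm.ppf(0.5 + confidence / 2.0)
    se = float(np.sqrt(max(var, 0.0)))
    return MeanEstimate(mean=mu, moe=z * se, n_obs=len(sub), se=se)


def change_estimate(dataset_a: AssessmentDataset, dataset_b: AssessmentDataset,
                    scheme: ThresholdScheme, parameter: str) -> pd.DataFrame:
    """Two-period change in percent-of-area per category (B minus A).

    Periods are treated as independent surveys, so the delta variance is the
    sum of the period variances; a change is flagged significant when its 95 %
    interval excludes zero.
    """
    a = category_estimates(dataset_a, scheme, parameter).set_index("category")
    b = category_estimates(dataset_b, scheme, parameter).set_index("category")
    rows = []
    for cat in scheme.categories:
        if cat not in a.index or cat not in b.index:
            raise KeyError(f"category {cat!r} missing from an estimate table")
        delta = b.at[cat, "pct_area"] - a.at[cat, "pct_area"]
        se = float(np.hypot(a.at[cat, "se"], b.at[cat, "se"]))
        lo, hi = delta - Z95 * se, delta + Z95 * se
        rows.append({"category": cat, "delta_pct": delta, "se": se,
                     "ci_low": lo, "ci_high": hi,
                     "significant": bool(lo > 0 or hi < 0)})
    return pd.DataFrame(rows)
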