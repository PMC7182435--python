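"""Pairwise developmental-variation statistic and its temporal profile.

The measure asks: among embryos of (nearly) the same computed age, how
different are their developmental states? For every within-strain pair of
embryos less than 0.25 cdpc apart, the developmental distance is the sum
over the four characters of the absolute score difference. Strains are
compared by a two-sided Wilcoxon rank-sum test on these pair distances, and
the temporal profile of variation is a LOESS curve of each embryo's mean
distance to its age-neighbours over cdpc.

The overlapping pairs are not independent samples; the rank-sum test is
applied to them as a descriptive comparison (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .devstate import DEFAULT_SCHEMA, DevState, ScoringSchema

__all__ = [
    "NeighborPair",
    "VariabilityProfile",
    "state_distance",
    "neighbor_pairs",
    "compare_strain_variability",
    "temporal_profile",
    "loess_fit",
]

DEFAULT_WINDOW = 0.25  # days; strict inequality


@dataclass(frozen=True)
class NeighborPair:
    """An unordered pair of age-matched embryos with their state distance."""

    embryo_a: str
    embryo_b: str
    delta_age: float
    distance: int


@dataclass
class VariabilityProfile:
    """Temporal profile of developmental variation.

    ``per_embryo``: embryo_id, cdpc, n_neighbors, mean_distance (embryos
    with no neighbour are dropped). ``curve``: grid of ages with the LOESS
    fit and a pointwise local weighted residual-sd band.
    """

    per_embryo: pd.DataFrame
    curve: pd.DataFrame


def state_distance(a: DevState, b: DevState, schema: ScoringSchema = DEFAULT_SCHEMA) -> int:
    """Sum over characters of the absolute score difference."""
    a.validate(schema)
    b.validate(schema)
    return int(sum(abs(x - y) for x, y in zip(a.scores, b.scores)))


def neighbor_pairs(
    embryos: pd.DataFrame,
    window: float = DEFAULT_WINDOW,
    within_strain: bool = True,
    schema: ScoringSchema = DEFAULT_SCHEMA,
    age_column: str = "cdpc",
) -> list[NeighborPair]:
    """All unordered pairs with age difference strictly below ``window``.

    Pairs are formed within strain by default (set ``within_strain=False``
    to pool strains). The embryo table needs the age column and the
    schema's score columns.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if age_column not in embryos.columns:
        raise ValueError(f"embryo table lacks the {age_column!r} column")
    cols = list(schema.columns)
    ids = embryos["embryo_id"].to_numpy()
    ages = embryos[age_column].to_numpy(float)
    scores = embryos[cols].to_numpy(int)
    strains = (
        embryos["strain"].to_numpy()
        if within_strain and "strain" in embryos.columns
        else np.zeros(len(embryos))
    )
    order = np.argsort(ages, kind="mergesort")
    pairs: list[NeighborPair] = []
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            d_age = ages[j] - ages[i]
            if d_age >= window:
                break
            if strains[i] != strains[j]:
                continue
            dist = int(np.abs(scores[i] - scores[j]).sum())
            pairs.append(
                NeighborPair(
                    embryo_a=str(ids[i]),
                    embryo_b=str(ids[j]),
                    delta_age=float(abs(d_age)),
                    distance=dist,
                )
            )
    return pairs


def _ranksum_statistic(x, y, axis=-1):
    """Rank sum of sample x within the pooled sample (vectorized)."""
    pooled = np.concatenate([x, y], axis=axis)
    ranks = sps.rankdata(pooled, axis=axis)
    nx = x.shape[axis]
    return np.take(ranks, np.arange(nx), axis=axis).sum(axis=axis)


def compare_strain_variability(
    pairs_a: list[NeighborPair] | np.ndarray,
    pairs_b: list[NeighborPair] | np.ndarray,
    exact_max_n: int = 25,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of pair-distance samples.

    Small samples (both n <= ``exact_max_n``) use the exact permutation
    null of the rank-sum statistic (full enumeration, valid with ties);
    larger samples use the normal approximation with tie correction.
    Returns the Mann-Whitney U statistic for group A, the p-value, group
    medians and sizes.
    """
    def _distances(pairs):
        if isinstance(pairs, (list, tuple)) and pairs and isinstance(pairs[0], NeighborPair):
            return np.array([p.distance for p in pairs], float)
        return np.asarray(pairs, float)

    da = _distances(pairs_a)
    db = _distances(pairs_b)
    if len(da) == 0 or len(db) == 0:
        raise ValueError("both groups must be non-empty")
    u_stat = float(sps.mannwhitneyu(da, db, alternative="two-sided", method="asymptotic").statistic)
    pooled = np.concatenate([da, db])
    small = len(da) <= exact_max_n and len(db) <= exact_max_n
    has_ties = len(np.unique(pooled)) < len(pooled)
    if small and np.ptp(pooled) == 0:
        p, method = 1.0, "exact"
    elif small and not has_ties:
        # tie-free small samples: scipy's exact rank-sum distribution
        p = float(sps.mannwhitneyu(da, db, alternative="two-sided", method="exact").pvalue)
        method = "exact"
    elif small and math.comb(len(da) + len(db), len(da)) <= 200_000:
        # ties, but full enumeration of group assignments is affordable
        res = sps.permutation_test(
            (da, db),
            _ranksum_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=math.inf,
            vectorized=True,
        )
        p, method = float(res.pvalue), "exact"
    else:
        p = float(sps.mannwhitneyu(da, db, alternative="two-sided", method="asymptotic").pvalue)
        method = "asymptotic"
    return {
        "U": u_stat,
        "p_value": p,
        "method": method,
        "median_a": float(np.median(da)),
        "median_b": float(np.median(db)),
        "n_a": int(len(da)),
        "n_b": int(len(db)),
    }


def loess_fit(
    x,
    y,
    span: float = 0.75,
    degree: int = 1,
    x_eval=None,
    return_sd: bool = False,
):
    """Locally weighted polynomial regression (LOESS) with tricube weights.

    For each evaluation point, the ``ceil(span * n)`` nearest observations
    (by |x - x0|) are fit by weighted least squares of the given degree,
    with tricube weights scaled by the furthest included neighbour's
    distance. ``degree`` 0 (local mean) and 1 (local line, the default and
    conventional choice) are supported. With ``return_sd=True`` the local
    weighted residual standard deviation is returned alongside.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if degree not in (0, 1):
        raise ValueError("degree must be 0 or 1")
    if len(x) < degree + 2:
        raise ValueError("need at least degree + 2 points")
    if not (0 < span <= 1):
        raise ValueError("span must lie in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: smoothing is undefined")
    x0s = x if x_eval is None else np.asarray(x_eval, float)
    n = len(x)
    k = max(int(math.ceil(span * n)), degree + 1)
    fitted = np.empty(len(x0s))
    sds = np.empty(len(x0s))
    for idx, x0 in enumerate(x0s):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
            if w.sum() == 0 or np.count_nonzero(w) <= degree:
                # everything in the window sits at distance h; fall back to
                # equal weights over the k nearest
                w = (d <= h).astype(float)
        if degree == 0:
            yhat = float(np.average(y, weights=w))
        else:
            xc = x - x0
            sw, swx = w.sum(), (w * xc).sum()
            swxx, swy, swxy = (w * xc * xc).sum(), (w * y).sum(), (w * xc * y).sum()
            det = sw * swxx - swx * swx
            if det <= 1e-14 * max(sw * swxx, 1e-300):
                yhat = float(swy / sw)
            else:
                yhat = float((swxx * swy - swx * swxy) / det)
        fitted[idx] = yhat
        if return_sd:
            if degree == 0:
                resid = y - yhat
            else:
                xc = x - x0
                slope = 0.0
                if det > 1e-14 * max(sw * swxx, 1e-300):
                    slope = float((sw * swxy - swx * swy) / det)
                resid = y - (yhat + slope * xc)
            sds[idx] = float(np.sqrt(np.average(resid**2, weights=w)))
    if return_sd:
        return fitted, sds
    return fitted


def temporal_profile(
    embryos: pd.DataFrame,
    window: float = DEFAULT_WINDOW,
    span: float = 0.75,
    degree: int = 1,
    schema: ScoringSchema = DEFAULT_SCHEMA,
    age_column: str = "cdpc",
    grid_points: int = 100,
) -> VariabilityProfile:
    """Mean neighbour distance per embryo, LOESS-smoothed over computed age.

    Embryos without any age-neighbour are excluded from the profile. The
    smoothed curve carries a pointwise band of the local weighted residual
    standard deviation.
    """
    pairs = neighbor_pairs(embryos, window=window, schema=schema, age_column=age_column)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in pairs:
        for e in (p.embryo_a, p.embryo_b):
            sums[e] = sums.get(e, 0.0) + p.distance
            counts[e] = counts.get(e, 0) + 1
    if not counts:
        raise ValueError("no embryo has an age-neighbour within the window")
    sub = embryos[embryos["embryo_id"].astype(str).isin(counts)].copy()
    eid = sub["embryo_id"].astype(str)
    per_embryo = pd.DataFrame(
        {
            "embryo_id": eid.to_numpy(),
            age_column: sub[age_column].to_numpy(float),
            "n_neighbors": [counts[e] for e in eid],
            "mean_distance": [sums[e] / counts[e] for e in eid],
        }
    ).sort_values(age_column, kind="mergesort").reset_index(drop=True)
    if len(per_embryo) < 5:
        raise ValueError("need at least 5 embryos with neighbours for a profile")
    xs = per_embryo[age_column].to_numpy()
    ys = per_embryo["mean_distance"].to_numpy()
    grid = np.linspace(xs.min(), xs.max(), grid_points)
    fit, sd = loess_fit(xs, ys, span=span, degree=degree, x_eval=grid, return_sd=True)
    curve = pd.DataFrame({age_column: grid, "fitted": fit, "sd": sd})
    return VariabilityProfile(per_embryo=per_embryo, curve=curve)
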