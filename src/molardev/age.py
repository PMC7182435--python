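"""Computed embryonic age (cdpc) from body weight and harvest dpc.

Harvest age in days post coitum (dpc) is only a rough guide to developmental
progress: litters differ by up to about half a day in conception time, and
embryos within a litter spread over up to a quarter day. Body weight is a
much better stage proxy within a litter, but between litters it is biased by
a pregnancy (nutrition) effect of up to ~10% of weight. The model here
combines both observations in a Bayesian hierarchical model, per strain:

* per litter j: conception offset ``c_j ~ Normal(0, sigma_c)`` truncated at
  +/- 0.75 d, and pregnancy multiplier ``m_j ~ Uniform(1-r, 1+r)`` with
  ``r`` the pregnancy-effect bound (0.10 realistic, 0.20 upper bound);
* per embryo i: true age ``a_ij = dpc_ij + c_j + u_ij`` with
  ``u_ij ~ Normal(0, sigma_u)``;
* likelihood ``log w_ij ~ Normal(log g_s(a_ij) + log m_j, sigma_eps)`` with
  ``g_s`` the strain's log-linear growth curve.

Because ``log g_s`` is linear in age, the within-litter jitter ``u``
integrates out analytically and the posterior over the two remaining latents
per litter, ``(c_j, m_j)``, is evaluated exactly on a dense grid. The
computed age is the posterior mean of ``a_ij`` (cdpc), with a central 95%
posterior interval from the exact normal-mixture posterior. The whole
computation is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthModel",
    "AgeModelConfig",
    "default_growth_model",
    "fit_growth_model",
    "compute_cdpc",
    "weight_only_age",
    "robustness_compare",
]

# weight range (mg) over which the growth curve is considered calibrated
CALIBRATED_RANGE_MG = (50.0, 600.0)


@dataclass(frozen=True)
class GrowthModel:
    """Strain-specific log-linear weight-age relation.

    ``log(weight mg) = log_w_ref + slope * (age - a_ref)``.
    """

    strain: str
    a_ref: float
    log_w_ref: float
    slope: float          # per day, must be positive
    residual_sd: float    # log-weight scale

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("growth slope must be positive (weight increases with age)")

    def predict_log_weight(self, age):
        return self.log_w_ref + self.slope * (np.asarray(age, float) - self.a_ref)

    def predict_weight(self, age):
        return np.exp(self.predict_log_weight(age))

    def invert(self, weight):
        """Age at which the curve passes through ``weight`` (mg)."""
        return self.a_ref + (np.log(np.asarray(weight, float)) - self.log_w_ref) / self.slope


def default_growth_model(strain: str = "FVB") -> GrowthModel:
    """The calibration anchored at 150 mg <-> 14.0 d and 250 mg <-> 15.0 d."""
    slope = float(np.log(250.0 / 150.0))
    return GrowthModel(
        strain=strain,
        a_ref=14.0,
        log_w_ref=float(np.log(150.0)),
        slope=slope,
        residual_sd=0.05,
    )


def fit_growth_model(embryos: pd.DataFrame, strain: str) -> GrowthModel:
    """Least-squares fit of log(weight) on dpc for one strain.

    Serves as the fixed growth curve g_s inside the hierarchical model.
    Requires at least two distinct harvest ages.
    """
    sub = embryos[embryos["strain"] == strain]
    if len(sub) == 0:
        raise ValueError(f"no embryos for strain {strain!r}")
    if (sub["weight_mg"] <= 0).any():
        raise ValueError("weights must be positive")
    dpc = sub["dpc"].to_numpy(float)
    if len(np.unique(dpc)) < 2:
        raise ValueError(
            "only one distinct dpc value: cannot fit a growth curve; "
            "supply a GrowthModel (e.g. default_growth_model()) instead"
        )
    logw = np.log(sub["weight_mg"].to_numpy(float))
    slope, intercept = np.polyfit(dpc, logw, 1)
    if slope <= 0:
        raise ValueError("fitted growth slope is non-positive; check the input table")
    resid = logw - (intercept + slope * dpc)
    dof = max(len(sub) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    a_ref = float(np.mean(dpc))
    return GrowthModel(
        strain=strain,
        a_ref=a_ref,
        log_w_ref=float(intercept + slope * a_ref),
        slope=float(slope),
        residual_sd=residual_sd,
    )


@dataclass(frozen=True)
class AgeModelConfig:
    """Priors and numerics of the hierarchical age model.

    ``pregnancy_effect_max`` is the bound r on the litter weight multiplier
    (0.10 realistic, 0.20 upper bound). ``residual_sd`` is the lognormal
    weight measurement noise; if None it is estimated from the pooled
    within-litter spread of log weight (subtracting the modeled
    within-litter age jitter contribution).
    """

    pregnancy_effect_max: float = 0.10
    conception_offset_sd: float = 0.25     # days
    conception_offset_bound: float = 0.75  # days
    within_litter_sd: float = 0.125        # days
    residual_sd: float | None = None       # log-weight scale
    grid_size: int = 41                    # per latent axis
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.pregnancy_effect_max < 1.0):
            raise ValueError("pregnancy_effect_max must lie in [0, 1)")
        if self.grid_size < 3:
            raise ValueError("grid_size must be >= 3")


def _estimate_residual_sd(
    embryos: pd.DataFrame, growth: GrowthModel, config: AgeModelConfig
) -> float:
    """Pooled within-litter log-weight variance minus the age-jitter part."""
    beta = growth.slope
    ss, dof = 0.0, 0
    for _, grp in embryos.groupby("litter_id"):
        if len(grp) < 2:
            continue
        lw = np.log(grp["weight_mg"].to_numpy(float))
        ss += float(np.sum((lw - lw.mean()) ** 2))
        dof += len(grp) - 1
    if dof == 0:
        return max(growth.residual_sd, 0.01)
    total_var = ss / dof
    eps_var = total_var - (beta * config.within_litter_sd) ** 2
    return float(np.sqrt(max(eps_var, 1e-4)))


def compute_cdpc(
    embryos: pd.DataFrame,
    growth: GrowthModel,
    config: AgeModelConfig = AgeModelConfig(),
    ci: bool = True,
) -> pd.DataFrame:
    """Posterior computed age (cdpc) per embryo of one strain.

    Returns a DataFrame with columns embryo_id, cdpc, ci_low, ci_high,
    litter_offset (posterior mean conception offset of the embryo's litter)
    and litter_multiplier (posterior mean pregnancy multiplier). Exact and
    deterministic: the per-litter posterior over (offset, multiplier) is
    evaluated on a ``grid_size x grid_size`` lattice with the embryo-level
    age jitter marginalized in closed form.
    """
    required = {"embryo_id", "litter_id", "dpc", "weight_mg"}
    missing = required - set(embryos.columns)
    if missing:
        raise ValueError(f"embryo table lacks columns: {sorted(missing)}")
    if (embryos["weight_mg"] <= 0).any():
        bad = embryos.loc[embryos["weight_mg"] <= 0, "embryo_id"].tolist()
        raise ValueError(f"non-positive weight for embryos: {bad}")
    if "strain" in embryos.columns and embryos["strain"].nunique() > 1:
        raise ValueError("compute_cdpc expects a single strain; split the table first")

    beta = growth.slope
    sigma_u = config.within_litter_sd
    sigma_eps = (
        config.residual_sd
        if config.residual_sd is not None
        else _estimate_residual_sd(embryos, growth, config)
    )
    sigma_eps = max(sigma_eps, 1e-9)
    s2 = (beta * sigma_u) ** 2 + sigma_eps**2  # marginal log-weight variance

    # latent grids; degenerate prior -> single point
    if config.conception_offset_sd > 0:
        c_grid = np.linspace(
            -config.conception_offset_bound, config.conception_offset_bound,
            config.grid_size,
        )
        log_prior_c = -0.5 * (c_grid / config.conception_offset_sd) ** 2
    else:
        c_grid = np.array([0.0])
        log_prior_c = np.array([0.0])
    r = config.pregnancy_effect_max
    if r > 0:
        m_grid = np.linspace(1.0 - r, 1.0 + r, config.grid_size)
    else:
        m_grid = np.array([1.0])

    C, M = np.meshgrid(c_grid, m_grid, indexing="ij")   # (nc, nm)
    log_prior = np.broadcast_to(log_prior_c[:, None], C.shape)

    # posterior mean/var of u_i given (c, m): Gaussian conjugacy
    k_u = (beta * sigma_u**2) / s2
    var_u_post = (sigma_u**2 * sigma_eps**2) / s2

    rows = []
    for litter_id, grp in embryos.groupby("litter_id", sort=False):
        dpc = grp["dpc"].to_numpy(float)
        logw = np.log(grp["weight_mg"].to_numpy(float))
        # residual of each embryo under each grid cell: (nc, nm, n)
        mu = (
            growth.predict_log_weight(dpc[None, None, :] + C[:, :, None])
            + np.log(M)[:, :, None]
        )
        resid = logw[None, None, :] - mu
        loglik = -0.5 * np.sum(resid**2, axis=2) / s2
        logpost = log_prior + loglik
        logpost -= logpost.max()
        w = np.exp(logpost)
        w /= w.sum()

        edge_mass = float(w[0, :].sum() + w[-1, :].sum()) if len(c_grid) > 1 else 0.0
        if edge_mass > 0.2:
            warnings.warn(
                f"litter {litter_id}: {edge_mass:.0%} of the posterior mass for the "
                "conception offset sits on the +/-"
                f"{config.conception_offset_bound} d truncation boundary",
                stacklevel=2,
            )

        c_mean = float(np.sum(w * C))
        m_mean = float(np.sum(w * M))
        e_u = k_u * resid                                 # (nc, nm, n)
        a_mean = dpc + np.sum(w[:, :, None] * (C[:, :, None] + e_u), axis=(0, 1))

        if ci:
            lo_q = (1.0 - config.ci_level) / 2.0
            hi_q = 1.0 - lo_q
            centers = dpc[None, :] + (C[:, :, None] + e_u).reshape(-1, len(dpc))
            wflat = w.reshape(-1)
            sd_post = float(np.sqrt(max(var_u_post, 1e-18)))
            span_lo = centers.min(axis=0) - 4 * sd_post
            span_hi = centers.max(axis=0) + 4 * sd_post
            ci_low = np.empty(len(dpc))
            ci_high = np.empty(len(dpc))
            for i in range(len(dpc)):
                grid = np.linspace(span_lo[i], span_hi[i], 301)
                cdf = ndtr((grid[None, :] - centers[:, i : i + 1]) / sd_post)
                mix = wflat @ cdf
                ci_low[i] = float(np.interp(lo_q, mix, grid))
                ci_high[i] = float(np.interp(hi_q, mix, grid))
        else:
            ci_low = np.full(len(dpc), np.nan)
            ci_high = np.full(len(dpc), np.nan)

        for i, (_, row) in enumerate(grp.iterrows()):
            rows.append(
                dict(
                    embryo_id=row["embryo_id"],
                    cdpc=float(a_mean[i]),
                    ci_low=float(ci_low[i]),
                    ci_high=float(ci_high[i]),
                    litter_offset=c_mean,
                    litter_multiplier=m_mean,
                )
            )
    return pd.DataFrame(rows)


def weight_only_age(embryos: pd.DataFrame, growth: GrowthModel) -> pd.DataFrame:
    """Simplified estimator: age read off the inverted growth curve.

    Ignores litter structure entirely; strictly increasing in weight.
    Weights outside the calibrated range trigger an extrapolation warning.
    """
    w = embryos["weight_mg"].to_numpy(float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    lo, hi = CALIBRATED_RANGE_MG
    if ((w < lo) | (w > hi)).any():
        warnings.warn(
            f"weights outside the calibrated {lo:.0f}-{hi:.0f} mg range: "
            "extrapolating the growth curve",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"embryo_id": embryos["embryo_id"].to_numpy(), "age": growth.invert(w)}
    )


def robustness_compare(est_a: pd.DataFrame, est_b: pd.DataFrame) -> dict:
    """Concordance of two cdpc runs (e.g. pregnancy bounds 0.10 vs 0.20).

    Returns the Spearman rank correlation of cdpc, the maximum absolute
    difference, and the per-embryo deltas.
    """
    a = est_a.set_index("embryo_id")["cdpc"]
    b = est_b.set_index("embryo_id")["cdpc"]
    if set(a.index) != set(b.index):
        raise ValueError("the two estimate tables cover different embryo sets")
    b = b.reindex(a.index)
    delta = (b - a).rename("delta")
    if a.nunique() <= 1 or b.nunique() <= 1:
        rho = 1.0 if np.allclose(a, b) else float("nan")
    else:
        rho = float(spearmanr(a.to_numpy(), b.to_numpy()).statistic)
    return {
        "rank_correlation": rho,
        "max_abs_delta": float(delta.abs().max()),
        "deltas": delta.reset_index(),
    }
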