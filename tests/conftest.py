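import numpy as np
import pandas as pd
import pytest

from molardev import age, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort with its ground-truth latents (seed 1)."""
    return synthetic.generate_cohort(synthetic.default_config(seed=1))


@pytest.fixture(scope="session")
def cohort_with_cdpc(default_cohort):
    """The default cohort with fitted cdpc merged in, per strain."""
    embryos, latents = default_cohort
    parts = []
    for strain in sorted(embryos["strain"].unique()):
        sub = embryos[embryos["strain"] == strain].copy()
        growth = age.fit_growth_model(embryos, strain)
        est = age.compute_cdpc(sub, growth, age.AgeModelConfig(), ci=False)
        parts.append(sub.merge(est[["embryo_id", "cdpc"]], on="embryo_id"))
    merged = pd.concat(parts, ignore_index=True)
    truth = default_cohort[1].embryos[["embryo_id", "true_age"]]
    return merged.merge(truth, on="embryo_id")


@pytest.fixture()
def noise_free_config():
    """All stochastic terms off: weights sit exactly on the growth curve."""
    return synthetic.default_config(
        seed=0,
        conception_offset_sd=0.0,
        within_litter_age_sd=0.0,
        pregnancy_effect_max=0.0,
        weight_noise_sd=0.0,
        timing_jitter_sd={"FVB": 0.0, "DUHi": 0.0},
    )


def polygon_area_halves(points, split_x=0.0):
    """Oracle: areas of a polygon left/right of a vertical line, by fine
    trapezoid integration of the polar radius representation about the
    split axis origin. Points must form a star-shaped polygon about (split_x, 0).
    """
    pts = np.asarray(points, float) - np.array([split_x, 0.0])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.argsort(ang)
    ang, r2 = ang[order], (pts[order] ** 2).sum(axis=1)
    dth = 2 * np.pi / len(ang)
    anterior = 0.5 * float(np.sum(r2[np.abs(ang) < np.pi / 2]) * dth)
    posterior = 0.5 * float(np.sum(r2[np.abs(ang) >= np.pi / 2]) * dth)
    return anterior, posterior
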