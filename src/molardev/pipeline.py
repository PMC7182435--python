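"""Configuration-driven pipeline tying the analysis stages together.

A run executes, as configured: cohort simulation -> computed age per strain
-> state census -> developmental-variation comparison and temporal profile
-> (optionally) outline morphometrics and pathway-polarity tallies. Every
run writes a machine-readable ``manifest.json`` recording the tool version,
seed, configuration hash and per-stage status; numeric outputs are
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, age, devstate, devvar, morphometrics, pathway, synthetic
from .io import config_hash, read_embryo_table, read_outline, read_table, write_table

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True},
    "age": {"pregnancy_effect_max": 0.10},
    "variability": {"window": 0.25, "span": 0.75},
    "morphometrics": {"enabled": False, "harmonics": 7},
    "pathway": {"enabled": False, "alpha": 0.05, "convention": "caption"},
}


def load_config(path_or_dict) -> dict:
    """Load a YAML pipeline configuration, filling in defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config, out_dir) -> Path:
    """Run the configured stages, writing all artifacts under ``out_dir``.

    Returns the output directory. On a stage failure the partial outputs
    are kept and a ``failed`` marker file names the stage and cause.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "stages": {},
    }
    meta = dict(seed=seed, config=cfg)

    def _finish(stage: str, exc: Exception | None = None):
        manifest["stages"][stage] = "failed" if exc else "ok"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if exc:
            (out / "failed").write_text(f"{stage}: {exc}\n")
            raise StageFailure(stage, exc)

    # --- simulate (or load) -------------------------------------------------
    stage = "simulate"
    try:
        if cfg["simulate"].get("enabled", True):
            overrides = {
                k: v for k, v in cfg["simulate"].items() if k not in ("enabled",)
            }
            config_fields = {f.name for f in dataclasses.fields(synthetic.CohortConfig)}
            unknown = set(overrides) - config_fields
            if unknown:
                raise ValueError(f"unknown simulate options: {sorted(unknown)}")
            cohort_cfg = synthetic.default_config(seed=seed, **overrides)
            embryos, latents = synthetic.generate_cohort(cohort_cfg)
            write_table(embryos, out / "embryos.csv", seed=seed, config=cfg)
            write_table(latents.litters, out / "true_litters.csv", seed=seed, config=cfg)
            write_table(latents.embryos, out / "true_embryos.csv", seed=seed, config=cfg)
        else:
            embryos = read_embryo_table(cfg["input"])
        _finish(stage)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001 - reported via the manifest
        _finish(stage, exc)

    # --- computed age per strain -------------------------------------------
    stage = "age"
    try:
        acfg = age.AgeModelConfig(
            pregnancy_effect_max=float(cfg["age"].get("pregnancy_effect_max", 0.10))
        )
        parts = []
        for strain in sorted(embryos["strain"].unique()):
            sub = embryos[embryos["strain"] == strain]
            growth = age.fit_growth_model(embryos, strain)
            parts.append(age.compute_cdpc(sub, growth, acfg))
        estimates = pd.concat(parts, ignore_index=True)
        embryos = embryos.merge(estimates, on="embryo_id")
        write_table(estimates, out / "cdpc.csv", seed=seed, config=cfg)
        _finish(stage)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)

    # --- state census -------------------------------------------------------
    stage = "states"
    try:
        census = devstate.census_states(embryos)
        write_table(census.table, out / "state_census.csv", seed=seed, config=cfg)
        _finish(stage)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)

    # --- developmental variation ---------------------------------------------
    stage = "variability"
    try:
        vcfg = cfg["variability"]
        window = float(vcfg.get("window", 0.25))
        span = float(vcfg.get("span", 0.75))
        strains = sorted(embryos["strain"].unique())
        report = {}
        for strain in strains:
            sub = embryos[embryos["strain"] == strain]
            profile = devvar.temporal_profile(sub, window=window, span=span)
            write_table(profile.curve, out / f"profile_{strain}.csv", seed=seed, config=cfg)
        if len(strains) == 2:
            pa = devvar.neighbor_pairs(embryos[embryos["strain"] == strains[0]], window=window)
            pb = devvar.neighbor_pairs(embryos[embryos["strain"] == strains[1]], window=window)
            report = devvar.compare_strain_variability(pa, pb)
            report["strain_a"], report["strain_b"] = strains
            (out / "variability_comparison.json").write_text(json.dumps(report, indent=2))
        _finish(stage)
    except StageFailure:
        raise
    except Exception as exc:  # noqa: BLE001
        _finish(stage, exc)

    # --- morphometrics (optional) --------------------------------------------
    if cfg["morphometrics"].get("enabled", False):
        stage = "morphometrics"
        try:
            mcfg = cfg["morphometrics"]
            manifest_df = read_table(mcfg["manifest"])
            outlines_dir = Path(mcfg["outlines_dir"])
            harmonics = int(mcfg.get("harmonics", 7))
            coeff_rows, size_rows = [], []
            for _, row in manifest_df.iterrows():
                ol = read_outline(
                    outlines_dir / f"{row['tooth_id']}.csv",
                    tooth_id=row["tooth_id"],
                    tooth_type=row.get("type", "UM1"),
                    anterior_index=int(row.get("anterior_index", 0)),
                )
                res = morphometrics.resample_outline(ol)
                coeffs = morphometrics.radial_fourier(res, harmonics=harmonics)
                size = morphometrics.length_width(ol)
                coeff_rows.append(
                    {"tooth_id": coeffs.tooth_id, "a0": coeffs.a0,
                     **{f"a{k+1}": v for k, v in enumerate(coeffs.a)},
                     **{f"b{k+1}": v for k, v in enumerate(coeffs.b)}}
                )
                size_rows.append(
                    {"tooth_id": size.tooth_id, "length": size.length,
                     "width": size.width, "ratio": size.ratio}
                )
            coeff_df = pd.DataFrame(coeff_rows)
            write_table(coeff_df, out / "shape_coefficients.csv", seed=seed, config=cfg)
            write_table(pd.DataFrame(size_rows), out / "size_measures.csv", seed=seed, config=cfg)
            shape_cols = [c for c in coeff_df.columns if c[0] in "ab" and c != "a0"]
            if len(coeff_df) >= 3:
                pca = morphometrics.shape_pca(coeff_df[shape_cols])
                scores = pd.DataFrame(
                    pca.scores,
                    columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
                )
                scores.insert(0, "tooth_id", coeff_df["tooth_id"])
                write_table(scores, out / "pca_scores.csv", seed=seed, config=cfg)
            _finish(stage)
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001
            _finish(stage, exc)

    # --- pathway polarity (optional) ------------------------------------------
    if cfg["pathway"].get("enabled", False):
        stage = "pathway"
        try:
            pcfg = cfg["pathway"]
            interactions = read_table(pcfg["interactions"])
            de = read_table(pcfg["de_table"])
            classes = pathway.classify_targets(
                interactions, primary_source=pcfg.get("primary_source")
            )
            tally = pathway.tally_polarity(
                classes, de, pathway=pcfg["pathway"],
                alpha=float(pcfg.get("alpha", 0.05)),
                convention=pcfg.get("convention", "caption"),
            )
            chi2, p = pathway.test_polarity(tally)
            (out / "polarity_tally.json").write_text(json.dumps({
                "pathway": tally.pathway,
                "n_weaker": tally.n_weaker,
                "n_greater": tally.n_greater,
                "chi2": chi2,
                "p": p,
            }, indent=2))
            write_table(tally.contributions, out / "polarity_contributions.csv",
                        seed=seed, config=cfg)
            _finish(stage)
        except StageFailure:
            raise
        except Exception as exc:  # noqa: BLE001
            _finish(stage, exc)

    return out
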