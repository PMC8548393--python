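"""End-to-end pipeline: simulate -> fit -> classify -> curves -> nulls.

Every stage is a pure function of its inputs and an explicit seed; a full
run is reproducible bit-for-bit from (config, seed).  Stage outputs are the
CSV artifacts defined in :mod:`coexar.io`; a ``manifest.json`` records the
configuration, seed and package version of each run.
"""

from __future__ import annotations

import shutil
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .curves import car_curve, heterogeneity_contribution, power_law_fit, sar_curve, transient_fraction
from .nulls import null_car_ensemble
from .persistence import DEFAULT_PRECEDENCE, classify_community
from .ricker import ALL_PLOTS, CommunityParams, fit_heterogeneous, fit_homogeneous
from .structural import LVCommunity, lv_growth_rate
from .synthetic import (
    StudyDesign,
    default_species_names,
    generate_ground_truth,
    generate_observations,
    presence_from_observations,
)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults mirror the study design."""

    out_dir: str = "coexar_out"
    seed: int = 0
    # study design
    n_years: int = 5
    n_plots: int = 9
    n_subplots_per_plot: int = 36
    plot_side_m: float = 8.5
    interaction_radius_cm: float = 7.5
    n_species: int = 19
    # simulation
    simulate: bool = True
    truth_scenario: str = "homogeneous"
    heterogeneity_sd: float = 0.0
    n_focal_per_species_plot: int = 34
    # inference
    shrinkage_sd: float = 0.5
    n_parameter_draws: int = 100
    # structural analysis
    omega_samples: int = 100_000
    lv_convention: str = "invasion"
    category_precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    # curves
    het_denominator: str = "het"  # denominator of the heterogeneity contribution
    # null models
    null_models: tuple[str, ...] = ("shuffle_all", "shuffle_offdiag")
    n_null_replicates: int = 100

    def __post_init__(self) -> None:
        for name in (
            "n_years", "n_plots", "n_subplots_per_plot", "n_species",
            "n_focal_per_species_plot", "n_parameter_draws", "omega_samples",
            "n_null_replicates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")

    def design(self) -> StudyDesign:
        return StudyDesign(
            n_years=self.n_years,
            n_plots=self.n_plots,
            n_subplots_per_plot=self.n_subplots_per_plot,
            plot_side_m=self.plot_side_m,
            interaction_radius_cm=self.interaction_radius_cm,
            species_names=default_species_names(self.n_species),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _subseed(master: int, label: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(master), digest])
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def _stage_seed(master: int, stage: str, *coords: object) -> int:
    return _subseed(master, stage + ":" + ":".join(map(str, coords)))


def simulate_stage(config: PipelineConfig, out: Path) -> pd.DataFrame:
    design = config.design()
    truth = generate_ground_truth(
        design,
        scenario=config.truth_scenario,
        heterogeneity_sd=config.heterogeneity_sd,
        seed=_stage_seed(config.seed, "truth"),
    )
    obs = generate_observations(
        truth,
        design,
        n_focal_per_species_plot=config.n_focal_per_species_plot,
        seed=_stage_seed(config.seed, "observations"),
    )
    cio.write_observations(obs, out / "observations.csv")
    cio.write_alpha(truth.alpha, truth.species, out / "truth" / "alpha.csv")
    cio.write_vitals(
        truth.species, truth.log_lambda, truth.g, truth.s, truth.dispersion,
        out / "truth" / "vitals.csv",
    )
    return obs


def fit_stage(
    config: PipelineConfig, out: Path, obs: pd.DataFrame
) -> tuple[dict, dict]:
    """Fit both parameterizations per year.

    Returns ``(hom, het)`` where ``hom[year]`` is the pooled fit and
    ``het[year][plot]`` the plot-specific fits.
    """
    vitals = cio.read_vitals(out / "truth" / "vitals.csv").set_index("species")
    g = vitals["g"].to_dict()
    s = vitals["s"].to_dict()
    hom: dict = {}
    het: dict = {}
    report = {}
    for year in sorted(obs["year"].unique()):
        fit = fit_homogeneous(obs, g, s, year)
        hom[year] = fit
        cio.write_params(fit, out / "fits" / f"year_{year}" / "hom")
        plot_fits = fit_heterogeneous(
            obs, g, s, year, shrinkage_sd=config.shrinkage_sd, pooled=fit
        )
        het[year] = {p.plot: p for p in plot_fits}
        for p in plot_fits:
            cio.write_params(p, out / "fits" / f"year_{year}" / "het" / f"plot_{p.plot}")
        report[str(year)] = {
            "hom": {
                "species": list(fit.species),
                "converged": [bool(c) for c in fit.converged],
                "loglik": [float(v) for v in fit.loglik],
            },
            "het": {
                str(p.plot): {
                    "species": list(p.species),
                    "converged": [bool(c) for c in p.converged],
                    "loglik": [float(v) for v in p.loglik],
                }
                for p in plot_fits
            },
        }
    cio.write_json(report, out / "fits" / "fit_report.json")
    return hom, het


def community_from_params(
    params: CommunityParams, species: list[str] | None = None,
    convention: str = "invasion",
) -> LVCommunity:
    """LV community from fitted parameters, optionally on a species subset."""
    sub = params if species is None else params.restricted_to(sorted(species))
    r = lv_growth_rate(sub.log_lambda, sub.g, sub.s, convention=convention)
    return LVCommunity(sub.species, np.atleast_1d(r), sub.alpha)


def classify_stage(
    config: PipelineConfig, out: Path, obs: pd.DataFrame, hom: Mapping, het: Mapping
) -> pd.DataFrame:
    frames = []
    for year in sorted(hom):
        presence = presence_from_observations(obs, year)
        for plot in sorted(presence, key=str):
            species_hom = sorted(set(presence[plot]) & set(hom[year].species))
            comm = community_from_params(
                hom[year], species_hom, convention=config.lv_convention
            )
            recs = classify_community(
                comm, year=year, plot=plot, precedence=config.category_precedence
            )
            frames.append(cio.persistence_frame(recs, "hom"))
            if plot in het[year]:
                pfit = het[year][plot]
                comm_het = community_from_params(
                    pfit, sorted(pfit.species), convention=config.lv_convention
                )
                recs_het = classify_community(
                    comm_het, year=year, plot=plot,
                    precedence=config.category_precedence,
                )
                frames.append(cio.persistence_frame(recs_het, "het"))
    persistence = pd.concat(frames, ignore_index=True)
    cio.write_csv(persistence, out / "persistence.csv")
    return persistence


def curves_stage(
    config: PipelineConfig, out: Path, obs: pd.DataFrame, persistence: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    area = config.plot_side_m**2
    curve_frames = []
    power_rows = []
    transient_by_year = {}
    for year in sorted(obs["year"].unique()):
        presence = presence_from_observations(obs, year)
        plots = sorted(presence, key=str)
        sar = sar_curve(presence, plot_area_m2=area)
        per_year = sar.copy()
        for label in ("hom", "het"):
            mask = (persistence["year"] == year) & (
                persistence["parameterization"] == label
            )
            recs = cio.records_from_frame(persistence[mask])
            car = car_curve(recs, plots=plots, plot_area_m2=area)
            per_year[f"car_{label}_mean"] = car["car_mean"]
            per_year[f"car_{label}_se"] = car["car_se"]
            if label == "het":
                transient_by_year[year] = transient_fraction(recs, presence)
        per_year.insert(0, "year", year)
        curve_frames.append(per_year)
        for curve_name, col in (
            ("sar", "sar_mean"),
            ("car_hom", "car_hom_mean"),
            ("car_het", "car_het_mean"),
        ):
            try:
                fitres = power_law_fit(per_year["area_m2"], per_year[col])
                power_rows.append(
                    {"year": year, "curve": curve_name, "c": fitres.c,
                     "z": fitres.z, "rss": fitres.residual_sum_squares}
                )
            except (ValueError, RuntimeError):
                power_rows.append(
                    {"year": year, "curve": curve_name, "c": np.nan,
                     "z": np.nan, "rss": np.nan}
                )
    curves = pd.concat(curve_frames, ignore_index=True)
    powerlaw = pd.DataFrame(power_rows)
    if config.het_denominator == "het":
        contrib = heterogeneity_contribution(curves)
    else:
        flipped = curves.rename(
            columns={"car_hom_mean": "car_het_mean", "car_het_mean": "car_hom_mean"}
        )
        contrib = -heterogeneity_contribution(flipped)
    summary = {
        "heterogeneity_contribution_pct": contrib,
        "transient_fraction_pct_by_year": {str(y): v for y, v in transient_by_year.items()},
        "transient_fraction_pct": float(np.mean(list(transient_by_year.values()))),
    }
    cio.write_csv(curves, out / "curves.csv")
    cio.write_csv(powerlaw, out / "powerlaw.csv")
    cio.write_json(summary, out / "summary.json")
    return curves, powerlaw, summary


def nulls_stage(
    config: PipelineConfig, out: Path, obs: pd.DataFrame, hom: Mapping
) -> tuple[pd.DataFrame, pd.DataFrame]:
    area = config.plot_side_m**2
    rows = []
    summary_rows = []
    for year in sorted(hom):
        presence = presence_from_observations(obs, year)
        communities = {}
        for plot in sorted(presence, key=str):
            species = sorted(set(presence[plot]) & set(hom[year].species))
            communities[plot] = community_from_params(
                hom[year], species, convention=config.lv_convention
            )
        for model in config.null_models:
            ens = null_car_ensemble(
                communities,
                model=model,
                n_replicates=config.n_null_replicates,
                seed=_stage_seed(config.seed, "nulls", year, model),
                plot_area_m2=area,
                year=year,
            )
            for rep, curve in enumerate(ens.replicate_curves):
                for row in curve.itertuples():
                    rows.append(
                        {"year": year, "model": model, "k": row.k,
                         "replicate": rep, "car_mean": row.car_mean}
                    )
            for row in ens.mean_curve.itertuples():
                summary_rows.append(
                    {"year": year, "model": model, "k": row.k,
                     "car_mean": row.car_mean, "car_se": row.car_se}
                )
    nulls = pd.DataFrame(rows)
    nulls_summary = pd.DataFrame(summary_rows)
    cio.write_csv(nulls, out / "nulls.csv")
    cio.write_csv(nulls_summary, out / "nulls_summary.csv")
    return nulls, nulls_summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the in-memory artifacts keyed by name.

    On any stage failure the partially written output directory is removed
    and the error re-raised with a stage label.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    stage = "setup"
    try:
        out.mkdir(parents=True, exist_ok=True)
        stage = "simulate"
        if config.simulate:
            obs = simulate_stage(config, out)
        else:
            obs = cio.read_observations(out / "observations.csv")
            if not (out / "truth" / "vitals.csv").exists():
                raise FileNotFoundError(
                    "vitals file missing and simulation disabled: "
                    f"{out / 'truth' / 'vitals.csv'}"
                )
        stage = "fit"
        hom, het = fit_stage(config, out, obs)
        stage = "classify"
        persistence = classify_stage(config, out, obs, hom, het)
        stage = "curves"
        curves, powerlaw, summary = curves_stage(config, out, obs, persistence)
        stage = "nulls"
        nulls, nulls_summary = nulls_stage(config, out, obs, hom)
        stage = "manifest"
        manifest = {
            "package": "coexar",
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
        }
        cio.write_json(manifest, out / "manifest.json")
    except Exception as exc:
        if created and out.exists():
            shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return {
        "observations": obs,
        "hom": hom,
        "het": het,
        "persistence": persistence,
        "curves": curves,
        "powerlaw": powerlaw,
        "summary": summary,
        "nulls": nulls,
        "nulls_summary": nulls_summary,
    }
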