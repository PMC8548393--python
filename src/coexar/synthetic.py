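"""Synthetic annual-plant community generator.

Emulates the statistical structure of a neighborhood-fecundity field study
in a Mediterranean grassland: nine 8.5 m x 8.5 m plots (each split into 36
subplots) arranged along an environmental gradient, sampled over five
years, with ~19 annual species whose per-germinant viable seed production
follows a Ricker model

    F_i = lambda_i * exp(-sum_j alpha_ij * N_j)

with negative-binomial noise, where ``N_j`` counts neighbors of species
``j`` within a 7.5 cm radius of the focal individual.  Ground truth
(``lambda``, ``alpha``, germination ``g``, seed survival ``s``,
overdispersion) is known, so every downstream stage — inference,
feasibility analysis, persistence classification, curve construction —
can be validated end-to-end without any external data.

Design choices that shape the defaults:

- Interactions are quasi-neutral: mostly weak competition with
  intraspecific strength similar to (often slightly below) interspecific
  strength, plus occasional weak facilitation.  Roughly a third of
  pairwise interactions have the intraspecific term exceeding the
  interspecific one.
- A small subset of species (~15%) is sink-prone: low intrinsic fecundity
  puts them below the seed-bank invasion boundary, so they are observed
  but predicted transient.
- Occupancy is gradient-structured through a logistic response to a 1-D
  plot covariate standing in for soil salinity; this is a realism device
  only and is never fitted.
- Neighbor counts are independent Poisson draws per focal individual
  (mean = per-species density, zero for species absent from the plot that
  year); only counts, not positions, enter the fecundity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SCENARIOS = ("homogeneous", "heterogeneous")
#: per-plot alpha deviations get sd = heterogeneity_sd * this scale, so that
#: sd=0.5 perturbs alpha by roughly the cross-species spread of alpha itself
ALPHA_HETEROGENEITY_SCALE = 0.04


def default_species_names(n: int = 19) -> tuple[str, ...]:
    return tuple(f"SP{i:02d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class StudyDesign:
    """Spatial and temporal layout of the sampling campaign."""

    n_years: int = 5
    n_plots: int = 9
    n_subplots_per_plot: int = 36
    plot_side_m: float = 8.5
    interaction_radius_cm: float = 7.5
    species_names: tuple[str, ...] = field(default_factory=default_species_names)

    def __post_init__(self) -> None:
        for name in ("n_years", "n_plots", "n_subplots_per_plot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.plot_side_m <= 0:
            raise ValueError("plot_side_m must be positive")
        if len(self.species_names) < 1:
            raise ValueError("at least one species is required")
        object.__setattr__(self, "species_names", tuple(self.species_names))

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def plot_area_m2(self) -> float:
        return self.plot_side_m**2

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_years + 1))

    @property
    def plots(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_plots + 1))

    def gradient(self) -> np.ndarray:
        """1-D plot covariate (e.g. soil salinity), in blocks of thirds."""
        thirds = np.array_split(np.arange(self.n_plots), 3)
        x = np.empty(self.n_plots)
        for level, block in zip((-1.0, 0.0, 1.0), thirds):
            x[block] = level
        return x


@dataclass
class GroundTruth:
    """Known parameters behind a synthetic observation table.

    ``alpha[i, j]`` is the per-capita effect of neighbor species ``j`` on
    focal species ``i`` (positive = competition, negative = facilitation).
    Per-plot deviations (``log_lambda_dev``, ``alpha_dev``) are identically
    zero under the homogeneous scenario.
    """

    species: tuple[str, ...]
    log_lambda: np.ndarray  # (S,)
    alpha: np.ndarray  # (S, S)
    g: np.ndarray  # (S,) germination probability
    s: np.ndarray  # (S,) seed survival probability
    dispersion: np.ndarray  # (S,) NB size parameter k; var = mu + mu^2/k
    occupancy: np.ndarray  # (S, P) probability of occurrence per plot-year
    density: np.ndarray  # (S,) mean neighbor count per focal when present
    log_lambda_dev: np.ndarray  # (P, S)
    alpha_dev: np.ndarray  # (P, S, S)
    scenario: str = "homogeneous"

    def __post_init__(self) -> None:
        S = len(self.species)
        if self.alpha.shape != (S, S):
            raise ValueError("alpha dimensions do not match species count")
        if np.any(np.diag(self.alpha) <= 0):
            raise ValueError("alpha diagonal entries must be positive")
        if np.any((self.g <= 0) | (self.g > 1)):
            raise ValueError("g must lie in (0, 1]")
        if np.any((self.s < 0) | (self.s >= 1)):
            raise ValueError("s must lie in [0, 1)")
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion must be positive")

    @property
    def n_plots(self) -> int:
        return self.log_lambda_dev.shape[0]

    def log_lambda_in_plot(self, plot_index: int) -> np.ndarray:
        return self.log_lambda + self.log_lambda_dev[plot_index]

    def alpha_in_plot(self, plot_index: int) -> np.ndarray:
        return self.alpha + self.alpha_dev[plot_index]


def generate_ground_truth(
    design: StudyDesign,
    scenario: str = "homogeneous",
    heterogeneity_sd: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw a complete parameter set for the study design.

    Under ``scenario="heterogeneous"`` each plot receives additive Gaussian
    deviations on log lambda (sd = ``heterogeneity_sd``) and on every alpha
    entry (sd = ``heterogeneity_sd * ALPHA_HETEROGENEITY_SCALE``), mirroring
    a crossed plot effect on intercept and slopes.  ``heterogeneity_sd``
    must be 0 under the homogeneous scenario.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if heterogeneity_sd < 0:
        raise ValueError("heterogeneity_sd must be nonnegative")
    if scenario == "homogeneous" and heterogeneity_sd != 0:
        raise ValueError("homogeneous scenario requires heterogeneity_sd = 0")
    S, P = design.n_species, design.n_plots
    rng = np.random.default_rng(seed)

    # a fixed ~15% of the pool is sink-prone: fecundity below the seed-bank
    # invasion boundary, so these species are observed yet predicted transient
    n_sink = max(1, round(0.15 * S)) if S > 1 else 0
    sink_prone = np.zeros(S, dtype=bool)
    sink_prone[rng.choice(S, size=n_sink, replace=False)] = True
    log_lambda = np.where(
        sink_prone,
        rng.normal(-1.2, 0.4, S),
        rng.normal(3.0, 0.4, S),
    )
    alpha = rng.normal(0.055, 0.018, (S, S))
    # weak facilitation among the core community only: sink-prone species sit
    # at their physiological limit and are not facilitation-rescued
    facilitation = (rng.random((S, S)) < 0.08) & ~sink_prone[:, None]
    alpha[facilitation] = -np.abs(rng.normal(0.0, 0.02, facilitation.sum()))
    diag = np.clip(rng.normal(0.045, 0.008, S), 0.01, None)
    np.fill_diagonal(alpha, diag)

    g = rng.uniform(0.3, 0.9, S)
    s = rng.uniform(0.2, 0.8, S)
    dispersion = rng.uniform(1.5, 4.0, S)

    x = design.gradient()
    intercept = np.where(
        sink_prone, rng.normal(0.0, 0.5, S), rng.normal(0.8, 0.8, S)
    )
    slope = np.where(sink_prone, rng.normal(0.0, 2.0, S), rng.normal(0.0, 1.5, S))
    occupancy = 1.0 / (1.0 + np.exp(-(intercept[:, None] + slope[:, None] * x[None, :])))
    density = rng.lognormal(np.log(1.5), 0.4, S)

    if scenario == "heterogeneous" and heterogeneity_sd > 0:
        log_lambda_dev = rng.normal(0.0, heterogeneity_sd, (P, S))
        # sink-prone species are gradient specialists: their fecundity rises
        # toward one end of the gradient, so spatial heterogeneity can lift
        # them over the invasion boundary in their favored plots
        affinity = np.where(
            sink_prone, rng.choice([-1.0, 1.0], S) * 3.0 * heterogeneity_sd, 0.0
        )
        log_lambda_dev += x[:, None] * affinity[None, :]
        alpha_dev = rng.normal(
            0.0, heterogeneity_sd * ALPHA_HETEROGENEITY_SCALE, (P, S, S)
        )
    else:
        log_lambda_dev = np.zeros((P, S))
        alpha_dev = np.zeros((P, S, S))

    return GroundTruth(
        species=design.species_names,
        log_lambda=log_lambda,
        alpha=alpha,
        g=g,
        s=s,
        dispersion=dispersion,
        occupancy=occupancy,
        density=density,
        log_lambda_dev=log_lambda_dev,
        alpha_dev=alpha_dev,
        scenario=scenario,
    )


def neighbor_columns(species: Sequence[str]) -> list[str]:
    return [f"n_{sp}" for sp in species]


def generate_observations(
    truth: GroundTruth,
    design: StudyDesign,
    n_focal_per_species_plot: int = 34,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the focal-individual observation table.

    For every year and plot, species presence is drawn from the occupancy
    probabilities (independently per year; at least one species is forced
    present per plot-year so no plot is ever empty).  Each present species
    contributes ``n_focal_per_species_plot`` focal individuals; each focal
    row gets independent Poisson neighbor counts for the species present in
    that plot-year and a negative-binomial seed count with Ricker mean.

    The default of 34 focals per species and plot gives ~300 observations
    per species and year, within the design's cap of one-per-subplot
    sampling (324 per species and year).  Because the fits downstream are
    per-year, this sampling effort gives each yearly fit roughly the
    information a multilevel model would borrow by pooling a sparser
    sample across years.

    Returns a wide table with columns
    ``year, plot, subplot, focal, seeds, n_<SPECIES>...``.
    """
    if n_focal_per_species_plot < 1:
        raise ValueError("n_focal_per_species_plot must be >= 1")
    if truth.species != design.species_names or truth.n_plots != design.n_plots:
        raise ValueError("ground truth does not match the study design")
    S = design.n_species
    rng = np.random.default_rng(seed)
    frames = []
    for year in design.years:
        for p, plot in enumerate(design.plots):
            present = rng.random(S) < truth.occupancy[:, p]
            if not present.any():
                present[int(np.argmax(truth.occupancy[:, p]))] = True
            present_idx = np.flatnonzero(present)
            log_lam = truth.log_lambda_in_plot(p)
            alpha = truth.alpha_in_plot(p)
            for i in present_idx:
                n = n_focal_per_species_plot
                counts = np.zeros((n, S), dtype=np.int64)
                counts[:, present_idx] = rng.poisson(
                    truth.density[present_idx], size=(n, len(present_idx))
                )
                mu = np.exp(log_lam[i] - counts @ alpha[i])
                k = truth.dispersion[i]
                seeds = rng.negative_binomial(k, k / (k + mu))
                frame = pd.DataFrame(counts, columns=neighbor_columns(design.species_names))
                frame.insert(0, "year", year)
                frame.insert(1, "plot", plot)
                frame.insert(
                    2, "subplot", rng.integers(1, design.n_subplots_per_plot + 1, n)
                )
                frame.insert(3, "focal", design.species_names[i])
                frame.insert(4, "seeds", seeds)
                frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def presence_from_observations(
    obs: pd.DataFrame, year: object | None = None
) -> dict[object, set[str]]:
    """Per-plot sets of species observed as focals (one year)."""
    if year is not None:
        obs = obs[obs["year"] == year]
    out: dict[object, set[str]] = {}
    for plot, grp in obs.groupby("plot"):
        out[plot] = set(grp["focal"].unique())
    return out
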