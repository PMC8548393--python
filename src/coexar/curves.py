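"""Species-area and coexistence-area relationship construction.

SARs here are "Type B" curves: for each number of plots ``k`` the richness
of every one of the C(P, k) plot combinations is computed as the union of
the per-plot species sets, and the curve reports mean and standard error
over combinations.  CARs are built identically from per-plot *persistent*
sets (species classified non-transient), under either the homogeneous
(study-wide parameters) or heterogeneous (plot-specific parameters)
parameterization.  Curves are fitted to the power law S = c * A^z.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .persistence import PersistenceRecord

#: side length of a sampling plot in meters; area 8.5^2 = 72.25 m^2
DEFAULT_PLOT_SIDE_M = 8.5


@dataclass
class PowerLawFit:
    """Least-squares fit of S = c * A^z on untransformed values."""

    c: float
    z: float
    residual_sum_squares: float


def _union_curve(
    sets_by_plot: Mapping[object, frozenset[str]], plot_area_m2: float
) -> pd.DataFrame:
    """Mean +/- SE of union set size over all plot combinations, per k."""
    plots = sorted(sets_by_plot, key=str)
    P = len(plots)
    if P < 1:
        raise ValueError("at least one plot is required")
    rows = []
    for k in range(1, P + 1):
        sizes = np.array(
            [
                len(frozenset().union(*(sets_by_plot[p] for p in combo)))
                for combo in combinations(plots, k)
            ],
            dtype=float,
        )
        n = len(sizes)
        se = float(sizes.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "k": k,
                "area_m2": k * plot_area_m2,
                "n_combinations": n,
                "mean": float(sizes.mean()),
                "se": se,
            }
        )
    return pd.DataFrame(rows)


def sar_curve(
    presence: Mapping[object, Iterable[str]],
    plot_area_m2: float = DEFAULT_PLOT_SIDE_M**2,
) -> pd.DataFrame:
    """SAR from per-plot observed species sets.

    Parameters
    ----------
    presence
        Mapping plot -> iterable of species observed in that plot.

    Returns
    -------
    DataFrame with columns ``k, area_m2, n_combinations, sar_mean, sar_se``;
    ``n_combinations`` equals C(P, k) (9, 36, 84, 126, 126, 84, 36, 9, 1
    for the nine-plot design).
    """
    sets = {p: frozenset(sp) for p, sp in presence.items()}
    out = _union_curve(sets, plot_area_m2)
    out = out.rename(columns={"mean": "sar_mean", "se": "sar_se"})
    assert (
        out["n_combinations"] == [comb(len(sets), k) for k in out["k"]]
    ).all()
    return out


def car_curve(
    records: Iterable[PersistenceRecord],
    plots: Sequence[object] | None = None,
    plot_area_m2: float = DEFAULT_PLOT_SIDE_M**2,
) -> pd.DataFrame:
    """CAR from per-plot persistence records (one parameterization).

    A species counts as coexisting in an area (plot combination) if it is
    non-transient in at least one constituent plot.  ``plots`` lists the
    plots to include; by default every plot appearing in the records.
    """
    records = list(records)
    persistent: dict[object, set[str]] = {}
    for rec in records:
        persistent.setdefault(rec.plot, set())
        if rec.category != "transient":
            persistent[rec.plot].add(rec.species)
    if plots is not None:
        missing = [p for p in plots if p not in persistent]
        if missing:
            raise ValueError(f"no persistence records for plots {missing}")
        persistent = {p: persistent[p] for p in plots}
    sets = {p: frozenset(s) for p, s in persistent.items()}
    out = _union_curve(sets, plot_area_m2)
    return out.rename(columns={"mean": "car_mean", "se": "car_se"})


def power_law_fit(area: Sequence[float], mean: Sequence[float]) -> PowerLawFit:
    """Fit S = c * A^z by nonlinear least squares on untransformed values.

    Initialized from the log-log linear regression.  Rows with
    non-positive mean are dropped (they carry no information about the
    exponent on the log scale and would otherwise break initialization).
    """
    area = np.asarray(area, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if np.any(area <= 0):
        raise ValueError("areas must be positive")
    keep = mean > 0
    area, mean = area[keep], mean[keep]
    if len(area) < 3:
        raise ValueError("need at least 3 points with positive mean")
    slope, intercept = np.polyfit(np.log(area), np.log(mean), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = curve_fit(
        lambda a, c, z: c * a**z, area, mean, p0=p0, maxfev=10_000
    )
    rss = float(np.sum((mean - popt[0] * area ** popt[1]) ** 2))
    return PowerLawFit(c=float(popt[0]), z=float(popt[1]), residual_sum_squares=rss)


def heterogeneity_contribution(curves: pd.DataFrame) -> float:
    """Percent of coexistence attributable to spatial heterogeneity.

    ``100 * mean over (year, k) of (CAR_het - CAR_hom) / CAR_het``, rows
    with zero heterogeneous CAR excluded.  ``curves`` must carry columns
    ``car_hom_mean`` and ``car_het_mean`` (one row per year and k).
    """
    het = curves["car_het_mean"].to_numpy(dtype=float)
    hom = curves["car_hom_mean"].to_numpy(dtype=float)
    keep = het != 0.0
    if not keep.any():
        raise ValueError("heterogeneous CAR is zero everywhere")
    return float(100.0 * np.mean((het[keep] - hom[keep]) / het[keep]))


def transient_fraction(
    records: Iterable[PersistenceRecord],
    presence: Mapping[object, Iterable[str]],
) -> float:
    """Average percent of an area's species pool that is transient.

    For every plot combination, a species present in the combination is
    transient at that scale if it is classified transient in *every*
    constituent plot where it occurs.  Returns 100 x the mean over all
    (k, combination) of transient count / union richness.  Records and
    presence must describe the same plots (one year, one parameterization).
    """
    presence_sets = {p: frozenset(sp) for p, sp in presence.items()}
    records = list(records)
    rec_plots = {r.plot for r in records}
    if set(presence_sets) != rec_plots:
        raise ValueError("records and presence cover different plots")
    transient_in_plot: dict[object, set[str]] = {p: set() for p in presence_sets}
    for rec in records:
        if rec.category == "transient":
            transient_in_plot[rec.plot].add(rec.species)
    plots = sorted(presence_sets, key=str)
    fractions = []
    for k in range(1, len(plots) + 1):
        for combo in combinations(plots, k):
            pool = frozenset().union(*(presence_sets[p] for p in combo))
            if not pool:
                raise ValueError(f"empty species pool for combination {combo}")
            n_trans = sum(
                1
                for sp in pool
                if all(
                    sp in transient_in_plot[p]
                    for p in combo
                    if sp in presence_sets[p]
                )
            )
            fractions.append(n_trans / len(pool))
    return float(100.0 * np.mean(fractions))
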