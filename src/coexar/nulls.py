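"""Interaction-reshuffling null models for coexistence-area curves.

Two complementary randomizations of a plot-year interaction matrix:
``shuffle_all`` redistributes the full multiset of coefficients (diagonal
included) uniformly over the matrix, erasing both species identity and the
intra/inter distinction; ``shuffle_offdiag`` keeps the self-limitation
(diagonal) terms in place and permutes only the interspecific coefficients.
Running the persistence classification and CAR construction on an ensemble
of reshuffled matrices asks whether the observed curves depend on *which*
pair carries which interaction strength, or only on the overall strength
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .curves import DEFAULT_PLOT_SIDE_M, car_curve
from .persistence import classify_community
from .structural import LVCommunity


def shuffle_all(alpha: np.ndarray, seed: int) -> np.ndarray:
    """Uniform random rearrangement of all matrix entries (diagonal included)."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
        raise ValueError("alpha must be square")
    rng = np.random.default_rng(seed)
    flat = rng.permutation(alpha.ravel())
    return flat.reshape(alpha.shape)


def shuffle_offdiag(alpha: np.ndarray, seed: int) -> np.ndarray:
    """Permute off-diagonal entries uniformly; the diagonal stays fixed."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[0] != alpha.shape[1]:
        raise ValueError("alpha must be square")
    rng = np.random.default_rng(seed)
    out = alpha.copy()
    mask = ~np.eye(alpha.shape[0], dtype=bool)
    out[mask] = rng.permutation(alpha[mask])
    return out


_SHUFFLERS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "shuffle_all": shuffle_all,
    "shuffle_offdiag": shuffle_offdiag,
}


@dataclass
class NullEnsemble:
    """Replicate CAR curves under a reshuffling null model, plus their mean."""

    model: str
    n_replicates: int
    replicate_curves: list[pd.DataFrame] = field(default_factory=list)
    mean_curve: pd.DataFrame | None = None


def null_car_ensemble(
    communities: Mapping[object, LVCommunity],
    model: str = "shuffle_all",
    n_replicates: int = 100,
    seed: int = 0,
    plot_area_m2: float = DEFAULT_PLOT_SIDE_M**2,
    year: object = None,
) -> NullEnsemble:
    """Null CAR ensemble for one year of plot communities.

    ``communities`` maps plot -> the plot's LV community under the baseline
    (homogeneous) parameterization, restricted to the species observed
    there.  Each replicate reshuffles every plot's interaction matrix
    independently, re-runs the persistence classification and rebuilds the
    CAR.  Replicate seeds are spawned from the master ``seed`` with
    ``np.random.SeedSequence`` so replicates are independent yet exactly
    reproducible.
    """
    if model not in _SHUFFLERS:
        raise ValueError(f"unknown null model {model!r}; choose from {sorted(_SHUFFLERS)}")
    shuffler = _SHUFFLERS[model]
    plots = sorted(communities, key=str)
    master = np.random.SeedSequence(seed)
    # one child stream per (replicate, plot), in a fixed grid order
    children = master.spawn(n_replicates * len(plots))
    ensemble = NullEnsemble(model=model, n_replicates=n_replicates)
    for rep in range(n_replicates):
        records = []
        for j, plot in enumerate(plots):
            comm = communities[plot]
            child_seed = int(
                children[rep * len(plots) + j].generate_state(1, np.uint32)[0]
            )
            shuffled = LVCommunity(
                comm.species, comm.r, shuffler(comm.A, child_seed)
            )
            records.extend(classify_community(shuffled, year=year, plot=plot))
        ensemble.replicate_curves.append(
            car_curve(records, plots=plots, plot_area_m2=plot_area_m2)
        )
    base = ensemble.replicate_curves[0][["k", "area_m2", "n_combinations"]].copy()
    stacked = np.stack(
        [c["car_mean"].to_numpy() for c in ensemble.replicate_curves]
    )
    base["car_mean"] = stacked.mean(axis=0)
    base["car_se"] = (
        stacked.std(axis=0, ddof=1) / np.sqrt(n_replicates)
        if n_replicates > 1
        else 0.0
    )
    ensemble.mean_curve = base
    return ensemble
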