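"""Structuralist coexistence analysis for Lotka-Volterra communities.

The annual-plant Ricker parameters (per-germinant fecundity ``lambda``,
interaction matrix ``alpha``, germination rate ``g``, seed survival ``s``)
map onto an equivalent continuous Lotka-Volterra (LV) system

    dN_i/dt = N_i (r_i - sum_j alpha_ij N_j),

with intrinsic growth rate ``r_i = ln(lambda_i) - ln((1 - (1-g_i) s_i)/g_i)``.
A species subset *coexists* in the structuralist sense when the interior
equilibrium ``A' N* = r'`` restricted to the subset is componentwise
positive (*feasible*).  The feasibility domain of an interaction matrix is
the cone of growth-rate directions admitting such an equilibrium; its
relative spherical volume Omega in [0, 1] measures how much room the
interaction structure leaves for coexistence.

Sign convention: ``alpha_ij > 0`` is competition (it enters the Ricker
exponent with a minus sign), ``alpha_ij < 0`` is facilitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: equilibrium abundances below this are treated as non-positive
FEASIBILITY_TOL = 1e-10
#: condition number above which a subset matrix is declared singular
SINGULARITY_COND = 1e12


@dataclass(frozen=True)
class LVCommunity:
    """A Lotka-Volterra community: growth rates ``r`` and interactions ``A``.

    ``A[i, j]`` is the per-capita effect of species ``j`` on species ``i``
    (positive = competition).
    """

    species: tuple[str, ...]
    r: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("interaction matrix must be square")
        if len(self.species) != A.shape[0] or r.shape != (A.shape[0],):
            raise ValueError("species, r and A dimensions do not match")
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "A", A)

    def index(self, subset: Sequence[str]) -> np.ndarray:
        pos = {sp: i for i, sp in enumerate(self.species)}
        try:
            return np.array([pos[sp] for sp in subset], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"species {exc.args[0]!r} not in community") from None


@dataclass
class FeasibilityResult:
    """Feasibility verdict for one species subset."""

    subset: tuple[str, ...]
    equilibrium: np.ndarray
    feasible: bool
    singular: bool = False
    omega: Optional[float] = None
    stable: Optional[bool] = None

    def __post_init__(self) -> None:
        self.subset = tuple(self.subset)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float)


def lv_growth_rate(
    log_lambda: float | np.ndarray,
    g: float | np.ndarray,
    s: float | np.ndarray,
    convention: str = "invasion",
) -> float | np.ndarray:
    """Map Ricker fecundity and seed-bank vital rates to an LV growth rate.

    With a seed bank, a rare species' seed count grows by the factor
    ``g * lambda + (1 - g) * s`` per season, so it can invade exactly when
    ``lambda`` exceeds ``(1 - (1-g) s)/g``.  The default ``"invasion"``
    convention returns

        r = log(lambda) - log((1 - (1-g) s) / g),

    which is zero precisely at that invasion boundary and reduces to
    ``ln lambda`` when ``g = 1`` (no seed bank).  ``convention="printed"``
    instead returns ``log((1 - (1-g) s)/g) + lambda`` for comparison with
    the alternative published form.

    Parameters
    ----------
    log_lambda
        Natural log of per-germinant fecundity in the absence of neighbors.
    g
        Seed germination probability, in (0, 1].
    s
        Seed survival probability in the soil bank, in [0, 1).
    """
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    log_lambda = np.asarray(log_lambda, dtype=float)
    if np.any(g <= 0) or np.any(g > 1):
        raise ValueError("germination rate g must be in (0, 1]")
    if np.any(s < 0) or np.any(s >= 1):
        raise ValueError("seed survival s must be in [0, 1)")
    bank = np.log((1.0 - (1.0 - g) * s) / g)
    if convention == "invasion":
        out = log_lambda - bank
    elif convention == "printed":
        out = bank + np.exp(log_lambda)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return out.item() if out.ndim == 0 else out


def equilibrium_abundances(
    comm: LVCommunity, subset: Sequence[str]
) -> FeasibilityResult:
    """Solve for the interior equilibrium of a species subset.

    Solves ``A' N* = r'`` on the subset and flags feasibility when every
    component exceeds the positivity tolerance.  A subset matrix with
    condition number above ``SINGULARITY_COND`` is reported singular and
    infeasible.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    idx = comm.index(subset)
    A_sub = comm.A[np.ix_(idx, idx)]
    r_sub = comm.r[idx]
    try:
        ill = not np.all(np.isfinite(A_sub)) or np.linalg.cond(A_sub) > SINGULARITY_COND
    except np.linalg.LinAlgError:
        ill = True
    if ill:
        return FeasibilityResult(
            subset, np.full(len(subset), np.nan), feasible=False, singular=True
        )
    n_star = np.linalg.solve(A_sub, r_sub)
    feasible = bool(np.all(n_star > FEASIBILITY_TOL))
    return FeasibilityResult(subset, n_star, feasible=feasible)


def feasibility_domain_volume(
    A: np.ndarray, n_samples: int = 100_000, seed: int | None = None
) -> float:
    """Relative spherical volume Omega of the feasibility cone of ``A``.

    The feasible growth-rate directions are ``{r : A^-1 r > 0}``, the cone
    positively spanned by the columns of ``A``.  Returns the fraction of
    the unit sphere it occupies: closed form for dimension <= 2 (1/2 in
    dimension 1; the angle between normalized columns over 2*pi in
    dimension 2), Monte-Carlo over uniform random directions otherwise.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    d = A.shape[0]
    if np.linalg.cond(A) > SINGULARITY_COND:
        raise np.linalg.LinAlgError("singular interaction matrix")
    if d == 1:
        return 0.5
    if d == 2:
        c0 = A[:, 0] / np.linalg.norm(A[:, 0])
        c1 = A[:, 1] / np.linalg.norm(A[:, 1])
        angle = np.arccos(np.clip(c0 @ c1, -1.0, 1.0))
        return float(angle / (2.0 * np.pi))
    if seed is None:
        raise ValueError("Monte-Carlo Omega (dim > 2) requires a seed")
    rng = np.random.default_rng(seed)
    # direction uniformity only; radius is irrelevant for cone membership
    directions = rng.standard_normal((n_samples, d))
    solutions = np.linalg.solve(A, directions.T)
    hits = np.all(solutions > 0.0, axis=0)
    return float(hits.mean())


def local_stability(res: FeasibilityResult, comm: LVCommunity) -> bool:
    """Local asymptotic stability of a feasible interior equilibrium.

    The LV Jacobian at ``N*`` is ``-diag(N*) A'``; the equilibrium is
    stable iff every eigenvalue has negative real part.
    """
    if not res.feasible:
        raise ValueError("local stability is defined only for feasible subsets")
    idx = comm.index(res.subset)
    A_sub = comm.A[np.ix_(idx, idx)]
    jac = -np.diag(res.equilibrium) @ A_sub
    eigvals = np.linalg.eigvals(jac)
    return bool(np.all(eigvals.real < 0.0))
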