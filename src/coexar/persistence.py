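"""Persistence classification of species from subset feasibility.

Every species observed in a plot-year community is assigned the *simplest*
community configuration under which it is predicted to persist:

- ``pair``: member of at least one feasible two-species subset;
- ``multispecies``: otherwise, member of a feasible subset of three or more
  species (persistence through indirect interactions, e.g.
  rock-paper-scissors);
- ``dominant``: persists alone (positive monoculture equilibrium
  ``r_i / alpha_ii``) but in no feasible multi-species subset;
- ``transient``: predicted unable to persist under any configuration of its
  local community — a sink maintained by dispersal or the seed bank.

The ``pair > multispecies > dominant`` precedence reflects that two-species
coexistence is the simplest configuration in which a species persists *with*
others; a species that could persist alone but also coexists in a pair is
classified ``pair``.  The precedence is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .structural import (
    FEASIBILITY_TOL,
    SINGULARITY_COND,
    FeasibilityResult,
    LVCommunity,
    equilibrium_abundances,
)

CATEGORIES = ("dominant", "pair", "multispecies", "transient")
DEFAULT_PRECEDENCE = ("pair", "multispecies", "dominant")
#: exhaustive subset enumeration refuses larger communities without override
HARD_CAP = 20


@dataclass
class PersistenceRecord:
    """Persistence category of one species in one plot-year community."""

    year: object
    plot: object
    species: str
    category: str
    #: smallest (then lexicographically first) feasible subset containing the
    #: species; empty for transients
    witness_subset: tuple[str, ...] = ()


def singleton_feasible(comm: LVCommunity, species: str) -> bool:
    """A species persists alone iff r_i > 0 and alpha_ii > 0."""
    i = comm.index([species])[0]
    return bool(comm.r[i] > FEASIBILITY_TOL and comm.A[i, i] > 0.0)


def enumerate_feasible_subsets(
    comm: LVCommunity, max_size: int | None = None, allow_large: bool = False
) -> list[FeasibilityResult]:
    """Feasibility of every species subset of size 1..max_size.

    Singletons are judged by the monoculture rule (``r_i > 0`` and
    ``alpha_ii > 0``); larger subsets by positivity of the interior
    equilibrium.  Results are keyed canonically: within each size, subsets
    appear in lexicographic species order.
    """
    S = len(comm.species)
    if max_size is None:
        max_size = S
    if max_size > S:
        raise ValueError("max_size exceeds community size")
    if S > HARD_CAP and not allow_large:
        raise ValueError(
            f"community of {S} species exceeds the exhaustive-enumeration cap "
            f"({HARD_CAP}); pass allow_large=True to override"
        )
    order = sorted(comm.species)
    results: list[FeasibilityResult] = []
    for sp in order:
        i = comm.index([sp])[0]
        if singleton_feasible(comm, sp):
            res = FeasibilityResult(
                (sp,), np.array([comm.r[i] / comm.A[i, i]]), feasible=True
            )
        else:
            res = FeasibilityResult((sp,), np.array([np.nan]), feasible=False)
        results.append(res)
    for size in range(2, max_size + 1):
        for subset in combinations(order, size):
            results.append(equilibrium_abundances(comm, subset))
    return results


def classify_species(
    feasible_subsets: Iterable[FeasibilityResult],
    comm: LVCommunity,
    year: object = None,
    plot: object = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> list[PersistenceRecord]:
    """Assign each species its persistence category from enumerated subsets."""
    if sorted(precedence) != sorted(DEFAULT_PRECEDENCE):
        raise ValueError(f"precedence must be a permutation of {DEFAULT_PRECEDENCE}")
    # smallest feasible witness per species per configuration class
    witness: dict[str, dict[str, tuple[str, ...]]] = {
        sp: {} for sp in comm.species
    }
    for res in feasible_subsets:
        if not res.feasible:
            continue
        if len(res.subset) == 1:
            kind = "dominant"
        elif len(res.subset) == 2:
            kind = "pair"
        else:
            kind = "multispecies"
        for sp in res.subset:
            prev = witness[sp].get(kind)
            if prev is None or (len(res.subset), res.subset) < (len(prev), prev):
                witness[sp][kind] = res.subset
    records = []
    for sp in sorted(comm.species):
        category = "transient"
        chosen: tuple[str, ...] = ()
        for kind in precedence:
            if kind in witness[sp]:
                category = kind
                chosen = witness[sp][kind]
                break
        records.append(PersistenceRecord(year, plot, sp, category, chosen))
    return records


def _feasible_mask(comm: LVCommunity, idx: np.ndarray) -> np.ndarray:
    """Feasibility of many equal-size subsets at once (batched solves).

    ``idx`` has shape (n_subsets, size), rows are index arrays into the
    community.  Exactly equivalent to per-subset
    :func:`~coexar.structural.equilibrium_abundances` verdicts: singular
    or ill-conditioned subset matrices (condition number above the
    singularity threshold) are infeasible.
    """
    A_subs = comm.A[idx[:, :, None], idx[:, None, :]]
    r_subs = comm.r[idx]
    n = len(idx)
    with np.errstate(all="ignore"):
        try:
            sols = np.linalg.solve(A_subs, r_subs[..., None])[..., 0]
            out = np.all(np.isfinite(sols) & (sols > FEASIBILITY_TOL), axis=1)
        except np.linalg.LinAlgError:
            # an exactly singular member aborts the whole batched solve:
            # screen by batched condition number, solve the rest
            conds = np.linalg.cond(A_subs)
            good = np.isfinite(conds) & (conds <= SINGULARITY_COND)
            out = np.zeros(n, dtype=bool)
            if good.any():
                try:
                    sols = np.linalg.solve(A_subs[good], r_subs[good][..., None])[..., 0]
                    out[good] = np.all(
                        np.isfinite(sols) & (sols > FEASIBILITY_TOL), axis=1
                    )
                except np.linalg.LinAlgError:  # pragma: no cover - last resort
                    for m in np.flatnonzero(good):
                        subset = tuple(comm.species[i] for i in idx[m])
                        out[m] = equilibrium_abundances(comm, subset).feasible
            return out
        # post-verify: an ill-conditioned subset that solved anyway is
        # declared singular (hence infeasible) by the per-subset contract
        if out.any():
            conds = np.linalg.cond(A_subs[out])
            bad = ~np.isfinite(conds) | (conds > SINGULARITY_COND)
            if bad.any():
                flip = np.flatnonzero(out)[bad]
                out[flip] = False
    return out


def classify_community(
    comm: LVCommunity,
    year: object = None,
    plot: object = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    allow_large: bool = False,
) -> list[PersistenceRecord]:
    """Classify all species of a community, enumerating subsets lazily.

    Equivalent to ``classify_species(enumerate_feasible_subsets(comm), comm)``
    under the default precedence, but with three exact shortcuts that keep
    species-rich plots and null-model ensembles tractable:

    - subsets of equal size are solved in one batched linear solve;
    - beyond pairs, only subsets containing a not-yet-classified species
      are visited, and enumeration stops once every species is placed;
    - a species with ``r_i <= 0`` whose row of ``A`` is entirely
      non-negative can never belong to a feasible subset (its equilibrium
      condition sums non-negative terms to a non-positive total), so it is
      transient without enumeration.
    """
    if tuple(precedence) != DEFAULT_PRECEDENCE:
        # non-default precedences take the exhaustive route
        return classify_species(
            enumerate_feasible_subsets(comm, allow_large=allow_large),
            comm, year, plot, precedence,
        )
    S = len(comm.species)
    if S > HARD_CAP and not allow_large:
        raise ValueError(
            f"community of {S} species exceeds the exhaustive-enumeration cap "
            f"({HARD_CAP}); pass allow_large=True to override"
        )
    order = sorted(comm.species)
    pos = {sp: comm.index([sp])[0] for sp in order}
    category: dict[str, str] = {}
    chosen: dict[str, tuple[str, ...]] = {}

    def note(sp: str, kind: str, subset: tuple[str, ...]) -> None:
        if sp not in category:
            category[sp] = kind
            chosen[sp] = subset

    if S >= 2:
        pairs = list(combinations(order, 2))
        idx = np.array([[pos[a], pos[b]] for a, b in pairs])
        for subset, ok in zip(pairs, _feasible_mask(comm, idx)):
            if ok:
                for sp in subset:
                    note(sp, "pair", subset)
    pending = [sp for sp in order if sp not in category]
    # exact pruning: r <= 0 with an all-competitive row is hopeless
    hopeless = {
        sp
        for sp in pending
        if comm.r[pos[sp]] <= FEASIBILITY_TOL and np.all(comm.A[pos[sp]] >= 0.0)
    }
    pending = [sp for sp in pending if sp not in hopeless]
    for size in range(3, S + 1):
        if not pending:
            break
        # inclusion chain over the pending species: subsets containing
        # pending[0]; then containing pending[1] but not pending[0]; ... —
        # exactly the subsets holding >= 1 pending species, each once,
        # without filtering all C(S, size) combinations in Python
        subsets: list[tuple[str, ...]] = []
        excluded: set[str] = set()
        for anchor in pending:
            rest = [sp for sp in order if sp != anchor and sp not in excluded]
            if len(rest) >= size - 1:
                subsets.extend(
                    tuple(sorted((anchor,) + tail))
                    for tail in combinations(rest, size - 1)
                )
            excluded.add(anchor)
        if subsets:
            idx = np.array([[pos[sp] for sp in sub] for sub in subsets])
            feasible = [sub for sub, ok in zip(subsets, _feasible_mask(comm, idx)) if ok]
            for subset in sorted(feasible):  # lexicographic witness order
                for sp in subset:
                    note(sp, "multispecies", subset)
        pending = [sp for sp in pending if sp not in category]
    for sp in order:
        if sp not in category and singleton_feasible(comm, sp):
            note(sp, "dominant", (sp,))
    return [
        PersistenceRecord(year, plot, sp, category.get(sp, "transient"), chosen.get(sp, ()))
        for sp in order
    ]


def persistent_set(records: Iterable[PersistenceRecord]) -> list[str]:
    """Species predicted to persist: every category except transient."""
    return sorted({r.species for r in records if r.category != "transient"})
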