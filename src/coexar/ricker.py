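"""Negative-binomial Ricker fecundity inference.

Per focal species ``i``, the viable seed count of a focal individual is
modeled as negative-binomial with mean

    mu = lambda_i * exp(-sum_j alpha_ij N_j),

i.e. a log-link NB regression of seeds on the neighbor-count columns: the
intercept is ``log lambda_i`` and the slope on neighbor ``j`` is
``-alpha_ij``.  Two parameterizations are provided per year:

- *homogeneous*: observations pooled over all plots, one NB2 maximum-
  likelihood fit per focal species (backed by
  ``statsmodels.discrete.NegativeBinomial``, which also yields asymptotic
  standard errors and a per-species dispersion estimate);
- *heterogeneous*: per-plot coefficients obtained by penalized maximum
  likelihood, with plot-level deviations from the pooled estimates shrunk
  by a Gaussian penalty (a deterministic partial-pooling analog of a
  crossed plot random effect on intercept and all slopes).  The penalty
  scale is ``shrinkage_sd`` on the intercept (log fecundity) and
  ``shrinkage_sd``, reduced to the natural scale of interaction
  coefficients, on the slopes; without the scale separation the optimizer
  would absorb fecundity deviations into many tiny slope deviations, since
  log-fecundities and per-capita interaction strengths differ by two
  orders of magnitude.

Neighbor species never observed next to a focal species carry no
information about their coefficient; those entries are fixed at zero and
flagged ``fixed_zero_unobserved``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

import statsmodels.api as sm

from .synthetic import ALPHA_HETEROGENEITY_SCALE, neighbor_columns

FLAG_ESTIMATED = "estimated"
FLAG_FIXED_ZERO = "fixed_zero_unobserved"
FLAG_BOUNDARY = "boundary"

#: plot label for pooled (study-wide) fits
ALL_PLOTS = "ALL"


@dataclass
class CommunityParams:
    """Fitted (or true) Ricker parameters for one year and plot scope."""

    year: object
    plot: object
    species: tuple[str, ...]
    log_lambda: np.ndarray  # (S,)
    alpha: np.ndarray  # (S, S), focal x neighbor
    g: np.ndarray  # (S,)
    s: np.ndarray  # (S,)
    dispersion: np.ndarray  # (S,) NB size k
    se_log_lambda: np.ndarray | None = None  # (S,)
    se_alpha: np.ndarray | None = None  # (S, S)
    fit_flags: np.ndarray | None = None  # (S, S) object array
    converged: np.ndarray | None = None  # (S,) bool
    loglik: np.ndarray | None = None  # (S,)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        S = len(self.species)
        if self.alpha.shape != (S, S):
            raise ValueError("alpha must be square over the species list")
        if self.se_alpha is not None and np.any(self.se_alpha < 0):
            raise ValueError("standard errors must be nonnegative")
        if np.any((self.g <= 0) | (self.g > 1)) or np.any((self.s < 0) | (self.s >= 1)):
            raise ValueError("vital rates out of range")

    def index(self, sp: str) -> int:
        return self.species.index(sp)

    def restricted_to(self, subset: Sequence[str]) -> "CommunityParams":
        """Parameters restricted to a species subset (order preserved)."""
        idx = np.array([self.index(sp) for sp in subset])
        return CommunityParams(
            year=self.year,
            plot=self.plot,
            species=tuple(subset),
            log_lambda=self.log_lambda[idx],
            alpha=self.alpha[np.ix_(idx, idx)],
            g=self.g[idx],
            s=self.s[idx],
            dispersion=self.dispersion[idx],
            se_log_lambda=None if self.se_log_lambda is None else self.se_log_lambda[idx],
            se_alpha=None if self.se_alpha is None else self.se_alpha[np.ix_(idx, idx)],
            fit_flags=None if self.fit_flags is None else self.fit_flags[np.ix_(idx, idx)],
            converged=None if self.converged is None else self.converged[idx],
            loglik=None if self.loglik is None else self.loglik[idx],
        )


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    """NB2 log-pmf with mean ``mu`` and size ``k`` (var = mu + mu^2/k)."""
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        + k * (np.log(k) - np.log(k + mu))
        + y * (np.log(mu) - np.log(k + mu))
    )


def neg_binomial_ricker_loglik(params: CommunityParams, obs: pd.DataFrame) -> float:
    """Total NB log-likelihood of an observation table under ``params``.

    Each row contributes the NB2 log-probability of its seed count with
    Ricker mean ``lambda_i * exp(-sum_j alpha_ij N_j)`` summed over the
    neighbor species present in ``params``.
    """
    total = 0.0
    cols = neighbor_columns(params.species)
    missing = [c for c in cols if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table lacks neighbor columns {missing}")
    for sp in obs["focal"].unique():
        if sp not in params.species:
            raise ValueError(f"focal species {sp!r} not present in params")
    for i, sp in enumerate(params.species):
        rows = obs[obs["focal"] == sp]
        if rows.empty:
            continue
        N = rows[cols].to_numpy(dtype=float)
        eta = params.log_lambda[i] - N @ params.alpha[i]
        mu = np.exp(eta)
        bad = ~np.isfinite(mu)
        if bad.any():
            raise FloatingPointError(
                f"nonfinite Ricker mean at observation row index "
                f"{rows.index[np.argmax(bad)]}"
            )
        total += float(
            _nb_logpmf(rows["seeds"].to_numpy(dtype=float), mu, params.dispersion[i]).sum()
        )
    return total


def _species_design(
    obs_i: pd.DataFrame, all_species: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response, design matrix (intercept + observed-neighbor columns)."""
    y = obs_i["seeds"].to_numpy(dtype=float)
    observed = [
        sp for sp in all_species if obs_i[f"n_{sp}"].to_numpy(dtype=float).sum() > 0
    ]
    X = np.column_stack(
        [np.ones(len(obs_i))]
        + [obs_i[f"n_{sp}"].to_numpy(dtype=float) for sp in observed]
    )
    return y, X, observed


def fit_homogeneous(
    obs: pd.DataFrame,
    g: Mapping[str, float],
    s: Mapping[str, float],
    year: object,
) -> CommunityParams:
    """Pooled (study-wide) NB Ricker fit for one year.

    One NB2 MLE per focal species over all plots; returns point estimates,
    asymptotic standard errors, per-species dispersion, and per-coefficient
    flags.  Species whose fit does not converge keep their estimates but
    are flagged unconverged; species with degenerate data (all-zero seed
    counts) are dropped with a warning.
    """
    obs = obs[obs["year"] == year]
    if obs.empty:
        raise ValueError(f"no observations for year {year!r}")
    species = sorted(obs["focal"].unique())
    kept: list[str] = []
    results: dict[str, dict] = {}
    for sp in species:
        obs_i = obs[obs["focal"] == sp]
        y, X, observed = _species_design(obs_i, species)
        if np.all(y == 0):
            warnings.warn(
                f"species {sp!r}: all seed counts are zero; species dropped from fit"
            )
            continue
        beta, se, k, se_k, converged, llf = _fit_nb2(y, X)
        kept.append(sp)
        results[sp] = {
            "observed": observed,
            "beta": beta,
            "se": se,
            "k": k,
            "converged": converged,
            "llf": llf,
        }
    S = len(kept)
    if S == 0:
        raise ValueError("no species could be fitted")
    log_lambda = np.zeros(S)
    alpha = np.zeros((S, S))
    se_ll = np.zeros(S)
    se_alpha = np.zeros((S, S))
    flags = np.full((S, S), FLAG_FIXED_ZERO, dtype=object)
    converged = np.zeros(S, dtype=bool)
    loglik = np.zeros(S)
    dispersion = np.zeros(S)
    for i, sp in enumerate(kept):
        res = results[sp]
        log_lambda[i] = res["beta"][0]
        se_ll[i] = res["se"][0]
        converged[i] = res["converged"]
        loglik[i] = res["llf"]
        dispersion[i] = res["k"]
        for m, nb in enumerate(res["observed"]):
            if nb not in kept:
                continue
            j = kept.index(nb)
            alpha[i, j] = -res["beta"][1 + m]  # slope is -alpha
            se_alpha[i, j] = res["se"][1 + m]
            flags[i, j] = FLAG_ESTIMATED
    return CommunityParams(
        year=year,
        plot=ALL_PLOTS,
        species=tuple(kept),
        log_lambda=log_lambda,
        alpha=alpha,
        g=np.array([g[sp] for sp in kept], dtype=float),
        s=np.array([s[sp] for sp in kept], dtype=float),
        dispersion=dispersion,
        se_log_lambda=se_ll,
        se_alpha=se_alpha,
        fit_flags=flags,
        converged=converged,
        loglik=loglik,
    )


def _fit_nb2(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, bool, float]:
    """NB2 MLE via statsmodels; returns (beta, se_beta, k, se_k, converged, llf)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start = sm.Poisson(y, X).fit(disp=0, maxiter=200).params
        except Exception:
            start = np.zeros(X.shape[1])
            start[0] = np.log(max(y.mean(), 0.1))
        start = np.append(start, 0.5)  # NB2 alpha = 1/k
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        try:
            res = model.fit(start_params=start, disp=0, maxiter=500, method="bfgs")
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
            converged = False
        if res is None:
            # fall back to an unpenalized scipy fit with fixed moderate dispersion
            beta = _penalized_nb_fit(y, X, start[:-1], np.inf, 2.0)[0]
            se = _wald_se(y, X, beta, 2.0, np.inf)
            mu = np.exp(X @ beta)
            llf = float(_nb_logpmf(y, mu, 2.0).sum())
            return beta, se, 2.0, np.nan, False, llf
        beta = np.asarray(res.params[:-1], dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)
        a = float(res.params[-1])  # statsmodels alpha = 1/k
        if not np.all(np.isfinite(res.params)) or a < 1e-4 or not np.all(np.isfinite(bse)):
            # dispersion at the Poisson boundary (or singular Hessian):
            # refit the mean structure at a near-Poisson fixed dispersion,
            # with expected-information SEs
            k = 1e6
            beta, ok = _penalized_nb_fit(y, X, start[:-1], np.inf, k)
            se = _wald_se(y, X, beta, k, np.inf)
            mu = np.exp(np.clip(X @ beta, -30, 30))
            return beta, se, k, np.nan, ok, float(_nb_logpmf(y, mu, k).sum())
    se = bse[:-1]
    a = max(a, 1e-6)
    k = 1.0 / a
    se_k = float(bse[-1]) / a**2
    return beta, se, k, se_k, converged, llf


def _penalized_nb_objective(
    beta: np.ndarray, y: np.ndarray, X: np.ndarray, beta0: np.ndarray,
    sd: float | np.ndarray, k: float,
) -> tuple[float, np.ndarray]:
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    nll = -float(_nb_logpmf(y, mu, k).sum())
    grad = -X.T @ ((y - mu) * k / (k + mu))
    finite = np.isfinite(sd)
    if np.any(finite):
        dev = np.where(finite, beta - beta0, 0.0)
        inv_var = np.where(finite, 1.0 / np.asarray(sd) ** 2, 0.0)
        nll += 0.5 * float(dev @ (inv_var * dev))
        grad = grad + inv_var * dev
    return nll, grad


def _penalized_nb_fit(
    y: np.ndarray, X: np.ndarray, beta0: np.ndarray,
    sd: float | np.ndarray, k: float,
) -> tuple[np.ndarray, bool]:
    sd = np.broadcast_to(np.asarray(sd, dtype=float), beta0.shape)
    res = minimize(
        _penalized_nb_objective,
        x0=beta0.copy(),
        args=(y, X, beta0, sd, k),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-20.0, 20.0)] * len(beta0),  # guards against separation
        options={"maxiter": 500},
    )
    return np.asarray(res.x, dtype=float), bool(res.success)


def _wald_se(
    y: np.ndarray, X: np.ndarray, beta: np.ndarray, k: float,
    sd: float | np.ndarray,
) -> np.ndarray:
    """SEs from the expected-information Hessian of the penalized objective."""
    mu = np.exp(np.clip(X @ beta, -30, 30))
    w = mu * k / (k + mu)
    H = X.T @ (X * w[:, None])
    sd = np.broadcast_to(np.asarray(sd, dtype=float), beta.shape)
    finite = np.isfinite(sd)
    if np.any(finite):
        H = H + np.diag(np.where(finite, 1.0 / sd**2, 0.0))
    H = np.where(np.isfinite(H), H, 0.0)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        d = np.clip(np.diag(H), 1e-12, None)
        se = 1.0 / np.sqrt(d)
    return se


def fit_heterogeneous(
    obs: pd.DataFrame,
    g: Mapping[str, float],
    s: Mapping[str, float],
    year: object,
    shrinkage_sd: float = 0.5,
    pooled: CommunityParams | None = None,
    slope_scale: float = ALPHA_HETEROGENEITY_SCALE,
) -> list[CommunityParams]:
    """Per-plot NB Ricker fits with Gaussian shrinkage toward the pooled fit.

    For every plot and focal species observed there, the coefficient vector
    (intercept and all estimated neighbor slopes) maximizes the NB
    log-likelihood of that plot's rows plus an elementwise Gaussian penalty
    on the deviation from the pooled estimates: scale ``shrinkage_sd`` for
    the intercept and ``shrinkage_sd * slope_scale`` for the neighbor
    slopes; dispersion is fixed at the pooled estimate.
    ``shrinkage_sd = 0`` returns the pooled estimates for every plot
    (infinite penalty).  Species absent from a plot carry no estimate
    there.
    """
    if shrinkage_sd < 0:
        raise ValueError("shrinkage_sd must be nonnegative")
    obs = obs[obs["year"] == year]
    if pooled is None:
        pooled = fit_homogeneous(obs, g, s, year)
    out: list[CommunityParams] = []
    for plot in sorted(obs["plot"].unique(), key=str):
        obs_p = obs[obs["plot"] == plot]
        plot_species = [sp for sp in pooled.species if (obs_p["focal"] == sp).any()]
        if not plot_species:
            continue
        sub = pooled.restricted_to(plot_species)
        sub.plot = plot
        if shrinkage_sd == 0:
            out.append(sub)
            continue
        S = len(plot_species)
        log_lambda = sub.log_lambda.copy()
        alpha = sub.alpha.copy()
        se_ll = sub.se_log_lambda.copy()
        se_alpha = sub.se_alpha.copy()
        converged = np.ones(S, dtype=bool)
        loglik = np.zeros(S)
        for i, sp in enumerate(plot_species):
            obs_i = obs_p[obs_p["focal"] == sp]
            pi = pooled.index(sp)
            # coefficients estimated in the pooled fit, restricted to the plot list
            est = [
                nb for nb in plot_species
                if pooled.fit_flags[pi, pooled.index(nb)] == FLAG_ESTIMATED
            ]
            X = np.column_stack(
                [np.ones(len(obs_i))]
                + [obs_i[f"n_{nb}"].to_numpy(dtype=float) for nb in est]
            )
            y = obs_i["seeds"].to_numpy(dtype=float)
            beta0 = np.concatenate(
                [
                    [pooled.log_lambda[pi]],
                    [-pooled.alpha[pi, pooled.index(nb)] for nb in est],
                ]
            )
            k = pooled.dispersion[pi]
            sd_vec = np.full(len(beta0), shrinkage_sd * slope_scale)
            sd_vec[0] = shrinkage_sd
            beta, ok = _penalized_nb_fit(y, X, beta0, sd_vec, k)
            se = _wald_se(y, X, beta, k, sd_vec)
            log_lambda[i] = beta[0]
            se_ll[i] = se[0]
            converged[i] = ok
            loglik[i] = float(_nb_logpmf(y, np.exp(np.clip(X @ beta, -30, 30)), k).sum())
            for m, nb in enumerate(est):
                j = plot_species.index(nb)
                alpha[i, j] = -beta[1 + m]
                se_alpha[i, j] = se[1 + m]
        out.append(
            CommunityParams(
                year=year,
                plot=plot,
                species=tuple(plot_species),
                log_lambda=log_lambda,
                alpha=alpha,
                g=sub.g,
                s=sub.s,
                dispersion=sub.dispersion,
                se_log_lambda=se_ll,
                se_alpha=se_alpha,
                fit_flags=sub.fit_flags,
                converged=converged,
                loglik=loglik,
            )
        )
    return out


def draw_parameter_replicates(
    fit: CommunityParams, n_draws: int = 100, seed: int = 0
) -> list[CommunityParams]:
    """Gaussian sampling-distribution draws of the fitted coefficients.

    Each draw perturbs ``log lambda`` and every estimated ``alpha`` entry
    by a Gaussian with its asymptotic standard error; coefficients flagged
    ``fixed_zero_unobserved`` stay exactly zero.  Used to check that the
    downstream curves are robust to parameter uncertainty.
    """
    if fit.se_log_lambda is None or fit.se_alpha is None:
        raise ValueError("fit carries no standard errors")
    rng = np.random.default_rng(seed)
    draws = []
    estimated = (
        fit.fit_flags == FLAG_ESTIMATED
        if fit.fit_flags is not None
        else np.ones_like(fit.alpha, dtype=bool)
    )
    for _ in range(n_draws):
        ll = fit.log_lambda + rng.normal(0.0, 1.0, len(fit.species)) * fit.se_log_lambda
        a = fit.alpha + np.where(
            estimated, rng.normal(0.0, 1.0, fit.alpha.shape) * fit.se_alpha, 0.0
        )
        draws.append(
            CommunityParams(
                year=fit.year,
                plot=fit.plot,
                species=fit.species,
                log_lambda=ll,
                alpha=a,
                g=fit.g,
                s=fit.s,
                dispersion=fit.dispersion.copy(),
                fit_flags=fit.fit_flags,
            )
        )
    return draws
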