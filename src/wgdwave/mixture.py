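"""Univariate Gaussian mixtures for locating WGD clustering in time.

A mixture of normal components is fitted to the independent WGD event ages
by expectation-maximization, and the number of components is chosen by the
Akaike Information Criterion, AIC = 2k - 2 ln L with k = 3m - 1 free
parameters for m components (m means, m variances, m - 1 free weights).
Fitting the mixture avoids any arbitrary cut-off for deciding which events
belong to a temporal cluster: the dominant component's location is the
cluster's age.

The one-component fit uses the closed-form maximum-likelihood estimate
(mean and biased, n-denominator variance).  Multi-component fits run EM
from several seeded initializations and keep the best log-likelihood.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import DegenerateInputError, ParameterError

__all__ = ["MixtureFit", "fit_gmm", "select_by_aic", "refit_excluding"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass(frozen=True)
class MixtureFit:
    """A fitted univariate Gaussian mixture, components sorted by mean."""

    m: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    n_params: int
    aic: float
    converged: bool
    n_iter: int
    n_restarts: int
    seed: int | None

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ParameterError("mixture weights must sum to 1")

    def dominant_component(self) -> int:
        """Index of the highest-weight component (ties: larger mean)."""
        order = np.lexsort((self.means, self.weights))
        return int(order[-1])


def _loglik_matrix(x: np.ndarray, w, mu, var) -> np.ndarray:
    # (n, m) matrix of log(w_j * phi(x_i; mu_j, var_j))
    return (
        np.log(w)[None, :]
        - 0.5 * (_LOG_2PI + np.log(var))[None, :]
        - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
    )


def fit_gmm(
    ages,
    m: int,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    variance_floor_fraction: float = 1e-6,
    min_component_support: float = 2.0,
    min_variance_ratio: float = 1e-2,
) -> MixtureFit:
    """Fit an m-component Gaussian mixture to event ages by EM.

    Initialization per restart: means at data quantiles with Gaussian
    jitter, variances at the total variance divided by m, uniform weights.
    Convergence when the relative log-likelihood change drops below
    ``tol``; the log-likelihood is asserted non-decreasing across
    iterations.  Variances are floored at ``variance_floor_fraction``
    times the total data variance to avoid likelihood singularities on
    small samples.
    """
    x = np.asarray(ages, dtype=float).ravel()
    n = x.size
    if m < 1:
        raise ParameterError("m must be at least 1")
    if n < m:
        raise ParameterError(f"need at least m={m} data points, got {n}")

    if m == 1:
        mean = float(x.mean())
        var = float(x.var())  # biased MLE (n denominator)
        if var <= 0:
            var = max(var, 1e-300)
        ll = float(-0.5 * n * (_LOG_2PI + np.log(var) + 1.0))
        n_params = 2
        return MixtureFit(
            m=1,
            weights=np.array([1.0]),
            means=np.array([mean]),
            variances=np.array([var]),
            log_likelihood=ll,
            n_params=n_params,
            aic=2.0 * n_params - 2.0 * ll,
            converged=True,
            n_iter=0,
            n_restarts=0,
            seed=seed,
        )

    total_var = float(x.var())
    if total_var == 0:
        raise DegenerateInputError(
            "all ages identical: a multi-component fit is degenerate"
        )
    var_floor = variance_floor_fraction * total_var
    rng = np.random.default_rng(seed)
    sd = np.sqrt(total_var)

    tiers: list = [None, None, None]
    for _ in range(n_restarts):
        q = np.quantile(x, (np.arange(m) + 1.0) / (m + 1.0))
        mu = q + rng.normal(0.0, 0.5 * sd, m)
        var = np.full(m, total_var / m)
        w = np.full(m, 1.0 / m)

        prev_ll = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            log_joint = _loglik_matrix(x, w, mu, var)
            log_norm = logsumexp(log_joint, axis=1)
            ll = float(log_norm.sum())
            if ll + 1e-9 * (1.0 + abs(ll)) < prev_ll:
                raise RuntimeError(
                    f"EM log-likelihood decreased ({prev_ll} -> {ll})"
                )
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
                converged = True
                break
            prev_ll = ll
            resp = np.exp(log_joint - log_norm[:, None])
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            w = nk / n
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            var = np.maximum(var, var_floor)
        # Evaluate the likelihood at the final parameters (the loop's last
        # ll may predate the closing M-step when max_iter is hit).
        log_joint = _loglik_matrix(x, w, mu, var)
        log_norm = logsumexp(log_joint, axis=1)
        final_ll = float(log_norm.sum())
        # Unequal-variance mixtures have an unbounded likelihood: a
        # component can collapse onto one or two close points.  Restarts
        # are ranked in three tiers.  Tier 0: the variance ratio respects
        # a Hathaway-style lower bound and every component is supported by
        # at least ~2 points.  Tier 1: supported but with collapsed
        # relative variance (a genuinely tight cluster next to a broad
        # one).  Tier 2: singleton spikes — admissible only when nothing
        # else exists (true point-mass data).
        nk_final = np.exp(log_joint - log_norm[:, None]).sum(axis=0)
        supported = bool(np.min(nk_final) >= min_component_support)
        ratio_ok = bool(var.min() / var.max() >= min_variance_ratio)
        tier = 0 if (supported and ratio_ok) else (1 if supported else 2)
        candidate = (final_ll, w, mu, var, converged, it)
        if tiers[tier] is None or candidate[0] > tiers[tier][0]:
            tiers[tier] = candidate

    best = next(t for t in tiers if t is not None)
    ll, w, mu, var, converged, it = best
    order = np.argsort(mu)
    n_params = 3 * m - 1
    return MixtureFit(
        m=m,
        weights=w[order],
        means=mu[order],
        variances=var[order],
        log_likelihood=float(ll),
        n_params=n_params,
        aic=float(2.0 * n_params - 2.0 * ll),
        converged=bool(converged),
        n_iter=int(it),
        n_restarts=int(n_restarts),
        seed=seed,
    )


def select_by_aic(
    ages,
    m_candidates=(1, 2, 3),
    n_restarts: int = 50,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Fit every candidate component count and pick the minimal AIC.

    Returns ``(best_fit, table)`` where the table lists per-m
    log-likelihood, parameter count, AIC and BIC.  AIC ties go to the
    smaller m.
    """
    candidates = sorted(set(int(m) for m in m_candidates))
    if not candidates:
        raise ParameterError("m_candidates must be non-empty")
    x = np.asarray(ages, dtype=float).ravel()
    fits = [
        fit_gmm(
            x, m, n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed
        )
        for m in candidates
    ]
    n = x.size
    table = pd.DataFrame(
        {
            "m": [f.m for f in fits],
            "log_likelihood": [f.log_likelihood for f in fits],
            "n_params": [f.n_params for f in fits],
            "aic": [f.aic for f in fits],
            "bic": [f.n_params * np.log(n) - 2.0 * f.log_likelihood for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    best = min(fits, key=lambda f: (f.aic, f.m))
    return best, table


def refit_excluding(
    events,
    exclude_ids,
    m_candidates=(1, 2, 3),
    n_restarts: int = 50,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Robustness run: mixture selection with and without named events.

    ``events`` is a sequence of objects with ``event_id`` and ``age``
    attributes (WGDEvent).  Returns a dict with the full and reduced
    selections side by side.
    """
    ids = [e.event_id for e in events]
    unknown = set(exclude_ids) - set(ids)
    if unknown:
        raise ParameterError(f"unknown event ids to exclude: {sorted(unknown)}")
    kept = [e for e in events if e.event_id not in set(exclude_ids)]
    max_m = max(int(m) for m in m_candidates)
    if len(kept) < max_m:
        raise ParameterError(
            f"excluding {sorted(set(exclude_ids))} leaves {len(kept)} events, "
            f"fewer than the largest candidate m={max_m}"
        )
    full_best, full_table = select_by_aic(
        [e.age for e in events],
        m_candidates=m_candidates,
        n_restarts=n_restarts,
        seed=seed,
        **kwargs,
    )
    reduced_best, reduced_table = select_by_aic(
        [e.age for e in kept],
        m_candidates=m_candidates,
        n_restarts=n_restarts,
        seed=seed,
        **kwargs,
    )
    return {
        "full": {"best": full_best, "table": full_table},
        "reduced": {"best": reduced_best, "table": reduced_table},
        "excluded": sorted(set(exclude_ids)),
    }
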