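"""Classical pseudo-R2 comparator indices and a univariate Cox fitter.

The four baselines against which the crossing-hazards index is compared are
all functions of a univariate Cox proportional-hazards fit:

* Allison's index ``1 - exp(-G/n)`` with ``G`` the likelihood-ratio
  statistic of the fit,
* its modified version ``1 - exp(-G/d)`` normalising by the number of
  events ``d`` instead of the sample size,
* Nagelkerke's rescaled index ``(1 - exp(-G/n)) / (1 - exp(2 l(0)/n))``,
* Xu & O'Quigley's explained-variation ratio built from risk-set covariate
  dispersion around the fitted and the null risk-set means.

The partial-likelihood fitter is written here (Newton–Raphson, Breslow tie
handling, step halving) so the comparators have no hidden model choices;
Efron ties and multivariable fits are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .datasets import SurvivalDataset
from .index import d0_index, d_ph_index

_BETA_CAP = 20.0
_SCORE_TOL = 1e-9
_MAX_ITER = 50


@dataclasses.dataclass(frozen=True)
class CoxFitResult:
    """Univariate Cox partial-likelihood fit summary."""

    beta_hat: float
    loglik_null: float
    loglik_hat: float
    lr_statistic: float
    n_events: int
    converged: bool
    iterations: int
    se_beta: float


def _partial_loglik_parts(time, event, z, beta):
    """Breslow partial log-likelihood, score and information at ``beta``."""
    order = np.argsort(time, kind="stable")
    t, e, zz = time[order], event[order], z[order]
    distinct = np.unique(t[e == 1])
    start = np.searchsorted(t, distinct, side="left")
    w = np.exp(beta * zz)
    # suffix sums over risk sets
    s0 = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))[start]
    s1 = np.concatenate((np.cumsum((w * zz)[::-1])[::-1], [0.0]))[start]
    s2 = np.concatenate((np.cumsum((w * zz * zz)[::-1])[::-1], [0.0]))[start]
    d = np.zeros(distinct.shape[0])
    zsum = np.zeros(distinct.shape[0])
    idx = np.searchsorted(distinct, t[e == 1])
    np.add.at(d, idx, 1.0)
    np.add.at(zsum, idx, zz[e == 1])
    loglik = float(beta * zsum.sum() - (d * np.log(s0)).sum())
    ebar = s1 / s0
    score = float(zsum.sum() - (d * ebar).sum())
    info = float((d * (s2 / s0 - ebar**2)).sum())
    return loglik, score, info


def cox_fit_univariate(
    data: SurvivalDataset, marker: str | np.ndarray | None = None
) -> CoxFitResult:
    """Fit the univariate Cox model by Newton–Raphson (Breslow ties).

    Convergence: ``|score| < 1e-9`` within 50 iterations, with step halving
    on any non-increase of the partial log-likelihood.  Monotone
    likelihoods (perfect risk-set separation) are capped at ``|beta| = 20``
    and flagged non-converged.
    """
    z = data.marker(marker) if marker is None or isinstance(marker, str) else np.asarray(marker, float)
    time, event = data.time, data.event
    if event.sum() == 0:
        raise ValueError("no observed failures")
    ll0, score0, info0 = _partial_loglik_parts(time, event, z, 0.0)
    beta, ll, score, info = 0.0, ll0, score0, info0
    converged = abs(score) < _SCORE_TOL
    iterations = 0
    while not converged and iterations < _MAX_ITER:
        iterations += 1
        step = score / info if info > 0 else math.copysign(1.0, score)
        new_beta = float(np.clip(beta + step, -_BETA_CAP, _BETA_CAP))
        new_ll, new_score, new_info = _partial_loglik_parts(time, event, z, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            halvings += 1
            new_beta = beta + (new_beta - beta) / 2.0
            new_ll, new_score, new_info = _partial_loglik_parts(time, event, z, new_beta)
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
        converged = abs(score) < _SCORE_TOL
        if abs(beta) >= _BETA_CAP:
            converged = False
            break
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return CoxFitResult(
        beta_hat=beta,
        loglik_null=ll0,
        loglik_hat=ll,
        lr_statistic=max(0.0, 2.0 * (ll - ll0)),
        n_events=int(event.sum()),
        converged=converged,
        iterations=iterations,
        se_beta=se,
    )


def allison_r2(fit: CoxFitResult, n: int) -> float:
    """Allison's likelihood-ratio index ``1 - exp(-G/n)``."""
    return 1.0 - math.exp(-fit.lr_statistic / n)


def allison_modified_r2(fit: CoxFitResult, k_events: int | None = None) -> float:
    """Modified Allison index ``1 - exp(-G/d)`` with ``d`` the event count."""
    d = fit.n_events if k_events is None else k_events
    return 1.0 - math.exp(-fit.lr_statistic / d)


def nagelkerke_r2(fit: CoxFitResult, n: int) -> float:
    """Nagelkerke's rescaled index ``(1 - exp(-G/n)) / (1 - exp(2 l(0)/n))``."""
    denom = 1.0 - math.exp(2.0 * fit.loglik_null / n)
    if denom <= 0:
        raise ValueError("degenerate null likelihood")
    return allison_r2(fit, n) / denom


def xu_oquigley_r2(
    data: SurvivalDataset,
    marker: str | np.ndarray | None = None,
    fit: CoxFitResult | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Xu & O'Quigley's explained-variation ratio.

    ``1 - sum_events w (Z_i - Ebar_bhat(t_i))^2 / sum_events w (Z_i - Ebar_0(t_i))^2``
    where ``Ebar_b(t)`` is the ``exp(b Z)``-weighted risk-set mean.  Unit
    event weights by default (``weights`` is a hook for other variants).
    """
    z = data.marker(marker) if marker is None or isinstance(marker, str) else np.asarray(marker, float)
    if fit is None:
        fit = cox_fit_univariate(data, z)
    time, event = data.time, data.event
    order = np.argsort(time, kind="stable")
    t, e, zz = time[order], event[order], z[order]

    def ebar_at(beta, times):
        w = np.exp(beta * zz)
        s0 = np.concatenate((np.cumsum(w[::-1])[::-1], [0.0]))
        s1 = np.concatenate((np.cumsum((w * zz)[::-1])[::-1], [0.0]))
        start = np.searchsorted(t, times, side="left")
        return s1[start] / s0[start]

    ev_times = t[e == 1]
    z_ev = zz[e == 1]
    w = np.ones_like(z_ev) if weights is None else np.asarray(weights, float)
    num = float((w * (z_ev - ebar_at(fit.beta_hat, ev_times)) ** 2).sum())
    den = float((w * (z_ev - ebar_at(0.0, ev_times)) ** 2).sum())
    if den == 0:
        raise ValueError("no covariate dispersion in risk sets")
    return 1.0 - num / den


INDEX_NAMES = ("D0", "D_PH", "allison", "allison_mod", "nagelkerke", "xu_oquigley")


def all_indices(
    data: SurvivalDataset, marker: str | np.ndarray | None = None
) -> dict[str, float]:
    """All six indices for one marker.

    Comparator failures (degenerate fits, flat markers) are recorded as
    ``nan`` and never abort the D0 / D_PH computation.
    """
    out: dict[str, float] = {}
    out["D0"] = d0_index(data, marker).value
    out["D_PH"] = d_ph_index(data, marker).value
    try:
        fit = cox_fit_univariate(data, marker)
        out["allison"] = allison_r2(fit, data.n)
        out["allison_mod"] = allison_modified_r2(fit)
        out["nagelkerke"] = nagelkerke_r2(fit, data.n)
    except ValueError:
        fit = None
        out.update(allison=np.nan, allison_mod=np.nan, nagelkerke=np.nan)
    try:
        out["xu_oquigley"] = xu_oquigley_r2(data, marker, fit=fit)
    except ValueError:
        out["xu_oquigley"] = np.nan
    return out
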