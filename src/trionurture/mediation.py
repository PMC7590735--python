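"""Maternal factor scores and covariate-based mediation of genetic nurture.

Mediation is operationalized as covariate attenuation: the trio variance-
component model is fitted with and without a measured maternal trait among
the fixed effects, and the drop in the genetic-nurture component quantifies
how much of the parental effect the measured trait carries. A stable
maternal trait is indexed by the common factor of repeated symptom
measurements, which suppresses occasion-specific fluctuation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .relatedness import RelatednessSet
from .varcomp import VarCompResult, fit_rdr

__all__ = [
    "FactorScoreModel",
    "MediationReport",
    "factor_score",
    "mediate",
    "attenuation_fraction",
]

_MIN_UNIQUENESS = 1e-4


@dataclass
class FactorScoreModel:
    loadings: np.ndarray  # per time point, standardized metric
    uniquenesses: np.ndarray
    scores: np.ndarray  # mean 0, variance 1
    heywood: bool
    degenerate: bool  # no common factor detected; scores are row means
    n_obs: int
    loglik: float | None = None


def _pairwise_corr(x: np.ndarray) -> np.ndarray:
    """Available-case correlation matrix of the columns of x (NaN = missing)."""
    t = x.shape[1]
    r = np.eye(t)
    for i in range(t):
        for j in range(i + 1, t):
            ok = np.isfinite(x[:, i]) & np.isfinite(x[:, j])
            if ok.sum() < 3:
                raise ValueError(f"columns {i} and {j} share fewer than 3 observations")
            r[i, j] = r[j, i] = np.corrcoef(x[ok, i], x[ok, j])[0, 1]
    return r


def factor_score(repeated_measures: np.ndarray) -> FactorScoreModel:
    """One-factor maximum-likelihood model with regression-method scores.

    Columns are standardized first; missing time points are handled by
    available-case covariances and, for scoring, by using each row's
    observed subset. A uniqueness hitting its lower bound is flagged as a
    Heywood case; mutually uncorrelated columns trigger a degenerate-factor
    warning and a row-mean fallback score.
    """
    x = np.asarray(repeated_measures, dtype=float)
    n, t = x.shape
    if t < 2:
        raise ValueError("need at least two time points")
    sd = np.nanstd(x, axis=0, ddof=1)
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        raise ValueError("every column needs positive variance")
    xs = (x - np.nanmean(x, axis=0)) / sd
    corr = _pairwise_corr(xs)
    n_eff = int(np.isfinite(xs).all(axis=1).sum()) or n

    eigvals, eigvecs = np.linalg.eigh(corr)
    lead = eigvals[-1]
    if lead <= 1.0 + 3.0 * math.sqrt(t / max(n_eff, 1)):
        warnings.warn(
            "no common factor detected (columns nearly uncorrelated); "
            "falling back to the row-mean score",
            stacklevel=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(xs, axis=1)
        scores = (means - np.nanmean(means)) / np.nanstd(means, ddof=1)
        return FactorScoreModel(
            loadings=np.full(t, np.nan),
            uniquenesses=np.full(t, np.nan),
            scores=scores,
            heywood=False,
            degenerate=True,
            n_obs=n,
        )

    v1 = eigvecs[:, -1]
    lam0 = v1 * math.sqrt(max(lead - 1.0, 0.05))
    psi0 = np.clip(1.0 - lam0**2, 0.05, 1.0)

    def negll(params):
        lam = params[:t]
        psi = np.exp(params[t:])
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return math.inf
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sinv = np.linalg.inv(sigma)
        return logdet + float(np.sum(sinv * corr))

    x0 = np.concatenate([lam0, np.log(psi0)])
    bounds = [(None, None)] * t + [(math.log(_MIN_UNIQUENESS), math.log(10.0))] * t
    opt = scipy.optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    lam = opt.x[:t]
    psi = np.exp(opt.x[t:])
    heywood = bool(np.any(psi <= _MIN_UNIQUENESS * 1.01))
    if lam.mean() < 0:
        lam = -lam

    sigma = np.outer(lam, lam) + np.diag(psi)
    complete = np.isfinite(xs).all(axis=1)
    scores = np.empty(n)
    weights = np.linalg.solve(sigma, lam)
    scores[complete] = xs[complete] @ weights
    for i in np.flatnonzero(~complete):
        obs = np.isfinite(xs[i])
        if not obs.any():
            scores[i] = np.nan
            continue
        sub = sigma[np.ix_(obs, obs)]
        scores[i] = xs[i, obs] @ np.linalg.solve(sub, lam[obs])
    good = np.isfinite(scores)
    scores[good] = (scores[good] - scores[good].mean()) / scores[good].std(ddof=1)
    return FactorScoreModel(
        loadings=lam,
        uniquenesses=psi,
        scores=scores,
        heywood=heywood,
        degenerate=False,
        n_obs=n,
        loglik=-float(opt.fun),
    )


@dataclass
class MediationReport:
    unadjusted: VarCompResult
    adjusted: VarCompResult
    attenuation_share: float  # on the variance-share scale
    attenuation_raw: float  # on the raw component scale
    component_deltas: dict[str, float]  # adjusted minus unadjusted, share scale


def attenuation_fraction(v_eta_unadjusted: float, v_eta_adjusted: float) -> float:
    """(unadjusted - adjusted) / unadjusted; NaN when the unadjusted
    nurture component is not positive."""
    if v_eta_unadjusted <= 0:
        return float("nan")
    return (v_eta_unadjusted - v_eta_adjusted) / v_eta_unadjusted


def mediate(
    y: np.ndarray,
    covariates: np.ndarray | None,
    relatedness: RelatednessSet | list[np.ndarray],
    mediator: np.ndarray,
) -> MediationReport:
    """Fit the trio model without and with the mediator as a fixed effect."""
    mediator = np.asarray(mediator, dtype=float)
    if len(mediator) != len(y):
        raise ValueError("mediator must align with the phenotype rows")
    base = (
        np.ones((len(y), 1))
        if covariates is None
        else np.column_stack([np.ones(len(y)), covariates])
    )
    proj, *_ = np.linalg.lstsq(base, mediator, rcond=None)
    resid = mediator - base @ proj
    if float(resid @ resid) < 1e-10 * float(mediator @ mediator + 1e-300):
        raise ValueError("mediator is collinear with the existing covariates")
    with_med = (
        mediator[:, None]
        if covariates is None
        else np.column_stack([covariates, mediator])
    )
    unadj = fit_rdr(y, covariates, relatedness)
    adj = fit_rdr(y, with_med, relatedness)
    deltas = {
        k: adj.shares[k] - unadj.shares[k] for k in unadj.components
    }
    return MediationReport(
        unadjusted=unadj,
        adjusted=adj,
        attenuation_share=attenuation_fraction(
            unadj.shares["v_eta"], adj.shares["v_eta"]
        ),
        attenuation_raw=attenuation_fraction(
            unadj.components["v_eta"], adj.components["v_eta"]
        ),
        component_deltas=deltas,
    )
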