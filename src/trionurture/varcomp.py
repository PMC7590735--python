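"""Variance-component estimation for trio relatedness models.

The trio model treats the child phenotype as multivariate normal,

    y ~ N(X beta,  v_delta K_oo + v_eta K_pp + c K_x + v_e I),

and estimates the components by restricted maximum likelihood with
average-information (Newton-type) updates. Components are unconstrained in
sign — negative direct-nurture covariance is expected for some traits —
except for the residual, which is floored at a small positive value. A
closed-form Haseman-Elston regression of phenotype products on relatedness
entries is provided as a method-of-moments cross-check, and the classical
one-matrix GREML fit is the special case with the parental and cross
matrices removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .relatedness import RelatednessSet

__all__ = [
    "VarCompResult",
    "RDR_NAMES",
    "reml_fit",
    "fit_rdr",
    "greml_single",
    "he_regression",
    "implied_single_component",
]

RDR_NAMES = ("v_delta", "v_eta", "c", "v_e")


@dataclass
class VarCompResult:
    """Fitted variance components with average-information standard errors."""

    names: tuple[str, ...]
    components: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray  # sampling covariance of the estimates (inverse AI)
    loglik: float
    n_used: int
    n_iter: int
    converged: bool
    gradient_norm: float
    phenotypic_variance: float  # covariate-adjusted sample variance of y
    loglik_trace: list[float] = field(default_factory=list)  # accepted iterates

    @property
    def shares(self) -> dict[str, float]:
        """Each component divided by the sum of fitted components."""
        total = sum(self.components.values())
        return {k: v / total for k, v in self.components.items()}


def _design_matrix(n: int, covariates: np.ndarray | None) -> np.ndarray:
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates) > 0:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match phenotype length")
        x = np.hstack([x, cov])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariates (columns {bad})")
    return x


def _loglik_terms(theta, vs, x, y):
    """Restricted log-likelihood and the pieces reused by the updates.

    Returns None when Sigma is not positive definite at ``theta``.
    """
    n = len(y)
    sigma = np.zeros((n, n))
    for t, v in zip(theta, vs):
        sigma += t * v
    chol, info = scipy.linalg.lapack.dpotrf(sigma, lower=1)
    if info != 0:
        return None
    logdet_sigma = 2.0 * np.log(np.diag(chol)).sum()
    inv, info = scipy.linalg.lapack.dpotri(chol, lower=1)
    if info != 0:
        return None
    sinv = np.tril(inv) + np.tril(inv, -1).T
    six = sinv @ x
    xtsix = x.T @ six
    sign, logdet_xtsix = np.linalg.slogdet(xtsix)
    if sign <= 0:
        return None
    xtsix_inv = np.linalg.inv(xtsix)
    py = sinv @ y - six @ (xtsix_inv @ (six.T @ y))
    ll = -0.5 * (logdet_sigma + logdet_xtsix + float(y @ py))
    return ll, sinv, six, xtsix_inv, py


def _score_and_ai(vs, sinv, six, xtsix_inv, py):
    k = len(vs)
    w = [v @ py for v in vs]
    pw = []
    for wk in w:
        pw.append(sinv @ wk - six @ (xtsix_inv @ (six.T @ wk)))
    score = np.empty(k)
    ai = np.empty((k, k))
    for a in range(k):
        # tr(P V_a) = tr(Sinv V_a) - tr(XtSiX^-1 (SiX)' V_a (SiX))
        tr_sv = float(np.sum(sinv * vs[a]))
        vsix = vs[a] @ six
        tr_corr = float(np.trace(xtsix_inv @ (six.T @ vsix)))
        ypvpy = float(py @ w[a])
        score[a] = -0.5 * (tr_sv - tr_corr - ypvpy)
        for b in range(a, k):
            ai[a, b] = ai[b, a] = 0.5 * float(w[a] @ pw[b])
    return score, ai


def reml_fit(
    y: np.ndarray,
    covariates: np.ndarray | None,
    matrices: list[np.ndarray],
    names: tuple[str, ...] | None = None,
    include_residual: bool = True,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> VarCompResult:
    """Unconstrained average-information REML.

    ``matrices`` are the genetic relatedness matrices; an identity residual
    matrix is appended unless ``include_residual`` is False. Convergence is
    declared when the relative change in restricted log-likelihood falls
    below ``tol``. Non-convergence returns the last iterate flagged
    ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = _design_matrix(n, covariates)
    vs = [np.asarray(v, dtype=float) for v in matrices]
    if names is None:
        names = tuple(f"v{i + 1}" for i in range(len(vs)))
    names = tuple(names)
    if include_residual:
        vs = vs + [np.eye(n)]
        if len(names) == len(vs) - 1:
            names = names + ("v_e",)
    if len(names) != len(vs):
        raise ValueError("one name per variance component required")
    for v in vs:
        if v.shape != (n, n):
            raise ValueError("matrix dimensions must match phenotype length")
    k = len(vs)

    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_ols
    vary = float(resid @ resid) / max(n - x.shape[1], 1)
    ve_floor = 1e-6 * vary
    residual_idx = k - 1 if include_residual else None

    theta = np.full(k, vary / k)
    state = _loglik_terms(theta, vs, x, y)
    if state is None:
        raise ValueError("covariance matrix not positive definite at the start")
    ll = state[0]
    trace = [ll]

    converged = False
    it = 0
    score = np.zeros(k)
    ai = np.eye(k)
    for it in range(1, max_iter + 1):
        _, sinv, six, xtsix_inv, py = state
        score, ai = _score_and_ai(vs, sinv, six, xtsix_inv, py)
        if np.linalg.cond(ai) > 1e12:
            raise ValueError(
                "singular average-information matrix: components are not "
                "jointly identifiable from these relatedness matrices"
            )
        directions = [np.linalg.solve(ai, score), score / n]  # AI step, gradient fallback
        new_state = None
        for direction in directions:
            step = 1.0
            for _ in range(30):
                cand = theta + step * direction
                if residual_idx is not None:
                    cand[residual_idx] = max(cand[residual_idx], ve_floor)
                trial = _loglik_terms(cand, vs, x, y)
                if trial is not None and trial[0] >= ll - 1e-10:
                    new_state, new_theta = trial, cand
                    break
                step *= 0.5
            if new_state is not None:
                break
        if new_state is None:
            break  # no admissible ascent step; flagged unconverged below
        delta_ll = new_state[0] - ll
        theta, state, ll = new_theta, new_state, new_state[0]
        trace.append(ll)
        if abs(delta_ll) / max(abs(ll), 1.0) < tol:
            converged = True
            break

    _, sinv, six, xtsix_inv, py = state
    score, ai = _score_and_ai(vs, sinv, six, xtsix_inv, py)
    cov = np.linalg.inv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return VarCompResult(
        names=names,
        components={nm: float(t) for nm, t in zip(names, theta)},
        se={nm: float(s) for nm, s in zip(names, se)},
        cov=cov,
        loglik=float(ll),
        n_used=n,
        n_iter=it,
        converged=converged,
        gradient_norm=float(np.linalg.norm(score)),
        phenotypic_variance=vary,
        loglik_trace=trace,
    )


def fit_rdr(
    y: np.ndarray,
    covariates: np.ndarray | None,
    relatedness: RelatednessSet | list[np.ndarray],
    **kwargs,
) -> VarCompResult:
    """Fit the three-matrix trio model; components named
    (v_delta, v_eta, c, v_e)."""
    mats = (
        relatedness.matrices
        if isinstance(relatedness, RelatednessSet)
        else list(relatedness)
    )
    return reml_fit(y, covariates, mats, names=RDR_NAMES[:3], **kwargs)


def greml_single(
    y: np.ndarray, covariates: np.ndarray | None, K_oo: np.ndarray, **kwargs
) -> VarCompResult:
    """Single-component GREML on the child relatedness matrix: the trio
    model with the nurture and covariance components fixed at zero."""
    return reml_fit(y, covariates, [K_oo], names=("v_g",), **kwargs)


def he_regression(
    y: np.ndarray,
    covariates: np.ndarray | None,
    matrices: list[np.ndarray],
    names: tuple[str, ...] | None = None,
    include_residual: bool = True,
) -> dict[str, float]:
    """Haseman-Elston regression: closed-form method-of-moments estimates.

    Regresses products of covariate-residualized phenotypes over all
    individual pairs (including self-pairs) on the matching relatedness
    entries, with an identity regressor for the residual component.
    Unbiased under the model; serves as the independent oracle for REML.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = _design_matrix(n, covariates)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    iu = np.triu_indices(n)
    vs = [np.asarray(v, dtype=float) for v in matrices]
    if names is None:
        names = tuple(f"v{i + 1}" for i in range(len(vs)))
    names = tuple(names)
    if include_residual:
        vs = vs + [np.eye(n)]
        if len(names) == len(vs) - 1:
            names = names + ("v_e",)
    design = np.column_stack([v[iu] for v in vs])
    z = (r[:, None] * r[None, :])[iu]
    if np.linalg.cond(design.T @ design) > 1e12:
        raise ValueError("collinear relatedness regressors")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    return {nm: float(c) for nm, c in zip(names, coef)}


def implied_single_component(
    v_delta: float | VarCompResult, v_eta: float | None = None, c: float | None = None
) -> float:
    """Single-matrix heritability implied by trio components:
    direct + half the nurture + the covariance.

    Only transmitted parental material contributes to the child matrix,
    which halves the nurture term. Accepts either the three components or a
    fitted trio result (applied to its shares).
    """
    if isinstance(v_delta, VarCompResult):
        s = v_delta.shares
        return s["v_delta"] + s["v_eta"] / 2.0 + s["c"]
    return v_delta + v_eta / 2.0 + c
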