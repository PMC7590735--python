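"""Maximum-likelihood ACE decomposition from relative-pair phenotypes.

Each relationship class r contributes pairs whose phenotypes are modelled
as standard bivariate normal with correlation a_r * A + c_r * C, where a_r
is the expected additive-genetic correlation (1.0 identical twins, 0.5
full siblings / fraternal twins, 0.25 maternal half-siblings, 0.125
cousins) and c_r the shared-environment correlation (1 for reared-together
siblings, 0 for cousins). The pairwise likelihood double-counts individuals
appearing in several pairs, so standard errors are approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .synthetic_data import RelativePairSet

__all__ = ["AceResult", "pair_loglik", "ace_fit"]


@dataclass
class AceResult:
    A: float  # additive-genetic share
    C: float  # shared-environment share
    E: float  # residual share (1 - A - C)
    se: dict[str, float]
    loglik: float
    n_pairs: dict[str, int]
    gradient_norm: float
    converged: bool
    boundary: bool = False


def _class_sums(pairs: RelativePairSet):
    """Sufficient statistics per class for the bivariate-normal likelihood."""
    out = []
    for cls in pairs.classes:
        p = np.asarray(pairs.phenotype_pairs[cls.label], dtype=float)
        if p.shape[0] != cls.n_pairs:
            raise ValueError(f"class {cls.label!r}: pair count mismatch")
        if p.shape[0] == 0:
            continue
        sxx = float(np.sum(p[:, 0] ** 2 + p[:, 1] ** 2))
        sxy = float(np.sum(p[:, 0] * p[:, 1]))
        out.append((cls.a_r, cls.c_r, p.shape[0], sxx, sxy))
    return out


def pair_loglik(A: float, C: float, pairs: RelativePairSet) -> float:
    """Log-likelihood of all pairs under class correlations a_r*A + c_r*C.

    Returns -inf when any class correlation leaves (-1, 1).
    """
    total = 0.0
    for a_r, c_r, n, sxx, sxy in _class_sums(pairs):
        rho = a_r * A + c_r * C
        if not -1.0 < rho < 1.0:
            return -math.inf
        q = 1.0 - rho * rho
        total += -n * math.log(2 * math.pi) - 0.5 * n * math.log(q)
        total += -(sxx - 2.0 * rho * sxy) / (2.0 * q)
    return total


_STARTS = [(0.2, 0.2), (0.5, 0.1), (0.1, 0.4), (0.4, 0.4), (0.05, 0.05)]


def _num_grad(f, x, eps=1e-6):
    g = np.zeros(len(x))
    for i in range(len(x)):
        e = np.zeros(len(x))
        e[i] = eps
        g[i] = (f(x + e) - f(x - e)) / (2 * eps)
    return g


def _num_hess(f, x, eps=1e-4):
    k = len(x)
    h = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return h


def ace_fit(pairs: RelativePairSet, constrain_nonneg: bool = False) -> AceResult:
    """Maximize the pairwise likelihood over (A, C); E = 1 - A - C.

    Phenotypes are standardized within the pooled sample first. Derivative-
    free simplex search from five deterministic starts, keeping the best,
    followed by a quasi-Newton polish; standard errors from the numerical
    Hessian. ``constrain_nonneg`` restricts A, C >= 0 (the default mirrors
    the unconstrained genomic fits)."""
    active = [(c, pairs.phenotype_pairs[c.label]) for c in pairs.classes if c.n_pairs > 0]
    designs = {(c.a_r, c.c_r) for c, _ in active}
    if len(designs) < 2:
        raise ValueError(
            "A and C are not separable: need at least two relationship classes "
            "with distinct (a_r, c_r) coefficients"
        )
    pooled = np.concatenate([p.ravel() for _, p in active])
    mu, sd = pooled.mean(), pooled.std()
    std_pairs = RelativePairSet(
        classes=[c for c, _ in active],
        phenotype_pairs={c.label: (p - mu) / sd for c, p in active},
    )

    def negll(x):
        a, c = x
        if constrain_nonneg and (a < 0 or c < 0):
            return math.inf
        ll = pair_loglik(a, c, std_pairs)
        return -ll if math.isfinite(ll) else math.inf

    best = None
    for start in _STARTS:
        res = scipy.optimize.minimize(
            negll, np.array(start), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    polish = scipy.optimize.minimize(negll, best.x, method="BFGS",
                                     options={"gtol": 1e-8})
    if math.isfinite(polish.fun) and polish.fun <= best.fun:
        best = polish
    a_hat, c_hat = best.x
    grad = _num_grad(negll, best.x)
    hess = _num_hess(negll, best.x)
    try:
        cov = np.linalg.inv(hess)
        se_a, se_c = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        se_e = math.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0))
    except np.linalg.LinAlgError:
        se_a = se_c = se_e = float("nan")
    boundary = constrain_nonneg and (a_hat < 1e-8 or c_hat < 1e-8)
    return AceResult(
        A=float(a_hat),
        C=float(c_hat),
        E=float(1.0 - a_hat - c_hat),
        se={"A": float(se_a), "C": float(se_c), "E": float(se_e)},
        loglik=-float(best.fun),
        n_pairs={c.label: c.n_pairs for c, _ in active},
        gradient_norm=float(np.linalg.norm(grad)),
        converged=bool(best.success),
        boundary=boundary,
    )
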