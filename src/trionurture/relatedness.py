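"""Genomic relatedness matrices for trio variance-component models.

Three matrices drive the trio regression of phenotypic resemblance on
genetic resemblance: the child relatedness K_oo, the parental-sum
relatedness K_pp, and the symmetrized child-parent cross relatedness K_x.
With child scores standardized to variance one, parental-sum scores to
variance two, and the normalizations below, each matrix's diagonal has
expectation ~1, so fitted variance components read directly as variance
shares.

Allele frequencies are estimated from the parents (the founder generation):
parents are the statistically independent draws, and using one frequency
set for both generations keeps the per-SNP child-parent score covariance
exactly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import MISSING, TrioCohort

__all__ = [
    "RelatednessSet",
    "allele_frequencies",
    "standardize",
    "parental_sum",
    "build_relatedness",
    "ld_prune",
    "relatedness_cutoff",
    "genotype_pca",
]


@dataclass
class RelatednessSet:
    """The three trio relatedness matrices over one id roster."""

    K_oo: np.ndarray  # child x child
    K_pp: np.ndarray  # parental-sum x parental-sum
    K_x: np.ndarray  # symmetrized child-parent cross
    n_snps: int
    sample_ids: pd.DataFrame
    n_monomorphic_dropped: int = 0

    @property
    def matrices(self) -> list[np.ndarray]:
        return [self.K_oo, self.K_pp, self.K_x]


def allele_frequencies(mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    """Per-SNP allele1 frequency estimated from the parental (founder)
    genotypes, ignoring missing entries."""
    m = np.array(mother, dtype=float, copy=True)
    f = np.array(father, dtype=float, copy=True)
    m[mother == MISSING] = np.nan
    f[father == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(np.concatenate([m, f], axis=0), axis=0) / 2.0


def standardize(
    genotypes: np.ndarray,
    allele_freqs: np.ndarray,
    target_variance: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale dosage columns; returns (Z, kept_snp_indices).

    Column j maps g -> (g - expectation) / sqrt(2 f_j (1 - f_j)), with
    expectation 2 f_j for child dosages (variance 1) or 4 f_j for
    parental-sum dosages (variance 2). Missing entries are imputed to the
    column mean, i.e. zero after centering. Monomorphic SNPs (f at 0 or 1,
    or all entries missing) are excluded with a warning.
    """
    if target_variance not in (1, 2):
        raise ValueError("target_variance must be 1 (child) or 2 (parental sum)")
    f = np.asarray(allele_freqs, dtype=float)
    if np.any(f[np.isfinite(f)] < 0) or np.any(f[np.isfinite(f)] > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    g = np.asarray(genotypes, dtype=float)
    missing = np.asarray(genotypes) == MISSING
    keep = np.isfinite(f) & (f > 0) & (f < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} monomorphic or all-missing SNPs", stacklevel=2
        )
    idx = np.flatnonzero(keep)
    fk = f[idx]
    center = (2.0 if target_variance == 1 else 4.0) * fk
    scale = np.sqrt(2.0 * fk * (1.0 - fk))
    z = (g[:, idx] - center) / scale
    z[missing[:, idx]] = 0.0
    return z, idx


def parental_sum(mother_genotypes: np.ndarray, father_genotypes: np.ndarray) -> np.ndarray:
    """Unnormalised maternal + paternal dosage sum in {0..4}; missing if
    either parent is missing."""
    m = np.asarray(mother_genotypes)
    f = np.asarray(father_genotypes)
    if m.shape != f.shape:
        raise ValueError(f"shape mismatch: mothers {m.shape} vs fathers {f.shape}")
    s = m.astype(np.int16) + f.astype(np.int16)
    s[(m == MISSING) | (f == MISSING)] = MISSING
    return s


def build_relatedness(cohort: TrioCohort) -> RelatednessSet:
    """Build K_oo, K_pp and K_x from a trio cohort.

    K_oo = Z_o Z_o' / M, K_pp = Z_par Z_par' / (2M),
    K_x = (Z_o Z_par' + Z_par Z_o') / (2M).
    """
    if cohort.n_trios < 2:
        raise ValueError("need at least 2 trios")
    freqs = allele_frequencies(cohort.mother_genotypes, cohort.father_genotypes)
    psum = parental_sum(cohort.mother_genotypes, cohort.father_genotypes)
    z_o, kept = standardize(cohort.child_genotypes, freqs, target_variance=1)
    z_par, kept_p = standardize(psum, freqs, target_variance=2)
    assert np.array_equal(kept, kept_p)
    m = len(kept)
    if m == 0:
        raise ValueError("no polymorphic SNPs left after filtering")
    k_oo = (z_o @ z_o.T) / m
    k_pp = (z_par @ z_par.T) / (2 * m)
    cross = z_o @ z_par.T
    k_x = (cross + cross.T) / (2 * m)
    return RelatednessSet(
        K_oo=k_oo,
        K_pp=k_pp,
        K_x=k_x,
        n_snps=m,
        sample_ids=cohort.sample_ids[["fid", "child_iid"]].rename(
            columns={"child_iid": "iid"}
        ),
        n_monomorphic_dropped=cohort.n_snps - m,
    )


def ld_prune(
    genotypes: np.ndarray, r2_threshold: float = 0.5, window_size: int = 50
) -> np.ndarray:
    """Greedy left-to-right linkage-disequilibrium pruning.

    Scanning SNPs in order, a SNP is removed when its squared correlation
    with any previously kept SNP fewer than ``window_size`` positions back
    exceeds ``r2_threshold``. Deterministic; returns kept column indices.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    g = np.array(genotypes, dtype=float, copy=True)
    g[np.asarray(genotypes) == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = np.inf  # constant columns never correlate
    g = g / sd
    n, m = g.shape
    kept: list[int] = []
    for j in range(m):
        ok = True
        for k in reversed(kept):
            if j - k >= window_size:
                break
            r = float(g[:, j] @ g[:, k]) / n
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def relatedness_cutoff(K: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy relatedness filtering: while any off-diagonal entry is at or
    above ``cutoff``, drop the individual in the most violating pairs
    (ties broken toward the lower index). Returns kept indices."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    K = np.asarray(K)
    n = K.shape[0]
    viol = K >= cutoff
    np.fill_diagonal(viol, False)
    active = np.ones(n, dtype=bool)
    while True:
        counts = (viol & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        worst = int(np.argmax(counts))
        if counts[worst] == 0:
            break
        active[worst] = False
    return np.flatnonzero(active)


def genotype_pca(z: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of a standardized genotype matrix.

    Scores have unit variance; each component's sign is fixed so its
    largest-magnitude SNP loading is positive.
    """
    n, m = z.shape
    if k < 0 or k >= min(n, m):
        if k == 0:
            return np.empty((n, 0))
        raise ValueError(f"k must satisfy 0 <= k < min(n, M) = {min(n, m)}")
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            scores[:, i] = -scores[:, i]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd
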