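"""Generative models for trio-genotype cohorts and relative-pair phenotypes.

The trio generator produces parent-offspring trios under random mating with
per-SNP direct (child) and nurturing (parental) effects drawn from a joint
Gaussian distribution, so that the child phenotype decomposes into

    y = Z_o @ delta + Z_par @ eta + e

where ``Z_o`` is the child genotype standardized to unit variance and
``Z_par`` the parental-sum genotype standardized to variance two. With
per-SNP scalings Var(delta_j) = v_delta / M, Var(eta_j) = v_eta / (2M) and
Cov(delta_j, eta_j) = c / (2M), the phenotypic variance decomposes exactly
as v_delta + v_eta + c + v_e (the per-SNP covariance of the standardized
child and parental-sum scores equals one in a random-mating population).

The nurture effect is split into a mediated and an unmediated part,
eta = eta_med + eta_res, with a measured maternal mediator built from the
mediated part; see :func:`split_covariance` for how the direct-nurture
covariance is allocated between the two parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for missing genotype dosages (int8 matrices)

__all__ = [
    "MISSING",
    "GenerativeParams",
    "TrioCohort",
    "RelativeClass",
    "RelativePairSet",
    "split_covariance",
    "simulate_trios",
    "simulate_pedigree_pairs",
]


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the trio generative model.

    All variance components are fractions of the (unit) phenotypic
    variance; ``c`` is the variance contribution of the direct-nurture
    covariance and may be negative.
    """

    n_trios: int
    n_snps: int
    v_delta: float
    v_eta: float
    c: float
    v_e: float
    maf_range: tuple[float, float] = (0.05, 0.5)
    mediated_fraction: float = 0.0
    mediator_reliability: float = 1.0
    assort_corr: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_trios < 2 or self.n_snps < 1:
            raise ValueError("need at least 2 trios and 1 SNP")
        for name in ("v_delta", "v_eta", "v_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.v_delta + self.v_eta + self.c + self.v_e
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"components must sum to 1 (phenotype scaled to unit variance); got {total:.6g}"
            )
        bound = math.sqrt(2.0 * self.v_delta * self.v_eta)
        if abs(self.c) > bound + 1e-12:
            raise ValueError(
                f"|c| = {abs(self.c):.4g} exceeds sqrt(2*v_delta*v_eta) = {bound:.4g}: "
                "no valid joint distribution of direct and nurturing effects exists"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.mediated_fraction <= 1.0:
            raise ValueError("mediated_fraction must be in [0, 1]")
        if self.mediated_fraction > 0 and self.v_eta == 0:
            raise ValueError("mediated_fraction > 0 requires v_eta > 0")
        if not 0.0 < self.mediator_reliability <= 1.0:
            raise ValueError("mediator_reliability must be in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not -1.0 < self.assort_corr < 1.0:
            raise ValueError("assort_corr must be in (-1, 1)")


@dataclass
class TrioCohort:
    """Aligned child/mother/father genotypes with phenotype and mediator.

    Genotype matrices are ``n_trios x n_snps`` int8 dosages in {0, 1, 2}
    with ``MISSING`` (-1) for missing entries; all three share SNP order.
    """

    child_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    father_genotypes: np.ndarray
    snp_info: pd.DataFrame
    sample_ids: pd.DataFrame
    child_phenotype: np.ndarray
    mediator: np.ndarray | None = None
    mediator_timepoints: np.ndarray | None = None
    covariates: np.ndarray | None = None
    truth: GenerativeParams | None = None

    @property
    def n_trios(self) -> int:
        return self.child_genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child_genotypes.shape[1]


@dataclass(frozen=True)
class RelativeClass:
    label: str
    a_r: float  # additive-genetic expectation coefficient
    c_r: float  # shared-environment expectation coefficient
    n_pairs: int


@dataclass
class RelativePairSet:
    """Phenotype pairs grouped by relationship class."""

    classes: list[RelativeClass]
    phenotype_pairs: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            pairs = self.phenotype_pairs[cls.label]
            rows.append(
                pd.DataFrame(
                    {
                        "class_label": cls.label,
                        "a_r": cls.a_r,
                        "c_r": cls.c_r,
                        "pheno1": pairs[:, 0],
                        "pheno2": pairs[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RelativePairSet":
        classes, pairs = [], {}
        for label, grp in df.groupby("class_label", sort=False):
            a_r = float(grp["a_r"].iloc[0])
            c_r = float(grp["c_r"].iloc[0])
            classes.append(RelativeClass(str(label), a_r, c_r, len(grp)))
            pairs[str(label)] = grp[["pheno1", "pheno2"]].to_numpy(float)
        return cls(classes, pairs)


def split_covariance(
    v_delta: float, v_eta: float, c: float, mediated_fraction: float
) -> tuple[float, float]:
    """Allocate the direct-nurture covariance between mediated and
    unmediated nurture components.

    Returns ``(c_med, c_res)`` with ``c_med + c_res = c``. The covariance is
    placed on the unmediated component (so the mediator stays independent of
    direct effects) whenever the implied effect correlation permits; any
    excess spills onto the mediated component, choosing the smallest
    |c_med| for which the joint correlation structure of
    (delta, eta_med, eta_res) remains positive semi-definite.
    """
    if c == 0 or v_eta == 0 or v_delta == 0:
        return 0.0, float(c)
    mf = mediated_fraction
    b_med = math.sqrt(2.0 * v_delta * mf * v_eta)
    b_res = math.sqrt(2.0 * v_delta * (1.0 - mf) * v_eta)
    if abs(c) <= b_res:
        return 0.0, float(c)
    # solve b_med*s + b_res*sqrt(1-s^2) = |c| for the smaller root s = rho_dm
    a2 = b_med**2 + b_res**2
    disc = (abs(c) * b_med) ** 2 - a2 * (c**2 - b_res**2)
    disc = max(disc, 0.0)
    s = (abs(c) * b_med - math.sqrt(disc)) / a2
    s = min(max(s, 0.0), 1.0)
    sign = math.copysign(1.0, c)
    c_med = sign * b_med * s
    c_res = c - c_med
    return float(c_med), float(c_res)


def _draw_effects(
    rng: np.random.Generator, params: GenerativeParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP effect triples (delta, eta_med, eta_res), jointly Gaussian."""
    m = params.n_snps
    mf = params.mediated_fraction
    c_med, c_res = split_covariance(params.v_delta, params.v_eta, params.c, mf)
    cov = np.array(
        [
            [params.v_delta / m, c_med / (2 * m), c_res / (2 * m)],
            [c_med / (2 * m), mf * params.v_eta / (2 * m), 0.0],
            [c_res / (2 * m), 0.0, (1 - mf) * params.v_eta / (2 * m)],
        ]
    )
    # eigen factorization tolerates the PSD boundary the covariance split can hit
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    eff = rng.standard_normal((m, 3)) @ root.T
    return eff[:, 0], eff[:, 1], eff[:, 2]


def _standardize_true(
    geno: np.ndarray, freqs: np.ndarray, target_variance: int
) -> np.ndarray:
    center = (2.0 if target_variance == 1 else 4.0) * freqs
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))
    return (geno - center) / scale


def _assortative_pairing(
    rng: np.random.Generator,
    mother_score: np.ndarray,
    father_score: np.ndarray,
    corr: float,
) -> np.ndarray:
    """Return a father permutation inducing approximate rank correlation
    ``corr`` between maternal and paternal mate phenotypes."""
    from scipy.special import ndtri

    n = len(mother_score)
    mother_rank = np.empty(n, int)
    mother_rank[np.argsort(mother_score)] = np.arange(n)
    normal_score = ndtri((mother_rank + 0.5) / n)
    latent = corr * normal_score + math.sqrt(
        max(1 - corr**2, 0.0)
    ) * rng.standard_normal(n)
    target_rank = np.empty(n, int)
    target_rank[np.argsort(latent)] = np.arange(n)
    fathers_sorted = np.argsort(father_score)
    return fathers_sorted[target_rank]


def simulate_trios(params: GenerativeParams) -> TrioCohort:
    """Simulate a trio cohort under the generative model; deterministic
    given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.n_trios, params.n_snps

    freqs = rng.uniform(params.maf_range[0], params.maf_range[1], m)
    mother = rng.binomial(2, freqs, (n, m)).astype(np.int8)
    father = rng.binomial(2, freqs, (n, m)).astype(np.int8)

    delta, eta_med, eta_res = _draw_effects(rng, params)

    if params.assort_corr != 0.0:
        z_m = _standardize_true(mother, freqs, 1)
        z_f = _standardize_true(father, freqs, 1)
        gm = z_m @ delta
        gf = z_f @ delta
        sd = math.sqrt(max(params.v_delta, 1e-12))
        mate_m = gm + sd * rng.standard_normal(n)
        mate_f = gf + sd * rng.standard_normal(n)
        order = _assortative_pairing(rng, mate_m, mate_f, params.assort_corr)
        father = father[order]

    child = (
        rng.binomial(1, mother / 2.0) + rng.binomial(1, father / 2.0)
    ).astype(np.int8)

    z_o = _standardize_true(child, freqs, 1)
    z_par = _standardize_true(mother.astype(np.int16) + father, freqs, 2)
    eta = eta_med + eta_res
    y = z_o @ delta + z_par @ eta + math.sqrt(params.v_e) * rng.standard_normal(n)

    mediator = None
    timepoints = None
    if params.mediated_fraction > 0:
        m0 = z_par @ eta_med
        var_m0 = params.mediated_fraction * params.v_eta
        noise_var = var_m0 * (1.0 - params.mediator_reliability) / params.mediator_reliability
        mediator = m0 + math.sqrt(noise_var) * rng.standard_normal(n)
        timepoints = m0[:, None] + math.sqrt(noise_var) * rng.standard_normal((n, 5))

    if params.missing_rate > 0:
        for g in (child, mother, father):
            mask = rng.random((n, m)) < params.missing_rate
            g[mask] = MISSING

    snp_info = pd.DataFrame(
        {
            "chrom": np.ones(m, int),
            "snp_id": [f"snp{j + 1:06d}" for j in range(m)],
            "cm": np.zeros(m),
            "pos": np.arange(1, m + 1) * 1000,
            "allele1": "A",
            "allele2": "G",
            "freq": freqs,
        }
    )
    sample_ids = pd.DataFrame(
        {
            "fid": [f"F{i + 1:06d}" for i in range(n)],
            "child_iid": [f"C{i + 1:06d}" for i in range(n)],
            "mother_iid": [f"M{i + 1:06d}" for i in range(n)],
            "father_iid": [f"D{i + 1:06d}" for i in range(n)],
        }
    )
    return TrioCohort(
        child_genotypes=child,
        mother_genotypes=mother,
        father_genotypes=father,
        snp_info=snp_info,
        sample_ids=sample_ids,
        child_phenotype=y,
        mediator=mediator,
        mediator_timepoints=timepoints,
        truth=params,
    )


def simulate_pedigree_pairs(
    classes_with_counts: list[tuple[str, float, float, int]] | list[RelativeClass],
    A: float,
    C: float,
    seed: int = 0,
) -> RelativePairSet:
    """Draw relative-pair phenotypes from bivariate normals with class
    correlation ``a_r * A + c_r * C`` (unit marginal variances)."""
    if A < 0 or C < 0 or A + C > 1:
        raise ValueError("need A, C >= 0 and A + C <= 1")
    rng = np.random.default_rng(seed)
    classes: list[RelativeClass] = []
    pairs: dict[str, np.ndarray] = {}
    for item in classes_with_counts:
        cls = item if isinstance(item, RelativeClass) else RelativeClass(*item)
        rho = cls.a_r * A + cls.c_r * C
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"class {cls.label!r}: correlation {rho} outside [-1, 1]")
        z = rng.standard_normal((cls.n_pairs, 2))
        x1 = z[:, 0]
        x2 = rho * z[:, 0] + math.sqrt(1 - rho**2) * z[:, 1]
        classes.append(cls)
        pairs[cls.label] = np.column_stack([x1, x2])
    return RelativePairSet(classes, pairs)
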