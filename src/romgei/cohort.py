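"""Family-based simulation of genotypes, exposures, and quantitative traits.

The generator emulates a cohort of 14,750 families (12,750 nuclear +
2,000 three-generation extended; 85,000 individuals, 35,500 founders)
typed at independent common variants.  Founder genotypes are drawn from
Binomial(2, MAF) and descendants receive one uniformly chosen haplotype
from each parent per variant (gene dropping), so genotypes respect
Mendelian transmission and the within-family additive correlation
structure 2 * Psi.

Traits follow

    y_i = 1 + alpha1 x1_i + alpha2 x1_i^2 + alpha3 x2_i + alpha4 x2_i^2
          + r_i + eps_i

with a heritable exposure x1 ~ N(0, 2 Psi), a non-heritable exposure
x2 ~ N(0, 2 I), a polygenic effect r ~ N(0, 2 Psi), and eps ~ N(0, I).
Effect sizes are calibrated in closed form so each exposure term
explains a fixed proportion of trait variance (defaults 0.1, 0.05, 0.1,
0.05).  The misspecified-null design drops the quadratic terms.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np

from .pedigree import KinshipModel, Pedigree

__all__ = [
    "VariantPanel",
    "TraitReplicate",
    "Alphas",
    "draw_mafs",
    "simulate_genotypes",
    "genotype_blocks",
    "simulate_exposures",
    "calibrate_effects",
    "simulate_trait",
    "null_design",
    "DEFAULT_VARIANCE_PROPORTIONS",
]

DEFAULT_VARIANCE_PROPORTIONS = (0.1, 0.05, 0.1, 0.05)
DEFAULT_MAF_RANGE = (0.05, 0.5)


@dataclass
class VariantPanel:
    """Allele-count genotypes (individuals x variants) with their MAFs."""

    mafs: np.ndarray
    genotypes: np.ndarray  # int8, values {0, 1, 2}

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class TraitReplicate:
    """One simulated trait replicate with its exposures and effect sizes."""

    y: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    alphas: "Alphas"
    seed: object


@dataclass(frozen=True)
class Alphas:
    """Exposure effect sizes (linear/quadratic for x1, then x2)."""

    a1: float
    a2: float
    a3: float
    a4: float
    var_y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3, self.a4])


def draw_mafs(n_variants: int, seed, low: float = 0.05, high: float = 0.5) -> np.ndarray:
    """Minor allele frequencies, uniform on (low, high]."""
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n_variants)


def _drop_genes(ped: Pedigree, mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gene-drop one block of unlinked variants; returns int8 (N x V)."""
    fa, mo = ped.parent_indices()
    n, v = ped.n_individuals, len(mafs)
    hap = np.zeros((n, 2, v), dtype=bool)
    founders = np.flatnonzero(fa < 0)
    hap[founders] = rng.random((len(founders), 2, v)) < mafs
    cols = np.arange(v)
    for i in np.flatnonzero(fa >= 0):
        hap[i, 0] = hap[fa[i], rng.integers(0, 2, v), cols]
        hap[i, 1] = hap[mo[i], rng.integers(0, 2, v), cols]
    return hap.sum(axis=1, dtype=np.int8)


def simulate_genotypes(ped: Pedigree, mafs: np.ndarray, seed) -> VariantPanel:
    """Simulate a full genotype panel in memory.

    Founder haplotype alleles are i.i.d. Bernoulli(MAF); every offspring
    inherits one uniformly chosen haplotype from each parent,
    independently per variant (variants unlinked).
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    return VariantPanel(mafs=mafs, genotypes=_drop_genes(ped, mafs, rng))


def genotype_blocks(
    ped: Pedigree, mafs: np.ndarray, seed, block_size: int = 4096
) -> Iterator[tuple[int, np.ndarray]]:
    """Stream genotype blocks ``(first_variant_index, N x b int8)``.

    Avoids materialising the full individuals-by-variants matrix; each
    block draws from an independent substream so the stream is
    reproducible for a fixed seed and block size.
    """
    mafs = np.asarray(mafs, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_blocks = int(np.ceil(len(mafs) / block_size))
    for child, start in zip(ss.spawn(n_blocks), range(0, len(mafs), block_size)):
        stop = min(start + block_size, len(mafs))
        yield start, _drop_genes(ped, mafs[start:stop], np.random.default_rng(child))


def _sample_block_mvn(
    km: KinshipModel, rng: np.random.Generator, scale: float = 2.0
) -> np.ndarray:
    """One draw from N(0, scale * Psi), family block by family block."""
    out = np.empty(km.n)
    chol_cache: dict[bytes, np.ndarray] = {}
    for fid, blk, idx in zip(km.family_ids, km.blocks, km.indices):
        key = blk.tobytes()
        ch = chol_cache.get(key)
        if ch is None:
            try:
                ch = np.linalg.cholesky(scale * blk)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"family {fid}: kinship block not positive definite") from exc
            chol_cache[key] = ch
        out[idx] = ch @ rng.standard_normal(len(idx))
    return out


def simulate_exposures(km: KinshipModel, seed) -> tuple[np.ndarray, np.ndarray]:
    """Heritable exposure x1 ~ N(0, 2 Psi) and non-heritable x2 ~ N(0, 2 I)."""
    rng = np.random.default_rng(seed)
    x1 = _sample_block_mvn(km, rng, scale=2.0)
    x2 = np.sqrt(2.0) * rng.standard_normal(km.n)
    return x1, x2


def calibrate_effects(
    target_props: tuple[float, float, float, float] = DEFAULT_VARIANCE_PROPORTIONS,
    var_x1: float = 1.0,
    var_x2: float = 2.0,
    var_r: float = 1.0,
    var_eps: float = 1.0,
) -> Alphas:
    """Closed-form effect sizes hitting the target variance proportions.

    For x ~ N(0, s), Cov(x, x^2) = 0 and Var(x^2) = 2 s^2, so the four
    exposure terms are mutually uncorrelated and the total trait
    variance solves Var(y) = var_r + var_eps + sum_j p_j Var(y), i.e.
    Var(y) = (var_r + var_eps) / (1 - sum_j p_j).  Each alpha_j is then
    the positive root of alpha_j^2 * Var(term_j basis) = p_j * Var(y).

    With the default kinship scaling, Var(x1_i) = diag(2 Psi) = 1 while
    Var(x2_i) = 2, so the calibration is deliberately asymmetric.
    """
    p = np.asarray(target_props, dtype=float)
    if np.any(p < 0):
        raise ValueError("variance proportions must be nonnegative")
    if p.sum() >= 1:
        raise ValueError("variance proportions must sum to less than 1")
    var_y = (var_r + var_eps) / (1.0 - p.sum())
    basis = np.array([var_x1, 2.0 * var_x1**2, var_x2, 2.0 * var_x2**2])
    a = np.sqrt(p * var_y / basis)
    return Alphas(a[0], a[1], a[2], a[3], var_y)


def simulate_trait(
    km: KinshipModel,
    x1: np.ndarray,
    x2: np.ndarray,
    alphas: Alphas,
    seed,
    polygenic_scale: float = 2.0,
) -> TraitReplicate:
    """Assemble one trait replicate from the quadratic-exposure model."""
    if len(x1) != km.n or len(x2) != km.n:
        raise ValueError("exposure length does not match kinship model")
    rng = np.random.default_rng(seed)
    r = (
        _sample_block_mvn(km, rng, scale=polygenic_scale)
        if polygenic_scale > 0
        else np.zeros(km.n)
    )
    eps = rng.standard_normal(km.n)
    y = 1.0 + alphas.a1 * x1 + alphas.a2 * x1**2 + alphas.a3 * x2 + alphas.a4 * x2**2 + r + eps
    return TraitReplicate(y=y, x1=x1, x2=x2, alphas=alphas, seed=seed)


def null_design(x1: np.ndarray, x2: np.ndarray, correct: bool = False) -> np.ndarray:
    """Covariate design for the null model.

    By default returns the misspecified design (intercept + linear x1 +
    linear x2, quadratic terms dropped); with ``correct=True`` the fully
    specified design including x1^2 and x2^2.
    """
    cols = [np.ones_like(x1), x1, x2]
    if correct:
        cols += [x1**2, x2**2]
    return np.column_stack(cols)
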