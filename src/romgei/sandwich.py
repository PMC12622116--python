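"""Per-variant robust score tests with clustered sandwich variance.

Given a fitted null mixed model, each variant contributes a design
W = (g, K) where g is the allele-count vector and K holds the
gene-environment interaction columns g * E_m.  The score of (beta,
gamma) at the null is W' R_tilde with R_tilde the scaled residuals, and

    bread   B_J = (W' P W)^-1                    (joint)
            B_I = (K' H K)^-1, the Schur complement of g' P g
                  (equivalently the K-block of B_J)
    meat    M_J = sum_j (sum_{i in c_j} S_i)' (sum_{i in c_j} S_i),
                  S_i = R_i * W_adj_i            (cluster sums of the
                  scaled residual times the covariate-adjusted design)
    effects zeta_hat = B_J W' R_tilde
    cov     cov(zeta_hat) = B_J M_J B_J,  cov(gamma_hat) = B_I M_I B_I
    tests   T_J = zeta' cov(zeta)^-1 zeta ~ chi2(1+q)
            T_I = gamma' cov(gamma)^-1 gamma ~ chi2(q)

With family clusters this is the RoM family-clustered Huber-White
test; with singleton clusters it degenerates to the individual-cluster
(HC0-style) sandwich.  The model-based comparison replaces the
sandwich with the bread inverse.  All projections go through the null
fit's O(N) block solves; no N x N matrix is formed, and the meat uses
a sparse cluster-membership indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .nullmodel import NullModelFit, NullModelSpec, fit_null_lm, fit_null_reml

__all__ = [
    "SkipVariant",
    "VariantDesign",
    "SandwichParts",
    "TestResult",
    "build_design",
    "bread_joint",
    "bread_interaction",
    "meat_joint",
    "sandwich_parts",
    "estimate_effects",
    "rom_test",
    "model_based_test",
    "icb_test",
    "two_step_null",
    "two_step_test",
    "lm_icb_test",
    "marginal_test",
    "scan",
    "STRATEGIES",
]

_LN10 = np.log(10.0)
_GPG_FLOOR = 1e-8  # times N: minimum genetic variance in the P inner product
_PD_RTOL = 1e-10

STRATEGIES = ("RoM", "LMM-MB", "LMM-ICB", "Two-step-ICB", "LM-ICB", "marginal")


class SkipVariant(Exception):
    """Signal that a variant cannot be tested; carries a machine-readable reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class VariantDesign:
    """Genotype vector g, interaction design K = g * E, and W = (g, K)."""

    g: np.ndarray
    K: np.ndarray
    exposure_names: list[str]
    variant_id: str = "."

    @property
    def q(self) -> int:
        return self.K.shape[1]

    @property
    def W(self) -> np.ndarray:
        return np.column_stack([self.g, self.K])


@dataclass
class SandwichParts:
    bread_joint: np.ndarray
    bread_int: np.ndarray
    meat_joint: np.ndarray
    meat_int: np.ndarray
    cluster_count: int


@dataclass
class TestResult:
    """Joint and interaction test statistics for one variant and strategy."""

    variant_id: str
    strategy: str
    zeta_hat: np.ndarray | None = None
    cov_joint: np.ndarray | None = None
    cov_int: np.ndarray | None = None
    T_J: float = np.nan
    T_I: float = np.nan
    df_J: int = 0
    df_I: int = 0
    p_J: float = np.nan
    p_I: float = np.nan
    neglog10_p_J: float = np.nan
    neglog10_p_I: float = np.nan
    skip_reason: str | None = None

    @property
    def beta_hat(self) -> float | None:
        return None if self.zeta_hat is None else float(self.zeta_hat[0])

    @property
    def gamma_hat(self) -> np.ndarray | None:
        return None if self.zeta_hat is None else self.zeta_hat[1:]


def build_design(
    g: np.ndarray,
    exposures,
    exposure_names: list[str] | None = None,
    null_columns: list[str] | None = None,
    override: bool = False,
    variant_id: str = ".",
) -> VariantDesign:
    """Assemble the per-variant design.

    ``exposures`` is an N x q array or DataFrame of exposure columns;
    each interaction column is the elementwise product g * E_m.  When
    ``null_columns`` (the covariate names of the null model) is given,
    every exposure must appear among them unless ``override`` is set —
    testing an interaction whose main effect is absent from the null is
    almost always a specification mistake.  Missing genotypes (NaN) are
    mean-imputed before products are taken.
    """
    if isinstance(exposures, pd.DataFrame):
        exposure_names = list(exposures.columns)
        E = exposures.to_numpy(dtype=float)
    else:
        E = np.atleast_2d(np.asarray(exposures, dtype=float))
        if E.shape[0] == 1 and len(g) != 1:
            E = E.T
        if exposure_names is None:
            exposure_names = [f"E{m}" for m in range(E.shape[1])]
    if null_columns is not None and not override:
        missing = [nm for nm in exposure_names if nm not in null_columns]
        if missing:
            raise ValueError(
                f"exposures {missing} are not covariates of the null model; "
                "pass override=True to test them anyway"
            )
    g = np.asarray(g, dtype=float).copy()
    bad = ~np.isfinite(g)
    if bad.any():
        g[bad] = g[~bad].mean() if (~bad).any() else 0.0
    return VariantDesign(g=g, K=g[:, None] * E, exposure_names=exposure_names, variant_id=variant_id)


# ---------------------------------------------------------------------------
# per-variant building blocks
# ---------------------------------------------------------------------------


def _gram(fit: NullModelFit, vd: VariantDesign) -> np.ndarray:
    W = vd.W
    return W.T @ fit.apply_projection(W)


def _check_gram(WtPW: np.ndarray, g: np.ndarray, n: int) -> None:
    mac = min(g.sum(), 2 * len(g) - g.sum())
    if mac < 1:
        raise SkipVariant("zero genetic variance")
    if WtPW[0, 0] < _GPG_FLOOR * n:
        raise SkipVariant("zero genetic variance")
    w = np.linalg.eigvalsh(WtPW)
    if w[0] <= _PD_RTOL * max(w[-1], 1.0):
        raise SkipVariant("singular design (interaction collinear with genotype)")


def bread_joint(fit: NullModelFit, vd: VariantDesign) -> np.ndarray:
    """B_J = (W' P W)^-1 via the cached projection; raises SkipVariant."""
    WtPW = _gram(fit, vd)
    _check_gram(WtPW, vd.g, fit.spec.n)
    return np.linalg.inv(WtPW)


def bread_interaction(fit: NullModelFit, vd: VariantDesign) -> np.ndarray:
    """B_I: inverse Schur complement of g'Pg in W'PW (genotype projected out)."""
    WtPW = _gram(fit, vd)
    _check_gram(WtPW, vd.g, fit.spec.n)
    gPg = WtPW[0, 0]
    gPK = WtPW[0, 1:]
    KtHK = WtPW[1:, 1:] - np.outer(gPK, gPK) / gPg
    return np.linalg.inv(KtHK)


def cluster_indicator(clusters: list[np.ndarray] | None, n: int) -> sp.csr_matrix | None:
    """Sparse (N_c x N) cluster-membership matrix; None means singletons."""
    if clusters is None:
        return None
    covered = np.concatenate(clusters)
    if len(covered) != n or len(np.unique(covered)) != n:
        raise ValueError("clusters must partition the samples")
    rows = np.concatenate([np.full(len(c), j) for j, c in enumerate(clusters)])
    return sp.csr_matrix(
        (np.ones(n), (rows, covered)), shape=(len(clusters), n)
    )


def meat_joint(
    fit: NullModelFit, vd: VariantDesign, clusters: list[np.ndarray] | None
) -> np.ndarray:
    """M_J: outer products of within-cluster sums of per-subject scores.

    The subject-level score contribution is S_i = R_i * W_adj_i: the
    scaled residual times the covariate-adjusted design row, where
    W_adj = W - X (X'S^-1X)^-1 X'S^-1 W is the GLS residual of W on the
    null covariates.  Summed over everyone this reproduces the total
    score W' R exactly (X' R = 0); partialling the covariates out of W
    before forming cluster sums is what makes each cluster's piece an
    honest score contribution and the sandwich consistent under
    misspecification.  With singleton clusters and an identity working
    covariance it reduces to the textbook HC0 empirical score variance.
    """
    S = fit.R_tilde[:, None] * fit.adjust_for_covariates(vd.W)
    J = cluster_indicator(clusters, fit.spec.n)
    CS = S if J is None else J @ S
    return CS.T @ CS


def sandwich_parts(
    fit: NullModelFit, vd: VariantDesign, clusters: list[np.ndarray] | None
) -> SandwichParts:
    B_J = bread_joint(fit, vd)
    M_J = meat_joint(fit, vd, clusters)
    return SandwichParts(
        bread_joint=B_J,
        bread_int=B_J[1:, 1:],
        meat_joint=M_J,
        meat_int=M_J[1:, 1:],
        cluster_count=fit.spec.n if clusters is None else len(clusters),
    )


def estimate_effects(fit: NullModelFit, vd: VariantDesign) -> np.ndarray:
    """zeta_hat = B_J W' R_tilde: genetic main effect then GEI effects."""
    return bread_joint(fit, vd) @ (vd.W.T @ fit.R_tilde)


def _pvals(T: float, df: int) -> tuple[float, float]:
    p = float(stats.chi2.sf(T, df))
    nl = float(-stats.chi2.logsf(T, df) / _LN10)
    return p, nl


def _quad_form_inv(v: np.ndarray, M: np.ndarray, what: str) -> float:
    w = np.linalg.eigvalsh(M)
    if w[0] <= _PD_RTOL * max(w[-1], 1.0):
        raise SkipVariant(f"non-positive-definite {what}")
    return float(v @ np.linalg.solve(M, v))


def _skip(vd: VariantDesign, strategy: str, reason: str) -> TestResult:
    return TestResult(variant_id=vd.variant_id, strategy=strategy, skip_reason=reason)


def _robust_result(
    fit: NullModelFit,
    vd: VariantDesign,
    clusters: list[np.ndarray] | None,
    strategy: str,
) -> TestResult:
    try:
        parts = sandwich_parts(fit, vd, clusters)
        zeta = parts.bread_joint @ (vd.W.T @ fit.R_tilde)
        cov_J = parts.bread_joint @ parts.meat_joint @ parts.bread_joint
        cov_I = parts.bread_int @ parts.meat_int @ parts.bread_int
        T_J = _quad_form_inv(zeta, cov_J, "sandwich covariance")
        T_I = _quad_form_inv(zeta[1:], cov_I, "sandwich covariance")
    except SkipVariant as s:
        return _skip(vd, strategy, s.reason)
    q = vd.q
    p_J, nl_J = _pvals(T_J, q + 1)
    p_I, nl_I = _pvals(T_I, q)
    return TestResult(
        variant_id=vd.variant_id,
        strategy=strategy,
        zeta_hat=zeta,
        cov_joint=cov_J,
        cov_int=cov_I,
        T_J=T_J,
        T_I=T_I,
        df_J=q + 1,
        df_I=q,
        p_J=p_J,
        p_I=p_I,
        neglog10_p_J=nl_J,
        neglog10_p_I=nl_I,
    )


def rom_test(
    fit: NullModelFit, vd: VariantDesign, clusters: list[np.ndarray] | None = None
) -> TestResult:
    """Family-clustered robust score test (the RoM test).

    ``clusters`` defaults to the null model's cluster partition.
    """
    if clusters is None:
        clusters = fit.clusters
    return _robust_result(fit, vd, clusters, "RoM")


def model_based_test(fit: NullModelFit, vd: VariantDesign) -> TestResult:
    """Model-based score test: variance from the bread alone (LMM-MB)."""
    try:
        B_J = bread_joint(fit, vd)
        zeta = B_J @ (vd.W.T @ fit.R_tilde)
        B_I = B_J[1:, 1:]
        T_J = _quad_form_inv(zeta, B_J, "information matrix")
        T_I = _quad_form_inv(zeta[1:], B_I, "information matrix")
    except SkipVariant as s:
        return _skip(vd, "LMM-MB", s.reason)
    q = vd.q
    p_J, nl_J = _pvals(T_J, q + 1)
    p_I, nl_I = _pvals(T_I, q)
    return TestResult(
        variant_id=vd.variant_id,
        strategy="LMM-MB",
        zeta_hat=zeta,
        cov_joint=B_J,
        cov_int=B_I,
        T_J=T_J,
        T_I=T_I,
        df_J=q + 1,
        df_I=q,
        p_J=p_J,
        p_I=p_I,
        neglog10_p_J=nl_J,
        neglog10_p_I=nl_I,
    )


def icb_test(fit: NullModelFit, vd: VariantDesign, strategy: str = "LMM-ICB") -> TestResult:
    """Individual-cluster sandwich: every observation its own cluster."""
    res = _robust_result(fit, vd, None, strategy)
    return res


def two_step_null(fit: NullModelFit, residual_type: str = "conditional") -> NullModelFit:
    """Step-2 linear-model null of the two-step strategy.

    Step 1 is the covariates-only LMM (``fit``); its residuals become
    the outcome of an ordinary linear model on the same covariates.
    Conditional residuals (subtracting the BLUP of the random effects)
    are the default; ``residual_type='marginal'`` uses y - X alpha_hat.
    """
    if residual_type == "conditional":
        e = fit.conditional_residuals()
    elif residual_type == "marginal":
        e = fit.marginal_residuals()
    else:
        raise ValueError("residual_type must be 'conditional' or 'marginal'")
    return fit_null_lm(e, fit.spec.X, column_names=fit.spec.column_names)


def two_step_test(
    y,
    X,
    components,
    clusters,
    vd: VariantDesign,
    residual_type: str = "conditional",
    step1_fit: NullModelFit | None = None,
) -> TestResult:
    """Two-step strategy: LMM residuals as outcome, then an individual-
    cluster sandwich score test in a plain linear model (Two-step-ICB)."""
    if step1_fit is None:
        step1_fit = fit_null_reml(
            NullModelSpec(y=y, X=X, components=components, clusters=clusters)
        )
    lm_fit = two_step_null(step1_fit, residual_type)
    return icb_test(lm_fit, vd, strategy="Two-step-ICB")


def lm_icb_test(y, X, vd: VariantDesign) -> TestResult:
    """Linear-model null (relatedness ignored) with individual clusters."""
    lm_fit = fit_null_lm(y, X)
    return icb_test(lm_fit, vd, strategy="LM-ICB")


def marginal_test(fit: NullModelFit, g: np.ndarray) -> TestResult:
    """Score test of the genetic main effect alone: (g'R)^2 / (g'Pg), chi2(1)."""
    g = np.asarray(g, dtype=float)
    vd = VariantDesign(g=g, K=np.empty((len(g), 0)), exposure_names=[])
    gPg = float(g @ fit.apply_projection(g))
    mac = min(g.sum(), 2 * len(g) - g.sum())
    if mac < 1 or gPg < _GPG_FLOOR * fit.spec.n:
        return _skip(vd, "marginal", "zero genetic variance")
    score = float(g @ fit.R_tilde)
    T = score**2 / gPg
    p, nl = _pvals(T, 1)
    return TestResult(
        variant_id=vd.variant_id,
        strategy="marginal",
        zeta_hat=np.array([score / gPg]),
        T_J=T,
        df_J=1,
        p_J=p,
        neglog10_p_J=nl,
    )


# ---------------------------------------------------------------------------
# batched genome scan
# ---------------------------------------------------------------------------


def _iter_blocks(genotypes, block_size: int):
    if hasattr(genotypes, "genotypes"):  # VariantPanel
        genotypes = genotypes.genotypes
    if isinstance(genotypes, np.ndarray):
        for start in range(0, genotypes.shape[1], block_size):
            yield start, genotypes[:, start : start + block_size]
    else:
        yield from genotypes


class _BlockCore:
    """Shared per-(working fit, genotype block) quantities.

    Holds the projected design, Gram matrices, scores, effect estimates
    and subject-level score rows for every variant of the block, so the
    model-based, family-clustered and singleton-clustered statistics
    can all be derived without repeating the O(N) projections.

    Internally variant designs are stored feature-major: ``flat`` has
    the genotype columns of the whole block first, then each
    interaction feature's columns, keeping every per-feature slice
    contiguous.
    """

    def __init__(self, wf: NullModelFit, G: np.ndarray, E: np.ndarray):
        n, B = G.shape
        q = E.shape[1]
        r = q + 1
        feats = [np.ascontiguousarray(G, dtype=float)]
        for m in range(q):
            feats.append(G * E[:, m : m + 1])
        flat = np.concatenate(feats, axis=1)  # n x (r B), feature-major
        # share X' Sigma^-1 flat between the projection and the adjustment
        st = wf._state
        t = st.C @ (st.A.T @ flat)
        Pflat = st.apply_sigma_inv(flat) - st.A @ t
        # W' P W per variant, assembled entry by entry (r is tiny)
        self.WtPW = np.empty((B, r, r))
        for a in range(r):
            fa = flat[:, a * B : (a + 1) * B]
            for b in range(a, r):
                v = np.add.reduce(fa * Pflat[:, b * B : (b + 1) * B], axis=0)
                self.WtPW[:, a, b] = self.WtPW[:, b, a] = v
        self.s = (wf.R_tilde @ flat).reshape(r, B).T
        # subject scores: scaled residual times covariate-adjusted design
        self.SW = wf.R_tilde[:, None] * (flat - wf.spec.X @ t)
        self.B, self.r, self.q, self.n = B, r, q, n

        ac = G.sum(axis=0)
        mac = np.minimum(ac, 2 * n - ac)
        self.skip = np.array([None] * B, dtype=object)
        valid = (mac >= 1) & (self.WtPW[:, 0, 0] >= _GPG_FLOOR * n)
        self.skip[~valid] = "zero genetic variance"
        ev = np.linalg.eigvalsh(self.WtPW)
        pd_ok = ev[:, 0] > _PD_RTOL * np.maximum(ev[:, -1], 1.0)
        self.skip[valid & ~pd_ok] = (
            "singular design (interaction collinear with genotype)"
        )
        valid &= pd_ok
        self.valid = valid
        self.vi = np.flatnonzero(valid)
        if self.vi.size:
            self.B_J = np.linalg.inv(self.WtPW[self.vi])
            self.zeta = np.matmul(self.B_J, self.s[self.vi][..., None])[..., 0]
        else:
            self.B_J = np.empty((0, r, r))
            self.zeta = np.empty((0, r))

    def cluster_sums(self, J: sp.csr_matrix | None) -> np.ndarray:
        return self.SW if J is None else np.asarray(J @ self.SW)

    def meat(self, J: sp.csr_matrix | None) -> np.ndarray:
        CS = self.cluster_sums(J)
        B, r = self.B, self.r
        M = np.empty((B, r, r))
        for a in range(r):
            ca = CS[:, a * B : (a + 1) * B]
            for b in range(a, r):
                v = np.add.reduce(ca * CS[:, b * B : (b + 1) * B], axis=0)
                M[:, a, b] = M[:, b, a] = v
        return M[self.vi]


def _batch_pd(M: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(M)
    return w[:, 0] > _PD_RTOL * np.maximum(w[:, -1], 1.0)


def _batch_quad(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum(
        "br,br->b", v, np.linalg.solve(M, v[..., None])[..., 0]
    )


def _stats_from_core(core: _BlockCore, robust: bool, J: sp.csr_matrix | None):
    """Per-variant statistics for one strategy flavour.

    ``robust=False`` -> model-based (bread-only) statistics; otherwise
    sandwich statistics with cluster sums given by ``J`` (``None`` means
    every subject is its own cluster).
    """
    B, r, q = core.B, core.r, core.q
    out = {
        "T_J": np.full(B, np.nan),
        "T_I": np.full(B, np.nan),
        "beta": np.full(B, np.nan),
        "gamma": np.full((B, q), np.nan),
        "se": np.full((B, r), np.nan),
        "skip": core.skip.copy(),
    }
    vi = core.vi
    if vi.size == 0:
        return out
    zeta = core.zeta
    out["beta"][vi] = zeta[:, 0]
    out["gamma"][vi] = zeta[:, 1:]
    if not robust:
        out["T_J"][vi] = np.einsum("br,brs,bs->b", core.s[vi], core.B_J, core.s[vi])
        out["T_I"][vi] = _batch_quad(core.B_J[:, 1:, 1:], zeta[:, 1:])
        out["se"][vi] = np.sqrt(np.diagonal(core.B_J, axis1=1, axis2=2))
        return out
    M = core.meat(J)
    cov_J = np.matmul(np.matmul(core.B_J, M), core.B_J)
    B_I = core.B_J[:, 1:, 1:]
    cov_I = np.matmul(np.matmul(B_I, M[:, 1:, 1:]), B_I)
    ok = _batch_pd(cov_J) & _batch_pd(cov_I)
    T_J = np.full(vi.size, np.nan)
    T_I = np.full(vi.size, np.nan)
    if ok.any():
        T_J[ok] = _batch_quad(cov_J[ok], zeta[ok])
        T_I[ok] = _batch_quad(cov_I[ok], zeta[ok, 1:])
    out["skip"][vi[~ok]] = "non-positive-definite sandwich"
    out["T_J"][vi] = T_J
    out["T_I"][vi] = T_I
    out["se"][vi] = np.sqrt(np.maximum(np.diagonal(cov_J, axis1=1, axis2=2), 0.0))
    return out


def _marginal_stats(core: _BlockCore):
    gPg = core.WtPW[:, 0, 0]
    score = core.s[:, 0]
    T = np.full(core.B, np.nan)
    beta = np.full(core.B, np.nan)
    ok = core.skip == None  # noqa: E711 -- object array of reasons
    np.divide(score**2, gPg, out=T, where=ok & (gPg > 0))
    np.divide(score, gPg, out=beta, where=ok & (gPg > 0))
    return T, beta


def scan(
    fit: NullModelFit,
    genotypes,
    exposures,
    clusters: list[np.ndarray] | None = None,
    strategies: tuple[str, ...] = ("RoM",),
    block_size: int = 1024,
    variant_ids=None,
    variant_meta: pd.DataFrame | None = None,
    residual_type: str = "conditional",
) -> pd.DataFrame:
    """Stream variants in blocks and run the requested strategies.

    ``genotypes`` may be an N x V array, a VariantPanel, or an iterator
    of ``(first_index, N x b block)`` pairs.  ``exposures`` is an N x q
    array or DataFrame.  Strategies sharing a working null fit also
    share the per-block projections, so adding a strategy is cheap.
    Output rows are ordered by variant index then strategy; results are
    invariant to ``block_size``.  Missing genotypes are mean-imputed
    per variant; unusable variants are reported with a machine-readable
    ``skip_reason`` instead of statistics.
    """
    unknown = [st for st in strategies if st not in STRATEGIES]
    if unknown:
        raise ValueError(f"unknown strategies {unknown}; choose from {STRATEGIES}")
    if clusters is None:
        clusters = fit.clusters
    if isinstance(exposures, pd.DataFrame):
        exposure_names = list(exposures.columns)
        E = exposures.to_numpy(dtype=float)
    else:
        E = np.atleast_2d(np.asarray(exposures, dtype=float))
        if E.shape[0] == 1 and fit.spec.n != 1:
            E = E.T
        exposure_names = [f"E{m}" for m in range(E.shape[1])]
    q = E.shape[1]
    J = cluster_indicator(clusters, fit.spec.n)

    # (working fit, robust?, family-clustered?) per strategy; fits built once
    work: dict[str, tuple[NullModelFit, bool, bool]] = {}
    aux: dict[str, NullModelFit] = {}
    for st in strategies:
        if st == "RoM":
            work[st] = (fit, True, True)
        elif st == "LMM-MB":
            work[st] = (fit, False, False)
        elif st == "LMM-ICB":
            work[st] = (fit, True, False)
        elif st == "marginal":
            work[st] = (fit, False, False)
        elif st == "Two-step-ICB":
            aux.setdefault("two-step", two_step_null(fit, residual_type))
            work[st] = (aux["two-step"], True, False)
        elif st == "LM-ICB":
            aux.setdefault(
                "lm",
                fit_null_lm(fit.spec.y, fit.spec.X, column_names=fit.spec.column_names),
            )
            work[st] = (aux["lm"], True, False)

    frames = []
    for start, G in _iter_blocks(genotypes, block_size):
        G = np.asarray(G, dtype=float)
        if not np.isfinite(G).all():
            mu = np.nanmean(np.where(np.isfinite(G), G, np.nan), axis=0)
            G = np.where(np.isfinite(G), G, mu[None, :])
        nb = G.shape[1]
        idx = np.arange(start, start + nb)
        if variant_ids is not None:
            ids = np.asarray(variant_ids)[idx]
        else:
            ids = np.array([f"v{i}" for i in idx])
        af = G.mean(axis=0) / 2.0
        cores: dict[int, _BlockCore] = {}
        for st in strategies:
            wf, robust, clustered = work[st]
            core = cores.get(id(wf))
            if core is None:
                core = cores[id(wf)] = _BlockCore(wf, G, E)
            base = {
                "variant_index": idx,
                "variant_id": ids,
                "af": af,
                "n": fit.spec.n,
                "strategy": st,
            }
            if st == "marginal":
                T, beta = _marginal_stats(core)
                df = pd.DataFrame(base | {"beta_main": beta, "T_I": np.nan, "T_J": T})
                df["skip_reason"] = core.skip
                df["df_I"], df["df_J"] = 0, 1
            else:
                res = _stats_from_core(core, robust, J if clustered else None)
                df = pd.DataFrame(
                    base
                    | {
                        "beta_main": res["beta"],
                        "T_I": res["T_I"],
                        "T_J": res["T_J"],
                        "skip_reason": res["skip"],
                    }
                )
                for m, nm in enumerate(exposure_names):
                    df[f"gamma_{nm}"] = res["gamma"][:, m]
                df["se_robust_g"] = res["se"][:, 0]
                for m, nm in enumerate(exposure_names):
                    df[f"se_robust_{nm}"] = res["se"][:, m + 1]
                df["df_I"], df["df_J"] = q, q + 1
            with np.errstate(divide="ignore", invalid="ignore"):
                df["p_I"] = stats.chi2.sf(df["T_I"], df["df_I"].where(df["df_I"] > 0, 1))
                df["p_J"] = stats.chi2.sf(df["T_J"], df["df_J"])
                df["neglog10_p_I"] = -stats.chi2.logsf(
                    df["T_I"], df["df_I"].where(df["df_I"] > 0, 1)
                ) / _LN10
                df["neglog10_p_J"] = -stats.chi2.logsf(df["T_J"], df["df_J"]) / _LN10
            frames.append(df)
    if not frames:
        return _empty_results(exposure_names)
    out = pd.concat(frames, ignore_index=True)
    out.sort_values(["variant_index", "strategy"], inplace=True, kind="stable")
    if variant_meta is not None:
        out = out.merge(variant_meta, on="variant_id", how="left")
    return out.reset_index(drop=True)


def _empty_results(exposure_names):
    cols = (
        [
            "variant_index",
            "variant_id",
            "af",
            "n",
            "strategy",
            "beta_main",
            "T_I",
            "T_J",
            "skip_reason",
        ]
        + [f"gamma_{nm}" for nm in exposure_names]
        + ["se_robust_g"]
        + [f"se_robust_{nm}" for nm in exposure_names]
        + ["df_I", "df_J", "p_I", "p_J", "neglog10_p_I", "neglog10_p_J"]
    )
    return pd.DataFrame(columns=cols)
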