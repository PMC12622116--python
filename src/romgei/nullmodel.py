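"""Null linear mixed model fitted by restricted maximum likelihood.

The model is y = X alpha + r + eps with r ~ N(0, sum_l lambda_l Psi_l)
and eps ~ N(0, lambda_0 I).  All relatedness matrices are block-diagonal
with blocks nested in a cluster (family) partition, so every solve with
the fitted covariance Sigma is done family by family; no N x N matrix
is ever formed.  Clusters of equal size are batched through numpy's
stacked linear algebra, which makes fitting and projection O(N) for
bounded family sizes.

Variance components are estimated by average-information (AI) REML with
step-halving, falling back to a derivative-free Nelder-Mead search on
the REML criterion if the AI updates stop making progress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse as sp

from .pedigree import KinshipModel

__all__ = [
    "NullModelSpec",
    "NullModelFit",
    "fit_null_reml",
    "fit_null_lm",
    "random_slope_component",
    "repeated_measures_clusters",
]

_VARIANCE_FLOOR_FRACTION = 1e-10


def _as_cluster_blocks(
    component, clusters: list[np.ndarray], n: int
) -> list[np.ndarray]:
    """Normalise a component to dense per-cluster blocks."""
    if isinstance(component, KinshipModel):
        component = component.to_sparse(scale=2.0)
    if sp.issparse(component):
        csr = component.tocsr()
        return [csr[np.ix_(idx, idx)].toarray() for idx in clusters]
    if isinstance(component, np.ndarray) and component.ndim == 2:
        return [component[np.ix_(idx, idx)] for idx in clusters]
    blocks = list(component)
    if len(blocks) != len(clusters):
        raise ValueError("per-cluster block list does not match cluster partition")
    return [np.asarray(b, dtype=float) for b in blocks]


@dataclass
class NullModelSpec:
    """Data and structure for a null mixed-model fit.

    ``components`` maps component names to relatedness structures given
    as a sparse/dense N x N matrix, a :class:`KinshipModel` (interpreted
    as the additive relationship 2 Psi), or a list of per-cluster dense
    blocks aligned with ``clusters``.  The residual identity component
    is implicit and always estimated.
    """

    y: np.ndarray
    X: np.ndarray
    components: dict[str, object]
    clusters: list[np.ndarray]
    column_names: list[str] | None = None
    _blocks: dict[str, list[np.ndarray]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X and y have different numbers of rows")
        if self.clusters is None or len(self.clusters) == 0:
            self.clusters = [np.array([i]) for i in range(n)]
        self.clusters = [np.asarray(c, dtype=np.int64) for c in self.clusters]
        covered = np.concatenate(self.clusters) if self.clusters else np.array([], int)
        if len(covered) != n or len(np.unique(covered)) != n:
            raise ValueError("clusters must partition the samples")
        if self.column_names is None:
            self.column_names = [f"x{j}" for j in range(self.X.shape[1])]
        self._blocks = {
            name: _as_cluster_blocks(comp, self.clusters, n)
            for name, comp in self.components.items()
        }
        for name, blocks in self._blocks.items():
            for b in blocks:
                if not np.allclose(b, b.T, atol=1e-8):
                    raise ValueError(f"component {name!r} has an asymmetric block")

    @classmethod
    def from_kinship(
        cls, y, X, km: KinshipModel, name: str = "kinship", column_names=None
    ) -> "NullModelSpec":
        """Single additive component 2 Psi clustered by family."""
        return cls(
            y=y,
            X=X,
            components={name: km.relationship_blocks()},
            clusters=km.clusters,
            column_names=column_names,
        )

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def component_names(self) -> list[str]:
        return list(self._blocks.keys())


class _Groups:
    """Clusters bucketed by size for batched linear algebra."""

    def __init__(self, spec: NullModelSpec):
        sizes = np.array([len(c) for c in spec.clusters])
        self.sizes = sorted(set(sizes.tolist()))
        self.idx: list[np.ndarray] = []
        self.comps: list[np.ndarray] = []  # (L, m, b, b) per group
        names = spec.component_names
        for b in self.sizes:
            which = np.flatnonzero(sizes == b)
            self.idx.append(np.stack([spec.clusters[k] for k in which]))
            if names:
                self.comps.append(
                    np.stack(
                        [
                            np.stack([spec._blocks[nm][k] for k in which])
                            for nm in names
                        ]
                    )
                )
            else:
                self.comps.append(np.zeros((0, len(which), b, b)))
        self.n = spec.n
        self.n_components = len(names)

    def gather(self, V: np.ndarray, g: int) -> np.ndarray:
        return V[self.idx[g]]  # (m, b, k)

    def scatter(self, out: np.ndarray, g: int, val: np.ndarray) -> None:
        out[self.idx[g]] = val


class _SigmaState:
    """Per-iteration quantities for a fixed set of variance components."""

    def __init__(self, groups: _Groups, X: np.ndarray, y: np.ndarray, lam: np.ndarray):
        self.lam = lam
        self.inv: list[np.ndarray] = []
        logdet = 0.0
        for g, b in enumerate(groups.sizes):
            m = groups.idx[g].shape[0]
            sigma = np.zeros((m, b, b))
            for l in range(groups.n_components):
                sigma += lam[l] * groups.comps[g][l]
            sigma[:, np.arange(b), np.arange(b)] += lam[-1]
            chol = np.linalg.cholesky(sigma)
            logdet += 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
            self.inv.append(np.linalg.inv(sigma))
        self.logdet = logdet
        self.groups = groups
        self._inv_diag = None
        if groups.sizes == [1]:
            d = np.empty(groups.n)
            d[groups.idx[0][:, 0]] = self.inv[0][:, 0, 0]
            self._inv_diag = d
        # GLS pieces: A = Sigma^-1 X, C = (X' Sigma^-1 X)^-1
        self.A = self.apply_sigma_inv(X)
        xtsx = X.T @ self.A
        self.C = np.linalg.inv(xtsx)
        _, ld = np.linalg.slogdet(xtsx)
        self.alpha = self.C @ (self.A.T @ y)
        resid = y - X @ self.alpha
        self.R_tilde = self.apply_sigma_inv(resid)
        self.loglik = -0.5 * (logdet + ld + resid @ self.R_tilde)

    def apply_sigma_inv(self, V: np.ndarray) -> np.ndarray:
        v = np.asarray(V, dtype=float)
        squeeze = v.ndim == 1
        if squeeze:
            v = v[:, None]
        if self._inv_diag is not None:  # all-singleton fast path
            out = v * self._inv_diag[:, None]
        else:
            out = np.empty_like(v)
            for g in range(len(self.groups.sizes)):
                idx = self.groups.idx[g]
                out[idx] = np.matmul(self.inv[g], v[idx])
        return out[:, 0] if squeeze else out

    def apply_projection(self, V: np.ndarray) -> np.ndarray:
        """P V = Sigma^-1 V - A C (A' V), never forming P."""
        v = np.asarray(V, dtype=float)
        squeeze = v.ndim == 1
        if squeeze:
            v = v[:, None]
        out = self.apply_sigma_inv(v) - self.A @ (self.C @ (self.A.T @ v))
        return out[:, 0] if squeeze else out

    def adjust_for_covariates(self, V: np.ndarray, X: np.ndarray) -> np.ndarray:
        """V - X (X'Sigma^-1 X)^-1 X'Sigma^-1 V: the GLS residual of each
        column of V on the covariates (so that Sigma^-1 @ result = P V)."""
        v = np.asarray(V, dtype=float)
        squeeze = v.ndim == 1
        if squeeze:
            v = v[:, None]
        out = v - X @ (self.C @ (self.A.T @ v))
        return out[:, 0] if squeeze else out


@dataclass
class NullModelFit:
    """A converged (or flagged) REML fit of the null mixed model."""

    spec: NullModelSpec
    alpha: np.ndarray
    lambdas: dict[str, float]
    R_tilde: np.ndarray
    xtsx_inv: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    _state: _SigmaState = field(repr=False)

    # -- linear operators --------------------------------------------
    def apply_sigma_inv(self, V: np.ndarray) -> np.ndarray:
        """Sigma^-1 V, block solves per family."""
        return self._state.apply_sigma_inv(V)

    def apply_projection(self, V: np.ndarray) -> np.ndarray:
        """P V where P = Sigma^-1 - Sigma^-1 X (X'Sigma^-1 X)^-1 X'Sigma^-1."""
        if np.asarray(V).shape[0] != self.spec.n:
            raise ValueError("V must have one row per sample")
        return self._state.apply_projection(V)

    def adjust_for_covariates(self, V: np.ndarray) -> np.ndarray:
        """GLS-adjust columns of V for the covariates: V - X (X'S^-1X)^-1 X'S^-1V."""
        if np.asarray(V).shape[0] != self.spec.n:
            raise ValueError("V must have one row per sample")
        return self._state.adjust_for_covariates(V, self.spec.X)

    def scaled_residuals(self) -> np.ndarray:
        """R_tilde = Sigma^-1 (y - X alpha_hat), identical to P y."""
        return self.R_tilde

    def marginal_residuals(self) -> np.ndarray:
        return self.spec.y - self.spec.X @ self.alpha

    def conditional_residuals(self) -> np.ndarray:
        """y - X alpha_hat - BLUP(r); equals lambda_residual * R_tilde."""
        return self.lambdas["residual"] * self.R_tilde

    @property
    def clusters(self) -> list[np.ndarray]:
        return self.spec.clusters


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")


def _score_and_ai(
    state: _SigmaState, groups: _Groups, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """REML score vector and average-information matrix over all components."""
    L = groups.n_components
    Py = state.R_tilde
    # v_l = Psi_l P y for each component; residual component uses identity
    V = np.empty((groups.n, L + 1))
    tr_sinv = np.zeros(L + 1)
    T = np.zeros((L + 1, X.shape[1], X.shape[1]))  # A' Psi_l A accumulators
    for g, b in enumerate(groups.sizes):
        idx = groups.idx[g]
        inv = state.inv[g]
        Ag = state.A[idx]  # (m, b, p)
        Pyg = Py[idx]  # (m, b)
        for l in range(L):
            psi = groups.comps[g][l]
            V[idx, l] = np.einsum("mbc,mc->mb", psi, Pyg)
            tr_sinv[l] += np.einsum("mij,mij->", inv, psi)
            psiA = np.einsum("mbc,mcp->mbp", psi, Ag)
            T[l] += np.einsum("mbp,mbq->pq", Ag, psiA)
        tr_sinv[L] += np.einsum("mii->", inv)
        T[L] += np.einsum("mbp,mbq->pq", Ag, Ag)
    V[:, L] = Py
    tr_P = np.array([tr_sinv[l] - np.trace(state.C @ T[l]) for l in range(L + 1)])
    quad = V.T @ Py  # (Py)' Psi_l (Py)
    score = -0.5 * (tr_P - quad)
    PV = state.apply_projection(V)
    AI = 0.5 * (V.T @ PV)
    return score, AI


def fit_null_reml(
    spec: NullModelSpec, tol: float = 1e-6, max_iter: int = 100
) -> NullModelFit:
    """Average-information REML fit of the null mixed model.

    Convergence is declared when the relative change of every variance
    component falls below ``tol``.  Components are floored at a small
    positive fraction of Var(y) so Sigma stays invertible.  If the AI
    update cannot improve the restricted likelihood, a Nelder-Mead
    search on the REML criterion takes over; a fit that still fails to
    converge is returned with ``converged=False`` rather than raised.
    """
    _check_full_rank(spec.X, spec.column_names)
    groups = _Groups(spec)
    L = groups.n_components
    vary = float(np.var(spec.y))
    if vary == 0:
        vary = 1.0
    floor = _VARIANCE_FLOOR_FRACTION * vary

    if L == 0:
        # degenerate case: ordinary linear model, closed-form REML
        n, p = spec.X.shape
        lam = np.array([max(floor, _ols_sigma2(spec))])
        state = _SigmaState(groups, spec.X, spec.y, lam)
        return _finalize(spec, state, {"residual": lam[0]}, True, 0)

    lam = np.full(L + 1, vary / (L + 1))
    state = _SigmaState(groups, spec.X, spec.y, lam)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, AI = _score_and_ai(state, groups, spec.X)
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)
        accepted = None
        for _ in range(30):
            cand = np.maximum(lam + step, floor)
            try:
                cand_state = _SigmaState(groups, spec.X, spec.y, cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if cand_state.loglik >= state.loglik - 1e-10:
                accepted = (cand, cand_state)
                break
            step *= 0.5
        if accepted is None:
            lam, state, converged = _simplex_fallback(groups, spec, lam, floor)
            break
        new_lam, new_state = accepted
        delta = np.max(np.abs(new_lam - lam) / np.maximum(np.abs(lam), vary * 1e-3))
        lam, state = new_lam, new_state
        if delta < tol:
            converged = True
            break

    lambdas = dict(zip(spec.component_names + ["residual"], lam.tolist()))
    return _finalize(spec, state, lambdas, converged, n_iter)


def _ols_sigma2(spec: NullModelSpec) -> float:
    n, p = spec.X.shape
    beta, *_ = np.linalg.lstsq(spec.X, spec.y, rcond=None)
    rss = float(np.sum((spec.y - spec.X @ beta) ** 2))
    return rss / max(n - p, 1)


def _simplex_fallback(groups, spec, lam0, floor):
    """Nelder-Mead on the REML criterion over log variance components."""

    def neg_loglik(log_lam):
        try:
            st = _SigmaState(groups, spec.X, spec.y, np.exp(log_lam))
        except np.linalg.LinAlgError:
            return np.inf
        return -st.loglik

    res = scipy.optimize.minimize(
        neg_loglik,
        np.log(np.maximum(lam0, floor)),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    lam = np.maximum(np.exp(res.x), floor)
    return lam, _SigmaState(groups, spec.X, spec.y, lam), bool(res.success)


def _finalize(spec, state, lambdas, converged, n_iter) -> NullModelFit:
    return NullModelFit(
        spec=spec,
        alpha=state.alpha,
        lambdas=lambdas,
        R_tilde=state.R_tilde,
        xtsx_inv=state.C,
        loglik=state.loglik,
        converged=converged,
        n_iter=n_iter,
        _state=state,
    )


def fit_null_lm(y, X, clusters=None, column_names=None) -> NullModelFit:
    """Ordinary linear model expressed as a mixed-model fit.

    The working covariance is sigma^2 I with the REML (unbiased) scale
    estimate, so scaled residuals are (y - X alpha_hat)/sigma^2 and the
    projection is the usual least-squares annihilator divided by
    sigma^2.  Useful as the second step of the two-step strategy and as
    the null for the linear-model comparison strategy.
    """
    spec = NullModelSpec(
        y=y, X=X, components={}, clusters=clusters, column_names=column_names
    )
    return fit_null_reml(spec)


def random_slope_component(
    base_blocks: list[np.ndarray], exposure: np.ndarray, clusters: list[np.ndarray]
) -> list[np.ndarray]:
    """Per-cluster blocks D Psi D with D = diag(exposure).

    Expresses a random slope on an exposure as an extra variance
    component over the same relatedness structure.
    """
    out = []
    for blk, idx in zip(base_blocks, clusters):
        d = exposure[idx]
        out.append(blk * np.outer(d, d))
    return out


def repeated_measures_clusters(subject_ids) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Clusters plus within-subject ones-blocks for repeated measures.

    Returns ``(clusters, blocks)`` where each cluster holds the
    observations of one subject and each block is a matrix of ones
    (random intercept per subject).
    """
    subject_ids = np.asarray(subject_ids)
    order = {}
    for i, s in enumerate(subject_ids):
        order.setdefault(s, []).append(i)
    clusters = [np.asarray(v, dtype=np.int64) for v in order.values()]
    blocks = [np.ones((len(c), len(c))) for c in clusters]
    return clusters, blocks
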