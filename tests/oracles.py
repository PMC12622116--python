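"""Independent reference implementations used only by the tests.

Everything here is deliberately naive: dense matrices, explicit
inverses, python loops over clusters and ancestor paths.  None of it
shares code with the package internals it checks.
"""

import numpy as np


# ---------------------------------------------------------------------------
# kinship by path counting
# ---------------------------------------------------------------------------


def _ancestor_chains(ped, i):
    """All chains [i, parent, ..., ancestor] (including the trivial [i])."""
    fa, mo = ped.parent_indices()
    chains = [[i]]
    out = []
    while chains:
        c = chains.pop()
        out.append(tuple(c))
        top = c[-1]
        if fa[top] >= 0:
            chains.append(c + [fa[top]])
            chains.append(c + [mo[top]])
    return out


def path_counting_kinship(ped, i, j):
    """phi(i, j) for a non-inbred pedigree by summing over disjoint
    ancestor-path pairs: each pair of chains from i and j meeting only
    at a common ancestor A contributes (1/2)^(d_i + d_j + 1)."""
    if i == j:
        return 0.5
    total = 0.0
    for ci in _ancestor_chains(ped, i):
        for cj in _ancestor_chains(ped, j):
            if ci[-1] != cj[-1]:
                continue
            if set(ci) & set(cj) != {ci[-1]}:
                continue
            total += 0.5 ** (len(ci) - 1 + len(cj) - 1 + 1)
    return total


# ---------------------------------------------------------------------------
# dense mixed-model pieces
# ---------------------------------------------------------------------------


def dense_pieces(y, X, sigma):
    """Explicit Sigma^-1, P, C, alpha, scaled residuals."""
    si = np.linalg.inv(sigma)
    C = np.linalg.inv(X.T @ si @ X)
    P = si - si @ X @ C @ X.T @ si
    alpha = C @ X.T @ si @ y
    R = si @ (y - X @ alpha)
    return si, P, C, alpha, R


def dense_reml_loglik(y, X, sigma):
    """REML criterion, same additive constant convention as the package:
    -0.5 (log|Sigma| + log|X'Sigma^-1 X| + r' Sigma^-1 r)."""
    si, P, C, alpha, R = dense_pieces(y, X, sigma)
    _, ld_s = np.linalg.slogdet(sigma)
    _, ld_x = np.linalg.slogdet(X.T @ si @ X)
    resid = y - X @ alpha
    return -0.5 * (ld_s + ld_x + resid @ si @ resid)


def dense_meat(R, W_adj, clusters, n):
    """Cluster-summed outer products of per-subject scores, python loops."""
    if clusters is None:
        clusters = [np.array([i]) for i in range(n)]
    r = W_adj.shape[1]
    M = np.zeros((r, r))
    for idx in clusters:
        s = np.zeros(r)
        for i in idx:
            s += R[i] * W_adj[i]
        M += np.outer(s, s)
    return M


def dense_strategy(y, X, sigma, g, K, clusters, flavor):
    """Dense reference for one strategy's (zeta, cov_J, cov_I, T_J, T_I).

    ``flavor``: 'robust' (sandwich with the given clusters; pass
    clusters=None for individual clusters) or 'model' (bread only).
    B_I is recomputed from the explicit H matrix, not from the
    partitioned inverse the implementation uses.
    """
    si, P, C, alpha, R = dense_pieces(y, X, sigma)
    W = np.column_stack([g, K])
    u = W.T @ R
    B_J = np.linalg.inv(W.T @ P @ W)
    zeta = B_J @ u
    gc = g[:, None]
    H = P - P @ gc @ np.linalg.inv(gc.T @ P @ gc) @ gc.T @ P
    B_I = np.linalg.inv(K.T @ H @ K)
    if flavor == "model":
        T_J = zeta @ np.linalg.inv(B_J) @ zeta
        T_I = zeta[1:] @ np.linalg.inv(B_I) @ zeta[1:]
        return zeta, B_J, B_I, T_J, T_I
    W_adj = W - X @ C @ X.T @ si @ W
    M = dense_meat(R, W_adj, clusters, len(y))
    cov_J = B_J @ M @ B_J
    cov_I = B_I @ M[1:, 1:] @ B_I
    T_J = zeta @ np.linalg.inv(cov_J) @ zeta
    T_I = zeta[1:] @ np.linalg.inv(cov_I) @ zeta[1:]
    return zeta, cov_J, cov_I, T_J, T_I


def hc0_score_test(y, X, W):
    """Brute-force heteroskedasticity-robust (HC0) linear-model score test.

    Null OLS of y on X; score u = W'e; empirical variance from the
    covariate-residualised design: M = sum_i e_i^2 w_i w_i' with
    w = (I - X(X'X)^-1 X') W.  Returns (T_joint, T_interaction).
    """
    hat = X @ np.linalg.inv(X.T @ X) @ X.T
    e = y - hat @ y
    Wt = W - hat @ W
    u = W.T @ e
    M = np.zeros((W.shape[1], W.shape[1]))
    for i in range(len(y)):
        M += e[i] ** 2 * np.outer(Wt[i], Wt[i])
    T_J = u @ np.linalg.inv(M) @ u
    # interaction part: effect estimate and its sandwich block
    B = np.linalg.inv(Wt.T @ Wt)
    zeta = B @ u
    cov = B @ M @ B
    B_I = B[1:, 1:]
    cov_I = B_I @ M[1:, 1:] @ B_I
    T_I = zeta[1:] @ np.linalg.inv(cov_I) @ zeta[1:]
    return T_J, T_I
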