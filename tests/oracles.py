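"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (brute force,
exhaustive enumeration, generic 1-D optimization, gradient-projection
rotation) and shares no code with the solver paths it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize_scalar


def penalized_row_objective(lam_row, A, b, psi, family, rho, gamma):
    """Exact M-step objective of one loading row (additive constant dropped)."""
    lam = np.asarray(lam_row, dtype=float)
    quad = (lam @ A @ lam - 2.0 * lam @ b) / (2.0 * psi)
    if family == "prenet":
        pen = 0.0
        m = lam.size
        for j in range(m):
            for k in range(j + 1, m):
                prod = lam[j] * lam[k]
                pen += gamma * abs(prod) + 0.5 * (1 - gamma) * prod**2
        return quad + rho * pen
    if family == "lasso":
        return quad + rho * np.abs(lam).sum()
    if family == "enet":
        return quad + rho * (
            gamma * np.abs(lam).sum() + 0.5 * (1 - gamma) * (lam**2).sum()
        )
    if family == "mcp":
        pen = 0.0
        for x in np.abs(lam):
            pen += rho * x - x**2 / (2 * gamma) if x <= rho * gamma \
                else 0.5 * rho**2 * gamma
        return quad + pen
    raise ValueError(family)


def minimize_coordinate_1d(lam_row, j, A, b, psi, family, rho, gamma,
                           lo=-3.0, hi=3.0, n_grid=2001):
    """Grid scan plus golden-section refinement of coordinate j's 1-D problem.

    The objective has a kink at 0, so each half-line is refined separately
    and 0 itself is always a candidate.
    """
    lam = np.asarray(lam_row, dtype=float).copy()

    def f(t):
        lam[j] = t
        return penalized_row_objective(lam, A, b, psi, family, rho, gamma)

    grid = np.linspace(lo, hi, n_grid)
    vals = [f(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    best_t, best_v = 0.0, f(0.0)
    for a, c in ((lo, 0.0), (0.0, hi)):
        res = minimize_scalar(f, bounds=(a, c), method="bounded",
                              options={"xatol": 1e-12})
        if res.fun < best_v:
            best_t, best_v = float(res.x), float(res.fun)
    # golden refinement near the best grid point as extra insurance
    res = minimize_scalar(
        f, bounds=(max(lo, t0 - 0.02), min(hi, t0 + 0.02)),
        method="bounded", options={"xatol": 1e-12},
    )
    if res.fun < best_v:
        best_t = float(res.x)
    return best_t


def ari_pair_counts(labels_a, labels_b) -> float:
    """Adjusted Rand index by exhaustive enumeration of all variable pairs."""
    a = list(labels_a)
    b = list(labels_b)
    n = len(a)
    together_a = together_b = together_both = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            together_a += sa
            together_b += sb
            together_both += sa and sb
    expected = together_a * together_b / n_pairs
    max_index = 0.5 * (together_a + together_b)
    if max_index == expected:
        return 1.0
    return (together_both - expected) / (max_index - expected)


def align_columnwise_signs(truth, estimate):
    """Alignment oracle: enumerate permutations; pick each column's sign
    independently (optimal because columns do not interact in the norm)."""
    T = np.asarray(truth, dtype=float)
    E = np.asarray(estimate, dtype=float)
    m = T.shape[1]
    best, best_err = None, np.inf
    for perm in permutations(range(m)):
        cols = []
        err = 0.0
        for j, pj in enumerate(perm):
            c = E[:, pj]
            e_plus = ((T[:, j] - c) ** 2).sum()
            e_minus = ((T[:, j] + c) ** 2).sum()
            if e_plus <= e_minus:
                cols.append(c)
                err += e_plus
            else:
                cols.append(-c)
                err += e_minus
        if err < best_err:
            best_err, best = err, np.column_stack(cols)
    return best


def _quartimin_value_grad(L):
    N = 1.0 - np.eye(L.shape[1])
    L2 = L**2
    return 0.5 * float(np.sum(L2 * (L2 @ N))), 2.0 * L * (L2 @ N)


def quartimin_rotate(A, n_starts=10, seed=0, max_iter=1000, eps=1e-10):
    """Orthogonal quartimin rotation by gradient projection with random restarts.

    Returns the rotated loading matrix minimizing the quartimin criterion
    over A @ T, T orthogonal.
    """
    rng = np.random.default_rng(seed)
    m = A.shape[1]
    best_L, best_f = None, np.inf
    for s in range(n_starts):
        T = np.eye(m) if s == 0 else np.linalg.qr(
            rng.standard_normal((m, m)))[0]
        al = 1.0
        L = A @ T
        f, Gq = _quartimin_value_grad(L)
        G = A.T @ Gq
        for _ in range(max_iter):
            M = T.T @ G
            Gp = G - T @ (0.5 * (M + M.T))
            step_norm = np.linalg.norm(Gp)
            if step_norm < eps:
                break
            al *= 2
            while True:
                U, _, Vt = np.linalg.svd(T - al * Gp)
                Tt = U @ Vt
                Lt = A @ Tt
                ft, Gqt = _quartimin_value_grad(Lt)
                if ft < f - 0.5 * step_norm**2 * al or al < 1e-12:
                    break
                al /= 2
            T, f, L, Gq = Tt, ft, Lt, Gqt
            G = A.T @ Gq
        if f < best_f:
            best_f, best_L = f, L
    return best_L, best_f


def random_pd_factor_model(rng, p, m, oblique=False):
    """Random valid factor model with unit-diagonal implied covariance scale."""
    from prenetfa import FactorModel

    Lam = rng.uniform(-0.7, 0.7, size=(p, m))
    # shrink rows so communalities stay below 1
    comm = (Lam**2).sum(axis=1)
    scale = np.minimum(1.0, np.sqrt(0.8 / np.maximum(comm, 1e-12)))
    Lam *= scale[:, None]
    if oblique:
        Z = rng.standard_normal((m, m + 2))
        Phi = Z @ Z.T
        d = 1 / np.sqrt(np.diag(Phi))
        Phi = Phi * np.outer(d, d)
        np.fill_diagonal(Phi, 1.0)
        orient = "oblique"
    else:
        Phi = np.eye(m)
        orient = "orthogonal"
    psi = 1.0 - np.diag(Lam @ Phi @ Lam.T)
    psi = np.maximum(psi, 0.05)
    return FactorModel(Lam, Phi, psi, orient)
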