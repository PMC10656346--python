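"""Variable clustering from loading matrices.

A perfect-simple-structure loading matrix partitions the observed variables:
variable i belongs to cluster j when its single nonzero loading sits in
column j.  For dense loading matrices the argmax of |l_ij| is used instead.
The large-rho prenet fit is a generalization of k-means clustering of
*variables* (columns of the data matrix): the k-means objective admits an
exact covariance-only form, and relaxing the equal-loading indicator
constraint to "orthonormal perfect simple structure" turns the k-means
problem into a low-rank covariance approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .model import ZERO_TOL, SampleCov, FactorModel, discrepancy, is_perfect_simple

__all__ = [
    "VariablePartition",
    "clusters_from_loadings",
    "adjusted_rand_index",
    "kmeans_variables_objective",
    "pss_vs_modified_kmeans_check",
]

logger = logging.getLogger(__name__)


@dataclass
class VariablePartition:
    """Assignment of each of p variables to one of m clusters (or None)."""

    labels: list
    m: int

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab is not None and not (0 <= int(lab) < self.m):
                raise ValueError(f"label {lab} outside 0..{self.m - 1}")

    @property
    def p(self) -> int:
        return len(self.labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": np.arange(self.p),
                "cluster": [(-1 if l is None else int(l)) for l in self.labels],
            }
        )


def clusters_from_loadings(
    loadings: np.ndarray, mode: str = "argmax", tol: float = ZERO_TOL
) -> VariablePartition:
    """Cluster variables by their loadings.

    ``pss`` mode requires a perfect simple structure and reads off the
    unique nonzero column per row; ``argmax`` mode assigns each variable to
    the column with the largest |loading| (smallest index on ties).
    All-zero rows get the label ``None``.
    """
    L = np.atleast_2d(np.asarray(loadings, dtype=float))
    m = L.shape[1]
    if mode == "pss":
        flag, cols = is_perfect_simple(L, tol)
        if not flag:
            raise ValueError("pss mode requires a perfect-simple-structure matrix")
        return VariablePartition(cols, m)
    if mode != "argmax":
        raise ValueError(f"unknown mode {mode!r}")
    labels: list = []
    for row in np.abs(L):
        labels.append(None if np.all(row <= tol) else int(np.argmax(row)))
    return VariablePartition(labels, m)


def adjusted_rand_index(a: VariablePartition, b: VariablePartition) -> float:
    """Chance-corrected agreement between two variable partitions in [-1, 1].

    Variables labelled ``None`` in either partition are excluded pairwise
    (and the count logged); identical partitions score exactly 1.
    """
    if a.p != b.p:
        raise ValueError("partitions must cover the same variables")
    keep = [
        i for i in range(a.p) if a.labels[i] is not None and b.labels[i] is not None
    ]
    dropped = a.p - len(keep)
    if dropped:
        logger.info("ARI: dropped %d unassigned variable(s)", dropped)
    if not keep:
        raise ValueError("no jointly assigned variables")
    la = [int(a.labels[i]) for i in keep]
    lb = [int(b.labels[i]) for i in keep]
    return float(adjusted_rand_score(la, lb))


def kmeans_variables_objective(X0: np.ndarray, partition: VariablePartition) -> float:
    """Within-cluster sum of squares for k-means on the *columns* of X0.

    Computes sum_j sum_{i in C_j} ||x_i* - mu_j||^2 on the column-centred
    data and verifies the exact covariance-side identity

        (n-1) ( sum_i s_ii - sum_j p_j^{-1} sum_{i,i' in C_j} s_ii' )

    with s_ii' the (n-1)-denominator sample covariance, to 1e-8.
    """
    X = np.asarray(X0, dtype=float)
    n, p = X.shape
    if partition.p != p:
        raise ValueError("partition size does not match number of columns")
    if any(l is None for l in partition.labels):
        raise ValueError("all variables must be assigned to a cluster")
    labels = np.array([int(l) for l in partition.labels])
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / (n - 1)
    lhs = 0.0
    rhs_sum = 0.0
    for j in range(partition.m):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            raise ValueError(f"cluster {j} is empty")
        mu = Xc[:, idx].mean(axis=1)
        lhs += ((Xc[:, idx] - mu[:, None]) ** 2).sum()
        rhs_sum += S[np.ix_(idx, idx)].sum() / idx.size
    rhs = (n - 1) * (np.trace(S) - rhs_sum)
    if abs(lhs - rhs) > 1e-8 * max(1.0, abs(lhs)):
        raise AssertionError(
            f"k-means identity violated: data side {lhs!r} vs covariance side {rhs!r}"
        )
    return float(lhs)


def _best_pss_orthonormal_loadings(
    S: np.ndarray, labels: np.ndarray, m: int
) -> np.ndarray:
    """Best-fitting orthonormal PSS loading matrix for a fixed partition.

    With disjoint supports and unit-norm columns, minimizing
    ||S - Lambda Lambda^T||_F^2 separates over clusters; column j is the top
    eigenvector of the S-block of cluster j, placed on that support.
    """
    p = S.shape[0]
    L = np.zeros((p, m))
    for j in range(m):
        idx = np.flatnonzero(labels == j)
        if idx.size == 0:
            raise ValueError(f"cluster {j} is empty")
        block = S[np.ix_(idx, idx)]
        w, v = np.linalg.eigh(block)
        L[idx, j] = v[:, -1]
    return L


def pss_vs_modified_kmeans_check(
    S: SampleCov,
    alpha: float,
    candidate_partitions: list[VariablePartition],
) -> bool:
    """Do the Frobenius and discrepancy criteria rank candidate partitions alike?

    For each candidate partition, builds the best orthonormal PSS loading
    matrix and evaluates both ||S - Lambda Lambda^T||_F^2 and the ML
    discrepancy under Psi = alpha I.  Returns True when the two criteria
    induce the same ordering of the candidates — the exact equivalence holds
    in the isotropic-uniqueness regime, and can fail outside it.
    """
    if len(candidate_partitions) == 0:
        raise ValueError("need at least one candidate partition")
    frob, disc = [], []
    for part in candidate_partitions:
        if any(l is None for l in part.labels):
            raise ValueError("candidate partitions must assign every variable")
        labels = np.array([int(l) for l in part.labels])
        L = _best_pss_orthonormal_loadings(S.S, labels, part.m)
        frob.append(float(np.linalg.norm(S.S - L @ L.T, "fro") ** 2))
        model = FactorModel(
            L, np.eye(part.m), np.full(S.p, alpha), "orthogonal"
        )
        disc.append(discrepancy(S, model))
    return list(np.argsort(frob, kind="stable")) == list(
        np.argsort(disc, kind="stable")
    )
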