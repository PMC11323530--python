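"""Independent dense-matrix oracles for the variance engine.

Literal transcriptions of the displayed covariance formulas using nothing
but explicit dense matrices, per-cluster loops, numpy.linalg.inv and
scipy.linalg.sqrtm — deliberately free of the structured/low-rank shortcuts
the package uses, so agreement is meaningful.
"""

import numpy as np
import scipy.linalg

from wedgepower.design import DesignSpec, build_design_matrices, build_layout


def dense_cluster_pieces(spec: DesignSpec):
    """Per-cluster (M_i, A_i, Sigma_i, V_i) with everything dense."""
    layout = build_layout(spec)
    mats = build_design_matrices(spec, layout)
    n = spec.n_periods * spec.cluster_size
    J, m = spec.n_periods, spec.cluster_size
    R = np.full((n, n), spec.icc * spec.cac)
    R += np.kron(np.eye(J), np.full((m, m), spec.icc * (1.0 - spec.cac)))
    np.fill_diagonal(R, 1.0)
    pieces = []
    for i in range(spec.n_clusters):
        g = mats.pattern_of[i]
        M = mats.M[g]
        A = np.diag(mats.A[g])
        Ah = np.diag(np.sqrt(mats.A[g]))
        Ahi = np.diag(1.0 / np.sqrt(mats.A[g]))
        Sigma = Ahi @ R @ Ahi
        V = Ah @ R @ Ah
        pieces.append((M, A, Sigma, V))
    return pieces


def dense_variance(spec: DesignSpec, method: str) -> np.ndarray:
    """Model-based or KC/MD-corrected covariance, transcribed literally."""
    pieces = dense_cluster_pieces(spec)
    p = pieces[0][0].shape[1]
    B = np.zeros((p, p))
    for M, A, Sigma, V in pieces:
        B += M.T @ np.linalg.inv(Sigma) @ M
    Binv = np.linalg.inv(B)
    if method == "gee":
        return Binv
    n = pieces[0][0].shape[0]
    middle = np.zeros((p, p))
    for M, A, Sigma, V in pieces:
        Sinv = np.linalg.inv(Sigma)
        Ainv = np.linalg.inv(A)
        H = A @ M @ Binv @ M.T @ Sinv @ Ainv
        ImH = np.eye(n) - H
        if method == "md":
            F = np.linalg.inv(ImH)
        elif method == "kc":
            F = np.linalg.inv(scipy.linalg.sqrtm(ImH).real)
        elif method == "identity":
            F = np.eye(n)
        else:
            raise ValueError(method)
        Omega_inv = Sinv @ Ainv @ F @ A @ Sigma @ A @ F.T @ Ainv @ Sinv
        middle += M.T @ Omega_inv @ M
    return Binv @ middle @ Binv


def dense_variance_eq5(spec: DesignSpec) -> np.ndarray:
    """The pre-simplification information form (M' A V^{-1} A M)^{-1}."""
    pieces = dense_cluster_pieces(spec)
    p = pieces[0][0].shape[1]
    B = np.zeros((p, p))
    for M, A, Sigma, V in pieces:
        B += M.T @ A @ np.linalg.inv(V) @ A @ M
    return np.linalg.inv(B)
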