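"""Design-stage covariance of the GEE coefficient estimator, with KC/MD corrections.

The model-based (naive) approximation is the inverse Fisher information

    Var(Theta_hat) ~= ( sum_i M_i' Sigma_i^{-1} M_i )^{-1},
    Sigma_i = A_i^{-1/2} R_i A_i^{-1/2},

whose last diagonal element is the predicted variance of the interaction
(HTE) coefficient.  Because the information ignores an O_P(1/I) remainder it
understates the truth when the number of clusters is small, so two
leverage-based corrections from the sandwich-variance literature are applied
at the design stage: Kauermann-Carroll (KC) multiplies the cluster residual
by (I - H_i)^{-1/2} and Mancl-DeRouen (MD) by (I - H_i)^{-1}, where

    H_i = A_i M_i B^{-1} M_i' Sigma_i^{-1} A_i^{-1},
    B   = sum_i M_i' Sigma_i^{-1} M_i

is the cluster leverage.  The corrected covariance is the sandwich

    B^{-1} ( sum_i T_i V_i T_i' ) B^{-1},
    T_i = M_i' Sigma_i^{-1} A_i^{-1} F_i,   V_i = A_i^{1/2} R_i A_i^{1/2},

which collapses exactly to the model-based form when F_i = I.

H_i has rank at most p = J + 3, so matrix functions of (I - H_i) are
evaluated through the rank-p identity  f(I - U W') = I + U phi(K) W'  with
K = W'U and phi(lam) = (f(1 - lam) - 1)/lam, keeping every computation at
O(n p^2) even for clusters of several hundred individuals.  Clusters sharing
a crossover pattern reuse all factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .correlation import CorrelationBundle, build_correlation
from .design import DesignMatrices, DesignSpec, build_design_matrices

Method = Literal["gee", "kc", "md"]


class CorrectionError(RuntimeError):
    """The leverage correction could not be computed (I - H numerically
    singular or with non-real principal root); a larger I or m usually
    resolves this."""


@dataclass(frozen=True)
class VarianceReport:
    """Predicted coefficient covariance with the effect-of-interest extracted.

    ``var_hte`` is the last diagonal element (the interaction coefficient
    under the full model; the treatment coefficient under the reduced
    model).  ``var_ote`` is the treatment-column diagonal element.
    """

    method: str
    full_cov: np.ndarray
    var_hte: float
    var_ote: float


def _information(
    matrices: DesignMatrices, bundle: CorrelationBundle
) -> tuple[np.ndarray, list[np.ndarray]]:
    """B = sum_i M' Sigma^{-1} M and the per-pattern A^{1/2} M factors."""
    p = matrices.M[0].shape[1]
    B = np.zeros((p, p))
    Xs = []
    for M, A, c in zip(matrices.M, matrices.A, matrices.counts):
        X = np.sqrt(A)[:, None] * M
        Xs.append(X)
        B += c * (X.T @ bundle.apply_inv(X))
    return B, Xs


def _report(method: str, cov: np.ndarray, matrices: DesignMatrices) -> VarianceReport:
    cov = 0.5 * (cov + cov.T)
    J = matrices.n_periods
    return VarianceReport(
        method=method,
        full_cov=cov,
        var_hte=float(cov[matrices.hte_index, matrices.hte_index]),
        var_ote=float(cov[J, J]),
    )


def model_based_variance(
    matrices: DesignMatrices, bundle: CorrelationBundle
) -> VarianceReport:
    """Inverse-information (naive) covariance of the GEE estimator."""
    B, _ = _information(matrices, bundle)
    try:
        cov = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "information matrix is singular; the design does not identify "
            "all coefficients (check the covariate allocation)"
        ) from exc
    return _report("gee", cov, matrices)


def _phi(lam: np.ndarray, method: str) -> np.ndarray:
    """phi(lam) = (f(1-lam) - 1)/lam for f = principal inverse square root
    (KC) or inverse (MD), with the removable singularity at lam = 0."""
    lam = lam.astype(complex)
    out = np.empty_like(lam)
    small = np.abs(lam) < 1e-12
    if method == "kc":
        out[~small] = ((1.0 - lam[~small]) ** -0.5 - 1.0) / lam[~small]
        out[small] = 0.5
    else:  # md
        out[~small] = 1.0 / (1.0 - lam[~small])
        out[small] = 1.0
    return out


def _phi_of_K(K: np.ndarray, method: str) -> np.ndarray:
    """phi(K) for the rank-p correction factor, via eigendecomposition of
    the (generally non-symmetric) p x p matrix K = W'U."""
    lam, S = np.linalg.eig(K)
    if np.any(lam.real >= 1.0 - 1e-10):
        raise CorrectionError(
            "I - H has an eigenvalue <= 0 (cluster leverage too high); "
            "increase the number of clusters or the cluster size"
        )
    Phi = (S * _phi(lam, method)[None, :]) @ np.linalg.inv(S)
    if np.max(np.abs(Phi.imag)) > 1e-8:
        # principal-root fallback on the dense matrix is handled by caller
        raise CorrectionError("non-real principal correction factor")
    return Phi.real


def corrected_variance(
    matrices: DesignMatrices,
    bundle: CorrelationBundle,
    method: Method,
) -> VarianceReport:
    """Design-stage KC- or MD-corrected sandwich covariance.

    ``method='gee'`` (identity residual modification) is accepted and
    reproduces :func:`model_based_variance` exactly, which is the collapse
    identity used as a self-check.
    """
    method = method.lower()
    if method not in ("gee", "kc", "md"):
        raise ValueError(f"method must be one of 'gee', 'kc', 'md', got {method!r}")
    B, _ = _information(matrices, bundle)
    Binv = np.linalg.inv(B)
    p = B.shape[0]
    middle = np.zeros((p, p))
    sq = np.sqrt
    for M, A, u, c in zip(matrices.M, matrices.A, matrices.u, matrices.counts):
        sA = sq(A)
        # W' = M' Sigma^{-1} A^{-1}  (p x n), via Sigma^{-1} = A^{1/2} R^{-1} A^{1/2}
        Wt = (bundle.apply_inv(sA[:, None] * M) / sA[:, None]).T
        if method == "gee":
            T = Wt
        else:
            U = (A[:, None] * M) @ Binv  # n x p
            K = Wt @ U
            try:
                Phi = _phi_of_K(K, method)
                # T = M' Sigma^{-1} A^{-1} F = (I + K phi(K)) W'
                T = (np.eye(p) + K @ Phi) @ Wt
            except CorrectionError:
                T = _dense_T(M, A, Binv, bundle, method)
        G = T * sA[None, :]
        middle += c * (G @ bundle.apply(G.T))
    cov = Binv @ middle @ Binv
    return _report(method, cov, matrices)


def _dense_T(M, A, Binv, bundle, method):
    """Dense fallback: principal root via Schur-based sqrtm on I - H."""
    n = M.shape[0]
    sA = np.sqrt(A)
    Sig_inv = sA[:, None] * bundle.inverse() * sA[None, :]
    H = (A[:, None] * M) @ Binv @ (M.T @ Sig_inv) / A[None, :]
    ImH = np.eye(n) - H
    if method == "md":
        F = np.linalg.inv(ImH)
    else:
        F = np.linalg.inv(scipy.linalg.sqrtm(ImH).real)
    return (M.T @ Sig_inv) @ ((1.0 / A)[:, None] * F)


def design_variance(spec: DesignSpec, method: Method = "gee") -> VarianceReport:
    """Predicted coefficient covariance for a design specification."""
    matrices = build_design_matrices(spec)
    bundle = build_correlation(spec.n_periods, spec.cluster_size, spec.icc, spec.cac)
    if method.lower() == "gee":
        return model_based_variance(matrices, bundle)
    return corrected_variance(matrices, bundle, method)
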