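"""Block-exchangeable outcome correlation structures and their fast inverses.

The nested exchangeable correlation for a cluster observed over J periods
with m individuals per period is

    R(alpha, rho) = alpha*rho * J_{Jm}
                    + alpha*(1 - rho) * I_J (x) J_m
                    + (1 - alpha) * I_{Jm}

where alpha is the within-period intraclass correlation (ICC) and rho the
cluster autocorrelation (CAC): two individuals share correlation ``alpha``
within a period and ``alpha * rho`` across periods.  ``rho = 1`` collapses to
the simple exchangeable structure.

R has exactly three distinct eigenvalues,

    lam1 = 1 - alpha                              (multiplicity J(m-1))
    lam2 = 1 - alpha + m*alpha*(1 - rho)          (multiplicity J-1)
    lam3 = lam2 + J*m*alpha*rho                   (multiplicity 1)

on, respectively, the within-period contrasts, the between-period contrasts
of period means, and the grand mean.  All products with R or its inverse are
therefore computable in O(n) per column via mean decompositions, which this
module exploits; dense matrices are materialized only on request.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AdmissibilityError(ValueError):
    """The (alpha, rho, J, m) combination is not positive definite."""


def eigenvalues(J: int, m: int, alpha: float, rho: float) -> tuple[float, float, float]:
    lam1 = 1.0 - alpha
    lam2 = 1.0 - alpha + m * alpha * (1.0 - rho)
    lam3 = lam2 + J * m * alpha * rho
    return lam1, lam2, lam3


def check_admissible(J: int, m: int, alpha: float, rho: float) -> None:
    """Raise AdmissibilityError unless R(alpha, rho) is positive definite."""
    names = (
        "1 - alpha",
        "1 - alpha + m*alpha*(1-rho)",
        "1 - alpha + m*alpha*(1-rho) + J*m*alpha*rho",
    )
    for lam, name in zip(eigenvalues(J, m, alpha, rho), names):
        if lam <= 0.0:
            raise AdmissibilityError(
                f"correlation structure not positive definite for J={J}, "
                f"m={m}, alpha={alpha}, rho={rho}: eigenvalue {name} = "
                f"{lam:.6g} <= 0"
            )


@dataclass(frozen=True)
class CorrelationBundle:
    """Nested exchangeable correlation R(alpha, rho) for one cluster.

    Provides structured O(n)-per-column products with R and R^{-1}; the
    dense matrix, its inverse, and the working covariance pieces
    Sigma = A^{-1/2} R A^{-1/2} and V = A^{1/2} R A^{1/2} are built on
    demand for small problems and oracle checks.
    """

    J: int
    m: int
    alpha: float
    rho: float

    def __post_init__(self):
        check_admissible(self.J, self.m, self.alpha, self.rho)

    @property
    def n(self) -> int:
        return self.J * self.m

    @property
    def eigs(self) -> tuple[float, float, float]:
        return eigenvalues(self.J, self.m, self.alpha, self.rho)

    # -- structured products ------------------------------------------------

    def _decompose(self, X: np.ndarray):
        """Split columns into within-period residual, period-mean contrast,
        and grand-mean components (the three eigenspaces)."""
        X = np.atleast_2d(X.T).T  # ensure 2-D with columns preserved
        blocks = X.reshape(self.J, self.m, -1)
        period_mean = blocks.mean(axis=1, keepdims=True)  # (J, 1, k)
        grand_mean = period_mean.mean(axis=0, keepdims=True)  # (1, 1, k)
        Pa = (blocks - period_mean).reshape(self.n, -1)
        Pb = np.broadcast_to(period_mean - grand_mean, blocks.shape).reshape(self.n, -1)
        Pc = np.broadcast_to(grand_mean, blocks.shape).reshape(self.n, -1)
        return Pa, Pb, Pc

    def apply(self, X: np.ndarray) -> np.ndarray:
        """R @ X without forming R."""
        squeeze = X.ndim == 1
        lam1, lam2, lam3 = self.eigs
        Pa, Pb, Pc = self._decompose(X)
        out = lam1 * Pa + lam2 * Pb + lam3 * Pc
        return out.ravel() if squeeze else out

    def apply_inv(self, X: np.ndarray) -> np.ndarray:
        """R^{-1} @ X without forming R."""
        squeeze = X.ndim == 1
        lam1, lam2, lam3 = self.eigs
        Pa, Pb, Pc = self._decompose(X)
        out = Pa / lam1 + Pb / lam2 + Pc / lam3
        return out.ravel() if squeeze else out

    # -- dense views ---------------------------------------------------------

    def matrix(self) -> np.ndarray:
        n, J, m = self.n, self.J, self.m
        R = np.full((n, n), self.alpha * self.rho)
        R += np.kron(np.eye(J), np.full((m, m), self.alpha * (1.0 - self.rho)))
        np.fill_diagonal(R, 1.0)
        return R

    def inverse(self) -> np.ndarray:
        """Closed-form dense inverse via the three-eigenvalue structure.

        R^{-1} = c1*I + c2*(I_J (x) J_m) + c3*J_{Jm} with
        c1 = 1/lam1, c2 = (1/lam2 - 1/lam1)/m, c3 = (1/lam3 - 1/lam2)/(J*m).
        """
        lam1, lam2, lam3 = self.eigs
        c1 = 1.0 / lam1
        c2 = (1.0 / lam2 - 1.0 / lam1) / self.m
        c3 = (1.0 / lam3 - 1.0 / lam2) / (self.J * self.m)
        out = np.full((self.n, self.n), c3)
        out += np.kron(np.eye(self.J), np.full((self.m, self.m), c2))
        out[np.diag_indices(self.n)] += c1
        return out

    def sigma(self, A: np.ndarray) -> np.ndarray:
        """Sigma = A^{-1/2} R A^{-1/2} (dense), A the variance diagonal."""
        s = 1.0 / np.sqrt(A)
        return s[:, None] * self.matrix() * s[None, :]

    def covariance(self, A: np.ndarray) -> np.ndarray:
        """V = A^{1/2} R A^{1/2} (dense), the outcome covariance."""
        s = np.sqrt(A)
        return s[:, None] * self.matrix() * s[None, :]


def build_correlation(J: int, m: int, alpha: float, rho: float) -> CorrelationBundle:
    """Validated nested exchangeable correlation bundle."""
    return CorrelationBundle(J=J, m=m, alpha=alpha, rho=rho)
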