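"""Gaussian-copula generation of correlated binary outcomes.

Outcomes are produced by thresholding a latent multivariate normal vector:
Y_jk = 1{ Z_jk <= Phi^{-1}(mu_jk) } with Z ~ N(0, Xi).  The latent
correlation xi for each pair is chosen so that the *outcome* correlation
matches the nested exchangeable target: the bivariate Gaussian copula
identity

    P(Y = 1, Y' = 1) = Phi2( Phi^{-1}(mu), Phi^{-1}(mu'); xi )

is inverted by bracketed root finding, with the required joint probability
target_corr * sqrt(v v') + mu mu' checked against the Frechet-Hoeffding
bounds first.  The assembled latent matrix Xi is not guaranteed positive
semi-definite; eigenvalues below a small floor are raised to the floor and
the matrix rescaled to unit diagonal before factorization.

Only the distinct (mu, mu', target) combinations are solved — a stepped
wedge cluster has at most two covariate groups per period, so a J-period
cluster needs a handful of roots regardless of cluster size — and clusters
sharing a crossover pattern share one factorized matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri, owens_t
from scipy.stats import norm

from .correlation import CorrelationBundle, build_correlation
from .design import DesignMatrices, DesignSpec, build_design_matrices


class InfeasibleCorrelationError(ValueError):
    """The requested pair correlation violates the Frechet bounds for the
    given marginal probabilities."""


def bivariate_normal_cdf(h: float, k: float, r: float) -> float:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation r.

    Owen's-T closed form; accurate to ~1e-14 away from |r| = 1.
    """
    if r >= 1.0 - 1e-15:
        return float(norm.cdf(min(h, k)))
    if r <= -1.0 + 1e-15:
        return float(max(0.0, norm.cdf(h) + norm.cdf(k) - 1.0))
    if r == 0.0:
        return float(norm.cdf(h) * norm.cdf(k))
    # guard the h=0 / k=0 removable singularities of the T-function form
    if h == 0.0:
        h = 1e-15
    if k == 0.0:
        k = 1e-15
    s = math.sqrt(1.0 - r * r)
    a1 = (k / h - r) / s
    a2 = (h / k - r) / s
    beta = 0.5 if h * k < 0.0 else 0.0
    val = (
        0.5 * (norm.cdf(h) + norm.cdf(k))
        - float(owens_t(h, a1))
        - float(owens_t(k, a2))
        - beta
    )
    return float(min(max(val, 0.0), 1.0))


def solve_pairwise_xi(mu1: float, mu2: float, target_corr: float, tol: float = 1e-8) -> float:
    """Latent correlation xi giving outcome correlation ``target_corr``.

    Solves Phi2(Phi^{-1}(mu1), Phi^{-1}(mu2); xi) = joint, where
    joint = target_corr*sqrt(v1 v2) + mu1*mu2, for xi in (-1, 1).
    """
    if target_corr == 0.0:
        return 0.0
    v1, v2 = mu1 * (1.0 - mu1), mu2 * (1.0 - mu2)
    joint = target_corr * math.sqrt(v1 * v2) + mu1 * mu2
    lo_bound = max(0.0, mu1 + mu2 - 1.0)
    hi_bound = min(mu1, mu2)
    if not lo_bound < joint < hi_bound:
        raise InfeasibleCorrelationError(
            f"outcome correlation {target_corr} for marginals ({mu1:.4g}, "
            f"{mu2:.4g}) needs joint probability {joint:.6g} outside the "
            f"Frechet bounds ({lo_bound:.6g}, {hi_bound:.6g})"
        )
    a, b = float(ndtri(mu1)), float(ndtri(mu2))

    def f(xi: float) -> float:
        return bivariate_normal_cdf(a, b, xi) - joint

    return float(brentq(f, -0.9999, 0.9999, xtol=tol, rtol=8.9e-16))


@dataclass
class LatentCorrelation:
    """Latent Gaussian correlation matrix for one cluster pattern."""

    Xi: np.ndarray
    repaired: bool
    factor: np.ndarray  # lower-triangular, Xi = factor @ factor.T
    max_adjustment: float = 0.0


def repair_non_psd(Xi: np.ndarray, floor: float = 1e-6) -> LatentCorrelation:
    """Clip eigenvalues at ``floor``, rescale to unit diagonal, factorize.

    Positive-semi-definite input passes through unchanged (repaired=False).
    """
    Xi = 0.5 * (Xi + Xi.T)
    eigval, eigvec = np.linalg.eigh(Xi)
    if eigval[0] >= floor:
        out = Xi
        repaired = False
        max_adj = 0.0
    else:
        clipped = np.maximum(eigval, floor)
        out = (eigvec * clipped[None, :]) @ eigvec.T
        d = np.sqrt(np.diag(out))
        out = out / d[:, None] / d[None, :]
        np.fill_diagonal(out, 1.0)
        repaired = True
        max_adj = float(np.max(np.abs(out - Xi)))
    try:
        factor = np.linalg.cholesky(out)
    except np.linalg.LinAlgError:
        # floor-level eigenvalues can leave the matrix semidefinite to
        # within rounding; a tiny ridge restores a usable factor
        factor = np.linalg.cholesky(out + 1e-10 * np.eye(out.shape[0]))
    return LatentCorrelation(Xi=out, repaired=repaired, factor=factor, max_adjustment=max_adj)


def build_latent_matrix(
    u: np.ndarray,
    groups: np.ndarray,
    bundle: CorrelationBundle,
    xi_cache: dict | None = None,
    floor: float = 1e-6,
) -> LatentCorrelation:
    """Latent matrix for one cluster with marginal means ``u``.

    ``groups`` assigns each of the J*m positions a small integer label such
    that positions with the same (period, label) share a marginal mean —
    under the deterministic allocation this is just the covariate value.
    Pairwise latent correlations are solved once per distinct
    (mu, mu', within/between) combination and cached.
    """
    J, m = bundle.J, bundle.m
    n = J * m
    if xi_cache is None:
        xi_cache = {}
    u2 = u.reshape(J, m)
    g2 = groups.reshape(J, m)
    Xi = np.eye(n)

    def xi_for(mu1: float, mu2: float, target: float) -> float:
        key = (round(min(mu1, mu2), 12), round(max(mu1, mu2), 12), round(target, 12))
        if key not in xi_cache:
            xi_cache[key] = solve_pairwise_xi(mu1, mu2, target)
        return xi_cache[key]

    for j1 in range(J):
        for j2 in range(j1, J):
            target = bundle.alpha if j1 == j2 else bundle.alpha * bundle.rho
            if target == 0.0:
                continue
            block = np.zeros((m, m))
            for ga in np.unique(g2[j1]):
                for gb in np.unique(g2[j2]):
                    mu1 = float(u2[j1][g2[j1] == ga][0])
                    mu2 = float(u2[j2][g2[j2] == gb][0])
                    mask = np.outer(g2[j1] == ga, g2[j2] == gb)
                    block[mask] = xi_for(mu1, mu2, target)
            if j1 == j2:
                np.fill_diagonal(block, 1.0)
                Xi[j1 * m : (j1 + 1) * m, j1 * m : (j1 + 1) * m] = block
            else:
                Xi[j1 * m : (j1 + 1) * m, j2 * m : (j2 + 1) * m] = block
                Xi[j2 * m : (j2 + 1) * m, j1 * m : (j1 + 1) * m] = block.T
    return repair_non_psd(Xi, floor=floor)


def simulate_cluster(
    latent: LatentCorrelation, u: np.ndarray, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw ``size`` binary outcome vectors for one cluster.

    Returns an array of shape (size, J*m); deterministic given the
    generator state.
    """
    n = latent.factor.shape[0]
    thresholds = ndtri(u)
    z = rng.standard_normal((size, n))
    latent_draws = z @ latent.factor.T
    return (latent_draws <= thresholds[None, :]).astype(np.int8)


class OutcomeSimulator:
    """Copula simulator for a full trial, with per-pattern factor reuse.

    Precomputes one latent factorization per crossover pattern; drawing a
    replicate then costs one matrix-vector product per cluster.
    """

    def __init__(self, spec: DesignSpec, matrices: DesignMatrices | None = None,
                 floor: float = 1e-6):
        self.spec = spec
        self.matrices = matrices if matrices is not None else build_design_matrices(spec)
        self.bundle = build_correlation(
            spec.n_periods, spec.cluster_size, spec.icc, spec.cac
        )
        from .design import build_layout

        groups = build_layout(spec).x
        self.xi_cache: dict = {}
        self.latents = [
            build_latent_matrix(u, groups, self.bundle, self.xi_cache, floor=floor)
            for u in self.matrices.u
        ]
        self.any_repaired = any(lat.repaired for lat in self.latents)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """One replicate: array of shape (I, J*m), rows ordered by cluster."""
        out = np.empty((self.matrices.n_clusters, self.bundle.n), dtype=np.int8)
        for i, g in enumerate(self.matrices.pattern_of):
            out[i] = simulate_cluster(self.latents[g], self.matrices.u[g], rng, size=1)[0]
        return out
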