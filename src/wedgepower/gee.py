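"""GEE fitting of the marginal logistic model with exchangeable-family
working correlation.

Fisher-scoring iterations for the coefficient vector alternate with moment
re-estimation of the working correlation parameters from standardized
Pearson-residual cross-products: within-period pair products estimate the
ICC alpha, cross-period products estimate alpha*rho.  Solving the scoring
system uses the same O(n)-per-column structured products with R^{-1} as the
design-stage variance engine.

After convergence four coefficient covariance estimators are produced: the
model-based (naive) inverse information, the uncorrected robust sandwich,
and the Kauermann-Carroll and Mancl-DeRouen leverage-corrected sandwiches,
with cluster residuals premultiplied by (I - H_i)^{-1/2} or (I - H_i)^{-1}
via the same rank-p identity used at the design stage.

Non-convergence and separation are flagged on the returned fit rather than
raised, so simulation harnesses can count and exclude such replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .correlation import build_correlation, check_admissible, AdmissibilityError
from .design import DesignMatrices
from .variance import _phi_of_K, CorrectionError

WORKINGS = ("independence", "simple", "nested")


@dataclass
class GeeFit:
    theta_hat: np.ndarray
    naive_cov: np.ndarray
    robust_cov: np.ndarray
    kc_cov: np.ndarray | None
    md_cov: np.ndarray | None
    alpha_hat: float
    rho_hat: float
    converged: bool
    n_iter: int
    separated: bool
    hte_index: int
    max_step: float

    def covariance(self, se_choice: str) -> np.ndarray:
        cov = {
            "naive": self.naive_cov,
            "robust": self.robust_cov,
            "kc": self.kc_cov,
            "md": self.md_cov,
        }[se_choice]
        if cov is None:
            raise ValueError(f"{se_choice} covariance was not computed for this fit")
        return cov

    def hte_se(self, se_choice: str = "naive") -> float:
        return float(np.sqrt(self.covariance(se_choice)[self.hte_index, self.hte_index]))


def _clip_admissible(J: int, m: int, alpha: float, rho: float) -> tuple[float, float]:
    """Shrink moment estimates into the positive-definite region."""
    alpha = float(np.clip(alpha, -0.95, 0.95))
    rho = float(np.clip(rho, -1.0, 1.0))
    for _ in range(60):
        try:
            check_admissible(J, m, alpha, rho)
            return alpha, rho
        except AdmissibilityError:
            alpha *= 0.8
    return 0.0, rho


def _moment_estimates(
    resid: list[np.ndarray], J: int, m: int, working: str
) -> tuple[float, float]:
    """ICC / CAC moment estimators from Pearson residuals.

    ``resid`` holds per-pattern arrays of shape (clusters, J*m).
    """
    within = between = sq = 0.0
    n_cl = 0
    for r in resid:
        c = r.shape[0]
        n_cl += c
        r3 = r.reshape(c, J, m)
        s_j = r3.sum(axis=2)  # (c, J)
        per_cluster_sq = (r3**2).sum(axis=(1, 2))
        within += float(((s_j**2).sum(axis=1) - per_cluster_sq).sum())
        S = s_j.sum(axis=1)
        between += float((S**2 - (s_j**2).sum(axis=1)).sum())
        sq += float(per_cluster_sq.sum())
    if working == "simple":
        pairs = n_cl * J * m * (J * m - 1)
        alpha = (within + between) / pairs if pairs else 0.0
        return alpha, 1.0
    # nested
    wpairs = n_cl * J * m * (m - 1)
    bpairs = n_cl * J * (J - 1) * m * m
    alpha = within / wpairs if wpairs else 0.0
    alpha_rho = between / bpairs if bpairs else 0.0
    rho = alpha_rho / alpha if abs(alpha) > 1e-12 else 0.0
    return alpha, float(np.clip(rho, -1.0, 1.0))


def fit_gee(
    Y: np.ndarray,
    matrices: DesignMatrices,
    working: str = "nested",
    max_iter: int = 100,
    tol: float = 1e-6,
    theta_init: np.ndarray | None = None,
    fix_correlation: tuple[float, float] | None = None,
    compute_corrected: bool = True,
) -> GeeFit:
    """Fit the marginal model to outcomes ``Y`` of shape (I, J*m).

    ``working`` selects the working correlation family; with
    ``fix_correlation=(alpha, rho)`` the correlation parameters are held
    fixed instead of re-estimated (an independence fit is
    ``fix_correlation=(0, 0)``, equivalent to pooled logistic regression).
    ``max_iter=0`` evaluates scores and covariances at ``theta_init``
    without updating, which is occasionally useful for diagnostics.
    """
    if working not in WORKINGS:
        raise ValueError(f"working must be one of {WORKINGS}, got {working!r}")
    J, m = matrices.n_periods, matrices.cluster_size
    p = matrices.M[0].shape[1]
    by_pattern = [
        Y[[i for i, g in enumerate(matrices.pattern_of) if g == gg]]
        for gg in range(matrices.n_patterns)
    ]
    ybar = float(Y.mean())
    if not 0.0 < ybar < 1.0:
        # only one outcome level observed: the intercept diverges
        return _failed_fit(p, matrices.hte_index)

    theta = np.zeros(p)
    theta[0] = logit(np.clip(ybar, 1e-6, 1 - 1e-6))
    if theta_init is not None:
        theta = np.asarray(theta_init, dtype=float).copy()

    if fix_correlation is not None or working == "independence":
        alpha, rho = fix_correlation or (0.0, 0.0)
    else:
        alpha, rho = 0.0, 1.0 if working == "simple" else 0.0

    converged = False
    separated = False
    n_iter = 0
    max_step = np.inf
    for n_iter in range(1, max_iter + 1):
        etas = [M @ theta for M in matrices.M]
        if any(np.max(np.abs(e)) > 30.0 for e in etas):
            separated = True
            break
        us = [expit(e) for e in etas]
        sAs = [np.sqrt(u * (1.0 - u)) for u in us]
        resid = [(yg - us[g][None, :]) / sAs[g][None, :] for g, yg in enumerate(by_pattern)]
        if fix_correlation is None and working != "independence":
            alpha, rho = _moment_estimates(resid, J, m, working)
            alpha, rho = _clip_admissible(J, m, alpha, rho)
        bundle = build_correlation(J, m, alpha, rho)
        B = np.zeros((p, p))
        score = np.zeros(p)
        for g, M in enumerate(matrices.M):
            X = sAs[g][:, None] * M
            RX = bundle.apply_inv(X)
            B += by_pattern[g].shape[0] * (X.T @ RX)
            # score contribution M' Sigma^{-1} A^{-1} e = X' R^{-1} (e / sqrtA)
            score += RX.T @ resid[g].sum(axis=0)
        try:
            step = np.linalg.solve(B, score)
        except np.linalg.LinAlgError:
            separated = True
            break
        max_step = float(np.max(np.abs(step)))
        if max_step > 5.0:  # guard against overshoot far from the optimum
            step = step * (5.0 / max_step)
            max_step = 5.0
        theta = theta + step
        if max_step < tol:
            converged = True
            break

    if separated or (max_iter > 0 and not converged):
        return _failed_fit(p, matrices.hte_index, theta=theta, alpha=alpha, rho=rho,
                           n_iter=n_iter, separated=separated, max_step=max_step)

    # covariances at the fitted (theta, alpha, rho)
    bundle = build_correlation(J, m, alpha, rho)
    B = np.zeros((p, p))
    per_pattern = []
    for g, M in enumerate(matrices.M):
        u = expit(M @ theta)
        A = u * (1.0 - u)
        sA = np.sqrt(A)
        X = sA[:, None] * M
        RX = bundle.apply_inv(X)
        B += by_pattern[g].shape[0] * (X.T @ RX)
        per_pattern.append((M, u, A, sA, X, RX))
    Binv = np.linalg.inv(B)
    meat = np.zeros((p, p))
    meat_kc = np.zeros((p, p)) if compute_corrected else None
    meat_md = np.zeros((p, p)) if compute_corrected else None
    corrected_ok = compute_corrected
    for g, (M, u, A, sA, X, RX) in enumerate(per_pattern):
        E = (by_pattern[g] - u[None, :]) / sA[None, :]  # (c, n) scaled residuals
        Q = RX.T @ E.T  # (p, c): per-cluster M' Sigma^{-1} A^{-1} e
        meat += Q @ Q.T
        if corrected_ok:
            Wt = (RX / sA[:, None]).T  # M' Sigma^{-1} A^{-1}
            U = (A[:, None] * M) @ Binv
            K = Wt @ U
            try:
                Qk = (np.eye(p) + K @ _phi_of_K(K, "kc")) @ Q
                Qm = (np.eye(p) + K @ _phi_of_K(K, "md")) @ Q
            except CorrectionError:
                corrected_ok = False
                continue
            meat_kc += Qk @ Qk.T
            meat_md += Qm @ Qm.T
    return GeeFit(
        theta_hat=theta,
        naive_cov=Binv,
        robust_cov=Binv @ meat @ Binv,
        kc_cov=Binv @ meat_kc @ Binv if corrected_ok else None,
        md_cov=Binv @ meat_md @ Binv if corrected_ok else None,
        alpha_hat=float(alpha),
        rho_hat=float(rho),
        converged=True,
        n_iter=n_iter,
        separated=False,
        hte_index=matrices.hte_index,
        max_step=max_step,
    )


def _failed_fit(p, hte_index, theta=None, alpha=0.0, rho=0.0, n_iter=0,
                separated=False, max_step=np.inf) -> GeeFit:
    nanm = np.full((p, p), np.nan)
    return GeeFit(
        theta_hat=theta if theta is not None else np.full(p, np.nan),
        naive_cov=nanm, robust_cov=nanm, kc_cov=None, md_cov=None,
        alpha_hat=float(alpha), rho_hat=float(rho), converged=False,
        n_iter=n_iter, separated=separated, hte_index=hte_index,
        max_step=float(max_step),
    )


def empirical_variances(fit: GeeFit) -> dict[str, np.ndarray]:
    """The four coefficient covariance estimators of a converged fit."""
    if not fit.converged:
        raise ValueError("empirical variances require a converged fit")
    out = {"naive": fit.naive_cov, "robust": fit.robust_cov}
    if fit.kc_cov is not None:
        out["kc"] = fit.kc_cov
    if fit.md_cov is not None:
        out["md"] = fit.md_cov
    return out


def wald_test_hte(
    fit: GeeFit,
    se_choice: str = "naive",
    sig_level: float = 0.05,
    test: str = "wald_z",
    t_df: int | None = None,
) -> bool:
    """Reject H0: interaction = 0 at the two-sided ``sig_level``?"""
    from scipy import stats

    se = fit.hte_se(se_choice)
    if se == 0.0:
        return bool(fit.theta_hat[fit.hte_index] != 0.0)
    stat = abs(float(fit.theta_hat[fit.hte_index])) / se
    if test == "wald_t":
        if t_df is None:
            raise ValueError("t_df required for wald_t")
        crit = stats.t.ppf(1.0 - sig_level / 2.0, t_df)
    else:
        crit = stats.norm.ppf(1.0 - sig_level / 2.0)
    return bool(stat > crit)
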