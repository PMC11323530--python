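"""Trial layout and per-cluster design matrices for cross-sectional stepped-wedge designs.

A stepped-wedge cluster randomized trial (SW-CRT) enrolls ``I`` clusters over
``J`` periods.  Every cluster starts in the control condition and crosses over
to the intervention at a staggered step, never crossing back; by the final
period all clusters are treated.  In the *cross-sectional* variant a fresh
sample of ``m`` individuals is observed in each cluster at each period.

The marginal mean model for the binary outcome of individual ``k`` in cluster
``i`` at period ``j`` is the logistic regression

    logit(mu_ijk) = theta0 + gamma_j + theta1*W_ij + theta2*X_ijk
                    + theta3*W_ij*X_ijk

where ``W_ij`` is the treatment indicator, ``X_ijk`` a binary individual
covariate (e.g. minority race), ``theta1`` the overall treatment effect (OTE)
and ``theta3`` the treatment-by-covariate interaction, i.e. the heterogeneity
of treatment effect (HTE).  ``gamma_1 = 0`` for identification, leaving
``J + 3`` free coefficients.

Design-matrix column order is ``[intercept, gamma_2..gamma_J, W, X, W*X]``:
the HTE coefficient is always the last column, so its variance is the
``(J+3, J+3)`` element of any coefficient covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit


class ConfigurationError(ValueError):
    """An inconsistent or inadmissible design configuration."""


class DegenerateCovariateError(ConfigurationError):
    """The covariate allocation leaves one covariate level empty."""


def covariate_count(m: int, p_x: float) -> int:
    """Number of individuals with ``X = 1`` in a cluster-period.

    Deterministic allocation: ``round(m * p_x)`` with halves rounded away
    from zero.  Both covariate levels must be present.
    """
    n1 = int(np.floor(m * p_x + 0.5))
    if n1 <= 0 or n1 >= m:
        raise DegenerateCovariateError(
            f"round(m * p_x) = {n1} with m = {m}: both covariate levels "
            "must be present in every cluster-period"
        )
    return n1


def default_size_step(p_x: float, cap: int = 50) -> int:
    """Smallest grid step s such that s * p_x is an integer (capped).

    Keeps the per-period covariate count exact along a cluster-size search:
    10 for 30% prevalence, 2 for 50%, 3 for 1/3.  Falls back to 1 when no
    step below ``cap`` achieves integrality.
    """
    frac = Fraction(p_x).limit_denominator(10_000)
    if abs(float(frac) - p_x) > 1e-9:
        return 1
    return frac.denominator if frac.denominator <= cap else 1


@dataclass(frozen=True)
class DesignSpec:
    """Complete configuration of a stepped-wedge HTE power analysis.

    Coefficients are on the log-odds scale.  ``theta3`` doubles as the
    alternative-hypothesis effect size delta for power calculations.
    ``icc`` (alpha) is the within-period intraclass correlation; ``cac``
    (rho) is the cluster autocorrelation, the ratio of between-period to
    within-period correlation.  ``cac = 1`` gives the simple exchangeable
    structure.
    """

    n_clusters: int
    n_periods: int
    cluster_size: int
    theta0: float
    gammas: tuple[float, ...]
    theta1: float
    theta2: float
    theta3: float
    prevalence: float
    icc: float
    cac: float = 1.0
    sig_level: float = 0.05
    test: Literal["wald_z", "wald_t"] = "wald_z"
    t_df: int | None = None

    def __post_init__(self):
        errors = []
        if self.n_periods < 2:
            errors.append(f"n_periods must be >= 2, got {self.n_periods}")
        if self.n_clusters < 1:
            errors.append(f"n_clusters must be positive, got {self.n_clusters}")
        elif self.n_periods >= 2 and self.n_clusters % (self.n_periods - 1) != 0:
            errors.append(
                f"n_clusters = {self.n_clusters} is not divisible by "
                f"n_periods - 1 = {self.n_periods - 1}: the balanced "
                "crossover schedule needs equal-size steps"
            )
        if self.cluster_size < 2:
            errors.append(f"cluster_size must be >= 2, got {self.cluster_size}")
        if len(self.gammas) != self.n_periods:
            errors.append(
                f"gammas has length {len(self.gammas)}, expected "
                f"n_periods = {self.n_periods}"
            )
        elif self.gammas[0] != 0.0:
            errors.append(f"gamma_1 must be 0 for identification, got {self.gammas[0]}")
        if not 0.0 < self.prevalence < 1.0:
            errors.append(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not -1.0 < self.icc < 1.0:
            errors.append(f"icc must be in (-1, 1), got {self.icc}")
        if not -1.0 <= self.cac <= 1.0:
            errors.append(f"cac must be in [-1, 1], got {self.cac}")
        if not 0.0 < self.sig_level < 1.0:
            errors.append(f"sig_level must be in (0, 1), got {self.sig_level}")
        if self.test not in ("wald_z", "wald_t"):
            errors.append(f"test must be 'wald_z' or 'wald_t', got {self.test!r}")
        if self.t_df is not None and self.t_df < 1:
            errors.append(f"t_df must be a positive integer, got {self.t_df}")
        if errors:
            raise ConfigurationError("; ".join(errors))
        object.__setattr__(self, "gammas", tuple(float(g) for g in self.gammas))
        # fail early on both degenerate allocation and an inadmissible
        # correlation structure (eigenvalue check lives with the structure)
        covariate_count(self.cluster_size, self.prevalence)
        from .correlation import check_admissible

        check_admissible(self.n_periods, self.cluster_size, self.icc, self.cac)

    @property
    def n_params(self) -> int:
        """Number of free coefficients, J + 3."""
        return self.n_periods + 3

    @property
    def wald_df(self) -> int:
        """Degrees of freedom for the t-based Wald test (default I - 4)."""
        return self.t_df if self.t_df is not None else self.n_clusters - 4

    def with_(self, **changes) -> "DesignSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class DesignLayout:
    """Treatment schedule and deterministic covariate allocation.

    ``W`` is the I x J binary treatment matrix (rows non-decreasing).
    ``x`` is the length-(J*m) covariate vector of one cluster-period-major
    stack; under the balanced design it is shared by all clusters, with the
    ``X = 1`` block placed last within each period.
    """

    W: np.ndarray
    x: np.ndarray
    n_x1: int


def build_layout(spec: DesignSpec) -> DesignLayout:
    """Balanced uni-directional crossover schedule plus covariate allocation.

    Clusters are split into ``J - 1`` equal blocks; block ``b`` (0-based)
    receives the intervention from period ``b + 2`` (1-based) onward, so the
    first period is all-control and the last all-treated.
    """
    I, J, m = spec.n_clusters, spec.n_periods, spec.cluster_size
    per_step = I // (J - 1)
    W = np.zeros((I, J), dtype=int)
    for i in range(I):
        first_treated = (i // per_step) + 1  # 0-based period index
        W[i, first_treated:] = 1
    n1 = covariate_count(m, spec.prevalence)
    x_period = np.concatenate([np.zeros(m - n1, dtype=int), np.ones(n1, dtype=int)])
    x = np.tile(x_period, J)
    return DesignLayout(W=W, x=x, n_x1=n1)


@dataclass(frozen=True)
class DesignMatrices:
    """Per-pattern design matrices, marginal means and variance diagonals.

    Clusters sharing a crossover pattern have identical ``M_i``, ``u_i`` and
    ``A_i``; they are stored once with a multiplicity ``counts[g]``.
    ``pattern_of[i]`` maps cluster ``i`` to its pattern index.
    """

    M: tuple[np.ndarray, ...]
    u: tuple[np.ndarray, ...]
    A: tuple[np.ndarray, ...]
    counts: tuple[int, ...]
    pattern_of: tuple[int, ...]
    n_periods: int
    cluster_size: int
    hte_index: int

    @property
    def n_patterns(self) -> int:
        return len(self.M)

    @property
    def n_clusters(self) -> int:
        return sum(self.counts)

    def cluster_matrix(self, i: int) -> np.ndarray:
        return self.M[self.pattern_of[i]]

    def theta(self, spec: DesignSpec) -> np.ndarray:
        """Coefficient vector in design-matrix column order."""
        return np.concatenate(
            [
                [spec.theta0],
                spec.gammas[1:],
                [spec.theta1, spec.theta2, spec.theta3],
            ]
        )


def marginal_mean(spec: DesignSpec, period: int, treated: int, covariate: int) -> float:
    """Marginal outcome probability for a (period, treatment, covariate) cell.

    ``period`` is 1-based; returns the inverse logit of
    theta0 + gamma_j + theta1*w + theta2*x + theta3*w*x, strictly in (0, 1).
    """
    if not 1 <= period <= spec.n_periods:
        raise ValueError(f"period must be in 1..{spec.n_periods}, got {period}")
    eta = (
        spec.theta0
        + spec.gammas[period - 1]
        + spec.theta1 * treated
        + spec.theta2 * covariate
        + spec.theta3 * treated * covariate
    )
    return float(expit(eta))


def _pattern_design(
    spec: DesignSpec, w_row: np.ndarray, x: np.ndarray, include_covariate: bool
) -> tuple[np.ndarray, np.ndarray]:
    J, m = spec.n_periods, spec.cluster_size
    n = J * m
    w_long = np.repeat(w_row, m)
    period = np.repeat(np.arange(J), m)
    if include_covariate:
        p = J + 3
        M = np.zeros((n, p))
        M[:, 0] = 1.0
        for j in range(1, J):
            M[period == j, j] = 1.0
        M[:, J] = w_long
        M[:, J + 1] = x
        M[:, J + 2] = w_long * x
        eta = (
            spec.theta0
            + np.asarray(spec.gammas)[period]
            + spec.theta1 * w_long
            + spec.theta2 * x
            + spec.theta3 * w_long * x
        )
    else:
        # reduced model for overall-treatment-effect diagnostics:
        # logit(mu) = theta0 + gamma_j + theta1 * W
        p = J + 1
        M = np.zeros((n, p))
        M[:, 0] = 1.0
        for j in range(1, J):
            M[period == j, j] = 1.0
        M[:, J] = w_long
        eta = spec.theta0 + np.asarray(spec.gammas)[period] + spec.theta1 * w_long
    return M, expit(eta)


def build_design_matrices(
    spec: DesignSpec,
    layout: DesignLayout | None = None,
    include_covariate: bool = True,
) -> DesignMatrices:
    """Stack the per-individual rows into per-pattern design matrices.

    With ``include_covariate=False`` the covariate and interaction columns
    are dropped, giving the reduced model used for overall-treatment-effect
    operating-characteristic checks; ``hte_index`` then points at the
    treatment column instead of the interaction column.
    """
    if layout is None:
        layout = build_layout(spec)
    pattern_keys: dict[bytes, int] = {}
    Ms, us, As, counts, pattern_of = [], [], [], [], []
    for i in range(spec.n_clusters):
        key = layout.W[i].tobytes()
        if key not in pattern_keys:
            M, u = _pattern_design(spec, layout.W[i], layout.x, include_covariate)
            pattern_keys[key] = len(Ms)
            Ms.append(M)
            us.append(u)
            As.append(u * (1.0 - u))
            counts.append(0)
        g = pattern_keys[key]
        counts[g] += 1
        pattern_of.append(g)
    hte_index = (spec.n_periods + 2) if include_covariate else spec.n_periods
    return DesignMatrices(
        M=tuple(Ms),
        u=tuple(us),
        A=tuple(As),
        counts=tuple(counts),
        pattern_of=tuple(pattern_of),
        n_periods=spec.n_periods,
        cluster_size=spec.cluster_size,
        hte_index=hte_index,
    )
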