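"""Wald-test power and design search for the interaction effect.

Power of the two-tailed Wald test of H0: theta3 = 0 against theta3 = delta,
given the predicted variance of the interaction estimator, is the full
two-sided rejection probability

    power = Phi( d - q ) + Phi( -d - q ),    d = delta / sqrt(Var(theta3_hat))

with Phi and q the standard-normal CDF and (1 - a/2) quantile, or their
Student-t counterparts (default df = I - 4: eight clusters minus the four
cluster-level coefficients theta0..theta3) for designs with few clusters.
The second term is negligible for the z test but contributes about half a
percentage point under a t with 4 df, and is required to reproduce printed
reference powers; a one-tailed variant is available via ``tails=1``.

The search helpers invert this relationship for the cluster size m, the
number of clusters I, or the minimal detectable interaction odds ratio.  In
every search the design variance is recomputed at each candidate (the
marginal means, hence the information, depend on m, I and theta3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .design import ConfigurationError, DesignSpec, covariate_count, default_size_step
from .variance import Method, design_variance


class SearchCeilingError(RuntimeError):
    """Target power not achievable below the configured search ceiling."""


@dataclass(frozen=True)
class PowerResult:
    power: float
    method: str
    spec: DesignSpec
    var_hte: float


def power_wald(
    delta: float,
    var_hte: float,
    sig_level: float = 0.05,
    test: Literal["wald_z", "wald_t"] = "wald_z",
    t_df: int | None = None,
    tails: int = 2,
) -> float:
    """Rejection probability of the two-tailed Wald test at effect ``delta``."""
    if var_hte <= 0:
        raise ValueError(f"var_hte must be positive, got {var_hte}")
    d = delta / math.sqrt(var_hte)
    if test == "wald_t":
        if t_df is None:
            raise ValueError("t_df is required for the wald_t test")
        dist = stats.t(t_df)
    elif test == "wald_z":
        dist = stats.norm
    else:
        raise ValueError(f"test must be 'wald_z' or 'wald_t', got {test!r}")
    q = dist.ppf(1.0 - sig_level / 2.0)
    p = dist.cdf(d - q)
    if tails == 2:
        p += dist.cdf(-d - q)
    elif tails != 1:
        raise ValueError("tails must be 1 or 2")
    return float(p)


def hte_power(spec: DesignSpec, method: Method = "gee", tails: int = 2) -> PowerResult:
    """Predicted power to detect the interaction effect of ``spec.theta3``."""
    report = design_variance(spec, method)
    p = power_wald(
        spec.theta3,
        report.var_hte,
        sig_level=spec.sig_level,
        test=spec.test,
        t_df=spec.wald_df if spec.test == "wald_t" else None,
        tails=tails,
    )
    return PowerResult(power=p, method=report.method, spec=spec, var_hte=report.var_hte)


def find_cluster_size(
    spec: DesignSpec,
    target_power: float = 0.8,
    method: Method = "gee",
    step: int | None = None,
    m_max: int = 10_000,
    tails: int = 2,
) -> tuple[int, float]:
    """Smallest cluster size on the grid {step, 2*step, ...} reaching the target.

    The default step is the smallest integer making ``m * prevalence``
    integral (10 for 30% prevalence, 2 for 50%, 3 for 1/3), so the
    deterministic covariate allocation stays exact along the grid.  Returns
    ``(m, predicted_power_at_m)``.
    """
    if step is None:
        step = default_size_step(spec.prevalence)
    m = step
    while m <= m_max:
        try:
            candidate = spec.with_(cluster_size=m)
        except ConfigurationError:
            m += step
            continue
        p = hte_power(candidate, method, tails=tails).power
        if p >= target_power:
            return m, p
        m += step
    raise SearchCeilingError(
        f"target power {target_power} not reached by m = {m - step} "
        f"(power {p:.4f}); raise m_max or weaken the design goal"
    )


def find_number_of_clusters(
    spec: DesignSpec,
    target_power: float = 0.8,
    method: Method = "gee",
    candidates: list[int] | None = None,
    max_clusters: int = 1_000,
    tails: int = 2,
) -> tuple[int, float]:
    """Smallest admissible number of clusters reaching the target power.

    Candidates default to multiples of J - 1 (the balanced-schedule
    constraint) up to ``max_clusters``.
    """
    if candidates is None:
        s = spec.n_periods - 1
        candidates = list(range(s, max_clusters + 1, s))
    last = None
    for I in sorted(candidates):
        candidate = spec.with_(n_clusters=I)
        last = hte_power(candidate, method, tails=tails).power
        if last >= target_power:
            return I, last
    raise SearchCeilingError(
        f"target power {target_power} not reached by I = {max(candidates)} "
        f"(power {last:.4f})"
    )


def find_min_detectable_hte(
    spec: DesignSpec,
    target_power: float = 0.8,
    method: Method = "gee",
    resolution: float = 0.01,
    or_max: float = 100.0,
    tails: int = 2,
) -> tuple[float, float]:
    """Smallest interaction odds ratio (at the given resolution) with
    predicted power >= target at the fixed design.

    The design variance is re-evaluated at every candidate effect size:
    theta3 shifts the marginal means of the treated-covariate cell, so the
    information is not constant along the search.  Bisection on the
    log-odds-ratio, then the crossing is rounded up to the resolution grid.
    Returns ``(odds_ratio, predicted_power_at_it)``.
    """

    def power_at(or_value: float) -> float:
        candidate = spec.with_(theta3=math.log(or_value))
        return hte_power(candidate, method, tails=tails).power

    lo, hi = 1.0, or_max
    if power_at(hi) < target_power:
        raise SearchCeilingError(
            f"target power {target_power} not reachable below OR = {or_max} "
            f"(power {power_at(hi):.4f} at the ceiling)"
        )
    if power_at(lo) >= target_power:
        return lo, power_at(lo)
    while hi - lo > resolution / 4.0:
        mid = math.sqrt(lo * hi) if hi / lo > 4 else 0.5 * (lo + hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    mde = math.ceil(hi / resolution - 1e-9) * resolution
    return round(mde, 10), power_at(mde)
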