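"""Replicate-level simulation of operating characteristics.

Each replicate draws correlated binary outcomes from the Gaussian-copula
generator, fits the marginal model by GEE, and applies the two-sided Wald
test to the coefficient of interest.  Aggregated over replicates this gives
the empirical type-I error psi0 (when the true effect is zero) or the
simulated power phi0 (otherwise), together with the bias of the chosen
standard-error estimator against the empirical spread of the estimates.

Seeding contract: the root seed is expanded through ``numpy``'s
``SeedSequence`` into one independent substream per replicate, so results
are reproducible and independent of any parallel execution order.
Non-converged or separated replicates are excluded from denominators and
reported as a count.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copula import OutcomeSimulator
from .design import DesignSpec, build_design_matrices
from .gee import fit_gee, wald_test_hte
from .power import hte_power
from .variance import design_variance


@dataclass
class SimulationResult:
    """Aggregated operating characteristics of one simulation experiment."""

    rejection_rate: float
    is_null: bool
    n_reps: int
    n_excluded: int
    se_choice: str
    mc_stderr: float
    delta_se: float  # mean(estimated SE) - empirical SD of the target estimate
    mean_estimate: float
    empirical_sd: float
    mean_se: float
    mean_alpha_hat: float
    mean_rho_hat: float
    seed: int
    target: str = "hte"

    @property
    def psi0(self) -> float | None:
        """Empirical type-I error (only defined for null experiments)."""
        return self.rejection_rate if self.is_null else None

    @property
    def phi0(self) -> float | None:
        """Simulated power (only defined for non-null experiments)."""
        return None if self.is_null else self.rejection_rate


def run_operating_characteristics(
    spec: DesignSpec,
    theta3_true: float | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    se_choice: str = "naive",
    working: str | None = None,
    test: str = "wald_z",
    target: str = "hte",
) -> SimulationResult:
    """Estimate psi0 / phi0 for a design by Monte-Carlo simulation.

    ``theta3_true`` overrides the interaction effect used to *generate* the
    data (0 gives the null experiment); the fitted model is always the full
    interaction model when ``target='hte'``.  With ``target='ote'`` the
    reduced model logit(mu) = theta0 + gamma_j + theta1*W is generated and
    fitted, and the test targets the treatment coefficient instead — the
    covariate plays no role.
    ``working`` defaults to 'simple' when the design CAC is 1, else 'nested'.
    """
    if target not in ("hte", "ote"):
        raise ValueError("target must be 'hte' or 'ote'")
    if theta3_true is not None:
        spec = spec.with_(theta3=float(theta3_true))
    if working is None:
        working = "simple" if spec.cac == 1.0 else "nested"
    include_covariate = target == "hte"
    matrices = build_design_matrices(spec, include_covariate=include_covariate)
    # in OTE mode both generation and fitting use the reduced mean model
    sim = OutcomeSimulator(spec) if include_covariate else _reduced_simulator(spec)
    is_null = (spec.theta3 == 0.0) if target == "hte" else (spec.theta1 == 0.0)

    t_df = spec.wald_df if test == "wald_t" else None
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    rejections = 0
    estimates, ses, alphas, rhos = [], [], [], []
    n_excluded = 0
    for child in children:
        rng = np.random.default_rng(child)
        Y = sim.sample(rng)
        fit = fit_gee(Y, matrices, working=working,
                      compute_corrected=se_choice in ("kc", "md"))
        if not fit.converged:
            n_excluded += 1
            continue
        if wald_test_hte(fit, se_choice=se_choice, sig_level=spec.sig_level,
                         test=test, t_df=t_df):
            rejections += 1
        estimates.append(float(fit.theta_hat[fit.hte_index]))
        ses.append(fit.hte_se(se_choice))
        alphas.append(fit.alpha_hat)
        rhos.append(fit.rho_hat)
    n_eff = n_reps - n_excluded
    if n_eff == 0:
        raise RuntimeError("all replicates failed to converge")
    rate = rejections / n_eff
    emp_sd = float(np.std(estimates, ddof=1)) if n_eff > 1 else 0.0
    mean_se = float(np.mean(ses))
    return SimulationResult(
        rejection_rate=rate,
        is_null=is_null,
        n_reps=n_reps,
        n_excluded=n_excluded,
        se_choice=se_choice,
        mc_stderr=float(np.sqrt(rate * (1 - rate) / n_eff)),
        delta_se=mean_se - emp_sd,
        mean_estimate=float(np.mean(estimates)),
        empirical_sd=emp_sd,
        mean_se=mean_se,
        mean_alpha_hat=float(np.mean(alphas)),
        mean_rho_hat=float(np.mean(rhos)),
        seed=seed,
        target=target,
    )


def _reduced_simulator(spec: DesignSpec) -> OutcomeSimulator:
    """Copula simulator whose marginal means follow the reduced (no
    covariate) model; implemented by zeroing the covariate coefficients."""
    reduced = spec.with_(theta2=0.0, theta3=0.0)
    return OutcomeSimulator(reduced)


# ---------------------------------------------------------------------------
# table reproduction


_TABLE1_GAMMAS = (0.0, 0.1, 0.2, 0.3, 0.4)


def _reference_spec(**overrides) -> DesignSpec:
    """The simulation-study base design: 8 clusters, 5 periods, 15% control
    outcome prevalence, increasing secular trend."""
    base = dict(
        n_clusters=8,
        n_periods=5,
        cluster_size=20,
        theta0=float(np.log(0.15 / 0.85)),
        gammas=_TABLE1_GAMMAS,
        theta1=float(np.log(1.68)),
        theta2=float(np.log(1.5)),
        theta3=float(np.log(1.5)),
        prevalence=0.5,
        icc=0.1,
        cac=1.0,
    )
    base.update(overrides)
    return DesignSpec(**base)


def predicted_power_grid(
    n_clusters: int = 8,
    cac: float = 1.0,
    cluster_sizes: tuple[int, ...] = (20, 40, 60, 80, 100, 120),
    hte_values: tuple[float, ...] = (np.log(1.5), np.log(2.0)),
    **spec_overrides,
) -> pd.DataFrame:
    """Analytic predicted-power grid over cluster sizes, effects and methods."""
    rows = []
    for th3 in hte_values:
        for method in ("gee", "kc", "md"):
            row = {"hte_or": float(np.exp(th3)), "method": method.upper()}
            for m in cluster_sizes:
                spec = _reference_spec(
                    n_clusters=n_clusters, cac=cac, cluster_size=m, theta3=float(th3),
                    **spec_overrides,
                )
                row[f"m={m}"] = round(hte_power(spec, method).power, 3)
            rows.append(row)
    return pd.DataFrame(rows)


def required_size_table(cac: float = 1.0, target_power: float = 0.8) -> pd.DataFrame:
    """Required cluster sizes (and the power achieved) across the design grid.

    Grid steps follow the integer-allocation convention: multiples of 10 at
    30% covariate prevalence, even sizes at 50%.
    """
    from .power import find_cluster_size

    rows = []
    for th1 in (np.log(1.35), np.log(1.68)):
        for th3 in (np.log(1.5), np.log(2.0)):
            for prev in (0.3, 0.5):
                for method in ("gee", "kc", "md"):
                    spec = _reference_spec(
                        theta1=float(th1), theta3=float(th3),
                        prevalence=prev, cac=cac,
                    )
                    m, p = find_cluster_size(spec, target_power, method)
                    rows.append(
                        {
                            "ote_or": round(float(np.exp(th1)), 2),
                            "hte_or": round(float(np.exp(th3)), 2),
                            "prevalence": prev,
                            "method": method.upper(),
                            "cluster_size": m,
                            "predicted_power": round(p, 3),
                        }
                    )
    return pd.DataFrame(rows)


def type_one_error_table(
    n_reps: int = 1000, seed: int = 0, cluster_size: int = 40
) -> pd.DataFrame:
    """Empirical type-I error of the naive-SE Wald test under null effects.

    Reproduces the diagnostic layout: data generated from the reduced
    secular-trend-only model for the treatment-effect columns and from the
    covariate-adjusted model for the interaction columns, across
    (ICC, CAC) combinations.
    """
    rows = []
    for rho in (1.0, 0.5):
        row = {"cac": rho}
        for alpha in (0.1, 0.05):
            spec = _reference_spec(
                cluster_size=cluster_size, icc=alpha, cac=rho,
                theta1=0.0, theta2=0.0, theta3=0.0,
            )
            res = run_operating_characteristics(
                spec, n_reps=n_reps, seed=seed, target="ote", working="nested",
            )
            row[f"ote_null_icc={alpha}"] = round(res.rejection_rate, 3)
            spec_h = _reference_spec(
                cluster_size=cluster_size, icc=alpha, cac=rho,
                theta1=float(np.log(1.68)), theta2=float(np.log(1.5)), theta3=0.0,
            )
            res_h = run_operating_characteristics(
                spec_h, n_reps=n_reps, seed=seed + 1, target="hte", working="nested",
            )
            row[f"hte_null_icc={alpha}"] = round(res_h.rejection_rate, 3)
        rows.append(row)
    return pd.DataFrame(rows)


TABLE_BUILDERS = {
    "6": lambda reps, seed: predicted_power_grid(n_clusters=8, cac=1.0),
    "7": lambda reps, seed: predicted_power_grid(n_clusters=8, cac=0.8),
    "8": lambda reps, seed: predicted_power_grid(n_clusters=20, cac=1.0),
    "9": lambda reps, seed: predicted_power_grid(n_clusters=20, cac=0.8),
    "10": lambda reps, seed: predicted_power_grid(n_clusters=40, cac=1.0),
    "11": lambda reps, seed: predicted_power_grid(n_clusters=40, cac=0.8),
    "2": lambda reps, seed: required_size_table(cac=1.0),
    "3": lambda reps, seed: required_size_table(cac=0.8),
    "14": lambda reps, seed: type_one_error_table(n_reps=reps, seed=seed),
}


def reproduce_table(table_id: str, n_reps: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Rebuild one of the reference comparison tables as a DataFrame.

    Analytic tables (2, 3, 6-11) ignore ``n_reps``; table 14 runs the null
    simulations.  Deterministic given ``seed``.
    """
    key = str(table_id)
    if key not in TABLE_BUILDERS:
        raise KeyError(
            f"unknown table id {table_id!r}; supported: {sorted(TABLE_BUILDERS)}"
        )
    return TABLE_BUILDERS[key](n_reps, seed)


def table_to_csv(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()
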