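"""Power analysis for the G x SES interaction term.

Two calculations:

* **Analytic minimum detectable incremental R²** — the smallest increment in
  explained variance from adding the (1-df) interaction term to the fully
  interacted model that an incremental F-test detects at level ``alpha``
  with the target power.  Under the linear model the F statistic for adding
  one regressor is F(1, n - k_full - 1) with noncentrality
  lambda = n * dR2 / (1 - R2_full), where R2_full = r2_base + dR2; the
  minimum dR2 is found by root-finding on that power curve (tolerance 1e-10).

* **Monte-Carlo post-hoc power** — simulate full cohorts under a scenario,
  run the complete chain (generate -> sample -> formula -> fit) and report
  the rejection rate of the focal interaction at level ``alpha``, with its
  binomial Monte-Carlo standard error.  Post-hoc power computed from
  *assumed generating* effect sizes is reported as such; observed-effect
  post-hoc power is known to be uninformative and is not offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .config import BINARY_OUTCOMES, CohortConfig
from .cohort import simulate_cohort
from .estimate import (
    SingularityError,
    StratumError,
    diff_stratified,
    fit_linear_clustered,
    fit_stratified_fe,
)
from .formulas import expand_baseline, expand_interacted
from .multiplicity import InstabilityError
from .samples import build_between, build_trio, build_within

__all__ = ["PowerResult", "min_detectable_delta_r2", "monte_carlo_power",
           "InfeasibleError"]


class InfeasibleError(ValueError):
    """Sample too small for the requested model/power."""


@dataclass
class PowerResult:
    mode: str  # "analytic" | "monte-carlo"
    n: int
    k_full: int
    alpha: float
    power: float  # target (analytic) or estimate (MC)
    min_delta_r2: float | None = None
    mc_se: float | None = None
    reps: int | None = None
    n_failed: int = 0
    seed: int | None = None
    note: str = ""


def ncf_power(delta_r2: float, n: int, k_full: int, alpha: float,
              r2_base: float = 0.0) -> float:
    """Power of the 1-df incremental F-test at incremental R² ``delta_r2``."""
    df2 = n - k_full - 1
    r2_full = r2_base + delta_r2
    if not 0 <= r2_full < 1:
        return 1.0
    lam = n * delta_r2 / (1.0 - r2_full)
    fcrit = stats.f.isf(alpha, 1, df2)
    return float(stats.ncf.sf(fcrit, 1, df2, lam))


def min_detectable_delta_r2(
    n: int,
    k_full: int,
    alpha: float = 0.05,
    power: float = 0.8,
    r2_base: float = 0.0,
) -> PowerResult:
    """Smallest incremental R² detectable by the 1-df F-test at the target
    power, via root-finding on the noncentral-F power curve."""
    if n <= k_full + 1:
        raise InfeasibleError(
            f"n={n} too small for a model with {k_full} slopes"
        )
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0,1)")
    if power <= alpha:
        return PowerResult("analytic", n, k_full, alpha, power, min_delta_r2=0.0)

    hi = 1.0 - r2_base - 1e-12
    f = lambda d: ncf_power(d, n, k_full, alpha, r2_base) - power
    if f(hi) < 0:
        raise InfeasibleError(
            f"target power {power} unattainable at n={n}, k_full={k_full}"
        )
    root = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    return PowerResult(
        "analytic", n, k_full, alpha, power, min_delta_r2=float(root)
    )


def _fit_cell(cohort, design: str, outcome: str, focal_pgi: str, seed: int):
    """One grid cell: interaction estimate, se, p.  Between/trio use the
    fully interacted model's focal x SES term; within uses the stratified
    FE slope difference."""
    focal = f"pgi_{focal_pgi}"
    if design == "within":
        sample = build_within(cohort, outcome, seed)
        formula = expand_baseline("within", outcome)
        hi = fit_stratified_fe(sample, formula, 1)
        lo = fit_stratified_fe(sample, formula, 0)
        d = diff_stratified(hi, lo, focal)
        return d.diff, d.se_diff, d.p, sample, formula, None
    build = build_between if design == "between" else build_trio
    sample = build(cohort, outcome, seed)
    formula = expand_interacted(design, outcome, focal_pgi)
    fit = fit_linear_clustered(sample, formula)
    term = f"{focal}:ses"
    return (
        float(fit.params[term]),
        float(fit.se[term]),
        float(fit.pvalues[term]),
        sample,
        formula,
        fit,
    )


def monte_carlo_power(
    config: CohortConfig,
    design: str,
    outcome: str,
    focal_pgi: str,
    reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo rejection rate of the focal G x SES interaction under the
    scenario's generating effects, running the full pipeline per replicate."""
    if reps < 50:
        raise ValueError(f"reps must be >= 50, got {reps}")
    rng = np.random.default_rng([int(seed) % (2**31), 41])
    rejections = 0
    n_failed = 0
    n_used = []
    k_full = None
    for r in range(reps):
        rep_seed = int(rng.integers(2**31 - 1))
        cfg = config.replace(seed=rep_seed)
        try:
            cohort = simulate_cohort(cfg, check_mendelian=False)
            est, se, p, sample, formula, _ = _fit_cell(
                cohort, design, outcome, focal_pgi, rep_seed
            )
        except (SingularityError, StratumError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > 0.1 * reps:
                raise InstabilityError(
                    f"more than 10% of replicates failed ({n_failed}/{r + 1})"
                )
            continue
        n_used.append(sample.n_obs)
        if p < alpha:
            rejections += 1
    n_ok = reps - n_failed
    rate = rejections / n_ok
    mc_se = float(np.sqrt(rate * (1 - rate) / n_ok))
    return PowerResult(
        mode="monte-carlo",
        n=int(np.mean(n_used)) if n_used else 0,
        k_full=-1,
        alpha=alpha,
        power=rate,
        mc_se=mc_se,
        reps=n_ok,
        n_failed=n_failed,
        seed=seed,
        note="power computed from generating (assumed) effect sizes",
    )
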