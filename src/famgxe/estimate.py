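"""Estimators with family-clustered sandwich covariance.

All designs are fitted by least squares (OLS for continuous outcomes, linear
probability models for binary ones) or, as a robustness variant, logistic
regression.  Standard errors are clustered by family using the CR1
small-sample factor G/(G-1) * (N-1)/(N-K) and t-tests on G-1 degrees of
freedom, where G is the number of family clusters — the de-facto convention
of the applied family-data literature.  The within-family design is fitted
by family-demeaning (equivalent to least squares with one dummy per family),
and SES-stratified fits yield high-minus-low slope differences with
se_diff^2 = se_high^2 + se_low^2.

Collinear design-matrix columns are dropped greedily in term order and
logged; regressors that are constant within every family are reported
inestimable in the fixed-effects design (family-constant terms, like SES,
cannot be identified there by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .formulas import ModelFormula, build_design_matrix

__all__ = [
    "FitResult",
    "SlopeDifference",
    "fit_linear_clustered",
    "fit_fe_clustered",
    "fit_stratified_fe",
    "diff_stratified",
    "fit_logit_clustered",
    "SingularityError",
    "ContractError",
    "StratumError",
    "DivergenceError",
]

_COLLIN_TOL = 1e-8


class SingularityError(np.linalg.LinAlgError):
    """Design matrix rank-deficient after permitted drops."""


class ContractError(ValueError):
    """A model/estimator combination that is invalid by construction."""


class StratumError(ValueError):
    """An SES stratum too small to fit."""


class DivergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. perfect separation)."""


@dataclass
class FitResult:
    """Coefficients and family-clustered inference for one fitted model."""

    formula: ModelFormula
    estimator: str  # "ols" | "lpm" | "fe" | "logit"
    params: pd.Series
    vcov: pd.DataFrame
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df: int
    n_obs: int
    n_clusters: int
    dropped: list = field(default_factory=list)
    inestimable: list = field(default_factory=list)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df)
        return pd.DataFrame(
            {"low": self.params - q * self.se, "high": self.params + q * self.se}
        )

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "design": self.formula.design,
                "outcome": self.formula.outcome,
                "focal_pgi": self.formula.focal_pgi,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.se.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "n": self.n_obs,
                "n_clusters": self.n_clusters,
            }
        )


@dataclass
class SlopeDifference:
    """High-SES minus low-SES slope for one term, from stratified FE fits."""

    term: str
    diff: float
    se_diff: float
    ci: tuple[float, float]
    p: float


def _rows_of(sample) -> pd.DataFrame:
    return sample.rows if hasattr(sample, "rows") else sample


def drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right rank filter: keep each column only if it adds
    rank (relative tolerance 1e-8).  Earlier terms take precedence."""
    arr = X.to_numpy(dtype=float)
    n, k = arr.shape
    keep: list[int] = []
    basis = np.empty((n, 0))
    for j in range(k):
        v = arr[:, j]
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        r = v - basis @ (basis.T @ v)
        # re-orthogonalise once for numerical safety
        r = r - basis @ (basis.T @ r)
        if np.linalg.norm(r) > _COLLIN_TOL * nv:
            keep.append(j)
            basis = np.column_stack([basis, r / np.linalg.norm(r)])
    dropped = [X.columns[j] for j in range(k) if j not in keep]
    return X.iloc[:, keep], dropped


def _clustered_sm_fit(model, groups, formula, estimator, dropped, inestimable=None):
    res = model.fit() if estimator != "logit" else model.fit(disp=0, maxiter=200)
    if estimator == "logit" and not res.mle_retvals.get("converged", True):
        raise DivergenceError(
            "logistic fit did not converge (possible perfect separation)"
        )
    res = model.fit(
        cov_type="cluster",
        cov_kwds={"groups": np.asarray(groups)},
        use_t=True,
        **({"disp": 0, "start_params": res.params} if estimator == "logit" else {}),
    )
    G = int(pd.unique(np.asarray(groups)).size)
    params = pd.Series(res.params, index=model.exog_names)
    vcov = pd.DataFrame(
        res.cov_params(), index=model.exog_names, columns=model.exog_names
    )
    se = pd.Series(np.sqrt(np.diag(vcov)), index=params.index)
    t = params / se
    p = pd.Series(2 * stats.t.sf(np.abs(t), G - 1), index=params.index)
    return FitResult(
        formula=formula,
        estimator=estimator,
        params=params,
        vcov=vcov,
        se=se,
        tvalues=t,
        pvalues=p,
        df=G - 1,
        n_obs=int(model.exog.shape[0]),
        n_clusters=G,
        dropped=list(dropped),
        inestimable=list(inestimable or []),
    )


def fit_linear_clustered(sample, formula: ModelFormula) -> FitResult:
    """OLS / linear probability model with family-clustered covariance."""
    rows = _rows_of(sample)
    if formula.has_family_fe:
        return fit_fe_clustered(sample, formula)
    y = rows[formula.outcome].to_numpy(dtype=float)
    X = build_design_matrix(formula, rows)
    X, dropped = drop_collinear(X)
    if X.shape[1] == 0 or np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularityError(
            f"design matrix rank-deficient; aliased terms: {dropped}"
        )
    estimator = "lpm" if set(np.unique(y)) <= {0.0, 1.0} else "ols"
    model = sm.OLS(y, X.to_numpy())
    model.exog_names[:] = list(X.columns)
    return _clustered_sm_fit(model, rows["family_id"], formula, estimator, dropped)


def fit_fe_clustered(sample, formula: ModelFormula) -> FitResult:
    """Family fixed effects by within-family demeaning, clustered by family.

    Regressors that are constant within every family (e.g. SES) cannot be
    estimated by design; a formula containing an SES main term is rejected
    outright, and any other family-constant column is dropped and reported
    in ``inestimable``.
    """
    rows = _rows_of(sample)
    if any(t.kind == "main" and t.vars == ("ses",) for t in formula.terms):
        raise ContractError(
            "SES is family-constant: its main effect cannot be estimated in the "
            "within-family design"
        )
    y = rows[formula.outcome].to_numpy(dtype=float)
    X = build_design_matrix(formula, rows, add_intercept=False)
    fam = rows["family_id"].to_numpy()
    _, pos = np.unique(fam, return_inverse=True)

    def demean(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        cnt = np.bincount(pos)
        if a.ndim == 1:
            means = np.bincount(pos, weights=a) / cnt
            return a - means[pos]
        out = np.empty_like(a)
        for j in range(a.shape[1]):
            means = np.bincount(pos, weights=a[:, j]) / cnt
            out[:, j] = a[:, j] - means[pos]
        return out

    Xd = pd.DataFrame(demean(X.to_numpy()), columns=X.columns, index=X.index)
    scale = X.to_numpy().std(axis=0)
    scale[scale == 0] = 1.0
    inest = [
        c
        for c, s in zip(X.columns, (np.abs(Xd.to_numpy()).max(axis=0) / scale))
        if s < 1e-10
    ]
    Xd = Xd.drop(columns=inest)
    if Xd.shape[1] == 0:
        raise SingularityError("no within-family variation in any regressor")
    Xd, dropped = drop_collinear(Xd)
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        raise SingularityError(f"rank-deficient after demeaning; aliased: {dropped}")
    if dropped:
        # zero within-family variance already handled; residual collinearity
        # (e.g. MZ pairs making both PGIs proportional) is a hard error
        raise SingularityError(
            f"collinear after family demeaning; aliased terms: {dropped}"
        )
    yd = demean(y)
    model = sm.OLS(yd, Xd.to_numpy())
    model.exog_names[:] = list(Xd.columns)
    return _clustered_sm_fit(
        model, fam, formula, "fe", dropped, inestimable=inest
    )


def fit_stratified_fe(sample, formula: ModelFormula, ses_stratum: int) -> FitResult:
    """Family-FE fit restricted to one SES stratum (SES is family-constant,
    so strata partition whole families)."""
    rows = _rows_of(sample)
    sub = rows[rows["ses"] == float(ses_stratum)]
    if sub["family_id"].nunique() < 2:
        raise StratumError(
            f"SES stratum {ses_stratum} has fewer than 2 families"
        )
    return fit_fe_clustered(sub.reset_index(drop=True), formula)


def diff_stratified(high: FitResult, low: FitResult, term: str) -> SlopeDifference:
    """High-SES minus low-SES slope difference for one term, with
    se_diff^2 = se_high^2 + se_low^2 (independent strata).  Inference uses a
    t reference with the smaller stratum's cluster degrees of freedom — a
    conservative convention for the unequal-variance difference."""
    d = float(high.params[term] - low.params[term])
    se = float(np.sqrt(high.se[term] ** 2 + low.se[term] ** 2))
    df = min(high.df, low.df)
    t = d / se if se > 0 else np.nan
    p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else np.nan
    q = stats.t.ppf(0.975, df)
    return SlopeDifference(term, d, se, (d - q * se, d + q * se), p)


def fit_logit_clustered(sample, formula: ModelFormula) -> FitResult:
    """Maximum-likelihood logit with family-clustered sandwich covariance
    (robustness variant for the binary outcomes)."""
    rows = _rows_of(sample)
    y = rows[formula.outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ContractError(f"{formula.outcome} is not binary; logit undefined")
    X = build_design_matrix(formula, rows)
    X, dropped = drop_collinear(X)
    model = sm.Logit(y, X.to_numpy())
    model.exog_names[:] = list(X.columns)
    try:
        return _clustered_sm_fit(model, rows["family_id"], formula, "logit", dropped)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise DivergenceError(f"logit failed: {e}") from e


# ---------------------------------------------------------------------------
# fast numpy path (used by the bootstrap)

def cluster_ols_arrays(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    group_starts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CR1-clustered OLS on raw arrays.

    ``group_idx`` must be dense integer cluster labels in [0, n_groups).
    When rows are already sorted by cluster, ``group_starts`` (the first row
    index of each cluster) enables a faster score reduction.  Returns
    (beta, se); raises numpy.linalg.LinAlgError when X'X is singular
    (callers treat that as a resample to redo).  Matches the statsmodels
    clustered fit to numerical precision.
    """
    n, k = X.shape
    XtX = X.T @ X
    np.linalg.cholesky(XtX)  # raises LinAlgError if singular
    beta = np.linalg.solve(XtX, X.T @ y)
    u = y - X @ beta
    Xu = X * u[:, None]
    if group_starts is not None:
        S = np.add.reduceat(Xu, group_starts, axis=0)
    else:
        S = np.zeros((n_groups, k))
        np.add.at(S, group_idx, Xu)
    meat = S.T @ S
    bread = np.linalg.inv(XtX)
    c = (n_groups / (n_groups - 1)) * ((n - 1) / (n - k))
    V = c * bread @ meat @ bread
    d = np.diag(V)
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise np.linalg.LinAlgError("ill-conditioned clustered covariance")
    return beta, np.sqrt(d)
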