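"""Multiple-testing control for the 7-outcome test family of each
(PGI, design) pair.

Bonferroni: adjusted p = min(1, m p); with the conventional familywise level
0.05 and m = 7 outcomes the per-test threshold is 0.05/7 ~ 0.007.

Romano-Wolf: step-down maxT adjustment with a family-cluster pairs
bootstrap.  Families are resampled with replacement *jointly* across the
seven outcome hypotheses (each drawn family copy becomes a new cluster), so
the bootstrap preserves the cross-outcome dependence even though every
outcome has its own analytical sample.  Each hypothesis is refitted on the
resample and contributes the recentred studentised statistic
t* = (beta* - beta_hat) / se*; adjusted p-values follow the step-down max
rule with enforced monotonicity.  For the within-family design, where the
quantity of interest is the high-minus-low SES slope difference from
stratified fixed-effects fits, the bootstrap statistic is that difference
(family demeaning commutes with cluster resampling, so demeaned data are
precomputed per family).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimate import cluster_ols_arrays
from .formulas import ModelFormula, build_design_matrix
from .estimate import drop_collinear

__all__ = [
    "CorrectionResult",
    "bonferroni_adjust",
    "romano_wolf_adjust",
    "InstabilityError",
]


class InstabilityError(RuntimeError):
    """Too many singular bootstrap refits."""


@dataclass
class CorrectionResult:
    """Raw and adjusted p-values for one test family."""

    family: tuple  # e.g. (design, focal_pgi)
    outcomes: list
    p_raw: np.ndarray
    p_bonferroni: np.ndarray
    p_romano_wolf: np.ndarray | None
    alpha: float
    n_bootstrap: int | None
    seed: int | None
    n_redrawn: int = 0
    #: marginal bootstrap-t p per hypothesis (same resamples as the
    #: step-down adjustment); the like-for-like base for comparing the
    #: Romano-Wolf rejection set against a Bonferroni rule
    p_bootstrap_raw: np.ndarray | None = None

    def table(self) -> pd.DataFrame:
        m = len(self.outcomes)
        out = pd.DataFrame(
            {
                "outcome": self.outcomes,
                "p_raw": self.p_raw,
                "p_bonf": self.p_bonferroni,
                "p_rw": (
                    self.p_romano_wolf
                    if self.p_romano_wolf is not None
                    else [np.nan] * m
                ),
            }
        )
        out["sig_raw"] = out["p_raw"] < self.alpha
        out["sig_bonf"] = out["p_raw"] < self.alpha / m
        out["sig_rw"] = out["p_rw"] < self.alpha
        return out


def bonferroni_adjust(
    pvals, alpha: float = 0.05, family=("", ""), outcomes=None
) -> CorrectionResult:
    """Bonferroni adjustment for a family of m tests."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0,1], got {p}")
    m = p.size
    adj = np.minimum(1.0, m * p)
    return CorrectionResult(
        family=tuple(family),
        outcomes=list(outcomes) if outcomes is not None else list(range(m)),
        p_raw=p,
        p_bonferroni=adj,
        p_romano_wolf=None,
        alpha=alpha,
        n_bootstrap=None,
        seed=None,
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 7) -> float:
    """Per-test significance threshold alpha/m (0.05/7 ~ 0.007 for the
    seven-outcome family)."""
    return alpha / m


# ---------------------------------------------------------------------------
# Romano-Wolf step-down bootstrap


def _gather_rows(starts: np.ndarray, counts: np.ndarray, pos: np.ndarray):
    """Row indices and cluster boundaries for a multiset of family positions
    (each drawn copy becomes its own cluster).  Fully vectorised."""
    c = counts[pos]
    total = int(c.sum())
    ends = np.cumsum(c)
    idx = np.arange(total) - np.repeat(ends - c, c) + np.repeat(starts[pos], c)
    return idx, ends - c, len(pos)


class _LinearHypothesis:
    """Coefficient of one term in a clustered linear fit, refittable on a
    family resample."""

    def __init__(self, sample, formula: ModelFormula, term: str):
        rows = sample.rows.sort_values("family_id", kind="stable")
        X = build_design_matrix(formula, rows)
        X, _ = drop_collinear(X)
        if term not in X.columns:
            raise ValueError(f"focal term {term!r} not estimable in this sample")
        self.k = list(X.columns).index(term)
        self.X = np.ascontiguousarray(X.to_numpy(dtype=float))
        self.y = rows[formula.outcome].to_numpy(dtype=float)
        fams = rows["family_id"].to_numpy()
        self.fam_ids, starts = np.unique(fams, return_index=True)
        self.starts = starts.astype(np.intp)
        self.counts = np.diff(np.r_[starts, len(fams)]).astype(np.intp)
        self._pos_map = None
        self.beta, self.se = self.refit(np.arange(len(self.fam_ids)), mapped=True)
        # analytic raw p, matching the reported clustered fit (t on G-1 df)
        from scipy import stats as _st

        self.p_raw = float(
            2 * _st.t.sf(abs(self.beta / self.se), len(self.fam_ids) - 1)
        )

    def prepare(self, union: np.ndarray) -> None:
        """Map union family ids to positions in this hypothesis's sample."""
        idx = np.searchsorted(self.fam_ids, union)
        idx[idx >= len(self.fam_ids)] = 0
        ok = self.fam_ids[idx] == union
        pos = np.where(ok, idx, -1)
        self._pos_map = pos

    def refit(self, drawn: np.ndarray, mapped: bool = False) -> tuple[float, float]:
        pos = drawn if mapped else self._pos_map[drawn]
        pos = pos[pos >= 0]
        if len(pos) < 2:
            raise np.linalg.LinAlgError("not enough families in resample")
        idx, gstarts, G = _gather_rows(self.starts, self.counts, pos)
        X, y = self.X[idx], self.y[idx]
        if X.shape[0] <= X.shape[1]:
            raise np.linalg.LinAlgError("resample smaller than parameter count")
        b, se = cluster_ols_arrays(X, y, None, G, group_starts=gstarts)
        return float(b[self.k]), float(se[self.k])


class _StratifiedDiffHypothesis:
    """High-minus-low SES slope difference of one term from stratified
    family-FE fits (within design), refittable on a family resample."""

    def __init__(self, sample, formula: ModelFormula, term: str):
        rows = sample.rows.sort_values("family_id", kind="stable")
        X = build_design_matrix(formula, rows, add_intercept=False)
        fams = rows["family_id"].to_numpy()
        _, pos = np.unique(fams, return_inverse=True)
        cnt = np.bincount(pos)
        Xd = X.to_numpy(dtype=float).copy()
        for j in range(Xd.shape[1]):
            means = np.bincount(pos, weights=Xd[:, j]) / cnt
            Xd[:, j] -= means[pos]
        y = rows[formula.outcome].to_numpy(dtype=float)
        ymeans = np.bincount(pos, weights=y) / cnt
        yd = y - ymeans[pos]

        # keep columns with within-family variation, mirroring the FE fit
        scale = X.to_numpy(dtype=float).std(axis=0)
        scale[scale == 0] = 1.0
        keep = np.abs(Xd).max(axis=0) / scale >= 1e-10
        cols = [c for c, k in zip(X.columns, keep) if k]
        Xd = Xd[:, keep]
        Xdf, _ = drop_collinear(pd.DataFrame(Xd, columns=cols))
        if term not in Xdf.columns:
            raise ValueError(f"focal term {term!r} not estimable within families")
        self.k = list(Xdf.columns).index(term)
        self.X = np.ascontiguousarray(Xdf.to_numpy())
        self.y = yd
        ses_by_fam = rows.groupby("family_id", sort=True)["ses"].first()
        self.fam_ids, starts = np.unique(fams, return_index=True)
        self.starts = starts.astype(np.intp)
        self.counts = np.diff(np.r_[starts, len(fams)]).astype(np.intp)
        self.fam_stratum = ses_by_fam.loc[self.fam_ids].to_numpy(dtype=float)
        self._pos_map = None
        self.beta, self.se = self.refit(np.arange(len(self.fam_ids)), mapped=True)
        from scipy import stats as _st

        # t-based raw p with the smaller stratum's cluster df, matching
        # diff_stratified
        g1 = int((self.fam_stratum == 1.0).sum())
        g0 = len(self.fam_stratum) - g1
        self._df = max(min(g1, g0) - 1, 1)
        self.p_raw = float(2 * _st.t.sf(abs(self.beta / self.se), self._df))

    prepare = _LinearHypothesis.prepare

    def refit(self, drawn: np.ndarray, mapped: bool = False) -> tuple[float, float]:
        pos = drawn if mapped else self._pos_map[drawn]
        pos = pos[pos >= 0]
        est = {}
        for stratum in (0.0, 1.0):
            ps = pos[self.fam_stratum[pos] == stratum]
            if len(ps) < 2:
                raise np.linalg.LinAlgError(f"stratum {stratum} too small")
            idx, gstarts, G = _gather_rows(self.starts, self.counts, ps)
            X, y = self.X[idx], self.y[idx]
            if X.shape[0] <= X.shape[1]:
                raise np.linalg.LinAlgError("resample smaller than parameter count")
            b, se = cluster_ols_arrays(X, y, None, G, group_starts=gstarts)
            est[stratum] = (float(b[self.k]), float(se[self.k]))
        d = est[1.0][0] - est[0.0][0]
        se = float(np.sqrt(est[1.0][1] ** 2 + est[0.0][1] ** 2))
        return d, se


def _make_hypothesis(sample, formula: ModelFormula, term: str):
    if formula.has_family_fe:
        return _StratifiedDiffHypothesis(sample, formula, term)
    return _LinearHypothesis(sample, formula, term)


def romano_wolf_adjust(
    grid,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    family=("", ""),
    max_redraw_factor: int = 2,
) -> CorrectionResult:
    """Romano-Wolf step-down maxT adjustment over a list of hypotheses.

    ``grid`` is a list of (sample, formula, focal term) triples drawn from
    one cohort; all samples' families are pooled and resampled jointly.
    A bootstrap iteration whose refit is singular in any hypothesis is
    redrawn; more than ``max_redraw_factor * B`` redraws raise
    :class:`InstabilityError`.
    """
    if len(grid) < 1:
        raise ValueError("need at least one hypothesis")
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    hyps = [_make_hypothesis(s, f, t) for (s, f, t) in grid]
    labels = [f.outcome for (_, f, _) in grid]
    m = len(hyps)

    union = np.unique(np.concatenate([h.fam_ids for h in hyps]))
    G = len(union)
    for h in hyps:
        h.prepare(union)
    rng = np.random.default_rng([int(seed) % (2**31), 97])

    t_obs = np.array([abs(h.beta / h.se) for h in hyps])
    p_raw = np.array([h.p_raw for h in hyps])

    T = np.empty((B, m))
    n_redrawn = 0
    b = 0
    while b < B:
        drawn = rng.integers(0, G, size=G)
        try:
            for j, h in enumerate(hyps):
                bstar, sestar = h.refit(drawn)
                T[b, j] = abs((bstar - h.beta) / sestar) if sestar > 0 else np.inf
        except np.linalg.LinAlgError:
            n_redrawn += 1
            if n_redrawn > max_redraw_factor * B:
                raise InstabilityError(
                    f"exceeded {max_redraw_factor * B} singular bootstrap redraws"
                )
            continue
        b += 1

    # marginal bootstrap-t p-values (for like-for-like comparisons)
    p_boot = (1.0 + (T >= t_obs[None, :]).sum(axis=0)) / (B + 1.0)

    # step-down maxT over hypotheses ordered by decreasing |t|
    order = np.argsort(-t_obs)
    Tord = T[:, order]
    # suffix max over remaining hypotheses at each step
    suffix_max = np.maximum.accumulate(Tord[:, ::-1], axis=1)[:, ::-1]
    p_adj_ord = np.empty(m)
    prev = 0.0
    for step in range(m):
        p = (1.0 + np.sum(suffix_max[:, step] >= t_obs[order[step]])) / (B + 1.0)
        prev = max(prev, p)
        p_adj_ord[step] = prev
    p_rw = np.empty(m)
    p_rw[order] = p_adj_ord

    bonf = bonferroni_adjust(p_raw, alpha=alpha, family=family, outcomes=labels)
    return CorrectionResult(
        family=tuple(family),
        outcomes=labels,
        p_raw=p_raw,
        p_bonferroni=bonf.p_bonferroni,
        p_romano_wolf=p_rw,
        alpha=alpha,
        n_bootstrap=B,
        seed=seed,
        n_redrawn=n_redrawn,
        p_bootstrap_raw=p_boot,
    )
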