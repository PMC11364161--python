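"""End-to-end orchestration of the 2 PGIs x 7 outcomes x 3 designs grid.

For each of the 42 analysis cells the pipeline builds the design-specific
analytical sample, fits the fully interacted model (between/trio: the focal
PGI x SES coefficient; within: the high-minus-low SES stratified
fixed-effects slope difference, the comparable quantity in that design) and
collects the interaction estimate with family-clustered inference.  Raw
p-values are then adjusted per (design, PGI) family of seven outcomes by
Bonferroni and Romano-Wolf.  A run is summarised by its sign/significance
tally — how many of the 42 interactions are negative (compensatory
direction) or positive (Scarr-Rowe direction) and how many survive each
correction.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BINARY_OUTCOMES, OUTCOMES, CohortConfig
from .cohort import simulate_cohort
from .formulas import build_design_matrix
from .multiplicity import bonferroni_adjust, romano_wolf_adjust
from .power import _fit_cell

logger = logging.getLogger("famgxe")

__all__ = ["GridResult", "run_grid", "classify_support", "plot_interactions"]

DESIGNS = ("between", "within", "trio")
PGIS = ("cog", "noncog")


@dataclass
class GridResult:
    """All 42 cells of one run, plus tallies and provenance."""

    cells: pd.DataFrame
    tally: dict
    corrections: dict  # (design, pgi) -> CorrectionResult
    scenario_hash: str
    seed: int
    fits: dict = field(default_factory=dict, repr=False)
    samples: dict = field(default_factory=dict, repr=False)

    def cell(self, design: str, outcome: str, focal_pgi: str) -> pd.Series:
        c = self.cells
        m = (
            (c["design"] == design)
            & (c["outcome"] == outcome)
            & (c["focal_pgi"] == focal_pgi)
        )
        return c[m].iloc[0]


def _tally(cells: pd.DataFrame, alpha: float) -> dict:
    ok = cells[cells["error"].isna()]
    est = ok["estimate"]
    return {
        "n_cells": int(len(cells)),
        "n_errors": int(cells["error"].notna().sum()),
        "n_negative": int((est < 0).sum()),
        "n_positive": int((est > 0).sum()),
        "n_zero": int((est == 0).sum()),
        "n_sig_raw": int((ok["p_raw"] < alpha).sum()),
        "n_sig_rw": int((ok["p_rw"] < alpha).sum()),
        "n_sig_bonf": int((ok["p_raw"] < alpha / len(OUTCOMES)).sum()),
    }


def run_grid(
    source: CohortConfig | pd.DataFrame,
    seed: int = 0,
    alpha: float = 0.05,
    romano_wolf: bool = True,
    rw_B: int = 1000,
) -> GridResult:
    """Run the full grid from a scenario config or a pre-built cohort table.

    Any per-cell stage failure is recorded in that cell's ``error`` column
    (its p-values become NaN and it is skipped by the Romano-Wolf family);
    cells are never silently dropped.
    """
    if isinstance(source, CohortConfig):
        cfg = source.replace(seed=seed)
        cohort = simulate_cohort(cfg)
        h = hashlib.sha256()
        import dataclasses as _dc

        h.update(repr(_dc.asdict(cfg)).encode())
        scenario_hash = h.hexdigest()[:16]
    else:
        cohort = source
        scenario_hash = hashlib.sha256(
            pd.util.hash_pandas_object(cohort[["person_id", "family_id"]]).to_numpy()
        ).hexdigest()[:16]

    records = []
    fits: dict = {}
    samples: dict = {}
    for design in DESIGNS:
        for pgi in PGIS:
            for outcome in OUTCOMES:
                key = (design, outcome, pgi)
                try:
                    est, se, p, sample, formula, fit = _fit_cell(
                        cohort, design, outcome, pgi, seed
                    )
                    samples[key] = (sample, formula)
                    if fit is not None:
                        fits[key] = fit
                    records.append(
                        dict(
                            design=design,
                            outcome=outcome,
                            focal_pgi=pgi,
                            estimate=est,
                            se=se,
                            p_raw=p,
                            n=sample.n_obs,
                            n_clusters=sample.n_families,
                            error=None,
                        )
                    )
                except Exception as e:  # attach, never drop
                    logger.warning("cell %s failed: %s", key, e)
                    records.append(
                        dict(
                            design=design,
                            outcome=outcome,
                            focal_pgi=pgi,
                            estimate=np.nan,
                            se=np.nan,
                            p_raw=np.nan,
                            n=0,
                            n_clusters=0,
                            error=f"{type(e).__name__}: {e}",
                        )
                    )
    cells = pd.DataFrame(records)
    cells["error"] = cells["error"].astype(object)

    corrections: dict = {}
    cells["p_bonf"] = np.nan
    cells["p_rw"] = np.nan
    for design in DESIGNS:
        for pgi in PGIS:
            mask = (cells["design"] == design) & (cells["focal_pgi"] == pgi)
            fam_cells = cells[mask & cells["error"].isna()]
            if fam_cells.empty:
                continue
            term = f"pgi_{pgi}" if design == "within" else f"pgi_{pgi}:ses"
            corr = None
            if romano_wolf:
                grid = [
                    (*samples[(design, oc, pgi)], term)
                    for oc in fam_cells["outcome"]
                ]
                try:
                    corr = romano_wolf_adjust(
                        grid,
                        B=rw_B,
                        seed=seed,
                        alpha=alpha,
                        family=(design, pgi),
                    )
                except Exception as e:
                    logger.warning(
                        "Romano-Wolf failed for family (%s, %s): %s; "
                        "falling back to Bonferroni only",
                        design, pgi, e,
                    )
            if corr is None:
                corr = bonferroni_adjust(
                    fam_cells["p_raw"],
                    alpha=alpha,
                    family=(design, pgi),
                    outcomes=list(fam_cells["outcome"]),
                )
            corrections[(design, pgi)] = corr
            idx = fam_cells.index
            cells.loc[idx, "p_bonf"] = corr.p_bonferroni
            if corr.p_romano_wolf is not None:
                cells.loc[idx, "p_rw"] = corr.p_romano_wolf

    m = len(OUTCOMES)
    cells["sig_raw"] = cells["p_raw"] < alpha
    cells["sig_bonf"] = cells["p_raw"] < alpha / m
    cells["sig_rw"] = cells["p_rw"] < alpha
    return GridResult(
        cells=cells,
        tally=_tally(cells, alpha),
        corrections=corrections,
        scenario_hash=scenario_hash,
        seed=seed,
        fits=fits,
        samples=samples,
    )


def classify_support(grid: GridResult) -> dict:
    """Verdict on the two competing hypotheses from the sign/significance
    pattern: positive interactions support the Scarr-Rowe hypothesis (H1:
    PGIs more predictive for high-SES children), negative ones the
    compensatory advantage hypothesis (H2)."""
    t = grid.tally
    ok = grid.cells[grid.cells["error"].isna()]
    res = {
        "H1_positive": t["n_positive"],
        "H2_negative": t["n_negative"],
        "H1_sig_raw": int(((ok["estimate"] > 0) & ok["sig_raw"]).sum()),
        "H2_sig_raw": int(((ok["estimate"] < 0) & ok["sig_raw"]).sum()),
        "H1_sig_rw": int(((ok["estimate"] > 0) & ok["sig_rw"]).sum()),
        "H2_sig_rw": int(((ok["estimate"] < 0) & ok["sig_rw"]).sum()),
        "H1_sig_bonf": int(((ok["estimate"] > 0) & ok["sig_bonf"]).sum()),
        "H2_sig_bonf": int(((ok["estimate"] < 0) & ok["sig_bonf"]).sum()),
    }
    n_ok = len(ok)
    for hyp, sign in (("H1", 1), ("H2", -1)):
        n_sign = res[f"{hyp}_positive" if sign > 0 else f"{hyp}_negative"]
        other = "H2" if hyp == "H1" else "H1"
        if res[f"{hyp}_sig_bonf"] > 0 and res[f"{other}_sig_bonf"] == 0 and n_sign > n_ok / 2:
            res["verdict"] = f"{hyp} supported (robust to Bonferroni)"
        elif res[f"{hyp}_sig_rw"] > 0 and res[f"{other}_sig_rw"] == 0 and n_sign > n_ok / 2:
            res.setdefault("verdict", f"{hyp} supported (robust to Romano-Wolf)")
        elif n_sign > n_ok / 2:
            res.setdefault(
                "verdict", f"sign-consistent with {hyp}, not robust"
            )
    res.setdefault("verdict", "null / mixed")
    return res


def plot_interactions(
    grid: GridResult, cohort: pd.DataFrame, outdir, pgi_range=(-2.0, 2.0)
):
    """Predicted-outcome lines over the focal PGI for low/high SES with 95%
    delta-method bands from the clustered covariance, one figure per fitted
    between/trio cell (the within design has no SES term to plot).  Returns
    the list of written files; cells without a stored fit are skipped with a
    log entry."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    xs = np.linspace(*pgi_range, 41)
    for (design, outcome, pgi), fit in grid.fits.items():
        sample, _ = grid.samples[(design, outcome, pgi)]
        rows = _prediction_rows(sample.rows, pgi, xs)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for ses, color in ((0.0, "tab:blue"), (1.0, "tab:red")):
            rows["ses"] = ses
            X = build_design_matrix(fit.formula, rows)
            X = X[[c for c in X.columns if c in fit.params.index]]
            X = X.reindex(columns=fit.params.index, fill_value=0.0)
            pred = X.to_numpy() @ fit.params.to_numpy()
            se = np.sqrt(
                np.einsum(
                    "ij,jk,ik->i", X.to_numpy(), fit.vcov.to_numpy(), X.to_numpy()
                )
            )
            lab = "high SES" if ses else "low SES"
            ax.plot(xs, pred, color=color, label=lab)
            ax.fill_between(
                xs, pred - 1.96 * se, pred + 1.96 * se, color=color, alpha=0.2
            )
        ax.set_xlabel(f"PGI {pgi} (z)")
        ax.set_ylabel(
            f"P({outcome})" if outcome in BINARY_OUTCOMES else outcome
        )
        ax.set_title(f"{design}: {outcome}, PGI {pgi} x SES")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        path = outdir / f"interaction_{design}_{outcome}_{pgi}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    skipped = [
        k
        for k in grid.samples
        if k not in grid.fits and k[0] != "within"
    ]
    for k in skipped:
        logger.info("plot skipped for cell %s: no stored fit", k)
    return written


def _prediction_rows(sample_rows: pd.DataFrame, focal_pgi: str, xs) -> pd.DataFrame:
    """Covariate-neutral prediction frame: focal PGI varies, everything else
    at zero / the reference platform level."""
    n = len(xs)
    d = {"pgi_cog": np.zeros(n), "pgi_noncog": np.zeros(n)}
    d[f"pgi_{focal_pgi}"] = np.asarray(xs, dtype=float)
    for c in sample_rows.columns:
        if c.startswith("pc") and c[2:].isdigit():
            d[c] = np.zeros(n)
        if c.startswith("pgi_") and (c.endswith("_father") or c.endswith("_mother")):
            d[c] = np.zeros(n)
    plat = sample_rows["platform"]
    if isinstance(plat.dtype, pd.CategoricalDtype):
        ref = [lv for lv in plat.cat.categories if (plat == lv).any()][0]
        d["platform"] = pd.Categorical([ref] * n, categories=plat.cat.categories)
    else:
        ref = sorted(plat.unique())[0]
        d["platform"] = [ref] * n
    d["ses"] = np.zeros(n)
    return pd.DataFrame(d)
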