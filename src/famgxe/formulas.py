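"""Regression specifications for the between, within and trio designs.

Each model is an explicit ordered term list.  The baseline between-family
model regresses an outcome on the two child PGIs, binary family SES and the
standard control set (10 ancestry PCs and the genotyping platform); the
within-family model drops SES (family-constant, absorbed by the family fixed
effect); the trio model adds the four parental PGIs.

The interacted models implement the full covariate-interaction ("Keller")
expansion: besides the focal PGI x SES term of interest, the focal PGI and
SES are each interacted with the other PGI and with every control variable
(and, in the trio design, with every parental PGI), so that the G x E
coefficient is not confounded by omitted covariate interactions.  Covariates
are never interacted with each other.

A categorical platform enters as indicator columns; "platform x PGI" means
one interaction per indicator level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Term",
    "ModelFormula",
    "CONTROLS",
    "PARENT_PGIS",
    "expand_baseline",
    "expand_interacted",
    "recode_terciles",
    "build_design_matrix",
    "formula_text",
    "FormulaError",
    "DegenerateCodingError",
]

#: Control set: 10 ancestry principal components and the genotyping platform.
CONTROLS = tuple(f"pc{i}" for i in range(1, 11)) + ("platform",)

PARENT_PGIS = (
    "pgi_cog_father",
    "pgi_cog_mother",
    "pgi_noncog_father",
    "pgi_noncog_mother",
)

_PGI = {"cog": "pgi_cog", "noncog": "pgi_noncog"}


class FormulaError(ValueError):
    """Raised on an invalid model request."""


class DegenerateCodingError(ValueError):
    """Raised when tercile boundaries are undefined (constant PGI)."""


@dataclass(frozen=True)
class Term:
    name: str
    vars: tuple[str, ...]
    kind: str  # "main" | "interaction" | "fixed-effect-absorbed"


@dataclass(frozen=True)
class ModelFormula:
    design: str
    outcome: str
    focal_pgi: str  # "cog" | "noncog" | "none"
    terms: tuple[Term, ...]
    pgi_coding: str = "zscore"  # or "terciles"
    tercile_cuts: dict = field(default_factory=dict)

    @property
    def has_family_fe(self) -> bool:
        return any(t.kind == "fixed-effect-absorbed" for t in self.terms)

    def term_names(self) -> list[str]:
        return [t.name for t in self.terms if t.kind != "fixed-effect-absorbed"]


def _main(var: str) -> Term:
    return Term(var, (var,), "main")


def _ix(a: str, b: str) -> Term:
    return Term(f"{a}:{b}", (a, b), "interaction")


def expand_baseline(design: str, outcome: str) -> ModelFormula:
    """Main-effects model for one design: PGIs (+ SES outside the FE design,
    + parental PGIs in the trio design) and the control set."""
    if design not in ("between", "within", "trio"):
        raise FormulaError(f"unknown design {design!r}")
    terms: list[Term] = [_main("pgi_cog"), _main("pgi_noncog")]
    if design != "within":
        terms.append(_main("ses"))
    if design == "trio":
        terms.extend(_main(v) for v in PARENT_PGIS)
    terms.extend(_main(v) for v in CONTROLS)
    if design == "within":
        terms.append(Term("family_fe", ("family_id",), "fixed-effect-absorbed"))
    return ModelFormula(design, outcome, "none", tuple(terms))


def expand_interacted(design: str, outcome: str, focal_pgi: str) -> ModelFormula:
    """Fully interacted G x E model for the between or trio design.

    Adds, to the baseline terms: focal x SES (the coefficient of interest),
    focal x other PGI, focal x every control, SES x other PGI, SES x every
    control; the trio design additionally gets focal x each parental PGI and
    SES x each parental PGI.
    """
    if focal_pgi not in ("cog", "noncog"):
        raise FormulaError("expand_interacted requires focal_pgi 'cog' or 'noncog'")
    if design not in ("between", "trio"):
        raise FormulaError(
            f"interacted models are defined for between/trio designs, not {design!r}"
        )
    base = expand_baseline(design, outcome)
    focal = _PGI[focal_pgi]
    other = _PGI["noncog" if focal_pgi == "cog" else "cog"]

    extra: list[Term] = [_ix(focal, "ses"), _ix(focal, other)]
    if design == "trio":
        extra.extend(_ix(focal, v) for v in PARENT_PGIS)
    extra.extend(_ix(focal, v) for v in CONTROLS)
    extra.append(_ix("ses", other))
    if design == "trio":
        extra.extend(_ix("ses", v) for v in PARENT_PGIS)
    extra.extend(_ix("ses", v) for v in CONTROLS)
    return ModelFormula(
        design, outcome, focal_pgi, base.terms + tuple(extra)
    )


def recode_terciles(formula: ModelFormula, sample: pd.DataFrame) -> ModelFormula:
    """Replace each PGI by middle/top-tercile indicators (bottom tercile is
    the reference), with boundaries computed on the given design sample.
    Every term containing a PGI is duplicated per indicator, so interacted
    formulas keep the full covariate-interaction structure."""
    if formula.pgi_coding != "zscore":
        raise FormulaError("formula already recoded")
    cuts: dict[str, tuple[float, float]] = {}
    mapping: dict[str, tuple[str, str]] = {}
    for var in ("pgi_cog", "pgi_noncog"):
        if not any(var in t.vars for t in formula.terms):
            continue
        v = sample[var].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        lo, hi = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0])
        if not lo < hi:
            raise DegenerateCodingError(
                f"tercile boundaries for {var} are tied ({lo}); coding undefined"
            )
        cuts[var] = (float(lo), float(hi))
        mapping[var] = (f"{var}_mid", f"{var}_top")

    new_terms: list[Term] = []
    for t in formula.terms:
        hit = [v for v in t.vars if v in mapping]
        if not hit:
            new_terms.append(t)
            continue
        # terms are at most bilinear and never PGI x PGI on both sides of
        # the same recoding pass twice, but handle the general product
        expansions = [(t.vars, t.name)]
        for v in hit:
            nxt = []
            for vars_, _ in expansions:
                for repl in mapping[v]:
                    vv = tuple(repl if x == v else x for x in vars_)
                    nxt.append((vv, ":".join(vv)))
            expansions = nxt
        for vv, name in expansions:
            new_terms.append(Term(name, vv, t.kind))
    return replace(
        formula,
        terms=tuple(new_terms),
        pgi_coding="terciles",
        tercile_cuts=cuts,
    )


# ---------------------------------------------------------------------------
# materialisation

def _resolve(var: str, rows: pd.DataFrame, cuts: dict) -> dict[str, np.ndarray]:
    """Resolve a symbolic variable to one or more named numeric columns."""
    if var == "platform":
        levels = [
            lv
            for lv in (
                rows["platform"].cat.categories
                if isinstance(rows["platform"].dtype, pd.CategoricalDtype)
                else sorted(rows["platform"].unique())
            )
            if (rows["platform"] == lv).any()
        ]
        return {
            f"platform[{lv}]": (rows["platform"] == lv).to_numpy(dtype=float)
            for lv in levels[1:]  # first observed level is the reference
        }
    if (var.endswith("_mid") or var.endswith("_top")) and var.rsplit("_", 1)[0] in cuts:
        base = var.rsplit("_", 1)[0]
        lo, hi = cuts[base]
        v = rows[base].to_numpy(dtype=float)
        if var.endswith("_mid"):
            return {var: ((v > lo) & (v <= hi)).astype(float)}
        return {var: (v > hi).astype(float)}
    if var not in rows.columns:
        raise FormulaError(f"sample lacks model column {var!r}")
    return {var: rows[var].to_numpy(dtype=float)}


def build_design_matrix(
    formula: ModelFormula, rows: pd.DataFrame, add_intercept: bool | None = None
) -> pd.DataFrame:
    """Materialise the ordered term list as a numeric design matrix.

    Categorical platform terms expand into indicator columns; interaction
    terms are elementwise products of their resolved constituents.  An
    intercept column is prepended except for family-FE formulas (where it is
    absorbed).
    """
    if add_intercept is None:
        add_intercept = not formula.has_family_fe
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["const"] = np.ones(len(rows))
    for t in formula.terms:
        if t.kind == "fixed-effect-absorbed":
            continue
        if len(t.vars) == 1:
            cols.update(_resolve(t.vars[0], rows, formula.tercile_cuts))
        else:
            a, b = t.vars
            for na, va in _resolve(a, rows, formula.tercile_cuts).items():
                for nb, vb in _resolve(b, rows, formula.tercile_cuts).items():
                    cols[f"{na}:{nb}"] = va * vb
    return pd.DataFrame(cols, index=rows.index)


def formula_text(formula: ModelFormula) -> str:
    """Human-readable audit form, e.g. ``cito_z ~ pgi_cog + ... | family``."""
    parts = [t.name for t in formula.terms if t.kind != "fixed-effect-absorbed"]
    rhs = " + ".join(parts)
    if formula.has_family_fe:
        rhs += " | family"
    tag = "" if formula.pgi_coding == "zscore" else " [terciles]"
    return f"{formula.outcome} ~ {rhs}{tag}"
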