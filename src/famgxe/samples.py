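"""Analytical-sample construction for the three research designs.

From one cohort, each (design, outcome) pair gets its own child sample:

* **between** — all children with complete data (both PGIs, SES, the
  outcome); from each complete MZ pair one co-twin is dropped at random,
  since MZ twins carry no independent genetic variation.
* **within** — a balanced two-children-per-family sample for family
  fixed effects, built per family by ordered rules: (1) a complete DZ twin
  pair; (2) a lone complete twin paired with a full sibling (a random one if
  several); (3) a complete MZ pair contributes one random co-twin paired
  with a sibling.  Families not matching any rule are dropped and logged.
* **trio** — the between sample further restricted to children whose father
  and mother both have observed PGIs.

Random draws use one named sub-seed per (design, outcome), so per-outcome
samples differ, and the trio sample reuses the between draw for the same
outcome (guaranteeing trio is a subset of between).  Every decision is
recorded in a per-family selection log.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSample", "build_between", "build_within", "build_trio", "SchemaError"]

CHILD_ROLES = ("twin1", "twin2", "sibling")
_DESIGN_CODE = {"between": 1, "within": 2, "trio": 3}


class SchemaError(KeyError):
    """Raised when a requested column is absent from the cohort table."""


@dataclass
class DesignSample:
    """A design-specific analytical sample of child rows.

    ``rows`` carries the retained children with parental PGI columns
    (``pgi_cog_father`` etc., observed values, NaN when the parent is not
    genotyped) merged in.  ``selection_log`` records, per family, which rule
    fired and which children were chosen or dropped.
    """

    design: str
    outcome: str
    rows: pd.DataFrame
    selection_log: pd.DataFrame
    seed: int

    @property
    def n_obs(self) -> int:
        return len(self.rows)

    @property
    def n_families(self) -> int:
        return self.rows["family_id"].nunique()


def _rng_for(seed: int, design: str, outcome: str) -> np.random.Generator:
    code = zlib.crc32(outcome.encode()) % (2**16)
    return np.random.default_rng([int(seed) % (2**31), _DESIGN_CODE[design], code])


def _check_outcome(cohort: pd.DataFrame, outcome: str) -> None:
    required = ["pgi_cog", "pgi_noncog", "ses", "family_id", "role", outcome]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table lacks required column(s): {missing}")


def _attach_parent_pgis(children: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    out = children.copy()
    for role, tag in (("father", "father"), ("mother", "mother")):
        par = cohort[cohort["role"] == role].set_index("family_id")
        for pgi in ("pgi_cog", "pgi_noncog"):
            col = (
                par[pgi].reindex(out["family_id"]).to_numpy()
                if pgi in par.columns
                else np.nan
            )
            out[f"{pgi}_{tag}"] = col
    return out


def _eligible_children(cohort: pd.DataFrame, outcome: str) -> pd.DataFrame:
    # analysis columns only: genotype dosage columns are dead weight here
    slim = cohort[
        [c for c in cohort.columns if not (c.startswith("g") and c[1:].isdigit())]
    ]
    kids = slim[slim["role"].isin(CHILD_ROLES)]
    ok = (
        kids["pgi_cog"].notna()
        & kids["pgi_noncog"].notna()
        & kids["ses"].notna()
        & kids[outcome].notna()
    )
    return kids[ok]


def build_between(cohort: pd.DataFrame, outcome: str, seed: int) -> DesignSample:
    """Between-family sample: complete-data children, one random co-twin
    dropped from each complete MZ pair."""
    _check_outcome(cohort, outcome)
    rng = _rng_for(seed, "between", outcome)
    elig = _eligible_children(cohort, outcome)

    mz = elig[
        (elig["zygosity"].astype(str) == "MZ")
        & elig["role"].isin(["twin1", "twin2"])
    ]
    pairs = mz.pivot_table(
        index="family_id", columns="role", values="person_id", aggfunc="first",
        observed=True,
    )
    complete = pairs.dropna(subset=["twin1", "twin2"]) if len(pairs) else pairs
    if len(complete):
        complete = complete.sort_index()
        draws = rng.integers(2, size=len(complete))
        t1 = complete["twin1"].to_numpy(dtype=np.int64)
        t2 = complete["twin2"].to_numpy(dtype=np.int64)
        dropped_ids = np.where(draws == 0, t1, t2)
        kept_ids = np.where(draws == 0, t2, t1)
    else:
        dropped_ids = np.empty(0, dtype=np.int64)
        kept_ids = np.empty(0, dtype=np.int64)
    log = pd.DataFrame(
        {
            "family_id": complete.index.to_numpy() if len(complete) else [],
            "rule": "mz_drop",
            "chosen": kept_ids,
            "dropped": dropped_ids,
        }
    )
    others = np.setdiff1d(elig["family_id"].unique(), log["family_id"].to_numpy())
    log = pd.concat(
        [
            log,
            pd.DataFrame(
                {"family_id": others, "rule": "keep_all", "chosen": -1, "dropped": -1}
            ),
        ],
        ignore_index=True,
    ).sort_values("family_id", kind="stable", ignore_index=True)
    rows = elig[~elig["person_id"].isin(dropped_ids)].reset_index(drop=True)
    rows = _attach_parent_pgis(rows, cohort)
    return DesignSample("between", outcome, rows, log, seed)


def build_within(cohort: pd.DataFrame, outcome: str, seed: int) -> DesignSample:
    """Balanced two-member family sample for the fixed-effects design."""
    _check_outcome(cohort, outcome)
    rng = _rng_for(seed, "within", outcome)
    elig = _eligible_children(cohort, outcome)

    keep_ids: list[int] = []
    log_rows = []
    for fam, grp in elig.groupby("family_id", sort=True):
        twins = grp[grp["role"].isin(["twin1", "twin2"])]
        sibs = grp[grp["role"] == "sibling"]
        zyg = set(twins["zygosity"].astype(str))
        if len(zyg) > 1:
            warnings.warn(
                f"family {fam}: co-twins with inconsistent zygosity; treating as MZ",
                stacklevel=2,
            )
            zyg = {"MZ"}
        is_mz = zyg == {"MZ"}

        if len(twins) == 2 and not is_mz:
            chosen = list(twins["person_id"])
            rule = 1
        elif len(twins) == 1 and len(sibs) >= 1:
            sib = sibs["person_id"].iloc[int(rng.integers(len(sibs)))]
            chosen = [twins["person_id"].iloc[0], sib]
            rule = 2
        elif len(twins) == 2 and is_mz:
            if len(sibs) == 0:
                log_rows.append((fam, 0, "dropped: MZ pair without sibling"))
                continue
            twin = twins["person_id"].iloc[int(rng.integers(2))]
            sib = sibs["person_id"].iloc[int(rng.integers(len(sibs)))]
            chosen = [twin, sib]
            rule = 3
        else:
            log_rows.append((fam, 0, "dropped: no eligible twin pairable"))
            continue
        keep_ids.extend(int(c) for c in chosen)
        log_rows.append((fam, rule, ",".join(str(int(c)) for c in chosen)))

    rows = elig[elig["person_id"].isin(keep_ids)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["family_id", "rule", "chosen"])
    rows = _attach_parent_pgis(rows, cohort)
    return DesignSample("within", outcome, rows, log, seed)


def build_trio(cohort: pd.DataFrame, outcome: str, seed: int) -> DesignSample:
    """Trio sample: the between sample restricted to children with both
    parents' PGIs observed (same random MZ exclusion as between)."""
    base = build_between(cohort, outcome, seed)
    rows = base.rows
    ok = (
        rows["pgi_cog_father"].notna()
        & rows["pgi_cog_mother"].notna()
        & rows["pgi_noncog_father"].notna()
        & rows["pgi_noncog_mother"].notna()
    )
    dropped = rows[~ok]
    log_extra = pd.DataFrame(
        {
            "family_id": dropped["family_id"].to_numpy(),
            "rule": "parent_pgi_missing",
            "chosen": -1,
            "dropped": dropped["person_id"].to_numpy(),
        }
    )
    log = pd.concat([base.selection_log, log_extra], ignore_index=True)
    return DesignSample("trio", outcome, rows[ok].reset_index(drop=True), log, seed)
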