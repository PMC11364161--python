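"""Synthetic twin-family cohort generator.

Simulates genotyped families (father, mother, a twin pair, optional full
siblings), computes two polygenic indices (PGIs, cognitive and noncognitive)
from the simulated dosages, assigns binary parental education with passive
gene-environment correlation (rGE) and the highest-parent ("dominance") SES
rule, and generates seven educational outcomes from a latent structural model
with a configurable G x SES interaction.

Genotype columns (``g000``, ``g001``, ...) always hold the *true* dosages;
observational genotype missingness is encoded by the boolean ``genotyped``
column, and the observed PGI columns (``pgi_cog``, ``pgi_noncog``) are NaN
for non-genotyped persons while the latent truth is kept in
``pgi_cog_true`` / ``pgi_noncog_true`` (the structural model acts on true
genotypes regardless of whether they were "assayed").

All randomness is drawn from named streams derived from ``config.seed``, so
an identical configuration reproduces a bit-identical cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import OUTCOMES, CohortConfig, ConfigError

__all__ = [
    "simulate_parents",
    "meiose_children",
    "compute_pgis",
    "assign_ses",
    "generate_outcomes",
    "simulate_cohort",
    "validate_mendelian",
    "write_cohort",
    "read_cohort",
    "COHORT_SCHEMA_VERSION",
]

COHORT_SCHEMA_VERSION = "1"

#: Children per family for each zygosity-mix arrangement.
_FAMILY_PLAN = {
    "mz": ("MZ", 0),
    "dz": ("DZ", 0),
    "mz_sib": ("MZ", 1),
    "dz_sib": ("DZ", 1),
    "dz_2sib": ("DZ", 2),
}

#: Latent z-scale cut-points for the 1-5 grade scale.  Fixed constants
#: calibrated once so the implied category distribution (2/7/31/45/15%)
#: has SD ~ 0.89 and mean ~ 3.6 on the 1-5 scale.
GRADE_CUTS = (-2.0537489106318225, -1.3407550336902165, -0.2533471031357997, 1.0364333894937898)

#: Pre-censoring mean/SD of the CITO latent scale.  Calibrated once so that
#: after clipping to [501, 550] the score has mean 538.9 and SD 9.0.
CITO_MU = 539.8116284159
CITO_SIGMA = 10.4456758259
CITO_MIN, CITO_MAX = 501.0, 550.0


class CohortStructureError(ValueError):
    """Raised when a cohort fragment violates family-structure preconditions."""


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # one named stream per generation stage; all derive from config.seed
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _gcols(n_loci: int) -> list[str]:
    return [f"g{l:03d}" for l in range(n_loci)]


def _meta_frame(person_id, family_id, role, zygosity) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": np.asarray(person_id, dtype=np.int64),
            "family_id": np.asarray(family_id, dtype=np.int64),
            "role": pd.Categorical(
                role, categories=["father", "mother", "twin1", "twin2", "sibling"]
            ),
            "zygosity": pd.Categorical(zygosity, categories=["MZ", "DZ", "not-twin"]),
        }
    )


# ---------------------------------------------------------------------------
# 1. parents

def simulate_parents(config: CohortConfig) -> pd.DataFrame:
    """Draw founder genotypes: per locus, dosage ~ Binomial(2, p_l) with
    p_l uniform on [maf_low, maf_high]; loci independent (no linkage)."""
    config.validate()
    rng = _rng(config, 1)
    n_fam, L = config.n_families, config.n_loci
    freqs = rng.uniform(config.maf_low, config.maf_high, size=L)
    geno = rng.binomial(2, freqs, size=(2 * n_fam, L)).astype(np.float64)

    fam = np.repeat(np.arange(n_fam, dtype=np.int64), 2)
    slot = np.tile(np.array([0, 1]), n_fam)
    meta = _meta_frame(
        fam * 8 + slot,
        fam,
        np.where(slot == 0, "father", "mother"),
        ["not-twin"] * (2 * n_fam),
    )
    out = pd.concat(
        [meta, pd.DataFrame(geno, columns=_gcols(L))], axis=1
    )
    out["genotyped"] = True
    return out


# ---------------------------------------------------------------------------
# 2. meiosis

def meiose_children(parents: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Transmit alleles: each non-MZ child draws, independently per locus, one
    allele from each parent (Bernoulli(dosage/2)); an MZ pair is a single
    meiosis duplicated.  Family arrangements are drawn from ``zygosity_mix``
    and children are flagged non-genotyped with ``missing_genotype_rate``."""
    config.validate()
    L = config.n_loci
    gcols = _gcols(L)
    rng = _rng(config, 2)

    fam_ids = np.sort(parents["family_id"].unique())
    f_rows = parents[parents["role"] == "father"].set_index("family_id")
    m_rows = parents[parents["role"] == "mother"].set_index("family_id")
    missing = set(fam_ids) - set(f_rows.index) | set(fam_ids) - set(m_rows.index)
    if missing or len(f_rows) != len(fam_ids) or len(m_rows) != len(fam_ids):
        raise CohortStructureError(
            "every family needs exactly one father and one mother; "
            f"offending families: {sorted(missing)[:5]}"
        )
    F = f_rows.loc[fam_ids, gcols].to_numpy(dtype=np.float64)
    M = m_rows.loc[fam_ids, gcols].to_numpy(dtype=np.float64)

    types = list(config.zygosity_mix)
    probs = np.array([config.zygosity_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    fam_type = rng.choice(len(types), size=len(fam_ids), p=probs)

    rows_fam: list[int] = []      # index into fam_ids per child
    roles: list[str] = []
    zygos: list[str] = []
    slots: list[int] = []
    mz_dup: list[tuple[int, int]] = []  # (twin2 child index, twin1 child index)
    for i, t_idx in enumerate(fam_type):
        zyg, n_sib = _FAMILY_PLAN[types[t_idx]]
        base = len(rows_fam)
        rows_fam += [i, i]
        roles += ["twin1", "twin2"]
        zygos += [zyg, zyg]
        slots += [2, 3]
        if zyg == "MZ":
            mz_dup.append((base + 1, base))
        for s in range(n_sib):
            rows_fam.append(i)
            roles.append("sibling")
            zygos.append("not-twin")
            slots.append(4 + s)

    idx = np.asarray(rows_fam, dtype=np.intp)
    n_children = len(idx)
    # one transmitted allele from each parent, independent across loci
    trans_f = rng.binomial(1, F[idx] / 2.0)
    trans_m = rng.binomial(1, M[idx] / 2.0)
    geno = (trans_f + trans_m).astype(np.float64)
    for twin2, twin1 in mz_dup:
        geno[twin2] = geno[twin1]

    fam_arr = fam_ids[idx]
    meta = _meta_frame(fam_arr * 8 + np.asarray(slots), fam_arr, roles, zygos)
    out = pd.concat([meta, pd.DataFrame(geno, columns=gcols)], axis=1)
    out["genotyped"] = rng.random(n_children) >= config.missing_genotype_rate
    return out


def validate_mendelian(cohort: pd.DataFrame, n_loci: int | None = None) -> None:
    """Hard assertion of Mendelian consistency on true dosages: every child
    allele must be attributable to the corresponding parent, i.e. there exist
    a_f in allowed(father dosage), a_m in allowed(mother dosage) with
    child = a_f + a_m.  Raises :class:`CohortStructureError` on violation."""
    gcols = [c for c in cohort.columns if c.startswith("g") and c[1:].isdigit()]
    if n_loci is not None:
        gcols = gcols[:n_loci]
    fathers = cohort[cohort["role"] == "father"].set_index("family_id")[gcols]
    mothers = cohort[cohort["role"] == "mother"].set_index("family_id")[gcols]
    kids = cohort[cohort["role"].isin(["twin1", "twin2", "sibling"])]
    C = kids[gcols].to_numpy()
    F = fathers.loc[kids["family_id"]].to_numpy()
    M = mothers.loc[kids["family_id"]].to_numpy()
    # allele from dosage d: {0} if d==0, {1} if d==2, {0,1} if d==1
    lo = (F == 2).astype(int) + (M == 2).astype(int)
    hi = 2 - (F == 0).astype(int) - (M == 0).astype(int)
    bad = (C < lo) | (C > hi)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CohortStructureError(
            f"Mendelian violation: child row {kids.index[i]} locus {gcols[j]} "
            f"dosage {C[i, j]} with parents {F[i, j]}/{M[i, j]}"
        )


# ---------------------------------------------------------------------------
# 3. polygenic indices

def compute_pgis(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Fixed weighted sums of dosages, z-standardised against the genotyped
    children.  Weight vectors for the two PGIs are drawn once per scenario
    (zero-mean normal, scale ``pgi_weights_scale``) and are independent."""
    config.validate()
    rng = _rng(config, 3)
    L = config.n_loci
    gcols = _gcols(L)
    w = rng.normal(0.0, config.pgi_weights_scale, size=(L, 2))
    if not np.any(w[:, 0]) or not np.any(w[:, 1]):
        raise ConfigError("degenerate PGI weight vector (all zero): z-scoring undefined")

    G = cohort[gcols].to_numpy(dtype=np.float64)
    raw = G @ w  # (n, 2)
    is_child = cohort["role"].isin(["twin1", "twin2", "sibling"]).to_numpy()
    ref = is_child & cohort["genotyped"].to_numpy()
    if ref.sum() == 0 and len(cohort) > 0:
        raise CohortStructureError("no genotyped children to standardise PGIs against")

    out = cohort.copy()
    for j, name in enumerate(("cog", "noncog")):
        if len(cohort) == 0:
            out[f"pgi_{name}_true"] = np.array([], dtype=float)
            out[f"pgi_{name}"] = np.array([], dtype=float)
            continue
        mu, sd = raw[ref, j].mean(), raw[ref, j].std(ddof=0)
        if sd == 0:
            raise ConfigError(f"pgi_{name} has zero variance in the reference set")
        z = (raw[:, j] - mu) / sd
        out[f"pgi_{name}_true"] = z
        out[f"pgi_{name}"] = np.where(out["genotyped"], z, np.nan)
    return out


# ---------------------------------------------------------------------------
# 4. SES with passive rGE

def assign_ses(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Binary parental education with passive rGE, and family SES under the
    dominance (highest-parent) rule.

    Each parent's education propensity is
    ``rge_strength * (pgi_cog + pgi_noncog)/sqrt(2) + N(0,1)``; the threshold
    is set so the family-level maximum of the two indicators hits
    ``ses_base_rate`` in expectation (parents are independent, so the
    per-parent rate is ``1 - sqrt(1 - ses_base_rate)``)."""
    config.validate()
    rng = _rng(config, 4)
    out = cohort.copy()
    is_parent = out["role"].isin(["father", "mother"]).to_numpy()
    n_par = int(is_parent.sum())
    prop = np.full(len(out), np.nan)
    prop[is_parent] = (
        config.rge_strength
        * (
            out.loc[is_parent, "pgi_cog_true"].to_numpy()
            + out.loc[is_parent, "pgi_noncog_true"].to_numpy()
        )
        / np.sqrt(2.0)
        + rng.standard_normal(n_par)
    )
    q_parent = 1.0 - np.sqrt(1.0 - config.ses_base_rate)
    scale = np.sqrt(1.0 + config.rge_strength**2)
    cut = scale * stats.norm.ppf(1.0 - q_parent)
    educ = (prop > cut).astype(float)

    par = out.loc[is_parent, ["family_id", "role"]].copy()
    par["educ"] = educ[is_parent]
    educ_f = par[par["role"] == "father"].set_index("family_id")["educ"]
    educ_m = par[par["role"] == "mother"].set_index("family_id")["educ"]
    fam = out["family_id"]
    out["educ_father"] = educ_f.reindex(fam).to_numpy()
    out["educ_mother"] = educ_m.reindex(fam).to_numpy()
    out["ses"] = np.maximum(out["educ_father"], out["educ_mother"])
    return out


# ---------------------------------------------------------------------------
# 5. outcomes, covariates

def generate_outcomes(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Fill the seven educational outcomes for children, plus the control
    covariates (10 ancestry-PC stand-ins, genotyping platform) for everyone.

    Each outcome has its own latent index (shared family effect + individual
    noise) on top of the common PGI/SES structural part; the latent is
    z-scaled within children and then mapped to the printed scale: grades by
    fixed cut-points, CITO by a censored affine map calibrated to mean 538.9
    / SD 9 on [501, 550], binary outcomes by a normal-quantile threshold at
    the configured prevalence."""
    config.validate()
    rng = _rng(config, 5)
    out = cohort.copy()
    n = len(out)
    is_child = out["role"].isin(["twin1", "twin2", "sibling"]).to_numpy()
    fam = out["family_id"].to_numpy()
    fam_ids, fam_pos = np.unique(fam, return_inverse=True)

    # covariates for everyone
    pcs = rng.standard_normal((n, 10))
    if config.pc1_structure > 0 and n > 0:
        gcols = _gcols(config.n_loci)
        gmean = out[gcols].to_numpy(dtype=float).mean(axis=1)
        sd = gmean.std(ddof=0)
        zg = (gmean - gmean.mean()) / sd if sd > 0 else np.zeros(n)
        s = config.pc1_structure
        pcs[:, 0] = np.sqrt(1 - s**2) * pcs[:, 0] + s * zg
    for k in range(10):
        out[f"pc{k + 1}"] = pcs[:, k]
    out["platform"] = pd.Categorical(
        [f"P{i + 1}" for i in rng.integers(0, config.n_platforms, size=n)],
        categories=[f"P{i + 1}" for i in range(config.n_platforms)],
    )

    # structural part common to all outcomes
    pgi_c = out["pgi_cog_true"].to_numpy()
    pgi_n = out["pgi_noncog_true"].to_numpy()
    ses = out["ses"].to_numpy()
    par = out[out["role"].isin(["father", "mother"])]
    pc_f = par[par["role"] == "father"].set_index("family_id")["pgi_cog_true"]
    pc_m = par[par["role"] == "mother"].set_index("family_id")["pgi_cog_true"]
    pn_f = par[par["role"] == "father"].set_index("family_id")["pgi_noncog_true"]
    pn_m = par[par["role"] == "mother"].set_index("family_id")["pgi_noncog_true"]
    fam_s = pd.Series(fam)
    par_cog = pc_f.reindex(fam_s).to_numpy() + pc_m.reindex(fam_s).to_numpy()
    par_non = pn_f.reindex(fam_s).to_numpy() + pn_m.reindex(fam_s).to_numpy()

    for name in OUTCOMES:
        eff = config.effects[name]
        u = rng.standard_normal(len(fam_ids)) * eff.family_sd
        e = rng.standard_normal(n) * eff.noise_sd
        latent = (
            eff.intercept
            + eff.beta_cog * pgi_c
            + eff.beta_noncog * pgi_n
            + eff.beta_ses * ses
            + eff.gamma_cog * pgi_c * ses
            + eff.gamma_noncog * pgi_n * ses
            + eff.eta_cog * par_cog
            + eff.eta_noncog * par_non
            + u[fam_pos]
            + e
        )
        if is_child.sum() == 0:
            z = latent
        else:
            mu = latent[is_child].mean()
            sd = latent[is_child].std(ddof=0)
            z = (latent - mu) / sd if sd > 0 else latent - mu

        col = np.full(n, np.nan)
        if name in ("math7", "read7", "math10", "read10"):
            col[is_child] = 1.0 + np.searchsorted(GRADE_CUTS, z[is_child])
            out[name] = col
        elif name == "cito_z":
            # printed scale: censored affine map with mean 538.9 / SD 9;
            # analysis scale: the z-scored score *before* the ceiling bites,
            # so regression coefficients carry the structural effects exactly
            raw = np.full(n, np.nan)
            raw[is_child] = np.clip(
                CITO_MU + CITO_SIGMA * z[is_child], CITO_MIN, CITO_MAX
            )
            out["cito_raw"] = raw
            # centred, not rescaled: the default calibration keeps the latent
            # near unit variance, and structural coefficients remain the
            # exact estimands of the linear fits
            cz = np.full(n, np.nan)
            if is_child.any():
                cz[is_child] = latent[is_child] - latent[is_child].mean()
            out["cito_z"] = cz
        else:
            prev = (
                config.track_prevalence if name == "track" else config.attain_prevalence
            )
            cut = stats.norm.ppf(1.0 - prev)
            col[is_child] = (z[is_child] > cut).astype(float)
            out[name] = col
    return out


# ---------------------------------------------------------------------------
# orchestration and I/O

def simulate_cohort(config: CohortConfig, check_mendelian: bool = True) -> pd.DataFrame:
    """Run the full generation chain for one scenario."""
    config.validate()
    parents = simulate_parents(config)
    children = meiose_children(parents, config)
    # parents are subject to the same person-wise genotype missingness
    # (this is what gives the trio design a stricter sample than between)
    rng = _rng(config, 6)
    parents["genotyped"] = rng.random(len(parents)) >= config.missing_genotype_rate
    cohort = pd.concat([parents, children], ignore_index=True)
    cohort = cohort.sort_values(["family_id", "person_id"], kind="stable").reset_index(
        drop=True
    )
    if check_mendelian and len(children):
        validate_mendelian(cohort, config.n_loci)
    cohort = compute_pgis(cohort, config)
    cohort = assign_ses(cohort, config)
    cohort = generate_outcomes(cohort, config)
    cohort.attrs["schema_version"] = COHORT_SCHEMA_VERSION
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as a tab-delimited table with a schema-version header."""
    with open(path, "w") as fh:
        fh.write(f"#famgxe-cohort-schema: {COHORT_SCHEMA_VERSION}\n")
        cohort.to_csv(fh, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#famgxe-cohort-schema:"):
            raise ValueError(f"{path}: missing cohort schema header")
        version = first.split(":", 1)[1].strip()
        if version != COHORT_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported cohort schema version {version!r}"
            )
        df = pd.read_csv(fh, sep="\t")
    for col in ("role", "zygosity"):
        if col in df:
            df[col] = pd.Categorical(df[col])
    df.attrs["schema_version"] = version
    return df
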