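"""Scenario configuration for the synthetic twin-family cohort generator.

A :class:`CohortConfig` fully determines a simulated cohort (given its seed):
family structure and zygosity mix, the genetic architecture behind the two
polygenic indices (PGIs), the strength of passive gene-environment correlation
(rGE) feeding parental education, and the structural model generating the
seven educational outcomes.

Default values emulate a Dutch twin-register-like analytical cohort: roughly
2,300 genotyped families yielding between-family samples of ~3,700 children,
~41% high-SES families under the highest-parent ("dominance") education rule,
CITO-like test scores with mean 538.9 and SD 9 on the 501-550 scale, and
mother-reported school grades with SD ~0.9 on a 1-5 scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "OUTCOMES",
    "BINARY_OUTCOMES",
    "FAMILY_TYPES",
    "OutcomeEffects",
    "CohortConfig",
    "ConfigError",
    "default_effects",
    "default_config",
    "read_scenario",
    "write_scenario",
]

#: The seven analysed educational outcomes, in life-course order.
OUTCOMES = ("math7", "read7", "math10", "read10", "cito_z", "track", "attain")

#: Outcomes modelled as binary (linear probability / logit).
BINARY_OUTCOMES = frozenset({"track", "attain"})

#: Supported family child arrangements for the zygosity mix.
#: "mz"/"dz": a twin pair only; "*_sib": pair plus one full sibling;
#: "dz_2sib": DZ pair plus two full siblings.
FAMILY_TYPES = ("mz", "dz", "mz_sib", "dz_sib", "dz_2sib")

_MIX_TOL = 1e-12


class ConfigError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass(frozen=True)
class OutcomeEffects:
    """Structural coefficients for one outcome's latent model.

    The latent outcome for child *i* in family *j* is

        Y* = intercept
             + beta_cog * PGIcog + beta_noncog * PGInoncog + beta_ses * SES
             + gamma_cog * PGIcog x SES + gamma_noncog * PGInoncog x SES
             + eta_cog * (PGIcog_father + PGIcog_mother)
             + eta_noncog * (PGInoncog_father + PGInoncog_mother)
             + u_j + e_ij

    with u_j ~ N(0, family_sd^2) shared by siblings and e_ij ~ N(0, noise_sd^2).
    ``gamma_*`` are the G x SES interactions of interest (positive under the
    Scarr-Rowe hypothesis, negative under compensatory advantage).  ``eta_*``
    are genetic-nurture ("family environment") effects of the parents' own
    PGIs, zero by default; switching them on together with rGE creates the
    confounding that the trio design is built to remove.
    """

    beta_cog: float = 0.2
    beta_noncog: float = 0.1
    beta_ses: float = 0.3
    gamma_cog: float = -0.1
    gamma_noncog: float = -0.05
    eta_cog: float = 0.0
    eta_noncog: float = 0.0
    family_sd: float = 0.55
    noise_sd: float = 0.75
    intercept: float = 0.0

    def validate(self, outcome: str) -> None:
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigError(
                    f"effects[{outcome}].{f.name} must be finite, got {v!r}"
                )
        if self.family_sd < 0 or self.noise_sd < 0:
            raise ConfigError(
                f"effects[{outcome}]: family_sd and noise_sd must be >= 0"
            )


def default_effects() -> dict[str, OutcomeEffects]:
    """Per-outcome structural coefficients.

    Magnitudes are on the latent (approximately unit-SD) scale and chosen so
    that realised associations fall in the ballpark reported for cognitive /
    noncognitive PGIs on grades (0.13-0.23 / 0.06-0.10 points), CITO z-scores
    (0.20-0.25 / 0.09-0.17 SD) and the binary outcomes (~9-11 / 5-8 points of
    probability per PGI SD); interactions default to the negative
    (compensatory) direction.
    """
    grade = OutcomeEffects(
        beta_cog=0.20, beta_noncog=0.10, beta_ses=0.30,
        gamma_cog=-0.10, gamma_noncog=-0.05,
    )
    return {
        "math7": grade,
        "read7": grade,
        "math10": grade,
        "read10": grade,
        "cito_z": OutcomeEffects(
            beta_cog=0.22, beta_noncog=0.13, beta_ses=0.40,
            gamma_cog=-0.08, gamma_noncog=-0.08,
        ),
        "track": OutcomeEffects(
            beta_cog=0.25, beta_noncog=0.15, beta_ses=0.50,
            gamma_cog=-0.12, gamma_noncog=-0.08,
        ),
        "attain": OutcomeEffects(
            beta_cog=0.22, beta_noncog=0.18, beta_ses=0.55,
            gamma_cog=-0.12, gamma_noncog=-0.10,
        ),
    }


def _default_mix() -> dict[str, float]:
    return {"mz": 0.25, "dz": 0.35, "mz_sib": 0.15, "dz_sib": 0.15, "dz_2sib": 0.10}


@dataclass(frozen=True)
class CohortConfig:
    """Complete scenario for one simulated cohort."""

    n_families: int = 2300
    n_loci: int = 200
    maf_low: float = 0.1
    maf_high: float = 0.5
    zygosity_mix: Mapping[str, float] = field(default_factory=_default_mix)
    pgi_weights_scale: float = 1.0
    rge_strength: float = 0.25
    ses_base_rate: float = 0.41
    effects: Mapping[str, OutcomeEffects] = field(default_factory=default_effects)
    missing_genotype_rate: float = 0.25
    track_prevalence: float = 0.5
    attain_prevalence: float = 0.35
    n_platforms: int = 2
    pc1_structure: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError(f"n_families must be >= 0, got {self.n_families}")
        if self.n_loci < 1:
            raise ConfigError(f"n_loci must be >= 1, got {self.n_loci}")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ConfigError(
                "allele frequencies must satisfy 0 < maf_low <= maf_high <= 0.5, "
                f"got maf_low={self.maf_low}, maf_high={self.maf_high}"
            )
        unknown = set(self.zygosity_mix) - set(FAMILY_TYPES)
        if unknown:
            raise ConfigError(f"unknown zygosity_mix keys: {sorted(unknown)}")
        total = sum(self.zygosity_mix.values())
        if abs(total - 1.0) > _MIX_TOL:
            raise ConfigError(
                f"zygosity_mix proportions must sum to 1 (tolerance {_MIX_TOL}), got {total!r}"
            )
        if any(v < 0 for v in self.zygosity_mix.values()):
            raise ConfigError("zygosity_mix proportions must be non-negative")
        if self.pgi_weights_scale <= 0:
            raise ConfigError(
                f"pgi_weights_scale must be > 0, got {self.pgi_weights_scale}"
            )
        if self.rge_strength < 0:
            raise ConfigError(f"rge_strength must be >= 0, got {self.rge_strength}")
        if not (0.0 < self.ses_base_rate < 1.0):
            raise ConfigError(
                f"ses_base_rate must lie strictly in (0,1), got {self.ses_base_rate}"
            )
        if not (0.0 <= self.missing_genotype_rate < 1.0):
            raise ConfigError(
                f"missing_genotype_rate must lie in [0,1), got {self.missing_genotype_rate}"
            )
        for name in ("track_prevalence", "attain_prevalence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie strictly in (0,1), got {v}")
        if self.n_platforms < 1:
            raise ConfigError(f"n_platforms must be >= 1, got {self.n_platforms}")
        if not (0.0 <= self.pc1_structure <= 1.0):
            raise ConfigError(
                f"pc1_structure must lie in [0,1], got {self.pc1_structure}"
            )
        missing = set(OUTCOMES) - set(self.effects)
        if missing:
            raise ConfigError(f"effects missing outcomes: {sorted(missing)}")
        for name in OUTCOMES:
            eff = self.effects[name]
            if not isinstance(eff, OutcomeEffects):
                raise ConfigError(f"effects[{name}] must be an OutcomeEffects")
            eff.validate(name)

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(scale: float = 1.0, **kwargs) -> CohortConfig:
    """The default scenario, with family count scalable by one multiplier.

    ``scale=1`` targets between-family analytical samples of ~3,700 children,
    comparable to the larger grade outcomes of the emulated register cohort.
    """
    n_fam = max(1, round(2300 * scale))
    cfg = CohortConfig(n_families=n_fam, **kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Scenario file round-trip (YAML key-value sidecar)

def write_scenario(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["zygosity_mix"] = dict(config.zygosity_mix)
    d["effects"] = {k: dataclasses.asdict(v) for k, v in config.effects.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_scenario(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "effects" in d:
        d["effects"] = {k: OutcomeEffects(**v) for k, v in d["effects"].items()}
    cfg = CohortConfig(**d)
    cfg.validate()
    return cfg
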