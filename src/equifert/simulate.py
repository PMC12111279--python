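"""Synthetic data with known truth for the fertility evaluation pipeline.

The generator emulates the structure of a closed horse studbook: a
multi-generation pedigree under random mating (no selfing, no
parent-offspring matings, full-sib matings optional), unlinked biallelic
SNPs dropped through the pedigree by Mendelian inheritance, and sex-limited
trait phenotypes

    y = mu + b_F * F + b_age * age + class effects + a + e

where the additive values ``a`` follow the pedigree covariance (founders
N(0, G0); non-founders parent average plus a Mendelian-sampling deviation
with variance ``(0.5 - 0.25 (F_s + F_d)) G0``) and ``e`` is i.i.d. noise.

Default trait variances are representative REML estimates for the seven
fertility traits of a closed studbook horse population, so the default
heritabilities span 0.07-0.35. All
randomness flows from the single ``seed`` through spawned child generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import relmat
from .pedigree import FEMALE, MALE, UNKNOWN, Pedigree
from .relmat import GenotypeMatrix
from .traits import ReproHistory, TRAIT_NAMES

__all__ = [
    "SimConfig",
    "SimTruth",
    "FoalingParams",
    "ConfigError",
    "simulate_pedigree",
    "simulate_genotypes",
    "gene_drop",
    "simulate_phenotypes",
    "simulate_foaling_histories",
    "simulate_dataset",
]

# traits whose model omits the age-at-last-foaling covariate (the age trait
# would otherwise appear on both sides)
AGE_EXEMPT_TRAITS = ("AFF", "ALF", "IF12")

# default additive / residual variances per trait: representative
# pedigree-REML estimates, giving h2 from 0.070 (IF12) to 0.349 (ALF)
DEFAULT_SIGMA_A2 = {
    "AFF": 0.124, "ALF": 1.270, "AIF": 10.360, "FN": 0.835,
    "IF12": 12.030, "PL": 0.111, "RE": 49.310,
}
DEFAULT_SIGMA_E2 = {
    "AFF": 0.360, "ALF": 2.366, "AIF": 97.140, "FN": 5.289,
    "IF12": 159.780, "PL": 0.443, "RE": 167.800,
}

CLASS_EFFECTS = ("ancestral_origin", "geo_zone", "stud_size")


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class FixedEffectSpec:
    """True fixed effects, expressed in phenotypic-SD units per trait.

    ``inb_slope`` multiplies the inbreeding coefficient (a mare with
    F = 0.25 shifts by ``0.25 * inb_slope`` phenotypic SDs: inbreeding
    depression when negative); ``age_slope`` multiplies the standardized
    age at last foaling (ignored for AFF/ALF/IF12). Class-effect level
    values are in SD units with the first level fixed at zero, matching
    the identifiability constraint used at fitting time.
    """

    inb_slope: float = -0.8
    age_slope: float = 0.2
    class_levels: dict = field(
        default_factory=lambda: {
            "ancestral_origin": [0.0, 0.25],
            "geo_zone": [0.0, 0.15, -0.10],
            "stud_size": [0.0, 0.10, 0.20],
        }
    )
    class_freqs: dict = field(
        default_factory=lambda: {
            "ancestral_origin": [0.80, 0.20],
            "geo_zone": [0.85, 0.10, 0.05],
            "stud_size": [0.40, 0.40, 0.20],
        }
    )


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic population."""

    n_founders: int = 100
    n_generations: int = 8
    offspring_per_mating: int = 2
    n_snps: int = 2000
    maf_range: tuple = (0.05, 0.5)
    traits: tuple = tuple(TRAIT_NAMES)
    sigma_a2: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA_A2))
    sigma_e2: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA_E2))
    genetic_correlations: np.ndarray | None = None  # identity if None
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    prop_genotyped: float = 0.2
    geno_missing_rate: float = 0.0
    sex_limited: bool = True  # record females only
    allow_full_sib_mating: bool = False
    seed: int = 20250509

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 1:
            raise ConfigError("need at least 2 founders and 1 generation")
        if self.offspring_per_mating < 1 or self.n_snps < 1:
            raise ConfigError("offspring_per_mating and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.prop_genotyped <= 1.0:
            raise ConfigError("prop_genotyped must be in [0, 1]")
        for t in self.traits:
            if self.sigma_a2[t] <= 0 or self.sigma_e2[t] <= 0:
                raise ConfigError(f"variances for {t} must be positive")
        if self.genetic_correlations is not None:
            C = np.asarray(self.genetic_correlations, dtype=float)
            if C.shape != (len(self.traits),) * 2 or not np.allclose(C, C.T):
                raise ConfigError("genetic_correlations must be symmetric t x t")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ConfigError("genetic_correlations not positive semi-definite")

    # true covariance matrices implied by the config
    def true_G0(self) -> np.ndarray:
        sa = np.sqrt([self.sigma_a2[t] for t in self.traits])
        C = (
            np.eye(len(self.traits))
            if self.genetic_correlations is None
            else np.asarray(self.genetic_correlations, dtype=float)
        )
        return np.outer(sa, sa) * C

    def true_R0(self) -> np.ndarray:
        return np.diag([self.sigma_e2[t] for t in self.traits])

    def rng_for(self, stream: int) -> np.random.Generator:
        """Independent child generator for one component of the simulation."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(16)[stream])


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    breeding_values: np.ndarray  # n x t
    fixed_effects: dict  # trait -> effect-name -> value(s), phenotype scale
    realized_F: np.ndarray
    G0: np.ndarray
    R0: np.ndarray
    traits: tuple


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.full(n, MALE, dtype=np.int64)
    sex[n // 2 :] = FEMALE
    return rng.permutation(sex)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation pedigree under random within-generation mating.

    Each generation, every female of the previous generation is mated to a
    random male of that generation (sires reused, so progeny counts vary);
    each mating yields ``offspring_per_mating`` offspring. Matings between
    full sibs are redrawn unless ``allow_full_sib_mating``; parent-offspring
    matings cannot occur because mates come from the same generation.
    """
    rng = config.rng_for(0)
    sire = [UNKNOWN] * config.n_founders
    dam = [UNKNOWN] * config.n_founders
    sex = list(_balanced_sexes(config.n_founders, rng))
    gen_start = 0
    for _ in range(config.n_generations):
        gen = np.arange(gen_start, len(sire))
        gen_start = len(sire)
        males = gen[np.asarray(sex)[gen] == MALE]
        females = gen[np.asarray(sex)[gen] == FEMALE]
        if males.size == 0 or females.size == 0:
            raise ConfigError("a generation ran out of one sex; enlarge the pedigree")
        n_off = females.size * config.offspring_per_mating
        child_sex = _balanced_sexes(n_off, rng)
        k = 0
        for dam_i in females:
            sire_i = int(rng.choice(males))
            if not config.allow_full_sib_mating:
                for _ in range(50):
                    full_sibs = (
                        sire[sire_i] != UNKNOWN
                        and sire[sire_i] == sire[dam_i]
                        and dam[sire_i] == dam[dam_i]
                    )
                    if not full_sibs or males.size == 1:
                        break
                    sire_i = int(rng.choice(males))
            for _ in range(config.offspring_per_mating):
                sire.append(sire_i)
                dam.append(int(dam_i))
                sex.append(int(child_sex[k]))
                k += 1
    ped = Pedigree(sire=np.array(sire), dam=np.array(dam), sex=np.array(sex))
    if config.prop_genotyped > 0:
        n_geno = int(round(config.prop_genotyped * ped.n))
        chosen = config.rng_for(1).choice(ped.n, size=n_geno, replace=False)
        ped.genotyped[chosen] = True
    return ped


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop founder alleles through the pedigree by Mendelian inheritance.

    ``founder_haplotypes`` has shape (n_founders, 2, m); returns the full
    (n, 2, m) haplotype array in pedigree order. Animals with an unknown
    parent draw that gamete from the founder allele-frequency distribution
    implied by the founder haplotypes.
    """
    n = pedigree.n
    m = founder_haplotypes.shape[2]
    founders = np.flatnonzero(pedigree.is_founder)
    if founder_haplotypes.shape[0] != founders.size:
        raise ValueError("founder_haplotypes rows must match the number of founders")
    H = np.zeros((n, 2, m), dtype=np.int8)
    H[founders] = founder_haplotypes
    p = founder_haplotypes.reshape(-1, m).mean(axis=0)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            continue
        for slot, par in enumerate((s, d)):
            if par == UNKNOWN:
                H[i, slot] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                H[i, slot] = np.where(pick == 0, H[par, 0], H[par, 1])
    return H


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Unlinked biallelic SNP dosages for the whole pedigree.

    Per-SNP founder allele frequencies are uniform on ``maf_range``;
    non-founders receive one gamete from each parent. The returned matrix
    covers every animal (``animal_index`` = 0..n-1); use
    ``pedigree.genotyped_index`` to take the genotyped panel. A positive
    ``geno_missing_rate`` masks dosages at random (for QC exercises).
    """
    rng = config.rng_for(2)
    founders = np.flatnonzero(pedigree.is_founder)
    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    founder_haps = (
        rng.random((founders.size, 2, config.n_snps)) < p[None, None, :]
    ).astype(np.int8)
    H = gene_drop(pedigree, founder_haps, rng)
    dosages = H.sum(axis=1).astype(float)
    if config.geno_missing_rate > 0:
        mask = rng.random(dosages.shape) < config.geno_missing_rate
        dosages[mask] = np.nan
    return GenotypeMatrix(dosages=dosages, animal_index=np.arange(pedigree.n))


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------


def _simulate_breeding_values(
    pedigree: Pedigree, G0: np.ndarray, F: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    t = G0.shape[0]
    L = np.linalg.cholesky(G0 + 1e-12 * np.eye(t))
    z = rng.standard_normal((pedigree.n, t))
    a = np.zeros((pedigree.n, t))
    for i in range(pedigree.n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            w, pa = 1.0, 0.0
        elif s == UNKNOWN:
            w, pa = 0.75 - 0.25 * F[d], 0.5 * a[d]
        elif d == UNKNOWN:
            w, pa = 0.75 - 0.25 * F[s], 0.5 * a[s]
        else:
            w, pa = 0.5 - 0.25 * (F[s] + F[d]), 0.5 * (a[s] + a[d])
        a[i] = pa + np.sqrt(w) * (L @ z[i])
    return a


def simulate_phenotypes(
    pedigree: Pedigree,
    config: SimConfig,
    age_at_last_foaling: np.ndarray | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Sex-limited phenotypes from the additive model with fixed effects.

    Records are generated for females only (every sex when
    ``config.sex_limited`` is False). The age covariate is the mare's age
    at her last foaling in months (supplied per animal, e.g. from
    :func:`simulate_foaling_histories`; drawn from N(140, 40) months when
    absent) and is standardized before entering the model. Returns the
    phenotype table (one row per recorded animal, with covariates and class
    labels) and the :class:`SimTruth`.
    """
    rng = config.rng_for(3)
    traits = list(config.traits)
    G0, R0 = config.true_G0(), config.true_R0()
    F = relmat.inbreeding(pedigree)
    a = _simulate_breeding_values(pedigree, G0, F, rng)

    n = pedigree.n
    fx = config.fixed_effects
    classes = {
        name: rng.choice(len(fx.class_freqs[name]), size=n, p=fx.class_freqs[name])
        for name in CLASS_EFFECTS
    }
    if age_at_last_foaling is None:
        age = np.clip(rng.normal(140.0, 40.0, size=n), 40.0, None)
    else:
        age = np.asarray(age_at_last_foaling, dtype=float)
        age = np.where(np.isnan(age), np.nanmean(age), age)
    age_std = (age - age.mean()) / age.std()

    recorded = np.ones(n, dtype=bool) if not config.sex_limited else (
        pedigree.sex == FEMALE
    )
    sp = {t: np.sqrt(config.sigma_a2[t] + config.sigma_e2[t]) for t in traits}
    e = rng.standard_normal((n, len(traits))) * np.sqrt(np.diag(R0))[None, :]

    data = {"animal": np.arange(n)[recorded]}
    true_fixed: dict = {}
    for j, t in enumerate(traits):
        b_inb = fx.inb_slope * sp[t]
        b_age = 0.0 if t in AGE_EXEMPT_TRAITS else fx.age_slope * sp[t]
        levels = {
            name: np.asarray(fx.class_levels[name]) * sp[t] for name in CLASS_EFFECTS
        }
        y = (
            b_inb * F
            + b_age * age_std
            + sum(levels[name][classes[name]] for name in CLASS_EFFECTS)
            + a[:, j]
            + e[:, j]
        )
        data[t] = y[recorded]
        true_fixed[t] = {
            "inb_slope": b_inb,
            "age_slope": b_age,
            **{name: levels[name] for name in CLASS_EFFECTS},
        }
    data["inbreeding"] = F[recorded]
    data["age_last_foaling"] = age_std[recorded]
    for name in CLASS_EFFECTS:
        data[name] = classes[name][recorded]
    table = pd.DataFrame(data)
    truth = SimTruth(
        breeding_values=a,
        fixed_effects=true_fixed,
        realized_F=F,
        G0=G0,
        R0=R0,
        traits=tuple(traits),
    )
    return table, truth


# ----------------------------------------------------------------------
# foaling histories
# ----------------------------------------------------------------------


@dataclass
class FoalingParams:
    """Reproductive-career parameters (months unless noted).

    Defaults target a realistic studbook's descriptive scale: mean first
    foaling near 64 months, mean foaling interval near 20 months (yearly
    foaling probability ~0.6), productive life of order 10 years.
    """

    first_age_mean: float = 64.0
    first_age_sd: float = 15.0
    first_age_min: float = 36.0
    foaling_prob: float = 0.6
    gap_jitter: int = 3  # uniform jitter on each 12-month cycle, months
    window_mean: float = 130.0
    window_sd: float = 60.0
    prop_active: float = 0.3  # mares still breeding (no culling age)


def simulate_foaling_histories(
    pedigree: Pedigree,
    params: FoalingParams | None = None,
    config: SimConfig | None = None,
) -> list[ReproHistory]:
    """Foaling careers for every female in the pedigree.

    Each mare foals at her first-foaling age, then per 12-month cycle with
    probability ``foaling_prob`` (so the gap is a geometric number of years
    plus jitter, never below 10 months) until her culling age. Mares flagged
    still-active carry no culling age.
    """
    params = params or FoalingParams()
    rng = config.rng_for(4) if config is not None else np.random.default_rng(20250509)
    histories = []
    for i in pedigree.females:
        first = max(
            params.first_age_min,
            rng.normal(params.first_age_mean, params.first_age_sd),
        )
        window = max(0.0, rng.normal(params.window_mean, params.window_sd))
        culling = first + window
        ages = [round(first, 1)]
        t = first
        while True:
            years = rng.geometric(params.foaling_prob) if params.foaling_prob < 1 else 1
            gap = 12.0 * years
            if params.gap_jitter:
                gap += rng.integers(-params.gap_jitter, params.gap_jitter + 1)
            gap = max(gap, 10.0)
            if t + gap > culling:
                break
            t += gap
            ages.append(round(t, 1))
        active = rng.random() < params.prop_active
        histories.append(
            ReproHistory(
                mare_id=int(i),
                foaling_ages=ages,
                culling_age=None if active else round(culling, 1),
            )
        )
    return histories


# ----------------------------------------------------------------------
# one-call dataset
# ----------------------------------------------------------------------


def simulate_dataset(config: SimConfig):
    """Pedigree, genotypes, foaling histories, phenotypes and truth in one call.

    The phenotype age covariate is taken from the simulated foaling
    histories (age at last foaling), closing the loop between the career
    generator and the trait model.
    """
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    histories = simulate_foaling_histories(ped, config=config)
    age = np.full(ped.n, np.nan)
    for h in histories:
        age[int(h.mare_id)] = h.foaling_ages[-1]
    table, truth = simulate_phenotypes(ped, config, age_at_last_foaling=age)
    return ped, geno, histories, table, truth
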