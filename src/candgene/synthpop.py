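"""Synthetic herd generator emulating a small candidate-gene study population.

Each simulated animal receives two haplotypes drawn independently from a
fixed 5-locus pool (random mating, so Hardy-Weinberg and the pool's
linkage structure hold at the population level); unphased genotypes are
the unordered per-locus allele pairs, and the true phase is retained so
phasing and diplotype calls can be checked against the truth.  Traits
are generated additively: baseline + diplotype-class effect + age-class
effect + sire effect + Gaussian residual, mirroring the fixed-effects
model the association stage fits.

The default pool is the five common haplotypes observed in the Dabieshan
cattle GDF8 panel (frequencies 31.5/23.8/23.5/5.8/5.2%) with the
residual 10.2% mass spread uniformly over 7 rare filler haplotypes, so
the <5% frequency filter behaves as in the real study; the default herd
size is 380.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Dataset, GenotypeMatrix, SnpDef, TraitTable, TRAIT_NAMES

#: The five-SNP GDF8 panel the default pool is written over.
DEFAULT_PANEL: tuple[SnpDef, ...] = (
    SnpDef("g.244C>G", "C", "G", region="exon", pos=244),
    SnpDef("g.400G>A", "G", "A", region="exon", pos=400),
    SnpDef("g.5070C>A", "C", "A", region="exon", pos=5070),
    SnpDef("g.5076T>C", "T", "C", region="exon", pos=5076),
    SnpDef("g.5148A>C", "A", "C", region="UTR3", pos=5148),
)

#: Common haplotypes and their population frequencies.
COMMON_HAPLOTYPES: dict[str, float] = {
    "CACTA": 0.315,
    "GAACC": 0.238,
    "GGCTA": 0.235,
    "GACTA": 0.058,
    "GGACC": 0.052,
}
RESIDUAL_RARE_MASS = 1.0 - sum(COMMON_HAPLOTYPES.values())  # 0.102


def _filler_haplotypes(panel: Sequence[SnpDef], exclude: set[str], k: int) -> list[str]:
    """First ``k`` haplotypes (ref-before-alt lexicographic order) not in ``exclude``."""
    out = []
    for combo in product(*[(s.allele_ref, s.allele_alt) for s in panel]):
        h = "".join(combo)
        if h not in exclude:
            out.append(h)
        if len(out) == k:
            return out
    raise ValidationError(f"cannot find {k} distinct filler haplotypes")


def default_hap_pool(n_fillers: int = 7) -> dict[str, float]:
    """The study-like pool: five common haplotypes + uniform rare fillers."""
    pool = dict(COMMON_HAPLOTYPES)
    fillers = _filler_haplotypes(DEFAULT_PANEL, set(pool), n_fillers)
    for h in fillers:
        pool[h] = RESIDUAL_RARE_MASS / n_fillers
    return pool


#: Invented per-trait baselines (cm) of the order a small Chinese yellow-cattle
#: breed shows, and residual SDs chosen so class-mean SEs land near 0.5-1.5 cm
#: at class sizes of 40-170.
DEFAULT_BASELINES: dict[str, float] = {
    "BL": 126.0, "WH": 110.0, "HH": 110.0, "HG": 149.0,
    "AGR": 168.0, "HW": 31.5, "PBW": 17.5,
}
DEFAULT_RESIDUAL_SD: dict[str, float] = {
    "BL": 7.0, "WH": 4.5, "HH": 4.5, "HG": 8.0,
    "AGR": 6.0, "HW": 3.0, "PBW": 1.8,
}


def homozygote_advantage_effects(
    haplotype: str = "CACTA",
    shifts: Mapping[str, float] | None = None,
) -> dict[str, dict[str, float]]:
    """Effect map giving one homozygous diplotype a positive shift on several traits.

    Mirrors the study condition in which animals homozygous for the most
    common haplotype show the largest wither height, hip height, heart
    girth, abdominal girth, and pin-bone width.
    """
    if shifts is None:
        shifts = {"WH": 2.0, "HH": 2.5, "HG": 5.0, "AGR": 6.0, "PBW": 1.5}
    return {f"{haplotype}/{haplotype}": dict(shifts)}


@dataclass
class SimConfig:
    """All knobs of the synthetic herd.

    ``trait_effects`` maps an effect key to ``{trait: shift_cm}``.  Keys
    may be diplotype strings ``"hap1/hap2"`` (lexicographically ordered)
    or ``(locus_id, genotype)`` tuples matching an individual's
    canonical call at one locus.
    """

    n_individuals: int = 380
    panel: tuple[SnpDef, ...] = DEFAULT_PANEL
    hap_pool: dict[str, float] = field(default_factory=default_hap_pool)
    trait_effects: dict = field(default_factory=homozygote_advantage_effects)
    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    residual_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RESIDUAL_SD))
    n_age_classes: int = 3
    n_sires: int = 10
    age_effect_sd: float = 1.5
    sire_effect_sd: float = 1.5
    missing_rate: float = 0.0
    inbreeding: float = 0.0  # probability the second gamete copies the first
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        total = sum(self.hap_pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"haplotype pool probabilities sum to {total}, not 1")
        for hap in self.hap_pool:
            if len(hap) != len(self.panel):
                raise ValidationError(f"haplotype {hap!r} length != panel size")
            for allele, snp in zip(hap, self.panel):
                if allele not in snp.alleles:
                    raise ValidationError(
                        f"haplotype {hap!r}: allele {allele!r} invalid at {snp.locus_id}"
                    )
        for t, sd in self.residual_sd.items():
            if sd < 0:
                raise ValidationError(f"residual SD for {t} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0 or not 0.0 <= self.inbreeding <= 1.0:
            raise ValidationError("missing_rate/inbreeding out of range")


@dataclass
class SimTruth:
    """Ground truth retained for oracle tests."""

    diplotypes: list[tuple[str, str]]
    age: list[str]
    sire: list[str]
    age_effects: dict[str, dict[str, float]]  # trait -> age class -> cm
    sire_effects: dict[str, dict[str, float]]  # trait -> sire -> cm
    applied_effects: pd.DataFrame  # individual x trait total class shift


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_population(config: SimConfig) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Draw diplotypes from the pool and return unphased genotypes + true phase.

    Seeded runs are bit-reproducible.  With ``inbreeding`` > 0 the second
    gamete copies the first with that probability, creating a
    heterozygote deficit relative to Hardy-Weinberg proportions.
    """
    config.validate()
    rng_gametes, rng_missing, _, _ = _streams(config.seed, 4)
    haps = sorted(config.hap_pool)
    probs = np.array([config.hap_pool[h] for h in haps])
    probs = probs / probs.sum()
    n = config.n_individuals
    first = rng_gametes.choice(len(haps), size=n, p=probs)
    second = rng_gametes.choice(len(haps), size=n, p=probs)
    if config.inbreeding > 0:
        copy = rng_gametes.random(n) < config.inbreeding
        second = np.where(copy, first, second)
    diplotypes = [tuple(sorted((haps[a], haps[b]))) for a, b in zip(first, second)]

    ids = [f"ind{i + 1:04d}" for i in range(n)]
    raw: dict[str, list[str | None]] = {s.locus_id: [] for s in config.panel}
    for h1, h2 in diplotypes:
        for j, snp in enumerate(config.panel):
            raw[snp.locus_id].append(h1[j] + h2[j])
    if config.missing_rate > 0:
        mask = rng_missing.random((n, len(config.panel))) < config.missing_rate
        for j, snp in enumerate(config.panel):
            col = raw[snp.locus_id]
            raw[snp.locus_id] = [None if mask[i, j] else col[i] for i in range(n)]
    gm = GenotypeMatrix.from_calls(ids, list(config.panel), pd.DataFrame(raw, index=ids))
    return gm, diplotypes


def _effect_for(ind_diplotype: tuple[str, str], calls: Mapping[str, str],
                effects: Mapping, trait: str) -> float:
    total = 0.0
    dip_key = f"{ind_diplotype[0]}/{ind_diplotype[1]}"
    for key, shifts in effects.items():
        if isinstance(key, str):
            if key == dip_key:
                total += shifts.get(trait, 0.0)
        else:
            locus, genotype = key
            if calls.get(locus) == genotype:
                total += shifts.get(trait, 0.0)
    return total


def simulate_traits(
    gm: GenotypeMatrix,
    diplotypes: Sequence[tuple[str, str]],
    config: SimConfig,
) -> tuple[TraitTable, SimTruth]:
    """Generate the trait table: baseline + class effect + age + sire + noise."""
    config.validate()
    for key in config.trait_effects:
        if isinstance(key, str):
            h1, _, h2 = key.partition("/")
            for h in (h1, h2):
                if h not in config.hap_pool:
                    raise ValidationError(f"effect key {key!r} names unknown haplotype {h!r}")
    _, _, rng_assign, rng_noise = _streams(config.seed, 4)
    n = gm.n
    age_levels = [f"age{k + 1}" for k in range(config.n_age_classes)]
    sire_levels = [f"sire{k + 1:02d}" for k in range(config.n_sires)]
    age = [age_levels[i] for i in rng_assign.integers(0, len(age_levels), size=n)]
    sire = [sire_levels[i] for i in rng_assign.integers(0, len(sire_levels), size=n)]
    age_eff = {
        t: dict(zip(age_levels, rng_assign.normal(0.0, config.age_effect_sd, len(age_levels))))
        for t in TRAIT_NAMES
    }
    sire_eff = {
        t: dict(zip(sire_levels, rng_assign.normal(0.0, config.sire_effect_sd, len(sire_levels))))
        for t in TRAIT_NAMES
    }
    calls_by_ind = gm.calls.to_dict(orient="index")
    applied = pd.DataFrame(
        [
            [
                _effect_for(diplotypes[i], calls_by_ind[ind], config.trait_effects, t)
                for t in TRAIT_NAMES
            ]
            for i, ind in enumerate(gm.individual_ids)
        ],
        index=gm.individual_ids,
        columns=list(TRAIT_NAMES),
    )
    values: dict[str, np.ndarray] = {}
    for t in TRAIT_NAMES:
        noise = rng_noise.normal(0.0, config.residual_sd[t], size=n)
        age_vec = np.array([age_eff[t][a] for a in age])
        sire_vec = np.array([sire_eff[t][s] for s in sire])
        values[t] = (
            config.baselines[t] + applied[t].to_numpy() + age_vec + sire_vec + noise
        )
    frame = pd.DataFrame({"age": age, "sire": sire, **values}, index=gm.individual_ids)
    truth = SimTruth(
        diplotypes=list(diplotypes),
        age=age,
        sire=sire,
        age_effects=age_eff,
        sire_effects=sire_eff,
        applied_effects=applied,
    )
    return TraitTable(frame), truth


def simulate_dataset(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Convenience wrapper: genotypes + traits as a joined :class:`Dataset`."""
    gm, diplotypes = generate_population(config)
    traits, truth = simulate_traits(gm, diplotypes, config)
    return Dataset(gm, traits), truth
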