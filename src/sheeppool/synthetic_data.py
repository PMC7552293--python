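"""Synthetic multi-breed populations, growth traits, and two-locus genotypes.

Generates the three kinds of input the analysis pipeline consumes:

* diploid single-locus genotypes drawn under Hardy–Weinberg equilibrium with
  breed-specific deletion-allele frequencies (the sampling frame of a
  multi-breed indel screen, where the variant is rare: MAF ~ 0.007–0.011);
* growth-trait tables with a configurable carrier effect and deliberately
  non-Gaussian noise (body-measurement data in livestock routinely fail
  normality screens, which is what forces the rank-based association test);
* unphased two-locus genotype pairs with a controllable Lewontin D', for
  exercising EM haplotype-frequency estimation and LD classification.

Genotypes are coded 0/1/2 copies of the deletion allele (II/ID/DD).
All draws are deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "TraitSpec",
    "TwoLocusSpec",
    "NOISE_FAMILIES",
    "generate_population",
    "generate_traits",
    "generate_two_locus",
    "two_locus_haplotype_freqs",
    "tan_sheep_population_spec",
    "tan_sheep_trait_specs",
]

NOISE_FAMILIES = ("skewed", "heavy-tailed", "normal")

# lognormal sigma for the skewed family; gives skewness ~1.75, enough that a
# normality screen at n in the hundreds rejects essentially always
_LOGNORMAL_SIGMA = 0.5


@dataclass(frozen=True)
class PopulationSpec:
    """Breed sizes and per-breed deletion-allele frequencies.

    ``maf`` may be a single frequency applied to every breed or a mapping
    breed -> frequency; every frequency must lie in [0, 0.5].  ``sex_counts``
    optionally fixes the (ram, ewe) split per breed; otherwise sex is
    Bernoulli(0.5).
    """

    breed_sizes: Mapping[str, int]
    maf: Mapping[str, float] | float
    seed: int
    sex_counts: Mapping[str, tuple[int, int]] | None = None

    def maf_for(self, breed: str) -> float:
        if isinstance(self.maf, Mapping):
            return float(self.maf[breed])
        return float(self.maf)

    def __post_init__(self) -> None:
        if not self.breed_sizes:
            raise ValueError("breed_sizes is empty")
        for breed, n in self.breed_sizes.items():
            if n < 1:
                raise ValueError(f"breed {breed!r}: count must be >= 1, got {n}")
            f = self.maf_for(breed)
            if not 0.0 <= f <= 0.5:
                raise ValueError(
                    f"breed {breed!r}: allele frequency must lie in [0, 0.5], got {f}"
                )
            if self.sex_counts is not None and breed in self.sex_counts:
                rams, ewes = self.sex_counts[breed]
                if rams + ewes != n:
                    raise ValueError(
                        f"breed {breed!r}: sex counts {rams}+{ewes} != size {n}"
                    )


@dataclass(frozen=True)
class TraitSpec:
    """Trait panel: per-trait baseline (location, scale) and carrier effect.

    The carrier effect is dominant: heterozygous and deletion-homozygous
    animals are shifted by ``genotype_effect[trait]`` (at realistic deletion
    frequencies no DD animals appear, so this is effectively an ID shift).
    ``noise_family``: "skewed" (shifted lognormal, the default), "heavy-tailed"
    (scaled t with 3 df) or "normal"; all standardized to mean 0, variance 1
    before scaling.
    """

    trait_names: tuple[str, ...]
    baseline: Mapping[str, tuple[float, float]]
    genotype_effect: Mapping[str, float]
    noise_family: str = "skewed"

    def __post_init__(self) -> None:
        if len(set(self.trait_names)) != len(self.trait_names):
            raise ValueError("trait labels must be unique")
        if self.noise_family not in NOISE_FAMILIES:
            raise ValueError(
                f"unknown noise_family {self.noise_family!r}; "
                f"expected one of {NOISE_FAMILIES}"
            )
        for t in self.trait_names:
            loc, scale = self.baseline[t]
            if scale <= 0:
                raise ValueError(f"trait {t!r}: scale must be > 0, got {scale}")


@dataclass(frozen=True)
class TwoLocusSpec:
    """Two biallelic loci with allele frequencies ``p_a``, ``p_b`` and target |D'|."""

    p_a: float
    p_b: float
    d_prime: float
    n: int
    seed: int

    def __post_init__(self) -> None:
        for name, f in (("p_a", self.p_a), ("p_b", self.p_b)):
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {f}")
        if not 0.0 <= self.d_prime <= 1.0:
            raise ValueError(f"d_prime must lie in [0, 1], got {self.d_prime}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw one diploid genotype per individual under Hardy–Weinberg.

    Returns a DataFrame with columns ``id, breed, sex, genotype`` where
    genotype is the 0/1/2 deletion-allele dosage drawn with probabilities
    ((1-p)^2, 2p(1-p), p^2) for the individual's breed.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for breed, n in spec.breed_sizes.items():
        p = spec.maf_for(breed)
        probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        geno = rng.choice(3, size=n, p=probs)
        if spec.sex_counts is not None and breed in spec.sex_counts:
            rams, ewes = spec.sex_counts[breed]
            sex = np.array(["ram"] * rams + ["ewe"] * ewes)
            rng.shuffle(sex)
        else:
            sex = np.where(rng.random(n) < 0.5, "ram", "ewe")
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{breed}_{i:05d}" for i in range(n)],
                    "breed": breed,
                    "sex": sex,
                    "genotype": geno.astype(np.int64),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _standardized_noise(rng: np.random.Generator, family: str, size: int) -> np.ndarray:
    if family == "normal":
        return rng.standard_normal(size)
    if family == "skewed":
        s = _LOGNORMAL_SIGMA
        raw = np.exp(s * rng.standard_normal(size))
        mean = np.exp(s**2 / 2)
        sd = np.sqrt((np.exp(s**2) - 1) * np.exp(s**2))
        return (raw - mean) / sd
    if family == "heavy-tailed":
        return rng.standard_t(3, size) / np.sqrt(3.0)  # t(3) variance is 3
    raise ValueError(f"unknown noise_family {family!r}")


def generate_traits(
    genotypes: pd.DataFrame,
    spec: TraitSpec | Mapping[str, TraitSpec],
    seed: int,
) -> pd.DataFrame:
    """Attach trait columns to a genotype table.

    ``spec`` is either one TraitSpec for everybody or a mapping sex -> TraitSpec
    (keys "ram"/"ewe") for per-sex baselines and effects.  Trait value =
    baseline location + carrier effect (genotype >= 1) + scale * noise.
    """
    if genotypes["genotype"].isna().any():
        raise ValueError("every individual needs a genotype before traits are drawn")
    by_sex = isinstance(spec, Mapping)
    specs: dict[str, TraitSpec]
    if by_sex:
        specs = dict(spec)
        names = next(iter(specs.values())).trait_names
        for s in specs.values():
            if s.trait_names != names:
                raise ValueError("per-sex TraitSpecs must share one trait panel")
    else:
        specs = {}
        names = spec.trait_names

    rng = np.random.default_rng(seed)
    out = genotypes.loc[:, ["id", "breed", "sex", "genotype"]].copy()
    carrier = (out["genotype"].to_numpy() >= 1).astype(float)
    sex_arr = out["sex"].to_numpy()
    n = len(out)
    for trait in names:
        vals = np.empty(n)
        if by_sex:
            # one noise draw per individual regardless of stratum order
            noise_by_fam = {
                fam: _standardized_noise(rng, fam, n)
                for fam in {s.noise_family for s in specs.values()}
            }
            for sex, s in specs.items():
                mask = sex_arr == sex
                loc, scale = s.baseline[trait]
                eff = s.genotype_effect.get(trait, 0.0)
                vals[mask] = (
                    loc
                    + eff * carrier[mask]
                    + scale * noise_by_fam[s.noise_family][mask]
                )
            unknown = ~np.isin(sex_arr, list(specs))
            if unknown.any():
                raise ValueError(
                    f"no TraitSpec for sex value(s) {sorted(set(sex_arr[unknown]))}"
                )
        else:
            loc, scale = spec.baseline[trait]
            eff = spec.genotype_effect.get(trait, 0.0)
            vals = loc + eff * carrier + scale * _standardized_noise(
                rng, spec.noise_family, n
            )
        out[trait] = vals
    return out


def two_locus_haplotype_freqs(spec: TwoLocusSpec) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) implied by the spec.

    A/B denote the variant allele at each locus.  ``p_AB = p_a p_b + D`` with
    ``D = d_prime * D_max`` and ``D_max = min(p_a (1-p_b), (1-p_a) p_b)``
    (the Lewontin bound for positive association).
    """
    pa, pb = spec.p_a, spec.p_b
    d_max = min(pa * (1 - pb), (1 - pa) * pb)
    d = spec.d_prime * d_max
    h = np.array(
        [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d, (1 - pa) * (1 - pb) + d]
    )
    if (h < -1e-12).any():
        raise ValueError(
            f"d_prime={spec.d_prime} infeasible at (p_a={pa}, p_b={pb}); "
            f"|D| must not exceed D_max={d_max:.6g}"
        )
    return np.clip(h, 0.0, None) / h.sum()


def generate_two_locus(spec: TwoLocusSpec) -> pd.DataFrame:
    """Unphased two-locus genotypes from random union of haplotypes.

    Each individual receives two haplotypes drawn independently from the
    spec's haplotype distribution; the table reports the per-locus variant
    dosage (columns ``id, locus1, locus2``), i.e. phase is discarded.
    """
    h = two_locus_haplotype_freqs(spec)
    rng = np.random.default_rng(spec.seed)
    # haplotypes indexed 0..3 = (AB, Ab, aB, ab); allele content by index
    hap_a = np.array([1, 1, 0, 0])
    hap_b = np.array([1, 0, 1, 0])
    pair = rng.choice(4, size=(spec.n, 2), p=h)
    return pd.DataFrame(
        {
            "id": [f"ind_{i:05d}" for i in range(spec.n)],
            "locus1": hap_a[pair].sum(axis=1).astype(np.int64),
            "locus2": hap_b[pair].sum(axis=1).astype(np.int64),
        }
    )


def tan_sheep_population_spec(seed: int = 0) -> PopulationSpec:
    """The seven-breed sampling frame of the motivating indel screen.

    Breed sizes and deletion-allele frequencies match the published cohort
    (2350 animals; four polymorphic breeds with MAF 0.007–0.011, three
    monomorphic); the Tan sheep sex split is fixed at 458 rams / 449 ewes.
    """
    return PopulationSpec(
        breed_sizes={
            "TS": 907,
            "LXBH": 629,
            "STHS": 190,
            "LFTS": 49,
            "HS": 201,
            "SS": 48,
            "AUW": 326,
        },
        maf={
            "TS": 0.007,
            "LXBH": 0.011,
            "STHS": 0.008,
            "LFTS": 0.010,
            "HS": 0.0,
            "SS": 0.0,
            "AUW": 0.0,
        },
        seed=seed,
        sex_counts={"TS": (458, 449)},
    )


# Growth panel defaults: locations are the published wild-type arm means; the
# scale is the published arm standard error rescaled to a per-animal SD
# (SE * sqrt(n_wild)); carrier effects are the published arm-mean differences.
_TAN_RAMS = {
    "BW": (33.71, 0.11, -0.68),
    "BH": (65.04, 0.15, -2.37),
    "BL": (64.85, 0.21, -3.63),
    "HHC": (62.52, 0.14, -1.96),
    "PG": (78.78, 0.19, -0.45),
    "CD": (26.54, 0.11, -1.88),
    "CW": (20.74, 0.09, -0.18),
    "CC": (8.14, 0.03, 0.19),
}
_TAN_EWES = {
    "BW": (33.33, 0.10, 0.15),
    "BH": (63.74, 0.15, -1.99),
    "BL": (65.12, 0.22, -1.12),
    "HHC": (61.94, 0.14, -0.94),
    "PG": (79.83, 0.18, -0.58),
    "CD": (26.42, 0.10, -0.92),
    "CW": (21.01, 0.09, 1.74),
    "CC": (8.03, 0.03, -0.03),
}


def _trait_spec_from(table: dict, n_arm: int, noise_family: str) -> TraitSpec:
    names = tuple(table)
    sqrt_n = float(np.sqrt(n_arm))
    return TraitSpec(
        trait_names=names,
        baseline={t: (loc, se * sqrt_n) for t, (loc, se, _) in table.items()},
        genotype_effect={t: eff for t, (_, _, eff) in table.items()},
        noise_family=noise_family,
    )


def tan_sheep_trait_specs(noise_family: str = "skewed") -> dict[str, TraitSpec]:
    """Per-sex trait specs emulating the Tan sheep growth panel (units kg/cm)."""
    return {
        "ram": _trait_spec_from(_TAN_RAMS, 449, noise_family),
        "ewe": _trait_spec_from(_TAN_EWES, 445, noise_family),
    }
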