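import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sheeppool.synthetic_data import (
    PopulationSpec,
    TraitSpec,
    TwoLocusSpec,
    generate_population,
    generate_traits,
    generate_two_locus,
    tan_sheep_population_spec,
    tan_sheep_trait_specs,
    two_locus_haplotype_freqs,
)


class TestGeneratePopulation:
    def test_rare_allele_heterozygote_count_matches_expectation(self):
        """n=907 at MAF 0.007 should yield ~12.6 heterozygotes (the cohort
        observed 13), within binomial sampling error across seeds."""
        expect = 907 * 2 * 0.007 * 0.993
        sd = np.sqrt(907 * 2 * 0.007 * 0.993 * (1 - 2 * 0.007 * 0.993))
        for seed in range(10):
            pop = generate_population(
                PopulationSpec(breed_sizes={"TS": 907}, maf=0.007, seed=seed)
            )
            hets = (pop["genotype"] == 1).sum()
            assert abs(hets - expect) <= 4 * sd

    def test_zero_maf_is_monomorphic(self):
        pop = generate_population(
            PopulationSpec(breed_sizes={"HS": 201}, maf=0.0, seed=3)
        )
        assert (pop["genotype"] == 0).all()

    def test_half_maf_genotype_proportions(self):
        n = 100_000
        pop = generate_population(
            PopulationSpec(breed_sizes={"X": n}, maf=0.5, seed=7)
        )
        props = pop["genotype"].value_counts(normalize=True)
        for code, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(props[code] - expected) <= 3 * se

    def test_hardy_weinberg_chi2_not_rejected(self):
        """Goodness of fit on 1e5 draws at alpha=0.001 across seeds."""
        p = 0.3
        probs = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        for seed in range(8):
            pop = generate_population(
                PopulationSpec(breed_sizes={"X": 100_000}, maf=p, seed=seed)
            )
            obs = pop["genotype"].value_counts().reindex([0, 1, 2], fill_value=0)
            chi2 = stats.chisquare(obs, 100_000 * probs)
            assert chi2.pvalue > 0.001

    def test_same_seed_byte_identical(self):
        spec = tan_sheep_population_spec(seed=99)
        a = generate_population(spec).to_csv(index=False)
        b = generate_population(spec).to_csv(index=False)
        assert a == b

    def test_fixed_sex_counts(self, seven_breed_population):
        ts = seven_breed_population[seven_breed_population["breed"] == "TS"]
        assert (ts["sex"] == "ram").sum() == 458
        assert (ts["sex"] == "ewe").sum() == 449

    def test_invalid_frequency_names_breed(self):
        with pytest.raises(ValueError, match="LXBH"):
            PopulationSpec(breed_sizes={"LXBH": 10}, maf=0.7, seed=0)


class TestGenerateTraits:
    @pytest.fixture()
    def carriers_population(self) -> pd.DataFrame:
        n = 2000
        return pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(n)],
                "breed": "TS",
                "sex": np.where(np.arange(n) % 2 == 0, "ram", "ewe"),
                "genotype": np.where(np.arange(n) < n // 2, 1, 0),
            }
        )

    def test_null_effect_arms_agree_in_law(self, carriers_population):
        spec = TraitSpec(
            trait_names=("BL",),
            baseline={"BL": (64.85, 4.45)},
            genotype_effect={"BL": 0.0},
            noise_family="skewed",
        )
        traits = generate_traits(carriers_population, spec, seed=4)
        wild = traits.loc[traits["genotype"] == 0, "BL"]
        carr = traits.loc[traits["genotype"] == 1, "BL"]
        assert stats.ks_2samp(wild, carr).pvalue > 0.01

    def test_carrier_shift_recovers_effect(self, carriers_population):
        spec = TraitSpec(
            trait_names=("BL",),
            baseline={"BL": (64.85, 4.45)},
            genotype_effect={"BL": -3.6},
            noise_family="skewed",
        )
        traits = generate_traits(carriers_population, spec, seed=4)
        diff = (
            traits.loc[traits["genotype"] == 1, "BL"].mean()
            - traits.loc[traits["genotype"] == 0, "BL"].mean()
        )
        se = 4.45 * np.sqrt(2 / 1000)
        assert diff == pytest.approx(-3.6, abs=3 * se)

    @pytest.mark.parametrize("family", ["skewed", "heavy-tailed"])
    def test_non_normal_families_fail_normality_screen(self, family):
        """The generator's non-Gaussian noise must be detectably non-normal
        at the cohort's arm size, otherwise the rank-test pathway would
        never be exercised: KS rejects in >=90% of 200 replicates."""
        from sheeppool.association import ks_normality

        rng_seeds = range(200)
        spec = TraitSpec(
            trait_names=("T",),
            baseline={"T": (0.0, 1.0)},
            genotype_effect={},
            noise_family=family,
        )
        pop = pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(449)],
                "breed": "TS",
                "sex": "ram",
                "genotype": 0,
            }
        )
        rejections = sum(
            ks_normality(generate_traits(pop, spec, seed=s)["T"]).p_value < 0.05
            for s in rng_seeds
        )
        assert rejections >= 180

    def test_per_sex_specs(self, carriers_population):
        traits = generate_traits(
            carriers_population, tan_sheep_trait_specs("normal"), seed=5
        )
        rams = traits.loc[(traits["sex"] == "ram") & (traits["genotype"] == 0), "BW"]
        ewes = traits.loc[(traits["sex"] == "ewe") & (traits["genotype"] == 0), "BW"]
        assert rams.mean() == pytest.approx(33.71, abs=0.5)
        assert ewes.mean() == pytest.approx(33.33, abs=0.5)

    def test_unknown_noise_family_rejected(self):
        with pytest.raises(ValueError, match="noise_family"):
            TraitSpec(
                trait_names=("T",),
                baseline={"T": (0, 1)},
                genotype_effect={},
                noise_family="cauchy",
            )

    def test_deterministic_given_seed(self, carriers_population):
        spec = tan_sheep_trait_specs()
        a = generate_traits(carriers_population, spec, seed=8).to_csv(index=False)
        b = generate_traits(carriers_population, spec, seed=8).to_csv(index=False)
        assert a == b


class TestGenerateTwoLocus:
    def test_equilibrium_haplotypes_are_products(self):
        spec = TwoLocusSpec(p_a=0.2, p_b=0.4, d_prime=0.0, n=10, seed=0)
        h = two_locus_haplotype_freqs(spec)
        assert h == pytest.approx([0.08, 0.12, 0.32, 0.48])

    def test_empirical_haplotypes_converge(self):
        spec = TwoLocusSpec(p_a=0.3, p_b=0.2, d_prime=0.5, n=100_000, seed=11)
        h = two_locus_haplotype_freqs(spec)
        # with full coupling information unavailable, check the dosage means
        df = generate_two_locus(spec)
        p_a_hat = df["locus1"].mean() / 2
        p_b_hat = df["locus2"].mean() / 2
        se_a = np.sqrt(0.3 * 0.7 / (2 * spec.n))
        se_b = np.sqrt(0.2 * 0.8 / (2 * spec.n))
        assert abs(p_a_hat - 0.3) <= 3 * se_a
        assert abs(p_b_hat - 0.2) <= 3 * se_b
        # covariance of dosages estimates 2D
        d = h[0] - 0.3 * 0.2
        cov = np.cov(df["locus1"], df["locus2"])[0, 1]
        assert cov == pytest.approx(2 * d, abs=0.005)

    def test_infeasible_d_prime_states_bound(self):
        # d_prime > 1 is rejected by the spec itself
        with pytest.raises(ValueError, match="d_prime"):
            TwoLocusSpec(p_a=0.1, p_b=0.5, d_prime=1.2, n=10, seed=0)

    def test_deterministic_given_seed(self):
        spec = TwoLocusSpec(p_a=0.1, p_b=0.2, d_prime=0.3, n=500, seed=21)
        assert generate_two_locus(spec).equals(generate_two_locus(spec))
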