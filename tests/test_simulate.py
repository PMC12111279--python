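"""Synthetic-population generator: pedigrees, gene dropping, phenotypes,
foaling histories, and their statistical structure."""

import numpy as np
import pytest

import equifert as eq
from equifert.pedigree import FEMALE, UNKNOWN
from equifert.simulate import (
    ConfigError,
    FixedEffectSpec,
    FoalingParams,
    gene_drop,
    simulate_foaling_histories,
)
from conftest import make_pedigree


def null_effects():
    """Fixed-effect spec with every true effect zeroed."""
    return FixedEffectSpec(
        inb_slope=0.0,
        age_slope=0.0,
        class_levels={
            "ancestral_origin": [0.0, 0.0],
            "geo_zone": [0.0, 0.0, 0.0],
            "stud_size": [0.0, 0.0, 0.0],
        },
    )


class TestPedigree:
    def test_smallest_mating(self):
        cfg = eq.SimConfig(n_founders=2, n_generations=1, offspring_per_mating=1,
                           n_snps=1, prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        assert ped.n == 3
        assert ped.sire[2] != UNKNOWN and ped.dam[2] != UNKNOWN

    def test_parents_precede_offspring(self):
        cfg = eq.SimConfig(n_founders=20, n_generations=8, n_snps=1, seed=9,
                           prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        idx = np.arange(ped.n)
        for par in (ped.sire, ped.dam):
            known = par != UNKNOWN
            assert np.all(par[known] < idx[known])
        # unknown parents only among founders
        non_founder = ~ped.is_founder
        assert np.all(ped.sire[non_founder] != UNKNOWN)
        # roughly half of each generation female overall
        assert 0.4 < (ped.sex == FEMALE).mean() < 0.6

    def test_determinism(self):
        cfg = eq.SimConfig(n_founders=30, n_generations=4, n_snps=50, seed=77)
        a = eq.simulate_dataset(cfg)
        b = eq.simulate_dataset(eq.SimConfig(n_founders=30, n_generations=4,
                                             n_snps=50, seed=77))
        assert np.array_equal(a[0].sire, b[0].sire)
        assert np.array_equal(a[1].dosages, b[1].dosages, equal_nan=True)
        assert a[3].equals(b[3])
        assert [h.foaling_ages for h in a[2]] == [h.foaling_ages for h in b[2]]

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            eq.SimConfig(n_founders=1)
        with pytest.raises(ConfigError):
            eq.SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigError):
            eq.SimConfig(traits=("FN",), sigma_a2={"FN": -1.0}, sigma_e2={"FN": 1.0})
        with pytest.raises(ConfigError):
            eq.SimConfig(traits=("FN", "RE"),
                         genetic_correlations=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGenotypes:
    def test_founder_mean_dosage_binomial(self):
        # founders only, MAF pinned at 0.5: mean dosage 1 within 3 SE
        n, m = 200, 10000
        sexes = np.array([0, 1] * (n // 2))
        ped = eq.Pedigree(sire=np.full(n, -1), dam=np.full(n, -1), sex=sexes)
        cfg = eq.SimConfig(n_founders=n, n_generations=1, n_snps=m,
                           maf_range=(0.5, 0.5), seed=4, prop_genotyped=0)
        geno = eq.simulate_genotypes(ped, cfg)
        se = np.sqrt(2 * 0.25 / (n * m))
        assert abs(geno.dosages.mean() - 1.0) < 3 * se

    def test_mendelian_forcing(self):
        # both parents homozygous alt -> offspring must be too
        ped = make_pedigree([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        founder_haps = np.ones((2, 2, 100), dtype=np.int8)
        H = gene_drop(ped, founder_haps, np.random.default_rng(0))
        assert np.all(H[2].sum(axis=0) == 2)

    def test_full_sib_genomic_relationship(self):
        # centered-dosage correlation between full sibs ~ 0.5
        # many independent sib pairs, each from its own founder couple;
        # centering uses the known base frequency (MAF pinned at 0.5)
        triples, sexes = [], []
        for f in range(40):
            s, d = 1 + 4 * f, 2 + 4 * f  # 1-based ids of the couple
            triples += [(s, 0, 0), (d, 0, 0), (s + 2, s, d), (d + 2, s, d)]
            sexes += [0, 1, 0, 1]
        ped = make_pedigree(triples, sex=sexes)
        cfg = eq.SimConfig(n_founders=80, n_generations=1, n_snps=4000,
                           maf_range=(0.5, 0.5), seed=12, prop_genotyped=0)
        geno = eq.simulate_genotypes(ped, cfg)
        Z = geno.dosages - 1.0
        corrs = []
        for f in range(40):
            z1, z2 = Z[4 * f + 2], Z[4 * f + 3]
            corrs.append((z1 @ z2) / np.sqrt((z1 @ z1) * (z2 @ z2)))
        assert np.mean(corrs) == pytest.approx(0.5, abs=0.05)

    def test_genomic_regresses_to_pedigree_with_more_snps(self, small_dataset):
        cfg, (ped, _, _, _, _) = small_dataset
        A = eq.build_A(ped)
        devs = []
        for m in (200, 3200):
            c = eq.SimConfig(n_founders=cfg.n_founders, n_generations=cfg.n_generations,
                             n_snps=m, seed=31, prop_genotyped=0)
            g = eq.simulate_genotypes(ped, c)
            gm = eq.GenotypeMatrix(dosages=g.dosages, animal_index=g.animal_index)
            G = eq.build_G(gm, A, blend=1.0)
            off = ~np.eye(ped.n, dtype=bool)
            devs.append(np.abs(G - A)[off].mean())
        assert devs[1] < devs[0]


class TestPhenotypes:
    def test_noise_free_limit_recovers_breeding_values(self):
        cfg = eq.SimConfig(n_founders=40, n_generations=2, n_snps=1, seed=3,
                           traits=("FN",), sigma_a2={"FN": 1.0},
                           sigma_e2={"FN": 1e-12}, fixed_effects=null_effects(),
                           prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        table, truth = eq.simulate_phenotypes(ped, cfg)
        idx = table["animal"].to_numpy()
        assert table["FN"].to_numpy() == pytest.approx(
            truth.breeding_values[idx, 0], abs=1e-4
        )

    def test_founder_breeding_value_variance(self):
        cfg = eq.SimConfig(n_founders=4000, n_generations=1, n_snps=1, seed=8,
                           traits=("FN",), sigma_a2={"FN": 0.835},
                           sigma_e2={"FN": 5.289}, prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        _, truth = eq.simulate_phenotypes(ped, cfg)
        founders = ped.is_founder
        v = truth.breeding_values[founders, 0].var()
        se = 0.835 * np.sqrt(2.0 / founders.sum())
        assert abs(v - 0.835) < 3 * se

    def test_parent_offspring_regression_half_h2(self):
        # dam-daughter phenotypic regression ~ h2/2 under the additive model
        h2 = 0.25
        cfg = eq.SimConfig(n_founders=1000, n_generations=4, offspring_per_mating=3,
                           n_snps=1, seed=15, traits=("FN",),
                           sigma_a2={"FN": h2}, sigma_e2={"FN": 1 - h2},
                           fixed_effects=null_effects(), prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        table, _ = eq.simulate_phenotypes(ped, cfg)
        y = np.full(ped.n, np.nan)
        y[table["animal"]] = table["FN"]
        daughters = np.flatnonzero((ped.sex == FEMALE) & (ped.dam != UNKNOWN))
        yd, ym = y[daughters], y[ped.dam[daughters]]
        keep = np.isfinite(yd) & np.isfinite(ym)
        slope = np.polyfit(ym[keep], yd[keep], 1)[0]
        assert keep.sum() > 4500
        assert slope == pytest.approx(h2 / 2, abs=0.04)

    def test_genetic_correlation_recovered(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        cfg = eq.SimConfig(n_founders=5000, n_generations=1, n_snps=1, seed=23,
                           traits=("FN", "RE"), sigma_a2={"FN": 0.835, "RE": 49.31},
                           sigma_e2={"FN": 5.289, "RE": 167.8},
                           genetic_correlations=corr, prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        _, truth = eq.simulate_phenotypes(ped, cfg)
        r = np.corrcoef(truth.breeding_values[:, 0], truth.breeding_values[:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_sex_limited_recording(self, small_dataset):
        cfg, (ped, _, _, table, _) = small_dataset
        assert np.all(ped.sex[table["animal"]] == FEMALE)

    def test_diag_A_matches_realized_F(self, small_dataset, small_matrices):
        _, (ped, _, _, _, truth) = small_dataset
        A = small_matrices["A"]
        assert np.abs((np.diag(A) - 1.0) - truth.realized_F).max() < 1e-12


class TestFoalingHistories:
    def test_deterministic_yearly_schedule(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0)], sex=[0, 1])
        params = FoalingParams(first_age_mean=48, first_age_sd=0, foaling_prob=1.0,
                               gap_jitter=0, window_mean=60, window_sd=0,
                               prop_active=0.0)
        (h,) = simulate_foaling_histories(ped, params)
        assert len(h.foaling_ages) == 6  # foaling at 48 plus one per year for 5 years
        assert h.foaling_ages == [48, 60, 72, 84, 96, 108]

    def test_histories_valid_and_gaps_bounded(self, small_dataset):
        cfg, (ped, _, histories, _, _) = small_dataset
        assert len(histories) == ped.females.size
        for h in histories:
            gaps = np.diff(h.foaling_ages)
            assert np.all(gaps >= 9.0)
            if h.culling_age is not None:
                assert h.culling_age >= h.foaling_ages[-1]

    def test_single_foaling_traits_undefined(self):
        ped = make_pedigree([(1, 0, 0), (2, 0, 0)], sex=[0, 1])
        params = FoalingParams(first_age_mean=48, first_age_sd=0, foaling_prob=1e-9,
                               window_mean=200, window_sd=0, prop_active=0.0)
        (h,) = simulate_foaling_histories(ped, params)
        row = eq.derive_traits(h)
        assert row["FN"] == 1
        assert np.isnan(row["AIF"]) and np.isnan(row["IF12"])
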