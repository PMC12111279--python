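"""REML variance components, reliabilities, and their degeneracies."""

import numpy as np
import pandas as pd
import pytest

import equifert as eq
from equifert.mme import ModelSpec, build_design
from equifert.reml import VarianceComponents, blup_evaluate, reml_loglik
from conftest import make_pedigree
from oracles import eigen_reml_oracle


def no_fixed_spec(traits=("y",)):
    return ModelSpec(traits=traits, covariates={t: () for t in traits},
                     class_effects=(), intercept=False)


@pytest.fixture(scope="module")
def reml_dataset():
    cfg = eq.SimConfig(n_founders=120, n_generations=3, n_snps=400, seed=6,
                       traits=("FN",), sigma_a2={"FN": 0.25},
                       sigma_e2={"FN": 0.75}, prop_genotyped=0.25)
    ped, geno, hist, table, truth = eq.simulate_dataset(cfg)
    A = eq.build_A(ped)
    F = eq.inbreeding(ped)
    Ainv = eq.build_Ainv(ped, F)
    return ped, table, A, F, Ainv


class TestEstimation:
    def test_matches_eigen_profile_oracle(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        spec = ModelSpec.default(("FN",))
        fit = eq.estimate_reml(spec, table, Ainv, K=A, F=F,
                               compute_reliability=False)
        rec = table["animal"].to_numpy()
        X, _ = build_design(table, spec, "FN")
        sa2, se2 = eigen_reml_oracle(table["FN"].to_numpy(), X,
                                     A[np.ix_(rec, rec)])
        assert fit.vc.G0[0, 0] == pytest.approx(sa2, rel=1e-5)
        assert fit.vc.R0[0, 0] == pytest.approx(se2, rel=1e-5)
        assert fit.converged

    def test_em_and_ai_reach_same_optimum(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        spec = ModelSpec.default(("FN",))
        ai = eq.estimate_reml(spec, table, Ainv, K=A, compute_reliability=False)
        em = eq.estimate_reml(spec, table, Ainv, K=A, method="em",
                              tol=1e-10, max_iter=5000, compute_reliability=False)
        assert ai.vc.G0[0, 0] == pytest.approx(em.vc.G0[0, 0], abs=1e-6)
        assert ai.vc.R0[0, 0] == pytest.approx(em.vc.R0[0, 0], abs=1e-6)

    def test_loglik_at_estimate_beats_truth(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        spec = ModelSpec.default(("FN",))
        fit = eq.estimate_reml(spec, table, Ainv, K=A, compute_reliability=False)
        ll_est = reml_loglik(spec, table, Ainv, fit.vc)
        ll_truth = reml_loglik(
            spec, table, Ainv,
            VarianceComponents.single(0.25, 0.75, "FN"),
        )
        assert ll_est >= ll_truth - 1e-6
        # the iteration trace itself is (weakly) increasing at the end
        assert fit.loglik >= fit.loglik_trace[0]

    def test_null_heritability_hits_boundary(self):
        cfg = eq.SimConfig(n_founders=150, n_generations=3, n_snps=1, seed=45,
                           traits=("FN",), sigma_a2={"FN": 1e-6},
                           sigma_e2={"FN": 1.0}, prop_genotyped=0)
        ped = eq.simulate_pedigree(cfg)
        table, _ = eq.simulate_phenotypes(ped, cfg)
        spec = ModelSpec.intercept_only(("FN",))
        Ainv = eq.build_Ainv(ped)
        fit = eq.estimate_reml(spec, table, Ainv, compute_reliability=False,
                               max_iter=200)
        assert fit.boundary
        assert fit.vc.G0[0, 0] < 0.02 * np.nanvar(table["FN"])

    def test_multitrait_diagonal_equals_single_trait_fits(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        # second synthetic trait from an independent simulation seed
        rng = np.random.default_rng(99)
        t2 = table.copy()
        t2["Z2"] = rng.standard_normal(len(table))
        traits = ("FN", "Z2")
        spec = ModelSpec(traits=traits,
                         covariates={"FN": ("inbreeding",), "Z2": ("inbreeding",)},
                         class_effects=())
        joint = eq.estimate_reml(spec, t2, Ainv, K=A, compute_reliability=False,
                                 constrain_diagonal=True,
                                 start=VarianceComponents(
                                     G0=np.diag([0.2, 0.2]), R0=np.diag([0.8, 0.8]),
                                     traits=traits))
        for j, tr in enumerate(traits):
            single = eq.estimate_reml(
                ModelSpec(traits=(tr,), covariates={tr: ("inbreeding",)},
                          class_effects=()),
                t2, Ainv, K=A, compute_reliability=False,
                start=VarianceComponents.single(0.2, 0.8, tr))
            assert joint.vc.G0[j, j] == pytest.approx(
                single.vc.G0[0, 0], abs=2e-5), tr
            assert joint.vc.R0[j, j] == pytest.approx(
                single.vc.R0[0, 0], abs=2e-5), tr

    def test_reported_standard_errors_finite(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        fit = eq.estimate_reml(ModelSpec.default(("FN",)), table, Ainv, K=A,
                               compute_reliability=False)
        assert np.isfinite(fit.vc_se["h2_se"][0])
        assert 0 < fit.vc_se["h2_se"][0] < 0.5


class TestReliability:
    def test_zero_pev_gives_full_reliability(self):
        r2, clipped = eq.reliability(np.array([[0.0]]), [0.5], F=np.array([0.1]))
        assert r2[0, 0] == 1.0 and clipped == 0

    def test_unrelated_unrecorded_founder_has_zero_reliability(self):
        # animal 0 recorded; animal 1 an unrelated founder without records
        ped = make_pedigree([(1, 0, 0), (2, 0, 0)], sex=[1, 1])
        table = pd.DataFrame({"animal": [0], "y": [1.3]})
        vc = VarianceComponents.single(0.4, 0.6, "y")
        fit = blup_evaluate(no_fixed_spec(), table, eq.build_Ainv(ped), vc,
                            F=np.zeros(2))
        assert fit.pev[1, 0] == pytest.approx(0.4, abs=1e-12)
        assert fit.r2[1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_record_reliability_equals_h2(self):
        # no relatives, fixed effects known: classic r2 = h2
        ped = make_pedigree([(1, 0, 0)], sex=[1])
        sa2, se2 = 0.25, 0.75
        table = pd.DataFrame({"animal": [0], "y": [0.7]})
        fit = blup_evaluate(no_fixed_spec(), table, eq.build_Ainv(ped),
                            VarianceComponents.single(sa2, se2, "y"),
                            F=np.zeros(1))
        assert fit.r2[0, 0] == pytest.approx(sa2 / (sa2 + se2), abs=1e-12)

    def test_pev_within_theoretical_bounds(self, reml_dataset):
        ped, table, A, F, Ainv = reml_dataset
        vc = VarianceComponents.single(0.25, 0.75, "FN")
        fit = blup_evaluate(ModelSpec.default(("FN",)), table, Ainv, vc, F=F)
        ub = (1.0 + F) * 0.25
        assert np.all(fit.pev[:, 0] > 0)
        assert np.all(fit.pev[:, 0] <= ub + 1e-10)
        assert np.all((fit.r2 >= 0) & (fit.r2 <= 1))

    def test_progeny_records_never_hurt_sire_reliability(self):
        # nested data: adding daughters with records to one sire
        vc = VarianceComponents.single(0.3, 0.7, "y")
        r2_prev = -1.0
        for n_prog in (1, 3, 6, 10):
            triples = [(1, 0, 0)] + [(2 + k, 0, 0) for k in range(n_prog)] \
                + [(2 + n_prog + k, 1, 2 + k) for k in range(n_prog)]
            sexes = [0] + [1] * n_prog + [1] * n_prog
            ped = make_pedigree(triples, sex=sexes)
            table = pd.DataFrame({
                "animal": np.arange(1 + n_prog, 1 + 2 * n_prog),
                "y": np.linspace(-1, 1, n_prog),
            })
            fit = blup_evaluate(no_fixed_spec(), table, eq.build_Ainv(ped), vc,
                                F=np.zeros(ped.n))
            r2_sire = fit.r2[0, 0]
            assert r2_sire > r2_prev - 1e-12
            r2_prev = r2_sire

    def test_degenerate_single_step_equals_pedigree(self, reml_dataset):
        # empty genotyped set: H^-1 is exactly A^-1, fits must agree to 1e-10
        ped, table, A, F, Ainv = reml_dataset
        spec = ModelSpec.default(("FN",))
        Hinv = eq.build_Hinv(Ainv, np.zeros((0, 0)), np.zeros((0, 0)),
                             np.array([], dtype=int))
        fit_ped = eq.estimate_reml(spec, table, Ainv, K=A, F=F)
        fit_ss = eq.estimate_reml(spec, table, Hinv, K=A, F=F)
        assert fit_ss.vc.G0[0, 0] == pytest.approx(fit_ped.vc.G0[0, 0], abs=1e-10)
        assert np.abs(fit_ss.ebv - fit_ped.ebv).max() < 1e-10
        assert np.abs(fit_ss.r2 - fit_ped.r2).max() < 1e-10
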