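"""Mixed-model engine tests."""

import numpy as np
import pandas as pd
import pytest

from mbgblup import gblup as gb
from mbgblup import popsim as ps
from mbgblup.grm import allele_frequencies, build_g1


def random_instance(rng, n=25):
    rec = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": rng.integers(1, 4, n) * 1000,
            "dam": rng.integers(1, 10, n) * 2000,
            "flock": rng.integers(1, 3, n),
            "birth_type": rng.integers(1, 3, n),
            "rear_type": rng.integers(1, 3, n),
            "sex": rng.choice(["M", "F"], n),
            "cg": rng.integers(1, 3, n),
            "age": rng.uniform(100, 300, n),
            "y": rng.normal(40, 5, n),
        }
    )
    A = rng.normal(size=(n, n + 5))
    G = A @ A.T / (n + 5) + 0.05 * np.eye(n)
    return rec, G


def gls_gbv(dm, G, vc):
    """Independent GLS oracle: ghat = sg2 G Z' V^-1 (y - X bhat)."""
    n = len(dm.y)
    V = vc["additive"] * dm.Z1 @ G @ dm.Z1.T + vc["residual"] * np.eye(n)
    if dm.W is not None:
        V += vc["maternal"] * dm.W @ dm.W.T
    if dm.Z2 is not None:
        V += vc["sire_flock"] * dm.Z2 @ dm.Z2.T
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(dm.X.T @ Vi @ dm.X, dm.X.T @ Vi @ dm.y)
    return vc["additive"] * G @ dm.Z1.T @ Vi @ (dm.y - dm.X @ b), b


class TestDesignMatrices:
    def test_animal_incidence_and_group_contrast(self):
        rec = pd.DataFrame(
            {"id": [1, 2, 3], "sire": [9, 9, 9], "dam": [5, 6, 7],
             "flock": [1, 1, 1], "cg": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]}
        )
        spec = gb.ModelSpec(fixed_factors=("cg",), covariates=(),
                            maternal=False, sire_flock=False)
        dm = gb.build_design_matrices(rec, spec)
        assert np.allclose(dm.Z1, np.eye(3))
        assert dm.X.shape == (3, 2)  # intercept + one contrast

    def test_shared_dam_column(self):
        rec = pd.DataFrame(
            {"id": [1, 2, 3], "sire": [9, 9, 9], "dam": [5, 5, 7],
             "flock": [1, 1, 1], "y": [1.0, 2.0, 3.0]}
        )
        spec = gb.ModelSpec(fixed_factors=(), covariates=(), sire_flock=False)
        dm = gb.build_design_matrices(rec, spec)
        col = dm.W[:, dm.w_ids.index(5)]
        assert col.tolist() == [1.0, 1.0, 0.0]

    def test_one_breed_covariate_for_two_breeds(self):
        rec = pd.DataFrame(
            {"id": [1, 2, 3, 4], "sire": 9, "dam": [5, 6, 7, 8], "flock": 1,
             "y": [1.0, 2.0, 3.0, 2.5]}
        )
        Q = pd.DataFrame({"MER": [1, 1, 0.5, 0.5], "BL": [0, 0, 0.5, 0.5]},
                         index=[1, 2, 3, 4])
        spec = gb.ModelSpec(fixed_factors=(), covariates=(),
                            breed_covariates=("BL",),
                            maternal=False, sire_flock=False)
        dm = gb.build_design_matrices(rec, spec, Q=Q)
        assert "breed[BL]" in dm.x_names
        assert dm.X.shape[1] == 2

    def test_aliased_columns_dropped_with_warning(self):
        rec = pd.DataFrame(
            {"id": [1, 2, 3], "sire": 9, "dam": [5, 6, 7], "flock": 1,
             "cg": ["a", "a", "a"], "y": [1.0, 2.0, 3.0]}
        )
        spec = gb.ModelSpec(fixed_factors=("cg",), covariates=(),
                            maternal=False, sire_flock=False)
        dm = gb.build_design_matrices(rec, spec)
        assert dm.dropped == [] and dm.X.shape[1] == 1  # constant factor absorbed


class TestSolveMME:
    def test_two_animal_closed_form_shrinkage(self):
        rec = pd.DataFrame({"id": [1, 2], "sire": 9, "dam": [7, 8],
                            "flock": 1, "y": [3.0, 5.0]})
        spec = gb.ModelSpec(fixed_factors=(), covariates=(),
                            maternal=False, sire_flock=False)
        dm = gb.build_design_matrices(rec, spec)
        fit = gb.solve_mme(dm, np.eye(2), {"additive": 1.0, "residual": 1.0})
        # lambda = 1: ghat_i = (y_i - ybar) / 2, exactly
        assert fit.gbv.loc[1] == pytest.approx(-0.5, abs=1e-12)
        assert fit.gbv.loc[2] == pytest.approx(0.5, abs=1e-12)

    def test_vanishing_additive_variance_shrinks_gbv_to_zero(self):
        rng = np.random.default_rng(0)
        rec, G = random_instance(rng, 15)
        spec = gb.ModelSpec()
        dm = gb.build_design_matrices(rec, spec)
        vc = {"additive": 1e-10, "residual": 3.0, "maternal": 1.0,
              "sire_flock": 0.5}
        fit = gb.solve_mme(dm, G, vc)
        assert np.abs(fit.gbv.to_numpy()).max() < 1e-6

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rec, G = random_instance(rng, n=int(rng.integers(12, 31)))
        spec = gb.ModelSpec()
        dm = gb.build_design_matrices(rec, spec)
        vc = {"additive": 2.0, "residual": 3.0, "maternal": 1.0,
              "sire_flock": 0.5}
        fit = gb.solve_mme(dm, G, vc)
        oracle, _ = gls_gbv(dm, G, vc)
        assert np.abs(fit.gbv.to_numpy() - oracle).max() < 1e-8
        assert (fit.pev >= 0).all()

    def test_shift_invariance_of_gbv(self):
        rng = np.random.default_rng(5)
        rec, G = random_instance(rng, 20)
        spec = gb.ModelSpec()
        dm = gb.build_design_matrices(rec, spec)
        vc = {"additive": 2.0, "residual": 3.0, "maternal": 1.0,
              "sire_flock": 0.5}
        fit1 = gb.solve_mme(dm, G, vc, compute_pev=False)
        rec2 = rec.assign(y=rec["y"] + 100.0)
        dm2 = gb.build_design_matrices(rec2, spec)
        fit2 = gb.solve_mme(dm2, G, vc, compute_pev=False)
        assert np.allclose(fit1.gbv, fit2.gbv, atol=1e-8)
        assert fit2.fixed_solutions["intercept"] == pytest.approx(
            fit1.fixed_solutions["intercept"] + 100.0, abs=1e-6
        )

    def test_validation_animals_without_records_get_predictions(self):
        rng = np.random.default_rng(9)
        rec, G5 = random_instance(rng, 5)
        A = rng.normal(size=(8, 12))
        G = A @ A.T / 12 + 0.05 * np.eye(8)
        spec = gb.ModelSpec(fixed_factors=(), covariates=())
        dm = gb.build_design_matrices(rec, spec, g_ids=list(range(1, 9)))
        vc = {"additive": 2.0, "residual": 3.0, "maternal": 1.0,
              "sire_flock": 0.5}
        fit = gb.solve_mme(dm, G, vc)
        assert len(fit.gbv) == 8
        assert np.isfinite(fit.gbv.loc[[6, 7, 8]]).all()


class TestEMReml:
    def test_pure_noise_stays_near_zero_heritability(self):
        rng = np.random.default_rng(1)
        n = 300
        y = rng.standard_normal(n)
        vc = gb.em_reml(y, np.ones((n, 1)), np.eye(n), max_iter=100)
        assert vc.sigma_g2 >= 0 and vc.sigma_e2 > 0
        diffs = np.diff(vc.loglik_trace)
        assert (diffs >= -1e-6).all()

    def test_likelihood_never_below_start(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 200
            A = rng.normal(size=(n, 250))
            G = A @ A.T / 250
            L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)
            vc = gb.em_reml(y, np.ones((n, 1)), G, max_iter=200)
            assert vc.loglik >= vc.loglik_trace[0] - 1e-9

    def test_recovers_moderate_heritability(self):
        h2s = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            n = 500
            A = rng.normal(size=(n, 600))
            A -= A.mean(0)
            G = A @ A.T / 600 + 1e-6 * np.eye(n)
            L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
            g = L @ rng.standard_normal(n) * np.sqrt(0.3)
            y = 5 + g + rng.standard_normal(n) * np.sqrt(0.7)
            h2s.append(gb.em_reml(y, np.ones((n, 1)), G).h2)
        assert abs(np.mean(h2s) - 0.3) < 0.06


class TestBreedCovariateAbsorption:
    def test_breed_effect_absorbed_out_of_gbv(self):
        """In a purebred + F1 reference with a true breed-mean difference,
        fitting the breed-proportion covariate removes the breed-class
        mean difference from the breeding values."""
        cfg = ps.SimConfig(seed=12, n_base=120, ld_generations=5,
                           effective_size=60, n_breeds=2,
                           breed_names=("A", "B"),
                           divergence_generations=(30, 30),
                           snps_per_chromosome=150, n_qtl=50,
                           family_size_range=(8, 15),
                           across_breed_qtl_correlation=0.8)
        breeds = ps.derive_breeds(ps.simulate_founders(cfg), cfg)
        breeds.qtl = ps.sample_qtl(breeds, cfg)
        design = ps.DesignSpec(n_purebred={"A": 120},
                               f1_crosses=[("B", "A", 120)],
                               n_sires={"A": 8, "B": 8})
        pop = ps.build_design(breeds, cfg, design)
        pop.qtl = breeds.qtl
        rec = ps.simulate_phenotypes(pop, cfg, seed=12)
        from mbgblup import breedcomp
        Q = breedcomp.breed_proportions(pop.pedigree)
        table = ps.genotype_table(pop, with_confidence=False,
                                  animal_rows=pop.rows(rec["id"]))
        f = np.clip(allele_frequencies(table), 1e-3, 1 - 1e-3)
        G = build_g1(table, f, animal_ids=rec["id"].tolist())
        vc = {"additive": cfg.trait_h2 * cfg.trait_sd**2,
              "maternal": 0.05 * cfg.trait_sd**2,
              "sire_flock": 0.05 * cfg.trait_sd**2,
              "residual": 0.6 * cfg.trait_sd**2}
        is_f1 = rec["cohort"].str.startswith("f1").to_numpy()

        gaps = {}
        for use_q in (False, True):
            spec = gb.ModelSpec(breed_covariates=("B",) if use_q else (),
                                variance_components=vc)
            dm = gb.build_design_matrices(rec, spec, Q=Q,
                                          g_ids=rec["id"].tolist())
            fit = gb.solve_mme(dm, G, vc, compute_pev=False)
            gbv = fit.gbv.to_numpy()
            gaps[use_q] = abs(gbv[is_f1].mean() - gbv[~is_f1].mean())
        assert gaps[True] < gaps[False]
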