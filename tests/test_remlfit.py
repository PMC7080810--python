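"""REML animal model: likelihood oracles, derived parameters, accuracy
formula, LRT behaviour, and dominance fitting."""

import numpy as np
import pandas as pd
import pytest

from polygs import kinship, remlfit, simpop, snpqc
from polygs.datatypes import RelationshipMatrix, TraitTable
from polygs.remlfit import ModelSpec, VarianceEstimates


def make_variances(components, order=None):
    order = order or list(components)
    return VarianceEstimates(
        components=dict(components),
        std_errors={k: 0.0 for k in components},
        loglik=0.0,
        ai_matrix=np.eye(len(order)),
        component_order=order,
        converged=True,
        n_iter=1,
    )


class TestDerivedParameters:
    def test_heritability_arithmetic(self):
        v = make_variances({"additive": 2.0, "site_additive": 1.0, "residual": 5.0})
        assert remlfit.heritability(v) == pytest.approx(0.25)

    def test_heritability_no_noise(self):
        v = make_variances({"additive": 3.0, "site_additive": 0.0, "residual": 0.0})
        assert remlfit.heritability(v) == 1.0

    def test_type_b_arithmetic(self):
        v = make_variances({"additive": 3.0, "site_additive": 1.0, "residual": 1.0})
        assert remlfit.type_b_correlation(v) == pytest.approx(0.75)

    def test_type_b_no_interaction(self):
        v = make_variances({"additive": 3.0, "site_additive": 0.0, "residual": 1.0})
        assert remlfit.type_b_correlation(v) == 1.0

    def test_delta_se_zero_covariance(self):
        v = make_variances({"additive": 2.0, "site_additive": 1.0, "residual": 5.0})
        v.ai_matrix = np.full((3, 3), np.inf)  # zero covariance after inversion
        v.ai_matrix = np.diag([1e30, 1e30, 1e30])
        assert remlfit.delta_method_se(v, "h2") == pytest.approx(0.0, abs=1e-12)

    def test_lrt_identical_fits(self):
        v = make_variances({"additive": 1.0, "residual": 1.0})
        stat, p = remlfit.lrt_variance(v, v)
        assert stat == 0.0 and p == 1.0

    def test_accuracy_limits(self):
        acc = remlfit.theoretical_accuracy_values(
            np.array([0.0, 1.0]), np.array([0.0, 0.0]), 1.0
        )
        assert acc[0] == 1.0  # SE = 0
        assert acc[1] == 0.0  # SE^2 = (1 + F) s2_a


def toy_traits(y, site=None, block=None, ids=None):
    n = len(y)
    return TraitTable(
        pd.DataFrame(
            {
                "id": ids or [f"i{k}" for k in range(n)],
                "site": site or ["S1"] * n,
                "block": block or ["B1"] * n,
                "t": y,
            }
        )
    )


def reml_loglik_direct(y, x, V):
    """Independent restricted log-likelihood evaluation (textbook formula)."""
    n, p = x.shape
    Vi = np.linalg.inv(V)
    xvx = x.T @ Vi @ x
    P = Vi - Vi @ x @ np.linalg.inv(xvx) @ x.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(xvx)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


class TestFitReml:
    def test_grid_search_oracle_12_individuals(self):
        # two unrelated full-sib families of six; REML maximum must agree
        # with a dense grid search over (s2_a, s2_e)
        rng = np.random.default_rng(7)
        block = np.full((6, 6), 0.5) + 0.5 * np.eye(6)
        K = np.block([[block, np.zeros((6, 6))], [np.zeros((6, 6)), block]])
        ids = [f"i{k}" for k in range(12)]
        kern = RelationshipMatrix(ids, K, "A_full")
        L = np.linalg.cholesky(K + 1e-10 * np.eye(12))
        y = 10 + L @ rng.standard_normal(12) * np.sqrt(2.0) + rng.standard_normal(12)
        traits = toy_traits(y, ids=ids)
        fit = remlfit.fit_reml(traits, kern, ModelSpec(trait="t", kernel_kind="A_full",
                                                       include_site_by_additive=False))
        x = np.ones((12, 1))
        grid = np.linspace(0.05, 6.0, 60)
        best = -np.inf
        best_par = None
        for sa in grid:
            for se in grid:
                ll = reml_loglik_direct(y, x, sa * K + se * np.eye(12))
                if ll > best:
                    best, best_par = ll, (sa, se)
        assert fit.variances.loglik >= best - 1e-6
        step = grid[1] - grid[0]
        assert abs(fit.variances.components["additive"] - best_par[0]) <= step
        assert abs(fit.variances.components["residual"] - best_par[1]) <= step

    def test_gblup_equals_ridge_mme(self):
        # independent oracle: Henderson's marker-effect mixed-model equations
        rng = np.random.default_rng(8)
        n, m = 40, 60
        calls = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(np.int8)
        from polygs.datatypes import GenotypeMatrix

        g = GenotypeMatrix([f"i{k}" for k in range(n)], [f"s{j}" for j in range(m)], calls)
        G = kinship.build_G(g)
        y = rng.standard_normal(n) * 3 + 5
        traits = toy_traits(y, ids=list(g.ids))
        s2a, s2e = 1.7, 2.3
        spec = ModelSpec(trait="t", kernel_kind="G", include_site_by_additive=False,
                         fix_variances={"additive": s2a, "residual": s2e})
        fit = remlfit.fit_reml(traits, G, spec)
        # MME route: y = 1 mu + W beta + e, var(beta) = s2a / c
        p = calls.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        W = calls[:, poly] - 2 * p[poly]
        c = 2 * np.sum(p[poly] * (1 - p[poly]))
        lam = c * s2e / s2a
        X = np.ones((n, 1))
        top = np.hstack([X.T @ X, X.T @ W])
        bot = np.hstack([W.T @ X, W.T @ W + lam * np.eye(W.shape[1])])
        sol = np.linalg.solve(np.vstack([top, bot]), np.concatenate([X.T @ y, W.T @ y]))
        a_mme = W @ sol[1:]
        a_gblup = fit.breeding_values.values[:n]
        assert np.allclose(a_gblup, a_mme, atol=1e-6 * max(1, np.abs(a_mme).max()))

    def test_permutation_invariance(self, small_config, small_polycross, small_phenotypes):
        _, offspring, _ = small_polycross
        traits, _, _ = small_phenotypes
        G = kinship.build_G(offspring)
        spec = ModelSpec(trait="t", kernel_kind="G")
        f1 = remlfit.fit_reml(traits, G, spec)
        perm = traits.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f2 = remlfit.fit_reml(TraitTable(perm), G, spec)
        assert f1.variances.loglik == pytest.approx(f2.variances.loglik, abs=1e-4)
        for k in f1.variances.components:
            assert f1.variances.components[k] == pytest.approx(
                f2.variances.components[k], rel=1e-3, abs=1e-6
            )

    def test_shrinkage_toward_zero(self):
        rng = np.random.default_rng(9)
        n = 25
        K = np.eye(n)
        kern = RelationshipMatrix([f"i{k}" for k in range(n)], K, "G")
        y = rng.standard_normal(n)
        traits = toy_traits(y, ids=list(kern.ids))
        spec = ModelSpec(trait="t", kernel_kind="G", include_site_by_additive=False,
                         fix_variances={"additive": 1e-8, "residual": 1.0})
        fit = remlfit.fit_reml(traits, kern, spec)
        assert np.abs(fit.breeding_values.values).max() < 1e-6

    def test_determinism(self, small_polycross, small_phenotypes):
        _, offspring, _ = small_polycross
        traits, _, _ = small_phenotypes
        G = kinship.build_G(offspring)
        spec = ModelSpec(trait="t", kernel_kind="G")
        f1 = remlfit.fit_reml(traits, G, spec)
        f2 = remlfit.fit_reml(traits, G, spec)
        assert f1.variances.components == f2.variances.components

    def test_needs_two_sites_for_gxe(self):
        y = np.arange(6.0)
        traits = toy_traits(y)
        kern = RelationshipMatrix(traits.ids, np.eye(6), "G")
        with pytest.raises(ValueError, match="two sites"):
            remlfit.fit_reml(traits, kern, ModelSpec(trait="t", kernel_kind="G"))

    def test_h2_se_invariant_to_scale(self, small_polycross, small_phenotypes):
        _, offspring, _ = small_polycross
        traits, _, _ = small_phenotypes
        G = kinship.build_G(offspring)
        spec = ModelSpec(trait="t", kernel_kind="G")
        f1 = remlfit.fit_reml(traits, G, spec)
        scaled = traits.data.copy()
        scaled["t"] = scaled["t"] * 3.7
        f2 = remlfit.fit_reml(TraitTable(scaled), G, spec)
        assert f1.params.h2 == pytest.approx(f2.params.h2, rel=1e-3)
        assert f1.params.h2_se == pytest.approx(f2.params.h2_se, rel=1e-2)


class TestDeltaMethodSE:
    def test_against_parametric_bootstrap(self):
        # small single-site model where the bootstrap is cheap
        rng = np.random.default_rng(10)
        n_fam, fam = 30, 6
        n = n_fam * fam
        block = np.full((fam, fam), 0.5) + 0.5 * np.eye(fam)
        K = np.kron(np.eye(n_fam), block)
        ids = [f"i{k}" for k in range(n)]
        kern = RelationshipMatrix(ids, K, "A_full")
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        s2a, s2e = 1.0, 2.0

        def simulate():
            return L @ rng.standard_normal(n) * np.sqrt(s2a) + rng.standard_normal(n) * np.sqrt(s2e)

        spec = ModelSpec(trait="t", kernel_kind="A_full", include_site_by_additive=False)
        fit = remlfit.fit_reml(toy_traits(simulate(), ids=ids), kern, spec)
        se_delta = fit.params.h2_se
        h2s = []
        for _ in range(200):
            f = remlfit.fit_reml(toy_traits(simulate(), ids=ids), kern, spec)
            h2s.append(f.params.h2)
        se_boot = np.std(h2s, ddof=1)
        assert se_delta == pytest.approx(se_boot, rel=0.30)


class TestDominance:
    def test_recovery_with_genomic_D(self):
        cfg = simpop.SimConfig(
            n_crosses=24, n_diallel_parents=24, n_groups=1, family_size=25,
            n_snp=1200, seed=51, contamination_rate=0.0,
            genotyping_error_rate=0.0, missing_rate=0.0, n_sites=2,
            marker_tagged_fraction=1.0,
            trait_specs=(simpop.TraitSpec("t", 0.3, 1.0, 100.0, 20.0,
                                          dominance_fraction=0.5),),
        )
        geno, ped = simpop.simulate_diallel(simpop.simulate_parents(cfg), cfg)
        arch = simpop.build_architecture(geno, cfg)
        traits = simpop.simulate_phenotypes(geno, arch, cfg)
        G = kinship.build_G(geno)
        D = kinship.build_D(geno)
        spec = ModelSpec(trait="t", kernel_kind="G", include_site_by_additive=False,
                         dominance_kernel=D)
        full, reduced, (stat, p) = remlfit.fit_dominance(traits, G, spec)
        s2d_true = arch.components["t"]["sigma2_d"]
        s2d_hat = full.variances.components["dominance"]
        s2d_se = full.variances.std_errors["dominance"]
        assert abs(s2d_hat - s2d_true) <= 2 * s2d_se
        assert s2d_hat > 0

    def test_null_dominance_near_boundary(self):
        cfg = simpop.SimConfig(
            n_crosses=12, n_diallel_parents=24, n_groups=1, family_size=15,
            n_snp=500, seed=52, contamination_rate=0.0,
            genotyping_error_rate=0.0, missing_rate=0.0, n_sites=2,
            marker_tagged_fraction=1.0,
            trait_specs=(simpop.TraitSpec("t", 0.3, 1.0, 100.0, 20.0),),
        )
        geno, ped = simpop.simulate_diallel(simpop.simulate_parents(cfg), cfg)
        arch = simpop.build_architecture(geno, cfg)
        traits = simpop.simulate_phenotypes(geno, arch, cfg)
        G = kinship.build_G(geno)
        D = kinship.build_D(geno)
        spec = ModelSpec(trait="t", kernel_kind="G", include_site_by_additive=False,
                         dominance_kernel=D)
        full, reduced, (stat, p) = remlfit.fit_dominance(traits, G, spec)
        s2p = traits.data["t"].var()
        assert full.variances.components["dominance"] < 0.15 * s2p
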