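import numpy as np
import pytest
from scipy.optimize import minimize

import tenderqtl as tq
from tenderqtl.reml import (ModelSpec, RemlFit, backsolve_ase,
                            build_model_spec, fit_reml, genetic_sample_size)
from tenderqtl.grm import Grm, build_grm, marker_design, regularize_grm
from tenderqtl.qc import apply_qc

from conftest import make_genotypes


def brute_force_reml(y, X, G):
    """Independent oracle: direct numerical maximization of the
    restricted log-likelihood with dense linear algebra."""
    n, p = X.shape

    def negll(theta):
        va, ve = np.exp(theta)
        V = va * G + ve * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        _, ld_v = np.linalg.slogdet(V)
        _, ld_x = np.linalg.slogdet(XtViX)
        return 0.5 * (ld_v + ld_x + r @ Vi @ r)

    best = None
    for start in [(-1.0, -1.0), (0.0, -2.0), (-2.0, 0.0)]:
        res = minimize(negll, start, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20_000})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x)


@pytest.fixture(scope="module")
def fitted_cohort(small_cohort):
    """QC'd cohort with GRM built from generative frequencies (full
    rank, so the back-solve identities are exact) and its REML fit."""
    g, pheno, truth = small_cohort
    g2, _ = apply_qc(g)
    idx = [list(g.snp_ids).index(s) for s in g2.snp_ids]
    freqs = truth.pool_freq_by_breed["Angus"][idx]
    grm = build_grm(g2, freqs=freqs)
    spec, _ = build_model_spec(pheno, grm)
    fit = fit_reml(spec)
    design = marker_design(g2, freqs=freqs)
    keep = [list(g2.animal_ids).index(a) for a in spec.animal_ids]
    design.M = design.M[keep]
    return g2, spec, fit, design


class TestFitReml:
    def test_matches_brute_force_oracle_on_small_problem(self):
        # half-sib covariance structure keeps the REML optimum interior
        cfg = tq.SimConfig(
            n_breeds=1, sires_per_breed=8, progeny_per_sire=12,
            n_snps=400, n_x_snps=0, dense_regions=(), qtl_spec=(),
            h2_per_breed=(0.5,), var_a_per_breed=(0.5,),
            n_herds=2, n_slaughter_dates=2,
            founder_haplotypes=30, pool_generations=10,
            missing_rate=0.0, cg_sd=0.3, seed=21)
        g, pheno, _ = tq.simulate_cohort(cfg)
        g2, _ = apply_qc(g)
        grm = regularize_grm(build_grm(g2), 0.01)
        spec, _ = build_model_spec(pheno, grm)
        fit = fit_reml(spec, tol_sigfigs=6)
        va, ve = brute_force_reml(spec.y, spec.X, spec.grm.G)
        assert fit.var_a == pytest.approx(va, rel=1e-6)
        assert fit.var_e == pytest.approx(ve, rel=1e-6)

    def test_loglik_trace_is_monotone_and_converged(self, fitted_cohort):
        _, _, fit, _ = fitted_cohort
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1]))
        assert fit.converged
        assert 0 <= fit.h2 <= 1

    def test_no_genetic_signal_gives_small_h2(self):
        cfg = tq.SimConfig(
            n_breeds=1, sires_per_breed=10, progeny_per_sire=60,
            n_snps=600, n_x_snps=0, dense_regions=(), qtl_spec=(),
            h2_per_breed=(0.0,), var_a_per_breed=(0.0,),
            var_e_per_breed=(0.8,), founder_haplotypes=40,
            pool_generations=10, missing_rate=0.0, cg_sd=0.4, seed=17)
        g, pheno, _ = tq.simulate_cohort(cfg)
        g2, _ = apply_qc(g)
        grm = regularize_grm(build_grm(g2), 0.01)
        spec, _ = build_model_spec(pheno, grm)
        fit = fit_reml(spec)
        assert fit.h2 < 0.1

    def test_scaling_y_scales_variances_not_h2_or_t(self, fitted_cohort):
        g2, spec, fit, design = fitted_cohort
        k = 2.5
        spec_k = ModelSpec(y=spec.y * k, X=spec.X, grm=spec.grm,
                           animal_ids=spec.animal_ids,
                           fixed_levels=spec.fixed_levels)
        fit_k = fit_reml(spec_k)
        assert fit_k.var_a == pytest.approx(k**2 * fit.var_a, rel=1e-3)
        assert fit_k.var_e == pytest.approx(k**2 * fit.var_e, rel=1e-3)
        assert fit_k.h2 == pytest.approx(fit.h2, rel=1e-4)
        ase = backsolve_ase(fit, design, spec.grm, g2.snp_map)
        ase_k = backsolve_ase(fit_k, design, spec.grm, g2.snp_map)
        assert np.allclose(ase_k["t_stat"], ase["t_stat"], rtol=1e-3)

    def test_non_positive_definite_grm_rejected(self):
        codes = np.array([[2, 1], [2, 1], [0, 1]], dtype=np.int8)
        grm = build_grm(make_genotypes(codes), freqs=np.array([0.5, 0.4]))
        with pytest.raises(ValueError, match="regularize_grm"):
            fit_reml(ModelSpec(y=np.array([1.0, 2.0, 3.0]),
                               X=np.ones((3, 1)), grm=grm,
                               animal_ids=np.array(["a", "b", "c"])))


class TestBuildModelSpec:
    def test_singleton_contemporary_groups_are_dropped(self, small_cohort):
        g, pheno, _ = small_cohort
        pheno = pheno.copy()
        pheno.loc[pheno.index[0], "cg"] = "lonely-cell"
        grm = regularize_grm(build_grm(apply_qc(g)[0]), 0.01)
        spec, log = build_model_spec(pheno, grm)
        assert "lonely-cell" in log["dropped_cg_levels"]
        assert len(spec.y) == len(pheno) - 1


class TestBacksolve:
    def test_zero_breeding_values_give_zero_effects(self, fitted_cohort):
        g2, spec, fit, design = fitted_cohort
        zero_fit = RemlFit(
            var_a=fit.var_a, var_e=fit.var_e, h2=fit.h2, beta=fit.beta,
            u=np.zeros_like(fit.u), fixed_levels=fit.fixed_levels,
            animal_ids=fit.animal_ids, loglik_trace=[], n_iter=0,
            converged=True)
        ase = backsolve_ase(zero_fit, design, spec.grm, g2.snp_map)
        assert np.allclose(ase["ase_kg"], 0.0)
        assert np.allclose(ase["t_stat"], 0.0)

    def test_m_alpha_reproduces_u(self, fitted_cohort):
        g2, spec, fit, design = fitted_cohort
        ase = backsolve_ase(fit, design, spec.grm, g2.snp_map)
        u_hat = design.M @ ase["ase_kg"].to_numpy()
        assert np.allclose(u_hat, fit.u,
                           atol=1e-8 * max(1.0, np.abs(fit.u).max()))

    def test_equals_snp_blup_solution(self, fitted_cohort):
        # the back-solve must coincide with ridge-regression SNP-BLUP of
        # the equivalent marker model u = Ma, Var(a) = I sigma2_M
        g2, spec, fit, design = fitted_cohort
        ase = backsolve_ase(fit, design, spec.grm, g2.snp_map)
        M, X, y = design.M, spec.X, spec.y
        lam = fit.var_e / (fit.var_a / design.c)
        p, m = X.shape[1], M.shape[1]
        lhs = np.block([[X.T @ X, X.T @ M],
                        [M.T @ X, M.T @ M + lam * np.eye(m)]])
        rhs = np.concatenate([X.T @ y, M.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        a_blup = sol[p:]
        scale = np.abs(a_blup).max()
        assert np.allclose(ase["ase_kg"].to_numpy(), a_blup,
                           atol=1e-8 * scale)

    def test_rank_is_permutation_with_genome_order_ties(self, fitted_cohort):
        g2, spec, fit, design = fitted_cohort
        ase = backsolve_ase(fit, design, spec.grm, g2.snp_map)
        assert sorted(ase["rank"]) == list(range(1, len(ase) + 1))
        top = ase.sort_values("rank").iloc[0]
        assert top["t_stat"] == ase["t_stat"].max()

    def test_epsilon_sensitivity_of_effects_is_negligible(self, fitted_cohort):
        g2, spec, fit, design = fitted_cohort
        a1 = backsolve_ase(fit, design, regularize_grm(spec.grm, 0.01),
                           g2.snp_map)
        a2 = backsolve_ase(fit, design, regularize_grm(spec.grm, 0.001),
                           g2.snp_map)
        r = np.corrcoef(a1["ase_kg"], a2["ase_kg"])[0, 1]
        assert r > 0.999


class TestGeneticSampleSize:
    @pytest.mark.parametrize("n,h2,expected", [
        (1095, 0.17, 451.5),       # Hereford genotyped count x sqrt(h2)
        (100, 1.0, 100.0),
        (0, 0.5, 0.0),
    ])
    def test_values(self, n, h2, expected):
        assert genetic_sample_size(n, h2) == expected

    def test_h2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            genetic_sample_size(100, 1.5)
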