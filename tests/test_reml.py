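"""REML likelihood, EM/AI updates, estimation and likelihood-ratio tests."""

import numpy as np
import pytest

from willham.mme import DataSet
from willham.oracles import dense_mixed_model_oracle, grid_reml_oracle
from willham.pedigree import load_and_sort
from willham.reml import (
    REMLProblem,
    ai_step,
    em_step,
    estimate,
    lrt,
    restricted_log_likelihood,
)
from willham.varmodels import ModelConfig, VarianceComponents

from conftest import make_structured_pedigree, simulate_records


def _vc(cfg, G0, E0, dummy=1.0):
    return VarianceComponents(cfg.genetic_factors, np.asarray(G0, float),
                              cfg.env_factors, np.asarray(E0, float), dummy)


class TestRestrictedLikelihood:
    def test_matches_dense_formula_on_tiny_data(self, coramepe_vc):
        ped = make_structured_pedigree(11, n_sires=1, n_dams=3, n_gen=1, per_gen=8)
        data = simulate_records(ped, coramepe_vc, seed=11)
        assert len(data) <= 8
        cfg = ModelConfig("coramepe", 1)
        sparse = restricted_log_likelihood(coramepe_vc, data, ped, cfg)
        dense = dense_mixed_model_oracle(data, ped, coramepe_vc, cfg)["minus2logl"]
        assert sparse == pytest.approx(dense, abs=1e-8)

    def test_scaling_y_tracks_dense_oracle(self, small_instance, coramepe_vc):
        ped, data = small_instance
        cfg = ModelConfig("coramepe", 1)
        scaled = DataSet(data.table.assign(bw=data.table.bw * 3.0),
                         data.trait_col, data.fixed_effects)
        sparse = restricted_log_likelihood(coramepe_vc, scaled, ped, cfg)
        dense = dense_mixed_model_oracle(scaled, ped, coramepe_vc, cfg)["minus2logl"]
        assert sparse == pytest.approx(dense, abs=1e-7)

    def test_duplicated_independent_copy_doubles_up_to_design_constant(self, coramepe_vc):
        # two disjoint copies of the same families: log|V| and y'Py double,
        # while X'V^-1X doubles entry-wise adding p*log(2)
        ped1 = make_structured_pedigree(13, n_sires=1, n_dams=3, n_gen=1, per_gen=8)
        data1 = simulate_records(ped1, coramepe_vc, seed=13)
        cfg = ModelConfig("coramepe", 1)
        single = restricted_log_likelihood(coramepe_vc, data1, ped1, cfg)

        # relabel the copy
        shift = 1000
        rows = []
        for a, s, d in zip(ped1.ids, ped1.sire, ped1.dam):
            rows.append((a, 0 if s < 0 else ped1.ids[s], 0 if d < 0 else ped1.ids[d],
                         ped1.sex[ped1.code([a])[0]], 0))
            rows.append((a + shift, 0 if s < 0 else ped1.ids[s] + shift,
                         0 if d < 0 else ped1.ids[d] + shift,
                         ped1.sex[ped1.code([a])[0]], 0))
        ped2 = load_and_sort(rows)
        tbl = data1.table
        both = DataSet(
            tbl._append(tbl.assign(animal=tbl.animal + shift), ignore_index=True),
            data1.trait_col, data1.fixed_effects,
        )
        double = restricted_log_likelihood(coramepe_vc, both, ped2, cfg)
        # log|V| and y'Py double; X'V^-1X doubles entry-wise, so its log-det
        # appears once plus p*log 2 instead of twice
        from willham.mme import build_design
        from willham.oracles import tabular_relationship

        d = build_design(data1, ped1, cfg)
        X, Z, U = d.X.toarray(), d.Z.toarray(), d.U.toarray()
        A = tabular_relationship(ped1)
        Senv = np.zeros((d.n_env, d.n_env))
        ptr = d.env_block_ptr
        for k in range(len(ptr) - 1):
            pat = list(d.env_factor[ptr[k]:ptr[k + 1]])
            Senv[ptr[k]:ptr[k + 1], ptr[k]:ptr[k + 1]] = coramepe_vc.E0[np.ix_(pat, pat)]
        V = Z @ np.kron(A, coramepe_vc.G0) @ Z.T + U @ Senv @ U.T + np.eye(len(d.y))
        _, ld_xvx = np.linalg.slogdet(X.T @ np.linalg.inv(V) @ X)
        p = X.shape[1]
        assert double == pytest.approx(2 * single - ld_xvx + p * np.log(2), abs=1e-6)


class TestSteps:
    @pytest.fixture
    def problem(self, small_instance):
        ped, data = small_instance
        return REMLProblem(data, ped, ModelConfig("coramepe", 1))

    def test_em_from_inflated_residual_decreases_minus2logl(self, problem, coramepe_vc):
        vc = coramepe_vc.copy()
        vc.E0[0, 0] *= 4.0
        vc = problem._sanitize(vc)
        sol = problem.fit(vc)
        vc2 = em_step(vc, sol, problem)
        assert problem.fit(vc2).minus2logl < sol.minus2logl

    def test_gradient_matches_finite_differences(self, problem, coramepe_vc):
        vc = problem._sanitize(coramepe_vc)
        sol = problem.fit(vc)
        g = problem.gradient(problem.statistics(sol))
        theta = problem.pm.get_free(vc)
        for q in range(len(theta)):
            h = 1e-5 * max(abs(theta[q]), 1.0)
            up, dn = theta.copy(), theta.copy()
            up[q] += h
            dn[q] -= h
            num = (problem.fit(problem.pm.set_free(vc, up)).minus2logl
                   - problem.fit(problem.pm.set_free(vc, dn)).minus2logl) / (2 * h)
            assert g[q] == pytest.approx(num, rel=5e-3, abs=1e-5)

    def test_masked_covariance_stays_zero_under_both_steps(self, small_instance):
        ped, data = small_instance
        cfg = ModelConfig("coram", 1)  # Cov(e, pe) structurally zero
        problem = REMLProblem(data, ped, cfg)
        vc = problem._sanitize(_vc(cfg, [[60.0, -8.0], [-8.0, 15.0]],
                                   [[100.0, 0.0], [0.0, 20.0]]))
        sol = problem.fit(vc)
        for stepper in (em_step, ai_step):
            new = stepper(vc, sol, problem)
            assert new.E0[0, 1] == 0.0
            assert new.sigma2_dummy == vc.sigma2_dummy

    def test_converged_point_is_a_likelihood_fixed_point(self, program_instance):
        ped, data = program_instance
        cfg = ModelConfig("modam", 1)
        res = estimate(data, ped, cfg, max_iter=100)
        problem = REMLProblem(data, ped, cfg)
        sol = problem.fit(res.vc)
        new = em_step(res.vc, sol, problem)
        # one more EM step cannot improve -2logL beyond numerical noise
        gain = sol.minus2logl - problem.fit(new).minus2logl
        assert gain < 1e-5 * (1 + abs(sol.minus2logl))


class TestEstimate:
    def test_matches_grid_oracle_along_a_and_e(self, program_instance):
        # coordinate slices through the optimum: the grid optimum of
        # (var_a, var_e) with the other components held at the joint
        # estimate must be the estimate itself, within one grid cell
        ped, data = program_instance
        cfg = ModelConfig("modam", 1)
        res = estimate(data, ped, cfg, max_iter=100)
        a_hat = res.vc.g("a")
        e_hat = res.vc.e("e")
        grid = {
            ("G", 0, 0): np.linspace(0.6 * a_hat, 1.4 * a_hat, 7),
            ("E", 0, 0): np.linspace(0.8 * e_hat, 1.2 * e_hat, 7),
        }
        best = grid_reml_oracle(data, ped, cfg, grid, res.vc)
        assert not best["on_boundary"]
        da = np.diff(grid[("G", 0, 0)])[0]
        de = np.diff(grid[("E", 0, 0)])[0]
        assert abs(best["values"][("G", 0, 0)] - a_hat) <= da
        assert abs(best["values"][("E", 0, 0)] - e_hat) <= de

    def test_monotone_descent_and_convergence(self, coramepe_vc):
        for seed in (31, 32, 33):
            ped = make_structured_pedigree(seed, n_sires=3, n_dams=9,
                                           n_gen=2, per_gen=40)
            data = simulate_records(ped, coramepe_vc, seed=seed)
            res = estimate(data, ped, ModelConfig("modam", 1), max_iter=60)
            lls = [ll for _, ll, _ in res.trace]
            tol = 1e-6 * (1 + abs(lls[0]))
            assert all(b <= a + tol for a, b in zip(lls, lls[1:]))
            assert res.se.shape == (4,)

    def test_dummy_never_updated(self, small_instance):
        ped, data = small_instance
        res = estimate(data, ped, ModelConfig("modam", 1), sigma2_dummy=2.5,
                       max_iter=30)
        assert res.vc.sigma2_dummy == 2.5

    def test_bivariate_estimation_runs_and_is_sane(self, program_instance):
        # female and male body weight as two traits: simulated as one trait,
        # so the cross-sex genetic correlation should estimate high and the
        # trait variances should be of the same order
        ped, data = program_instance
        cfg = ModelConfig("modam", 2)
        res = estimate(data, ped, cfg, max_iter=40, keep_solution=False)
        est = res.free_estimates()
        assert np.isfinite(res.minus2logl)
        aF, aM = est["var(a_F)"], est["var(a_M)"]
        cross = est["cov(a_F,a_M)"]
        assert aF > 0 and aM > 0
        assert cross / np.sqrt(aF * aM) > 0.3
        eF, eM = est["var(e_F)"], est["var(e_M)"]
        assert 0.2 < eF / eM < 5.0

    def test_result_reproducible(self, small_instance):
        ped, data = small_instance
        cfg = ModelConfig("modam", 1)
        r1 = estimate(data, ped, cfg, max_iter=30, keep_solution=False)
        r2 = estimate(data, ped, cfg, max_iter=30, keep_solution=False)
        assert r1.minus2logl == r2.minus2logl
        assert np.array_equal(r1.pm.get_free(r1.vc), r2.pm.get_free(r2.vc))


@pytest.fixture(scope="module")
def fits(program_instance):
    # warm-start each model from the optimum of the model nested in it:
    # monotone descent then guarantees the likelihood ordering that the
    # LRT relies on, independent of how hard each surface is
    ped, data = program_instance
    out = {"moda": estimate(data, ped, ModelConfig("moda", 1), max_iter=60,
                            keep_solution=False)}
    moda = out["moda"].vc
    cfg2 = ModelConfig("modam", 1)
    bridge = VarianceComponents(
        cfg2.genetic_factors,
        np.diag([moda.g("a"), 1e-6 * moda.g("a")]),
        cfg2.env_factors, moda.E0.copy(), moda.sigma2_dummy,
    )
    out["modam"] = estimate(data, ped, cfg2, init=bridge, max_iter=60,
                            keep_solution=False)
    out["coramepe"] = estimate(data, ped, ModelConfig("coramepe", 1),
                               init=out["modam"].vc, max_iter=60,
                               keep_solution=False)
    return out


class TestLRT:

    def test_identical_models_give_zero(self, fits):
        out = lrt(fits["modam"], fits["modam"])
        assert out["statistic"] == 0.0 and out["df"] == 0

    def test_nested_positive_statistic_and_df(self, fits):
        out = lrt(fits["modam"], fits["coramepe"])
        assert out["df"] == 2
        assert out["statistic"] >= -0.01
        deeper = lrt(fits["moda"], fits["coramepe"])
        assert deeper["statistic"] >= out["statistic"] - 0.01

    def test_non_nested_rejected(self, small_instance):
        ped, data = small_instance
        a = estimate(data, ped, ModelConfig("coram", 1), max_iter=20,
                     keep_solution=False)
        b = estimate(data, ped, ModelConfig("corepe", 1), max_iter=20,
                     keep_solution=False)
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)
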