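"""Design building and mixed-model equations against the dense GLS oracle."""

import numpy as np
import pandas as pd
import pytest

from willham.mme import (
    DataSet,
    assemble_mme,
    build_design,
    environmental_block_structure,
    solve,
    solve_model,
)
from willham.oracles import dense_mixed_model_oracle
from willham.pedigree import load_and_sort
from willham.varmodels import ModelConfig, VarianceComponents, build_structure

from conftest import make_structured_pedigree, simulate_records


def _vc(cfg, G0, E0, dummy=1.0):
    return VarianceComponents(cfg.genetic_factors, np.asarray(G0, float),
                              cfg.env_factors, np.asarray(E0, float), dummy)


@pytest.fixture
def trio_family():
    """One dam with three phenotyped offspring; dam unphenotyped."""
    ped = load_and_sort([(1, 0, 0, "M", 0), (2, 0, 0, "F", 0)]
                        + [(i, 1, 2, "F", 1) for i in (3, 4, 5)])
    data = DataSet(pd.DataFrame([
        dict(animal=i, sex="F", bw=100.0 + i) for i in (3, 4, 5)
    ]), fixed_effects=())
    return ped, data


class TestBuildDesign:
    def test_e_levels_per_record_and_one_pe_per_dam(self, trio_family):
        ped, data = trio_family
        d = build_design(data, ped, ModelConfig("modam", 1))
        e_levels = (d.env_factor == 0).sum()
        pe_levels = (d.env_factor == 1).sum()
        assert e_levels == 3 and pe_levels == 1
        assert d.U.shape == (3, 4)
        # every record links its own e and the dam's pe
        assert np.all(d.U.sum(axis=1) == 2)

    def test_phenotyped_dam_joins_e_and_pe_in_one_block(self):
        ped = load_and_sort([(1, 0, 0, "M", 0), (2, 0, 0, "F", 0),
                             (3, 1, 2, "F", 1), (4, 1, 3, "M", 2)])
        data = DataSet(pd.DataFrame([dict(animal=3, sex="F", bw=90.0),
                                     dict(animal=4, sex="M", bw=95.0)]),
                       fixed_effects=())
        d = build_design(data, ped, ModelConfig("coramepe", 1))
        dam3 = ped.code([3])[0]
        blocks = [d.env_owner[d.env_block_ptr[k]:d.env_block_ptr[k + 1]]
                  for k in range(len(d.env_block_ptr) - 1)]
        sizes = {b[0]: len(b) for b in blocks}
        assert sizes[dam3] == 2  # her own e and her pe share one block

    def test_unknown_dam_leaves_maternal_links_empty(self):
        ped = load_and_sort([(1, 0, 0, "M", 0), (2, 1, 0, "M", 1)])
        data = DataSet(pd.DataFrame([dict(animal=2, sex="M", bw=80.0)]),
                       fixed_effects=())
        d = build_design(data, ped, ModelConfig("modam", 1))
        assert d.n_unknown_dam == 1
        assert (d.env_factor == 1).sum() == 0          # no pe level at all
        assert d.Z[0].nnz == 1                          # own a only, no m link

    def test_duplicate_record_rejected(self):
        ped = load_and_sort([(1, 0, 0, "F", 0)])
        data = DataSet(pd.DataFrame([dict(animal=1, sex="F", bw=1.0),
                                     dict(animal=1, sex="F", bw=2.0)]),
                       fixed_effects=())
        with pytest.raises(ValueError, match="more than one record"):
            build_design(data, ped, ModelConfig("moda", 1))


class TestEnvironmentalBlocks:
    def test_joint_block_is_inverse_of_e0(self):
        ped = load_and_sort([(1, 0, 0, "M", 0), (2, 0, 0, "F", 0),
                             (3, 1, 2, "F", 1), (4, 1, 3, "M", 2)])
        data = DataSet(pd.DataFrame([dict(animal=3, sex="F", bw=90.0),
                                     dict(animal=4, sex="M", bw=95.0)]),
                       fixed_effects=())
        cfg = ModelConfig("coramepe", 1)
        d = build_design(data, ped, cfg)
        E0 = np.array([[80.0, 6.0], [6.0, 15.0]])
        prec, logdet = environmental_block_structure(d, _vc(cfg, [[50, -5], [-5, 10]], E0))
        dam3 = ped.code([3])[0]
        k = list(d.env_owner[d.env_block_ptr[:-1]]).index(dam3)
        s = d.env_block_ptr[k]
        block = prec.toarray()[s:s + 2, s:s + 2]
        assert np.allclose(block, np.linalg.inv(E0))

    def test_zero_covariance_decouples(self):
        ped = load_and_sort([(1, 0, 0, "M", 0), (2, 0, 0, "F", 0),
                             (3, 1, 2, "F", 1), (4, 1, 3, "M", 2)])
        data = DataSet(pd.DataFrame([dict(animal=3, sex="F", bw=90.0),
                                     dict(animal=4, sex="M", bw=95.0)]),
                       fixed_effects=())
        cfg = ModelConfig("coramepe", 1)
        d = build_design(data, ped, cfg)
        prec, _ = environmental_block_structure(
            d, _vc(cfg, [[50, 0], [0, 10]], [[80.0, 0.0], [0.0, 15.0]]))
        dense = prec.toarray()
        assert np.allclose(dense, np.diag(np.diag(dense)))


class TestSolveAgainstDenseOracle:
    @pytest.mark.parametrize("model", ["moda", "modam", "coram", "corepe", "coramepe"])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_solution_and_likelihood_match(self, model, seed, coramepe_vc):
        ped = make_structured_pedigree(seed, n_sires=2, n_dams=5, n_gen=2, per_gen=10)
        data = simulate_records(ped, coramepe_vc, seed=seed + 50, frac=0.85)
        assert len(data) <= 30
        cfg = ModelConfig(model, 1)
        vc = _vc(cfg,
                 [[55.0]] if model == "moda" else [[55.0, -8.0], [-8.0, 12.0]],
                 [[90.0, 9.0], [9.0, 18.0]])
        sol = solve_model(data, ped, cfg, vc)
        orc = dense_mixed_model_oracle(data, ped, vc, cfg)
        assert np.abs(sol.b - orc["b"]).max() < 1e-6
        assert np.abs(sol.genetic - orc["genetic"]).max() < 1e-6
        assert np.abs(sol.env - orc["env"]).max() < 1e-6
        assert sol.minus2logl == pytest.approx(orc["minus2logl"], abs=1e-6)

    def test_translation_invariance(self, small_instance, coramepe_vc):
        ped, data = small_instance
        cfg = ModelConfig("coramepe", 1)
        sol = solve_model(data, ped, cfg, coramepe_vc)
        shifted = DataSet(data.table.assign(bw=data.table.bw + 500.0),
                          data.trait_col, data.fixed_effects)
        sol2 = solve_model(shifted, ped, cfg, coramepe_vc)
        assert np.abs(sol.genetic - sol2.genetic).max() < 1e-7
        assert np.abs(sol.env - sol2.env).max() < 1e-7
        # only the intercept moves
        assert sol2.b[0] - sol.b[0] == pytest.approx(500.0, abs=1e-7)
        assert np.abs(sol.b[1:] - sol2.b[1:]).max() < 1e-7

    def test_record_order_invariance(self, small_instance, coramepe_vc):
        ped, data = small_instance
        cfg = ModelConfig("coramepe", 1)
        sol = solve_model(data, ped, cfg, coramepe_vc)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data))
        data2 = DataSet(data.table.iloc[perm].reset_index(drop=True),
                        data.trait_col, data.fixed_effects)
        sol2 = solve_model(data2, ped, cfg, coramepe_vc)
        assert np.abs(sol.genetic - sol2.genetic).max() < 1e-8

    def test_moda_with_vanishing_pe_approaches_plain_animal_model(self, small_instance):
        ped, data = small_instance
        cfg = ModelConfig("moda", 1)
        vc = _vc(cfg, [[60.0]], [[100.0, 0.0], [0.0, 1e-8]])
        sol = solve_model(data, ped, cfg, vc)
        # dense animal-model BLUP: V = Z A Z' s2a + I (s2e + dummy)
        from willham.oracles import tabular_relationship
        d = build_design(data, ped, cfg)
        X, Z = d.X.toarray(), d.Z.toarray()
        A = tabular_relationship(ped)
        V = Z @ A @ Z.T * 60.0 + np.eye(len(data)) * 101.0
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d.y)
        a_hat = 60.0 * A @ Z.T @ (Vi @ (d.y - X @ b))
        assert np.abs(sol.ebv("a") - a_hat).max() < 1e-4

    def test_coramepe_with_zero_covariances_equals_modam(self, small_instance):
        ped, data = small_instance
        E0 = [[95.0, 0.0], [0.0, 17.0]]
        G0 = [[58.0, 0.0], [0.0, 13.0]]
        sol_full = solve_model(data, ped, ModelConfig("coramepe", 1),
                               _vc(ModelConfig("coramepe", 1), G0, E0))
        sol_nested = solve_model(data, ped, ModelConfig("modam", 1),
                                 _vc(ModelConfig("modam", 1), G0, E0))
        assert np.abs(sol_full.genetic - sol_nested.genetic).max() < 1e-7
        assert sol_full.minus2logl == pytest.approx(sol_nested.minus2logl, abs=1e-5)


class TestBivariate:
    def test_bivariate_solution_matches_dense_oracle(self):
        ped = make_structured_pedigree(7, n_sires=2, n_dams=5, n_gen=2, per_gen=10)
        rng = np.random.default_rng(3)
        rows = []
        for i in range(7, ped.n):
            if ped.dam[i] >= 0 and rng.random() < 0.8:
                rows.append(dict(animal=ped.ids[i], sex=ped.sex[i],
                                 bw=float(rng.normal(100, 12))))
        data = DataSet(pd.DataFrame(rows), fixed_effects=())
        cfg = ModelConfig("coramepe", 2)
        G0 = np.array([[50, 30, -6, -4], [30, 60, -5, -7],
                       [-6, -5, 12, 8], [-4, -7, 8, 14]], dtype=float)
        E0 = np.array([[90, 0, 8, 6], [0, 120, 0, 0],
                       [8, 0, 16, 9], [6, 0, 9, 20]], dtype=float)
        vc = _vc(cfg, G0, E0)
        sol = solve_model(data, ped, cfg, vc)
        orc = dense_mixed_model_oracle(data, ped, vc, cfg)
        assert np.abs(sol.genetic - orc["genetic"]).max() < 1e-7
        assert sol.minus2logl == pytest.approx(orc["minus2logl"], abs=1e-7)

    def test_dam_has_one_pe_per_offspring_sex(self):
        ped = load_and_sort([(1, 0, 0, "M", 0), (2, 0, 0, "F", 0),
                             (3, 1, 2, "F", 1), (4, 1, 2, "M", 1)])
        data = DataSet(pd.DataFrame([dict(animal=3, sex="F", bw=90.0),
                                     dict(animal=4, sex="M", bw=120.0)]),
                       fixed_effects=())
        cfg = ModelConfig("modam", 2)
        d = build_design(data, ped, cfg)
        pe_F = cfg.env_factors.index("pe_F")
        pe_M = cfg.env_factors.index("pe_M")
        dam = ped.code([2])[0]
        owners = d.env_owner[np.isin(d.env_factor, [pe_F, pe_M])]
        assert list(owners) == [dam, dam]
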