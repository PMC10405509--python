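"""Shared fixtures: random pedigrees and small model-simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from willham.mme import DataSet
from willham.pedigree import Pedigree, load_and_sort
from willham.varmodels import ModelConfig, VarianceComponents


def make_random_pedigree(seed: int, n_founders: int = 10, n_offspring: int = 190,
                         window: int = 60) -> Pedigree:
    """Random multi-generation pedigree; parents drawn from a recent window
    so that inbreeding accumulates."""
    rng = np.random.default_rng(seed)
    recs = [(i, 0, 0, "M" if i % 2 else "F", 0) for i in range(1, n_founders + 1)]
    nid = n_founders + 1
    while len(recs) < n_founders + n_offspring:
        lo = max(1, nid - window)
        s, d = rng.integers(lo, nid, size=2)
        if s == d:
            continue
        recs.append((int(nid), int(s), int(d), "", 1 + (nid - n_founders) // 50))
        nid += 1
    # drop sexes so that arbitrary animals can act as sire or dam
    return load_and_sort([(a, s, d) for a, s, d, _, _ in recs])


def make_structured_pedigree(seed: int, n_sires: int = 5, n_dams: int = 15,
                             n_gen: int = 2, per_gen: int = 60) -> Pedigree:
    """Sexed hierarchical pedigree suitable for maternal models."""
    rng = np.random.default_rng(seed)
    recs = [(i, 0, 0, "M" if i <= n_sires else "F", 0)
            for i in range(1, n_sires + n_dams + 1)]
    nid = n_sires + n_dams + 1
    sires = list(range(1, n_sires + 1))
    dams = list(range(n_sires + 1, n_sires + n_dams + 1))
    for gen in range(1, n_gen + 1):
        newd, news = [], []
        for _ in range(per_gen):
            s, d = int(rng.choice(sires)), int(rng.choice(dams))
            sex = str(rng.choice(["F", "M"]))
            recs.append((nid, s, d, sex, gen))
            (newd if sex == "F" else news).append(nid)
            nid += 1
        dams = newd[:n_dams] or dams
        sires = news[:n_sires] or sires
    return load_and_sort(recs)


def simulate_records(ped: Pedigree, vc: VarianceComponents, seed: int,
                     *, mean: float = 100.0, phenotype_founder_dams: bool = False,
                     frac: float = 1.0) -> DataSet:
    """Draw phenotypes from the generative maternal model on a pedigree.

    Every female receives a joint (e, pe) draw so the direct-maternal
    environmental covariance is real; males get e only.
    """
    rng = np.random.default_rng(seed)
    N = ped.n
    gen = np.zeros((N, 2))
    full_g = vc.G0 if vc.G0.shape[0] == 2 else np.diag([vc.G0[0, 0], 0.0])
    Lg = np.linalg.cholesky(full_g + np.eye(2) * 1e-9)
    Le = np.linalg.cholesky(vc.E0)
    env = np.zeros((N, 2))
    for i in range(N):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 or d < 0:
            gen[i] = Lg @ rng.standard_normal(2)
        else:
            gen[i] = 0.5 * (gen[s] + gen[d]) + np.sqrt(0.5) * (Lg @ rng.standard_normal(2))
        env[i] = Le @ rng.standard_normal(2)
    rows = []
    for i in range(N):
        d = ped.dam[i]
        if d < 0:
            if not (phenotype_founder_dams and ped.sex[i] == "F"):
                continue
            m_part = pe_part = 0.0
        else:
            m_part, pe_part = gen[d, 1], env[d, 1]
        if rng.random() > frac:
            continue
        bw = (mean + gen[i, 0] + m_part + pe_part + env[i, 0]
              + np.sqrt(vc.sigma2_dummy) * rng.standard_normal())
        rows.append(dict(animal=ped.ids[i], sr=int(ped.sr[i]),
                         sex=ped.sex[i] or str(rng.choice(["F", "M"])), bw=bw))
    return DataSet(pd.DataFrame(rows), fixed_effects=("sex",))


@pytest.fixture(scope="session")
def coramepe_vc() -> VarianceComponents:
    cfg = ModelConfig("coramepe", 1)
    return VarianceComponents(
        cfg.genetic_factors, np.array([[60.0, -10.0], [-10.0, 15.0]]),
        cfg.env_factors, np.array([[100.0, 12.0], [12.0, 20.0]]), 1.0,
    )


@pytest.fixture(scope="session")
def program_instance():
    """A small random-mating breeding-program population (600 records, 40
    dams with ~5 offspring each): enough maternal replication that the
    variance components are well identified and REML converges quickly."""
    from willham.simulate import SimConfig, run_program

    cfg = SimConfig.reduced(n_sr=3, offspring_per_sr=200, n_males_selected=1,
                            n_females_selected=10, random_selection_until_sr=99)
    pop = run_program(cfg, seed=17)
    return pop.ped, pop.data


@pytest.fixture(scope="session")
def validation_population():
    """A 7-round selected program plus full-data REML fits of two models,
    shared by the cross-validation tests."""
    from willham.reml import estimate
    from willham.simulate import SimConfig, run_program

    cfg = SimConfig.reduced(n_sr=7, offspring_per_sr=600, n_males_selected=1,
                            n_females_selected=10, random_selection_until_sr=2)
    pop = run_program(cfg, seed=23)
    results = {m: estimate(pop.data, pop.ped, ModelConfig(m, 1), max_iter=40)
               for m in ("moda", "modam")}
    return pop, results


@pytest.fixture(scope="session")
def small_instance(coramepe_vc):
    """A ~25-record maternal-model dataset with phenotyped dams (dense-oracle
    territory)."""
    ped = make_structured_pedigree(5, n_sires=2, n_dams=6, n_gen=2, per_gen=12)
    data = simulate_records(ped, coramepe_vc, seed=5, frac=0.9)
    return ped, data
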