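"""Stochastic simulation of a broiler breeding program with maternal effects.

The simulated population mimics a pedigreed body-weight (BW) breeding
scheme: discrete selection rounds (SR) with overlapping use of parents, a
hierarchical mating design (each dam mated to a single sire, each sire to
``dams_per_sire`` dams), random parent replacement during a burn-in phase
and truncation selection on pedigree-BLUP breeding values afterwards.

Phenotypes follow the infinitesimal Willham model

    BW = Xb + Za + Wm + Wpe + Be + eps,

with direct (``a``) and maternal (``m``) genetic effects drawn jointly
(covariance ``G0``) down the pedigree with exact Mendelian-sampling
variances, a joint ``(e, pe)`` environmental draw per female (covariance
``E0`` — this is what creates the direct-maternal environmental
covariance), and an independent unit-variance noise ``eps`` matching the
dummy residual of the estimation models.  Every component of every
phenotype is stored, so the simulation truth is exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mme import DataSet, build_design, solve_model
from .pedigree import Pedigree, load_and_sort
from .varmodels import ModelConfig, VarianceComponents


def _moda_blup_ebv(data: DataSet, ped: Pedigree, vc: VarianceComponents) -> np.ndarray:
    """Direct-effect BLUPs under the univariate Moda model, with the iid
    residual absorbed into the dummy residual.

    Without an e-pe covariance the explicit residual effect is iid per
    record, so the model is exactly equivalent to a standard animal model
    with residual variance ``sigma2_e + sigma2_dummy``; absorbing it
    halves the size of the equations.  Used in the hot selection loop of
    the simulator.
    """
    import scipy.sparse as sp

    from .pedigree import a_inverse
    from .sparsela import SymFactor

    cfg = ModelConfig("moda", 1)
    design = build_design(data, ped, cfg)
    s2a = vc.g("a")
    s2pe = vc.e("pe")
    s2res = vc.e("e") + vc.sigma2_dummy
    # keep only the pe columns of the joint environmental incidence
    pe_cols = np.flatnonzero(design.env_factor == 1)
    W = sp.hstack([design.X, design.Z,
                   design.U[:, pe_cols] if len(pe_cols) else
                   sp.csr_matrix((design.n_records, 0))], format="csr")
    p = design.n_fixed
    N = design.n_animals
    prec = sp.block_diag([
        sp.csc_matrix((p, p)),
        a_inverse(ped) * (1.0 / s2a),
        sp.identity(len(pe_cols), format="csc") * (1.0 / s2pe),
    ], format="csc")
    C = (W.T @ W) * (1.0 / s2res) + prec
    sol = SymFactor(C.tocsc()).solve((W.T @ design.y) / s2res)
    return sol[p:p + N]

__all__ = ["SimConfig", "SimulatedPopulation", "broiler_true_components", "run_program"]


def broiler_true_components(
    *,
    cov_am: float = -912.0,
    cov_epe: float = 1272.0,
    sigma2_dummy: float = 1.0,
) -> VarianceComponents:
    """The univariate simulation truth: direct genetic variance 8046 g^2,
    maternal genetic 829, Cov(a,m) -912, permanent environmental 906,
    residual 19860, Cov(e,pe) 1272, plus the unit dummy residual."""
    cfg = ModelConfig("coramepe", 1)
    return VarianceComponents(
        cfg.genetic_factors,
        np.array([[8046.0, cov_am], [cov_am, 829.0]]),
        cfg.env_factors,
        np.array([[19860.0, cov_epe], [cov_epe, 906.0]]),
        sigma2_dummy,
    )


@dataclass
class SimConfig:
    """Breeding-program layout and simulation truth.

    Defaults follow the full-scale design: 40 SR of 7800 birds from 52
    active sires and 520 active dams, 13 males and 130 females selected
    per SR (so each male serves 10 dams), parents serving 4 SR, random
    selection for the first 6 SR and Moda-BLUP truncation selection after.
    ``reduced()`` gives a down-scaled program with the same family
    structure (10 dams per sire, ~15 offspring per dam).
    """

    n_sr: int = 40
    offspring_per_sr: int = 7800
    n_males_selected: int = 13
    n_females_selected: int = 130
    dams_per_sire: int = 10
    service_rounds: int = 4
    hatches_per_sr: int = 6
    random_selection_until_sr: int = 6
    offspring_rate_young: float = 2.49   # per dam per hatch, newest cohort
    offspring_rate_old: float = 2.15     # oldest cohort
    true_vc: VarianceComponents = field(default_factory=broiler_true_components)
    mean_bw: float = 2000.0
    sex_effect: float = 207.0            # males heavier, g
    hatch_sd_frac: float = 0.1           # hatch effects, fraction of phenotypic SD
    dam_age_slope: float = -2.0          # g per dam-age class

    @property
    def n_sires_active(self) -> int:
        return self.n_males_selected * self.service_rounds

    @property
    def n_dams_active(self) -> int:
        return self.n_females_selected * self.service_rounds

    def __post_init__(self):
        if self.n_dams_active != self.n_sires_active * self.dams_per_sire:
            raise ValueError(
                "active dams must equal active sires times dams_per_sire"
            )

    @classmethod
    def reduced(cls, **overrides) -> "SimConfig":
        """Down-scaled program: 10 SR x 1200 birds (8 sires, 80 dams active;
        10 dams per sire, 15 offspring per dam per SR)."""
        base = dict(
            n_sr=10, offspring_per_sr=1200,
            n_males_selected=2, n_females_selected=20,
            dams_per_sire=10, service_rounds=4,
            # burn-in scaled with the programme so that most training
            # rounds are under BLUP selection, as in the full design
            random_selection_until_sr=3,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def phenotypic_sd(self) -> float:
        vc = self.true_vc
        total = vc.g("a") + vc.g("m") + vc.e("e") + vc.e("pe") + vc.sigma2_dummy
        return float(np.sqrt(total))


@dataclass
class SimulatedPopulation:
    """Pedigree, phenotypes and full per-animal truth of one simulation."""

    ped: Pedigree
    data: DataSet
    truth: pd.DataFrame          # per animal: a, m, pe, e (pe/e NaN if absent)
    components: pd.DataFrame     # per record: fixed, a, m_dam, pe_dam, e, dummy
    config: SimConfig
    vc_selection: VarianceComponents | None   # components used for BLUP selection

    def tbv(self, animals) -> np.ndarray:
        """True breeding values (direct genetic effects) for animals."""
        t = self.truth.set_index("animal")
        return t.loc[list(animals), "a"].to_numpy()


class _Population:
    """Growing arrays of animals during simulation."""

    def __init__(self, vc: VarianceComponents, rng: np.random.Generator):
        self.vc = vc
        self._Lg = np.linalg.cholesky(vc.G0)
        self._Le = np.linalg.cholesky(vc.E0)
        self.sire: list = []
        self.dam: list = []
        self.sex: list = []
        self.sr: list = []
        self.a: list = []
        self.m: list = []
        self.e: list = []
        self.pe: list = []
        self.F = np.zeros(0)

    @property
    def n(self):
        return len(self.sire)

    def add_founders(self, n_males: int, n_females: int, rng) -> np.ndarray:
        ids = []
        for sex, count in (("M", n_males), ("F", n_females)):
            for _ in range(count):
                g = self._Lg @ rng.standard_normal(2)
                if sex == "F":
                    env = self._Le @ rng.standard_normal(2)
                    e, pe = env[0], env[1]
                else:
                    e, pe = np.sqrt(self.vc.e("e")) * rng.standard_normal(), np.nan
                ids.append(self._push(-1, -1, sex, 0, g[0], g[1], e, pe))
        return np.array(ids)

    def _push(self, s, d, sex, sr, a, m, e, pe) -> int:
        self.sire.append(s)
        self.dam.append(d)
        self.sex.append(sex)
        self.sr.append(sr)
        self.a.append(a)
        self.m.append(m)
        self.e.append(e)
        self.pe.append(pe)
        return self.n - 1

    def drop_offspring(self, sires, dams, counts, sr, rng):
        """Create offspring; ``counts[k]`` per dam k mated to ``sires[k]``."""
        out = []
        Fs = self.F
        for s, d, cnt in zip(sires, dams, counts):
            # exact Mendelian-sampling covariance given parental inbreeding
            scale = 0.5 * (1.0 - 0.5 * (Fs[s] + Fs[d]))
            Lm = self._Lg * np.sqrt(scale)
            mid_a = 0.5 * (self.a[s] + self.a[d])
            mid_m = 0.5 * (self.m[s] + self.m[d])
            for _ in range(cnt):
                dev = Lm @ rng.standard_normal(2)
                sex = "F" if rng.random() < 0.5 else "M"
                if sex == "F":
                    env = self._Le @ rng.standard_normal(2)
                    e, pe = env[0], env[1]
                else:
                    e, pe = np.sqrt(self.vc.e("e")) * rng.standard_normal(), np.nan
                out.append(self._push(s, d, sex, sr, mid_a + dev[0], mid_m + dev[1], e, pe))
        return np.array(out)

    def refresh_inbreeding(self):
        from .pedigree import _inbreeding_ml

        self.F = _inbreeding_ml(
            np.asarray(self.sire, dtype=np.int64), np.asarray(self.dam, dtype=np.int64)
        )

    def pedigree(self) -> Pedigree:
        n = self.n
        ids = np.arange(1, n + 1, dtype=object)
        return Pedigree(
            ids=ids,
            sire=np.asarray(self.sire, dtype=np.int64),
            dam=np.asarray(self.dam, dtype=np.int64),
            sex=np.asarray(self.sex, dtype=object),
            sr=np.asarray(self.sr, dtype=np.int64),
        )


def _allocate_counts(weights: np.ndarray, total: int, rng) -> np.ndarray:
    """Integer allocation proportional to weights summing exactly to total
    (largest-remainder with random tie order)."""
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = raw - base
        order = np.argsort(-(frac + 1e-9 * rng.random(len(frac))))
        base[order[:short]] += 1
    return base


def run_program(config: SimConfig, seed: int = 1) -> SimulatedPopulation:
    """Run the full breeding program and return population plus truth.

    SR 1..``random_selection_until_sr`` use random parent replacement;
    variance components are then estimated once with the univariate Moda
    model and reused for every later BLUP evaluation; each subsequent SR
    selects the top males and females of the newest cohort on their Moda
    EBV.  Selected birds serve ``service_rounds`` rounds.
    """
    from .reml import estimate

    ss = np.random.SeedSequence(seed)
    rng_master, rng_found, rng_mate = [np.random.default_rng(s) for s in ss.spawn(3)]
    vc = config.true_vc
    pop = _Population(vc, rng_master)

    # founder pool: service_rounds cohorts of selected-size groups
    sire_cohorts, dam_cohorts = [], []
    for _ in range(config.service_rounds):
        ids = pop.add_founders(config.n_males_selected, config.n_females_selected, rng_found)
        sire_cohorts.append(ids[: config.n_males_selected])
        dam_cohorts.append(ids[config.n_males_selected:])
    pop.refresh_inbreeding()

    hatch_sd = config.hatch_sd_frac * config.phenotypic_sd
    records = []
    comps = []
    vc_hat = None

    for sr in range(1, config.n_sr + 1):
        rng_sr = np.random.default_rng(ss.spawn(1)[0])
        sires_active = np.concatenate(sire_cohorts)
        dams_active = np.concatenate(dam_cohorts)
        # dam age class = cohort age in rounds (1 newest .. service oldest)
        dam_age = np.concatenate([
            np.full(len(c), config.service_rounds - k)
            for k, c in enumerate(dam_cohorts)
        ])

        # hierarchical mating: shuffle dams once, chunk per sire
        order = rng_mate.permutation(len(dams_active))
        dam2sire = np.empty(len(dams_active), dtype=np.int64)
        for k, s in enumerate(rng_mate.permutation(sires_active)):
            dam2sire[order[k * config.dams_per_sire:(k + 1) * config.dams_per_sire]] = s

        # offspring per dam per hatch declines linearly with dam age
        ages = np.linspace(1, config.service_rounds, config.service_rounds)
        rate_of_age = np.interp(
            dam_age, ages,
            np.linspace(config.offspring_rate_young, config.offspring_rate_old,
                        config.service_rounds),
        )
        hatch_effects = rng_sr.normal(0.0, hatch_sd, size=config.hatches_per_sr)
        new_ids = []
        rec_hatch = []
        rec_damage = []
        for h in range(config.hatches_per_sr):
            per_hatch = config.offspring_per_sr // config.hatches_per_sr + (
                1 if h < config.offspring_per_sr % config.hatches_per_sr else 0
            )
            counts = _allocate_counts(rate_of_age, per_hatch, rng_sr)
            born = pop.drop_offspring(dam2sire, dams_active, counts, sr, rng_sr)
            new_ids.append(born)
            rec_hatch.extend([h] * len(born))
            rec_damage.extend(np.repeat(dam_age, counts))
        new_ids = np.concatenate(new_ids)
        pop.refresh_inbreeding()

        # phenotype the new cohort
        for i, h, ag in zip(new_ids, rec_hatch, rec_damage):
            d = pop.dam[i]
            male = pop.sex[i] == "M"
            fixed = (config.mean_bw + hatch_effects[h]
                     + (config.sex_effect if male else 0.0)
                     + config.dam_age_slope * ag)
            eta = rng_sr.normal(0.0, np.sqrt(vc.sigma2_dummy))
            bw = fixed + pop.a[i] + pop.m[d] + pop.pe[d] + pop.e[i] + eta
            records.append(dict(animal=i + 1, sr=sr, hatch=h, sex=pop.sex[i],
                                dam_age=int(ag), bw=bw))
            comps.append(dict(animal=i + 1, fixed=fixed, a=pop.a[i], m_dam=pop.m[d],
                              pe_dam=pop.pe[d], e=pop.e[i], dummy=eta))

        # --- selection -----------------------------------------------------
        if sr == config.n_sr:
            break
        cand = new_ids
        cand_sex = np.array([pop.sex[i] for i in cand])
        # parents selected at the end of round `sr` produce round `sr + 1`:
        # random replacement while the burn-in rounds are being produced,
        # BLUP truncation selection from then on
        if sr + 1 <= config.random_selection_until_sr:
            males = rng_sr.permutation(cand[cand_sex == "M"])[: config.n_males_selected]
            females = rng_sr.permutation(cand[cand_sex == "F"])[: config.n_females_selected]
        else:
            if vc_hat is None:
                ped_now = pop.pedigree()
                data_now = DataSet(pd.DataFrame(records),
                                   fixed_effects=(("sr", "hatch"), "sex", "dam_age"))
                res = estimate(data_now, ped_now, ModelConfig("moda", 1),
                               keep_solution=False)
                vc_hat = res.vc
            ped_now = pop.pedigree()
            data_now = DataSet(pd.DataFrame(records),
                               fixed_effects=(("sr", "hatch"), "sex", "dam_age"))
            ebv = _moda_blup_ebv(data_now, ped_now, vc_hat)
            males = cand[cand_sex == "M"]
            males = males[np.argsort(-ebv[males])][: config.n_males_selected]
            females = cand[cand_sex == "F"]
            females = females[np.argsort(-ebv[females])][: config.n_females_selected]
        if len(males) < config.n_males_selected or len(females) < config.n_females_selected:
            raise RuntimeError("selection pool underflow")
        sire_cohorts = [males] + sire_cohorts[:-1]
        dam_cohorts = [females] + dam_cohorts[:-1]

    ped = pop.pedigree()
    data = DataSet(pd.DataFrame(records),
                   fixed_effects=(("sr", "hatch"), "sex", "dam_age"))
    truth = pd.DataFrame({
        "animal": np.arange(1, pop.n + 1),
        "sire": np.asarray(pop.sire) + 1,
        "dam": np.asarray(pop.dam) + 1,
        "sex": pop.sex,
        "sr": pop.sr,
        "a": pop.a, "m": pop.m, "e": pop.e, "pe": pop.pe,
    })
    return SimulatedPopulation(
        ped=ped, data=data, truth=truth,
        components=pd.DataFrame(comps), config=config,
        vc_selection=vc_hat,
    )
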