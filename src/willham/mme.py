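"""Design matrices and Henderson mixed-model equations for maternal models.

The observation model is ``y = X b + Z g + U u + eps`` where ``g`` stacks
the genetic factors (direct ``a`` and maternal ``m``, per trait) over all
pedigree animals with covariance ``A (x) G0``, ``u`` stacks the
environmental levels — one residual ``e`` per phenotyped animal and one
permanent maternal effect ``pe`` per dam (per offspring sex in bivariate
mode) — and ``eps`` is the dummy residual with variance fixed to
``sigma2_dummy``.  The environmental levels of one individual (her own
``e`` and her ``pe``) form a small joint covariance block taken from
``E0``, which is what makes the direct-maternal environmental covariance
estimable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger("willham")

from .pedigree import Pedigree
from .sparsela import NotPositiveDefiniteError, SymFactor
from .varmodels import ModelConfig, ParameterMap, VarianceComponents

__all__ = [
    "DataSet",
    "DesignSet",
    "MMESystem",
    "Solution",
    "build_design",
    "assemble_mme",
    "solve",
    "solve_model",
]


@dataclass
class DataSet:
    """Phenotype records plus the fixed-effect layout.

    ``table`` must carry an ``animal`` column (identifiers known to the
    pedigree) and the trait column; ``fixed_effects`` entries are column
    names, or tuples of column names for interaction factors such as
    hatch-within-selection-round.
    """

    table: pd.DataFrame
    trait_col: str = "bw"
    fixed_effects: tuple = (("sr", "hatch"), "sex", "dam_age")

    def __post_init__(self):
        if "animal" not in self.table.columns:
            raise ValueError("phenotype table needs an 'animal' column")
        if self.trait_col not in self.table.columns:
            raise ValueError(f"missing trait column {self.trait_col!r}")

    def __len__(self):
        return len(self.table)

    def subset(self, mask) -> "DataSet":
        return DataSet(self.table[np.asarray(mask)].reset_index(drop=True),
                       self.trait_col, self.fixed_effects)


@dataclass
class DesignSet:
    """Incidence matrices and environmental-block bookkeeping."""

    y: np.ndarray
    X: sp.csr_matrix
    Z: sp.csr_matrix
    U: sp.csr_matrix
    fixed_labels: list
    record_animal: np.ndarray
    record_dam: np.ndarray
    record_trait: np.ndarray
    # environmental levels, grouped contiguously per owning individual
    env_owner: np.ndarray
    env_factor: np.ndarray
    env_block_ptr: np.ndarray          # block k = levels [ptr[k], ptr[k+1])
    patterns: list                     # unique tuples of env-factor indices
    block_pattern: np.ndarray          # pattern index per block
    n_animals: int
    n_genetic_factors: int
    n_unknown_dam: int = 0
    config: ModelConfig | None = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_env(self) -> int:
        return self.env_owner.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]


def _trait_of(config: ModelConfig, sex) -> int:
    if config.n_traits == 1:
        return 0
    return 0 if str(sex).upper().startswith("F") else 1


def build_design(dataset: DataSet, ped: Pedigree, config: ModelConfig) -> DesignSet:
    """Build X, Z and the joint environmental incidence matrix U.

    Every phenotyped animal gets exactly one ``e`` level for its trait;
    every dam linked to at least one record gets a ``pe`` level per
    offspring sex group (bivariate) or one overall (univariate).  Records
    with an unknown dam carry no maternal links.
    """
    tbl = dataset.table
    n = len(tbl)
    y = tbl[dataset.trait_col].to_numpy(dtype=float)
    animal = ped.code(tbl["animal"])
    dam = ped.dam[animal]
    if config.n_traits == 2 or "sex" in tbl.columns:
        sexes = tbl["sex"].to_numpy()
    else:
        sexes = ped.sex[animal]
    trait = np.array([_trait_of(config, s) for s in sexes], dtype=np.int64)

    dup = pd.MultiIndex.from_arrays([animal, trait]).duplicated()
    if dup.any():
        bad = tbl["animal"].iloc[int(np.argmax(dup))]
        raise ValueError(f"animal {bad!r} has more than one record for a trait")

    # ---- fixed effects: per-trait intercept + drop-first dummies ----------
    cols_i, cols_j, labels = [], [], []
    rows = np.arange(n)
    for t in range(config.n_traits):
        sel = rows[trait == t]
        labels.append((t, "intercept", ""))
        cols_i.append(sel)
        cols_j.append(np.full(len(sel), len(labels) - 1))
    for fe in dataset.fixed_effects:
        name = fe if isinstance(fe, str) else ":".join(fe)
        if isinstance(fe, str):
            vals = tbl[fe].astype(str).to_numpy()
        else:
            vals = np.array([":".join(map(str, v)) for v in zip(*(tbl[c] for c in fe))])
        for t in range(config.n_traits):
            sel = rows[trait == t]
            levels = pd.unique(vals[sel])
            if len(levels) < 2:
                continue  # constant factor: absorbed by the intercept
            lmap = {lv: k for k, lv in enumerate(levels)}
            codes = np.array([lmap[v] for v in vals[sel]])
            for lv in levels[1:]:  # first level dropped (reference)
                labels.append((t, name, lv))
            keep = codes > 0
            cols_i.append(sel[keep])
            cols_j.append(len(labels) - (len(levels) - 1) + codes[keep] - 1)
    p = len(labels)
    X = sp.csr_matrix(
        (np.ones(sum(len(c) for c in cols_i)), (np.concatenate(cols_i), np.concatenate(cols_j))),
        shape=(n, p),
    )

    # ---- genetic design ---------------------------------------------------
    # genetic effects are stored animal-major (all factors of one animal
    # adjacent): the precision A^-1 (x) G0^-1 then carries a full small
    # block per A^-1 entry, which keeps every posterior-covariance entry
    # needed by REML inside the factor's sparsity pattern
    gf = config.genetic_factors
    gidx = {f: k for k, f in enumerate(gf)}
    N = ped.n
    kg = len(gf)
    zi, zj = [rows], []
    if config.n_traits == 1:
        zj.append(animal * kg + gidx["a"])
    else:
        af = np.where(trait == 0, gidx["a_F"], gidx["a_M"])
        zj.append(animal * kg + af)
    if config.include_maternal_genetic:
        known = dam >= 0
        zi.append(rows[known])
        if config.n_traits == 1:
            zj.append(dam[known] * kg + gidx["m"])
        else:
            mf = np.where(trait[known] == 0, gidx["m_F"], gidx["m_M"])
            zj.append(dam[known] * kg + mf)
    Z = sp.csr_matrix(
        (np.ones(sum(len(c) for c in zi)), (np.concatenate(zi), np.concatenate(zj))),
        shape=(n, len(gf) * N),
    )

    # ---- environmental levels --------------------------------------------
    ef = config.env_factors
    eidx = {f: k for k, f in enumerate(ef)}
    if config.n_traits == 1:
        e_fac = np.full(n, eidx["e"])
        pe_fac_of_trait = {0: eidx["pe"]}
    else:
        e_fac = np.where(trait == 0, eidx["e_F"], eidx["e_M"])
        pe_fac_of_trait = {0: eidx["pe_F"], 1: eidx["pe_M"]}

    levels = {}  # (owner, factor) -> level id
    for a, f in zip(animal, e_fac):
        levels[(int(a), int(f))] = -1
    known = dam >= 0
    for d, t in zip(dam[known], trait[known]):
        levels[(int(d), pe_fac_of_trait[int(t)])] = -1
    ordered = sorted(levels)  # groups by owner, factors ascending within owner
    for k, key in enumerate(ordered):
        levels[key] = k
    env_owner = np.array([o for o, _ in ordered], dtype=np.int64)
    env_factor = np.array([f for _, f in ordered], dtype=np.int64)

    ui = [rows]
    uj = [np.array([levels[(int(a), int(f))] for a, f in zip(animal, e_fac)])]
    ui.append(rows[known])
    uj.append(np.array([levels[(int(d), pe_fac_of_trait[int(t)])]
                        for d, t in zip(dam[known], trait[known])], dtype=np.int64))
    U = sp.csr_matrix(
        (np.ones(len(ui[0]) + len(ui[1])), (np.concatenate(ui), np.concatenate(uj))),
        shape=(n, len(ordered)),
    )

    if (~known).any():
        log.info("%d records with unknown dam: maternal links disabled for them",
                 int((~known).sum()))

    # block boundaries where the owner changes
    starts = np.flatnonzero(np.r_[True, env_owner[1:] != env_owner[:-1]])
    env_block_ptr = np.r_[starts, len(env_owner)]
    patterns: list = []
    pat_index: dict = {}
    block_pattern = np.empty(len(starts), dtype=np.int64)
    for k in range(len(starts)):
        pat = tuple(env_factor[env_block_ptr[k]:env_block_ptr[k + 1]])
        if pat not in pat_index:
            pat_index[pat] = len(patterns)
            patterns.append(pat)
        block_pattern[k] = pat_index[pat]

    return DesignSet(
        y=y, X=X, Z=Z, U=U, fixed_labels=labels,
        record_animal=animal, record_dam=dam, record_trait=trait,
        env_owner=env_owner, env_factor=env_factor,
        env_block_ptr=env_block_ptr, patterns=patterns, block_pattern=block_pattern,
        n_animals=N, n_genetic_factors=len(gf),
        n_unknown_dam=int((~known).sum()), config=config,
    )


def environmental_block_structure(design: DesignSet, vc: VarianceComponents):
    """Block-diagonal precision over the environmental levels.

    One block per individual: E0 restricted to her present ``(e, pe...)``
    factors, inverted.  Returns ``(precision csc, log|Sigma_env|)``.
    """
    rows, cols, vals = [], [], []
    logdet = 0.0
    ptr = design.env_block_ptr
    for pat_id, pat in enumerate(design.patterns):
        sub = vc.E0[np.ix_(pat, pat)]
        sign, ld = np.linalg.slogdet(sub)
        if sign <= 0:
            raise NotPositiveDefiniteError(
                f"environmental block {tuple(vc.env_factors[f] for f in pat)} "
                "is not positive definite"
            )
        inv = np.linalg.inv(sub)
        blocks = np.flatnonzero(design.block_pattern == pat_id)
        starts = ptr[blocks]
        logdet += len(blocks) * ld
        k = len(pat)
        for r in range(k):
            for c in range(k):
                rows.append(starts + r)
                cols.append(starts + c)
                vals.append(np.full(len(starts), inv[r, c]))
    prec = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(design.n_env, design.n_env),
    ).tocsc()
    return prec, logdet


@dataclass
class MMESystem:
    C: sp.csc_matrix
    rhs: np.ndarray
    W: sp.csr_matrix
    design: DesignSet
    ped: Pedigree
    vc: VarianceComponents
    pm: ParameterMap
    yty: float
    logdet_G: float
    logdet_E: float
    logdet_R: float

    @property
    def offsets(self):
        d = self.design
        p = d.n_fixed
        kg = d.n_genetic_factors
        return p, kg, d.n_animals, d.n_env


@dataclass
class Solution:
    b: np.ndarray
    genetic: np.ndarray        # (kg, N) BLUPs per genetic factor
    env: np.ndarray            # per environmental level, design order
    minus2logl: float
    factor: SymFactor = field(repr=False)
    system: MMESystem = field(repr=False)

    def ebv(self, factor: str = "a") -> np.ndarray:
        """BLUP vector for one genetic factor over all pedigree animals."""
        k = self.system.vc.genetic_factors.index(factor)
        return self.genetic[k]

    def fitted_fixed(self) -> np.ndarray:
        return self.system.design.X @ self.b


def assemble_mme(
    design: DesignSet,
    ped: Pedigree,
    vc: VarianceComponents,
    pm: ParameterMap,
    *,
    ainv: sp.spmatrix | None = None,
    use_inbreeding: bool = True,
) -> MMESystem:
    """Henderson equations with the dummy residual as the only least-squares
    residual; ``e`` and ``pe`` enter as correlated random effects."""
    from .pedigree import a_inverse

    vcm = pm.mask(vc)
    # pattern guard: a *free* covariance sitting exactly at zero would put
    # exact zeros into the precision, which the sparse factorization prunes
    # from its stored pattern — and the REML trace terms need the inverse
    # exactly there.  A relatively negligible offset keeps the position.
    for mat, i, j in pm.free:
        if i != j:
            M = vcm.G0 if mat == "G" else vcm.E0
            if M[i, j] == 0.0:
                M[i, j] = M[j, i] = 1e-10 * np.sqrt(M[i, i] * M[j, j])
    G0m = vcm.G0
    sign, ld_g0 = np.linalg.slogdet(G0m)
    if sign <= 0:
        raise NotPositiveDefiniteError("masked G0 is not positive definite")
    if ainv is None:
        ainv = a_inverse(ped, use_inbreeding)
    kg = design.n_genetic_factors
    # animal-major kron with *explicit* zeros in G0^-1 so that the full
    # kg x kg block pattern is materialized per A^-1 entry
    G0inv = np.linalg.inv(G0m)
    kk = np.arange(kg)
    G0inv_sp = sp.coo_matrix(
        (G0inv.ravel(), (np.repeat(kk, kg), np.tile(kk, kg))), shape=(kg, kg)
    ).tocsr()
    Gprec = sp.kron(ainv, G0inv_sp, format="csc")
    Eprec, logdet_E = environmental_block_structure(design, vcm)

    W = sp.hstack([design.X, design.Z, design.U], format="csr")
    lam = 1.0 / vcm.sigma2_dummy
    p = design.n_fixed
    # assemble from raw triplets: sparse addition would prune the explicit
    # zeros that keep masked-covariance positions inside the pattern (the
    # REML trace terms read the selected inverse exactly there)
    wtw = ((W.T @ W) * lam).tocoo()
    gp = Gprec.tocoo()
    ep = Eprec.tocoo()
    dim = p + Gprec.shape[0] + Eprec.shape[0]
    rows = np.concatenate([wtw.row, gp.row + p, ep.row + p + Gprec.shape[0]])
    cols = np.concatenate([wtw.col, gp.col + p, ep.col + p + Gprec.shape[0]])
    vals = np.concatenate([wtw.data, gp.data, ep.data])
    C = sp.coo_matrix((vals, (rows, cols)), shape=(dim, dim)).tocsc()
    C.sum_duplicates()
    rhs = (W.T @ design.y) * lam
    logdet_G = design.n_animals * ld_g0 + kg * ped.log_det_a(use_inbreeding)
    logdet_R = design.n_records * np.log(vcm.sigma2_dummy)
    return MMESystem(
        C=C, rhs=rhs, W=W, design=design, ped=ped, vc=vcm, pm=pm,
        yty=float(design.y @ design.y),
        logdet_G=logdet_G, logdet_E=logdet_E, logdet_R=logdet_R,
    )


def solve(system: MMESystem, factor=None) -> Solution:
    """Solve the MME by sparse LDL' factorization.

    The restricted -2 log-likelihood reported is
    ``log|C| + log|G| + log|R| + y'Py`` (the additive constant
    ``(n - rank X) log 2 pi`` is dropped throughout the package).
    ``factor`` may supply a pre-computed factorization of ``system.C``
    (used by REML to reuse the symbolic analysis across iterations).
    """
    if factor is None:
        factor = SymFactor(system.C)
    sol = factor.solve(system.rhs)
    p, kg, N, ne = system.offsets
    lam = 1.0 / system.vc.sigma2_dummy
    ypy = system.yty * lam - float(sol @ system.rhs)
    m2ll = factor.logdet + system.logdet_G + system.logdet_E + system.logdet_R + ypy
    return Solution(
        b=sol[:p],
        genetic=sol[p:p + kg * N].reshape(N, kg).T,
        env=sol[p + kg * N:],
        minus2logl=m2ll,
        factor=factor,
        system=system,
    )


def solve_model(
    dataset: DataSet,
    ped: Pedigree,
    config: ModelConfig,
    vc: VarianceComponents,
    *,
    ainv: sp.spmatrix | None = None,
) -> Solution:
    """Convenience: design + assembly + solve for a model and components."""
    from .varmodels import build_structure

    design = build_design(dataset, ped, config)
    pm = build_structure(config)
    return solve(assemble_mme(design, ped, vc, pm, ainv=ainv))
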