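"""The five maternal-model variance structures and their parameter maps.

A Willham maternal animal model decomposes body weight into a direct
additive genetic effect ``a``, a maternal genetic effect ``m`` of the dam,
a permanent environmental maternal effect ``pe`` of the dam and a direct
environmental effect ``e``.  Five nested variants are supported:

=========  ==============================================================
moda       no maternal genetic effect, both covariances zero
modam      maternal genetic effect, both covariances zero
coram      direct-maternal genetic covariance Cov(a, m) free
corepe     direct-maternal environmental covariance Cov(e, pe) free
coramepe   both covariances free
=========  ==============================================================

The environmental covariance is only estimable because the model carries a
*dummy residual*: a residual with variance fixed to a small constant
(default 1), which turns the real residual ``e`` into an ordinary random
effect per phenotyped animal that may covary with the dam's ``pe``.  The
true residual variance is then the estimated ``sigma2_e`` plus the dummy
constant.

In bivariate mode female and male body weight are distinct traits of
distinct individuals; a dam keeps one ``pe`` per offspring sex, and her own
residual is ``e_F``, so the male residual never covaries with any maternal
effect (structural zeros).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MODEL_NAMES = ("moda", "modam", "coram", "corepe", "coramepe")

__all__ = [
    "ModelConfig",
    "VarianceComponents",
    "ParameterMap",
    "build_structure",
    "total_residual_variance",
    "derived_ratios",
    "bend",
]


@dataclass(frozen=True)
class ModelConfig:
    """Which model variant, and for how many traits (1 or 2)."""

    name: str
    n_traits: int = 1

    def __post_init__(self):
        name = self.name.lower()
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        object.__setattr__(self, "name", name)
        if self.n_traits not in (1, 2):
            raise ValueError("n_traits must be 1 or 2")

    @property
    def include_maternal_genetic(self) -> bool:
        return self.name != "moda"

    @property
    def include_cor_am(self) -> bool:
        return self.name in ("coram", "coramepe")

    @property
    def include_cor_epe(self) -> bool:
        return self.name in ("corepe", "coramepe")

    @property
    def genetic_factors(self) -> tuple:
        if self.n_traits == 1:
            return ("a", "m") if self.include_maternal_genetic else ("a",)
        base = ("a_F", "a_M")
        return base + ("m_F", "m_M") if self.include_maternal_genetic else base

    @property
    def env_factors(self) -> tuple:
        if self.n_traits == 1:
            return ("e", "pe")
        return ("e_F", "e_M", "pe_F", "pe_M")


@dataclass
class VarianceComponents:
    """Dense (co)variance matrices per factor group plus the dummy constant.

    ``G0`` is the genetic covariance over :attr:`ModelConfig.genetic_factors`
    (distributed over animals as ``A (x) G0``); ``E0`` the environmental
    covariance over the per-individual ``(e, pe)`` profile.  Masked entries
    are exactly zero.  ``sigma2_dummy`` is never estimated.
    """

    genetic_factors: tuple
    G0: np.ndarray
    env_factors: tuple
    E0: np.ndarray
    sigma2_dummy: float = 1.0

    def __post_init__(self):
        self.G0 = np.asarray(self.G0, dtype=float)
        self.E0 = np.asarray(self.E0, dtype=float)
        kg, ke = len(self.genetic_factors), len(self.env_factors)
        if self.G0.shape != (kg, kg) or self.E0.shape != (ke, ke):
            raise ValueError("covariance matrix shape does not match factors")
        if self.sigma2_dummy <= 0:
            raise ValueError("sigma2_dummy must be positive")

    def copy(self) -> "VarianceComponents":
        return replace(self, G0=self.G0.copy(), E0=self.E0.copy())

    def g(self, row: str, col: str | None = None) -> float:
        i = self.genetic_factors.index(row)
        j = i if col is None else self.genetic_factors.index(col)
        return float(self.G0[i, j])

    def e(self, row: str, col: str | None = None) -> float:
        i = self.env_factors.index(row)
        j = i if col is None else self.env_factors.index(col)
        return float(self.E0[i, j])


@dataclass
class ParameterMap:
    """Addresses of the free parameters of a model.

    ``free`` lists ``(matrix, i, j)`` with ``matrix in {'G', 'E'}`` and
    ``i <= j`` in the factor ordering of the model; everything not free and
    not on a within-block diagonal/covariance is fixed at zero, and the
    dummy variance is always in the fixed-constant set.  ``g_blocks`` /
    ``e_blocks`` partition the factors into independent sub-matrices — the
    masks of all five models are block-structured, which the EM and
    likelihood code exploits.
    """

    config: ModelConfig
    free: list = field(default_factory=list)
    g_blocks: list = field(default_factory=list)
    e_blocks: list = field(default_factory=list)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def get_free(self, vc: VarianceComponents) -> np.ndarray:
        out = np.empty(self.n_free)
        for q, (mat, i, j) in enumerate(self.free):
            out[q] = (vc.G0 if mat == "G" else vc.E0)[i, j]
        return out

    def set_free(self, vc: VarianceComponents, theta: np.ndarray) -> VarianceComponents:
        new = vc.copy()
        for q, (mat, i, j) in enumerate(self.free):
            M = new.G0 if mat == "G" else new.E0
            M[i, j] = M[j, i] = theta[q]
        return new

    def mask(self, vc: VarianceComponents) -> VarianceComponents:
        """Zero every entry outside the model's block structure."""
        new = vc.copy()
        for M, blocks in ((new.G0, self.g_blocks), (new.E0, self.e_blocks)):
            keep = np.zeros(M.shape, dtype=bool)
            for b in blocks:
                keep[np.ix_(b, b)] = True
            M[~keep] = 0.0
        # bivariate structural zero inside the joint e/pe block: e_F never
        # covaries with e_M even when both sit in one block
        if self.config.n_traits == 2:
            ef = self.config.env_factors.index("e_F")
            em = self.config.env_factors.index("e_M")
            new.E0[ef, em] = new.E0[em, ef] = 0.0
            if not self.config.include_cor_epe:
                for pe in ("pe_F", "pe_M"):
                    p = self.config.env_factors.index(pe)
                    new.E0[ef, p] = new.E0[p, ef] = 0.0
                    new.E0[em, p] = new.E0[p, em] = 0.0
        return new


def build_structure(config: ModelConfig) -> ParameterMap:
    """Free-parameter map for one of the five models.

    Univariate free counts: moda 3, modam 4, coram 5, corepe 5, coramepe 6.
    """
    gf, ef = config.genetic_factors, config.env_factors
    gi = {f: i for i, f in enumerate(gf)}
    ei = {f: i for i, f in enumerate(ef)}
    free: list = []

    if config.n_traits == 1:
        free.append(("G", gi["a"], gi["a"]))
        if config.include_maternal_genetic:
            if config.include_cor_am:
                free.append(("G", gi["a"], gi["m"]))
            free.append(("G", gi["m"], gi["m"]))
            g_blocks = [(gi["a"], gi["m"])] if config.include_cor_am else [(gi["a"],), (gi["m"],)]
        else:
            g_blocks = [(gi["a"],)]
        free.append(("E", ei["e"], ei["e"]))
        if config.include_cor_epe:
            free.append(("E", ei["e"], ei["pe"]))
            e_blocks = [(ei["e"], ei["pe"])]
        else:
            e_blocks = [(ei["e"],), (ei["pe"],)]
        free.append(("E", ei["pe"], ei["pe"]))
        return ParameterMap(config, free, g_blocks, e_blocks)

    # bivariate: female and male BW as correlated traits
    free += [("G", gi["a_F"], gi["a_F"]), ("G", gi["a_F"], gi["a_M"]), ("G", gi["a_M"], gi["a_M"])]
    if config.include_maternal_genetic:
        if config.include_cor_am:
            for am in ("a_F", "a_M"):
                for mm in ("m_F", "m_M"):
                    free.append(("G", min(gi[am], gi[mm]), max(gi[am], gi[mm])))
            g_blocks = [tuple(range(4))]
        else:
            g_blocks = [(gi["a_F"], gi["a_M"]), (gi["m_F"], gi["m_M"])]
        free += [("G", gi["m_F"], gi["m_F"]), ("G", gi["m_F"], gi["m_M"]), ("G", gi["m_M"], gi["m_M"])]
    else:
        g_blocks = [(gi["a_F"], gi["a_M"])]

    free += [("E", ei["e_F"], ei["e_F"]), ("E", ei["e_M"], ei["e_M"])]
    if config.include_cor_epe:
        # the dam's own residual is e_F; sigma_eF.peF and sigma_eF.peM are
        # free, every covariance touching e_M is structurally zero
        free += [("E", ei["e_F"], ei["pe_F"]), ("E", ei["e_F"], ei["pe_M"])]
        e_blocks = [(ei["e_F"], ei["pe_F"], ei["pe_M"]), (ei["e_M"],)]
    else:
        e_blocks = [(ei["e_F"],), (ei["e_M"],), (ei["pe_F"], ei["pe_M"])]
    free += [("E", ei["pe_F"], ei["pe_F"]), ("E", ei["pe_F"], ei["pe_M"]), ("E", ei["pe_M"], ei["pe_M"])]
    return ParameterMap(config, free, g_blocks, e_blocks)


def initial_components(
    config: ModelConfig,
    phenotypic_variance,
    sigma2_dummy: float = 1.0,
) -> VarianceComponents:
    """Default REML starting values from the raw phenotypic variance.

    40% of the phenotypic variance goes to the residual, 30% to the direct
    genetic variance, 10% each to the maternal genetic and permanent
    environmental variances; covariances start at zero.
    """
    pv = np.atleast_1d(np.asarray(phenotypic_variance, dtype=float))
    if config.n_traits == 2 and pv.size == 1:
        pv = np.repeat(pv, 2)
    gf, ef = config.genetic_factors, config.env_factors
    G0 = np.zeros((len(gf), len(gf)))
    E0 = np.zeros((len(ef), len(ef)))
    for i, f in enumerate(gf):
        t = 0 if (config.n_traits == 1 or f.endswith("_F")) else 1
        G0[i, i] = (0.3 if f.startswith("a") else 0.1) * pv[t]
    for i, f in enumerate(ef):
        t = 0 if (config.n_traits == 1 or f.endswith("_F")) else 1
        E0[i, i] = (0.4 if f.startswith("e") else 0.1) * pv[t]
    vc = VarianceComponents(gf, G0, ef, E0, sigma2_dummy)
    validate_dummy(vc)
    return vc


def validate_dummy(vc: VarianceComponents) -> None:
    """Warn when the dummy variance is not small against the residual.

    The reparameterization requires the fixed constant to be smaller than
    the true residual variance; a large dummy leaves no room for the
    estimable part of the residual.
    """
    e_idx = [i for i, f in enumerate(vc.env_factors) if f.startswith("e")]
    smallest_e = min(vc.E0[i, i] for i in e_idx)
    if smallest_e > 0 and vc.sigma2_dummy >= 0.5 * smallest_e:
        warnings.warn(
            f"dummy residual variance {vc.sigma2_dummy} is not small relative "
            f"to the residual variance {smallest_e}; it must stay below the "
            "true residual for the reparameterization to be meaningful",
            stacklevel=2,
        )


def total_residual_variance(vc: VarianceComponents):
    """True residual variance per trait: estimated sigma2_e + dummy."""
    e_idx = [i for i, f in enumerate(vc.env_factors) if f.startswith("e")]
    out = np.array([vc.E0[i, i] + vc.sigma2_dummy for i in e_idx])
    return float(out[0]) if len(out) == 1 else out


def derived_ratios(vc: VarianceComponents, config: ModelConfig) -> dict:
    """Heritability and direct-maternal correlations per trait.

    ``h2 = sigma2_a / (sigma2_a + sigma2_m + sigma2_pe + sigma2_e + dummy)``
    (maternal term omitted when the model excludes it; covariance terms are
    not part of the phenotypic variance).  ``r_am`` and ``r_epe`` are plain
    correlations; a zero covariance gives 0, a zero variance under a
    requested nonzero covariance is an error.
    """
    out = {}
    suffixes = [""] if config.n_traits == 1 else ["_F", "_M"]
    for sfx in suffixes:
        key = sfx.strip("_") or None
        s2a = vc.g("a" + sfx)
        s2m = vc.g("m" + sfx) if config.include_maternal_genetic else 0.0
        s2pe = vc.e("pe" + sfx)
        s2e = vc.e("e" + sfx)
        denom = s2a + s2m + s2pe + s2e + vc.sigma2_dummy
        if denom <= 0:
            raise ZeroDivisionError("non-positive phenotypic variance")
        res = {"h2": s2a / denom}
        if config.include_maternal_genetic:
            cam = vc.g("a" + sfx, "m" + sfx)
            res["r_am"] = _corr(cam, s2a, s2m)
        # the dam's own residual is the female trait in bivariate mode
        e_own = "e" if config.n_traits == 1 else "e_F"
        cepe = vc.e(e_own, "pe" + sfx)
        res["r_epe"] = _corr(cepe, vc.e(e_own), s2pe)
        out[key] = res
    return out if config.n_traits == 2 else out[None]


def _corr(cov: float, v1: float, v2: float) -> float:
    if cov == 0.0:
        return 0.0
    if v1 <= 0 or v2 <= 0:
        raise ZeroDivisionError("zero variance under a nonzero covariance")
    return float(cov / np.sqrt(v1 * v2))


def bend(M: np.ndarray, blocks, rel_floor: float = 1e-8) -> np.ndarray:
    """Project each block of a symmetric matrix back into the PD cone.

    Eigenvalues below ``rel_floor`` times the largest block eigenvalue are
    clipped up to that floor; PD inputs pass through unchanged.
    """
    out = M.copy()
    for b in blocks:
        idx = np.ix_(b, b)
        sub = out[idx]
        w, V = np.linalg.eigh(sub)
        floor = rel_floor * max(w.max(), 1e-300)
        if w.min() < floor:
            w = np.clip(w, floor, None)
            out[idx] = (V * w) @ V.T
    return out
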