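"""Brute-force dense reference implementations.

These oracles compute the same quantities as the sparse machinery by the
most transparent route available — tabular relationship matrices, explicit
phenotypic covariance ``V``, generalized least squares, exhaustive grid
evaluation — and exist to verify the production code on small instances.
They are shipped inside the package so an installation can be checked
(``willham selftest``), but they are not meant for production-scale data.
"""

from __future__ import annotations

import numpy as np

from .mme import DataSet, DesignSet, build_design
from .pedigree import Pedigree, _tabular_a
from .varmodels import ModelConfig, ParameterMap, VarianceComponents, build_structure

__all__ = ["tabular_relationship", "dense_mixed_model_oracle", "grid_reml_oracle"]


def tabular_relationship(ped: Pedigree) -> np.ndarray:
    """Dense additive relationship matrix A by the recursive tabular method.

    Diagonal is ``1 + F``.  Quadratic memory: keep pedigrees small.
    """
    return _tabular_a(ped.sire, ped.dam)


def _dense_covariances(design: DesignSet, ped: Pedigree, vc: VarianceComponents):
    A = tabular_relationship(ped)
    Gfull = np.kron(A, vc.G0)  # animal-major, matching the sparse design
    Senv = np.zeros((design.n_env, design.n_env))
    ptr = design.env_block_ptr
    for k in range(len(ptr) - 1):
        pat = list(design.env_factor[ptr[k]:ptr[k + 1]])
        Senv[ptr[k]:ptr[k + 1], ptr[k]:ptr[k + 1]] = vc.E0[np.ix_(pat, pat)]
    return Gfull, Senv


def dense_mixed_model_oracle(
    dataset: DataSet,
    ped: Pedigree,
    vc: VarianceComponents,
    config: ModelConfig,
    pm: ParameterMap | None = None,
) -> dict:
    """GLS solution and restricted likelihood from the explicit dense V.

    ``V = Z (A (x) G0) Z' + U Sigma_env U' + I sigma2_dummy`` and
    ``-2logL = log|V| + log|X'V^-1 X| + y'Py`` (same constant convention as
    the sparse path).  Returns fixed effects, BLUPs of every random effect
    and the likelihood.
    """
    pm = pm or build_structure(config)
    vcm = pm.mask(vc)
    design = build_design(dataset, ped, config)
    X = design.X.toarray()
    Z = design.Z.toarray()
    U = design.U.toarray()
    y = design.y
    Gfull, Senv = _dense_covariances(design, ped, vcm)
    V = Z @ Gfull @ Z.T + U @ Senv @ U.T + np.eye(len(y)) * vcm.sigma2_dummy
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    XVX = XtVi @ X
    b = np.linalg.solve(XVX, XtVi @ y)
    Py = Vi @ (y - X @ b)
    ypy = float(y @ Py)
    sign_v, ld_v = np.linalg.slogdet(V)
    sign_x, ld_x = np.linalg.slogdet(XVX)
    if sign_v <= 0 or sign_x <= 0:
        raise np.linalg.LinAlgError("singular V or X'V^-1X")
    genetic = (Gfull @ Z.T @ Py).reshape(ped.n, design.n_genetic_factors).T
    env = Senv @ U.T @ Py
    return {
        "b": b,
        "genetic": genetic,
        "env": env,
        "minus2logl": ld_v + ld_x + ypy,
        "design": design,
    }


def grid_reml_oracle(
    dataset: DataSet,
    ped: Pedigree,
    config: ModelConfig,
    grid: dict,
    base_vc: VarianceComponents,
) -> dict:
    """Exhaustive REML over a small parameter grid.

    ``grid`` maps free-parameter addresses ``(matrix, i, j)`` to value
    arrays; all other components stay at ``base_vc``.  Returns the best
    grid point, its likelihood, and whether it sits on the grid boundary.
    """
    from itertools import product

    pm = build_structure(config)
    addrs = list(grid)
    best = None
    for values in product(*(grid[a] for a in addrs)):
        vc = base_vc.copy()
        for (mat, i, j), v in zip(addrs, values):
            M = vc.G0 if mat == "G" else vc.E0
            M[i, j] = M[j, i] = v
        try:
            m2ll = dense_mixed_model_oracle(dataset, ped, vc, config, pm)["minus2logl"]
        except np.linalg.LinAlgError:
            continue
        if best is None or m2ll < best[0]:
            best = (m2ll, values)
    if best is None:
        raise ValueError("no admissible grid point")
    on_boundary = any(
        v in (min(grid[a]), max(grid[a])) for a, v in zip(addrs, best[1])
    )
    return {
        "minus2logl": best[0],
        "values": dict(zip(addrs, best[1])),
        "on_boundary": on_boundary,
    }
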