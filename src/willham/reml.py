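"""Restricted maximum likelihood for the maternal-model variance components.

The free (co)variance parameters are estimated by average-information (AI)
REML with step halving and an expectation-maximization fallback; the dummy
residual variance is a fixed constant throughout.  Both the AI update and
the EM update are driven by the same per-iteration quantities: the BLUP
solution of the mixed-model equations and selected entries of the inverse
coefficient matrix (posterior covariances), obtained from the sparse
factorization by Takahashi recurrences.

Likelihood convention: ``-2logL = log|C| + log|G| + log|R| + y'Py`` with
the additive constant ``(n - rank X) log 2 pi`` dropped, identical to the
dense-V formula ``log|V| + log|X'V^-1 X| + y'Py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mme import DataSet, DesignSet, MMESystem, Solution, assemble_mme, build_design, solve
from .pedigree import Pedigree, a_inverse
from .sparsela import NotPositiveDefiniteError
from .varmodels import (
    ModelConfig,
    ParameterMap,
    VarianceComponents,
    bend,
    build_structure,
    initial_components,
)

__all__ = [
    "REMLResult",
    "REMLProblem",
    "estimate",
    "restricted_log_likelihood",
    "em_step",
    "ai_step",
    "lrt",
]


@dataclass
class REMLResult:
    """Outcome of a variance-component estimation."""

    vc: VarianceComponents
    minus2logl: float
    converged: bool
    status: str                       # converged | max_iterations | boundary
    n_iter: int
    trace: list                       # (iteration, -2logL, step kind)
    se: np.ndarray                    # per free parameter, AI-based
    covariance: np.ndarray            # asymptotic covariance of free params
    pm: ParameterMap
    solution: Solution | None = field(default=None, repr=False)

    def free_estimates(self) -> dict:
        names = [_param_name(self.pm, q) for q in range(self.pm.n_free)]
        vals = self.pm.get_free(self.vc)
        return dict(zip(names, vals))


def _param_name(pm: ParameterMap, q: int) -> str:
    mat, i, j = pm.free[q]
    cfg = pm.config
    fac = cfg.genetic_factors if mat == "G" else cfg.env_factors
    return f"var({fac[i]})" if i == j else f"cov({fac[i]},{fac[j]})"


class REMLProblem:
    """One dataset/pedigree/model combination, reused across iterations."""

    def __init__(
        self,
        dataset: DataSet,
        ped: Pedigree,
        config: ModelConfig,
        *,
        use_inbreeding: bool = True,
    ):
        self.ped = ped
        self.config = config
        self.pm = build_structure(config)
        self.design = build_design(dataset, ped, config)
        self.ainv = a_inverse(ped, use_inbreeding)
        self.use_inbreeding = use_inbreeding
        coo = self.ainv.tocoo()
        self._ai_r, self._ai_c, self._ai_v = coo.row, coo.col, coo.data
        self._ldl = None  # symbolic analysis shared across iterations

    def fit(self, vc: VarianceComponents) -> Solution:
        from .sparsela import LDLSolver

        system = assemble_mme(
            self.design, self.ped, vc, self.pm,
            ainv=self.ainv, use_inbreeding=self.use_inbreeding,
        )
        if self._ldl is None:
            self._ldl = LDLSolver(system.C)
        return solve(system, factor=self._ldl.factor(system.C))

    # ---- per-iteration derived statistics ---------------------------------

    def statistics(self, sol: Solution) -> dict:
        """Posterior quantities needed by both the EM and the AI update."""
        d = self.design
        p, kg, N, _ = sol.system.offsets
        vcm = sol.system.vc
        U_hat = sol.genetic.T                           # (N, kg)
        G0inv = np.linalg.inv(vcm.G0)
        AU = self.ainv @ U_hat                          # (N, kg)
        UAU = U_hat.T @ AU                              # (kg, kg)
        S = U_hat @ G0inv
        Q = S.T @ (self.ainv @ S)                       # quadratic terms

        # trace of A^-1 against the genetic blocks of C^-1, per model block
        T = np.zeros((kg, kg))
        for blk in self.pm.g_blocks:
            for a_f in blk:
                for b_f in blk:
                    if b_f < a_f:
                        continue
                    rows = p + self._ai_r * kg + a_f
                    cols = p + self._ai_c * kg + b_f
                    t = float(self._ai_v @ sol.factor.inverse_entries(rows, cols))
                    T[a_f, b_f] = T[b_f, a_f] = t

        # environmental pattern aggregates
        eoff = p + kg * N
        ptr = d.env_block_ptr
        env_stats = []
        for pat_id, pat in enumerate(d.patterns):
            blocks = np.flatnonzero(d.block_pattern == pat_id)
            starts = ptr[blocks]
            k = len(pat)
            lev = starts[:, None] + np.arange(k)[None, :]       # (nP, k)
            u = sol.env[lev]                                     # (nP, k)
            Vsum = np.zeros((k, k))
            for r in range(k):
                for s in range(r, k):
                    v = float(np.sum(sol.factor.inverse_entries(
                        eoff + lev[:, r], eoff + lev[:, s])))
                    Vsum[r, s] = Vsum[s, r] = v
            E_P = vcm.E0[np.ix_(pat, pat)]
            Einv = np.linalg.inv(E_P)
            env_stats.append({
                "pat": pat, "n": len(starts), "lev": lev,
                "uu": u.T @ u, "Vsum": Vsum, "Einv": Einv,
                "t": u @ Einv,                                  # (nP, k)
            })
        return {
            "p": p, "kg": kg, "N": N, "vcm": vcm,
            "U_hat": U_hat, "UAU": UAU, "G0inv": G0inv, "Q": Q, "T": T,
            "env": env_stats, "sol": sol,
        }

    # ---- EM ---------------------------------------------------------------

    def em_update(self, stats: dict) -> VarianceComponents:
        """One EM step: new G0 from posterior genetic moments, new E0 from
        the missing-pattern augmented environmental moments.  Masked
        entries stay exactly zero; the dummy variance is untouched."""
        vcm, N = stats["vcm"], stats["N"]
        new = vcm.copy()
        for blk in self.pm.g_blocks:
            b = np.ix_(blk, blk)
            new.G0[b] = (stats["UAU"][b] + stats["T"][b]) / N

        E0 = vcm.E0
        for blk in self.pm.e_blocks:
            blk = list(blk)
            kb = len(blk)
            M = np.zeros((kb, kb))
            n_tot = 0
            for st in stats["env"]:
                pat = list(st["pat"])
                pres_b = [t for t, f in enumerate(blk) if f in pat]
                if not pres_b:
                    continue
                pres_p = [pat.index(blk[t]) for t in pres_b]
                miss_b = [t for t in range(kb) if t not in pres_b]
                Wpp = (st["uu"] + st["Vsum"])[np.ix_(pres_p, pres_p)]
                n = st["n"]
                n_tot += n
                M[np.ix_(pres_b, pres_b)] += Wpp
                if miss_b:
                    fp = [blk[t] for t in pres_b]
                    fm = [blk[t] for t in miss_b]
                    B = E0[np.ix_(fm, fp)] @ np.linalg.inv(E0[np.ix_(fp, fp)])
                    BW = B @ Wpp
                    M[np.ix_(miss_b, pres_b)] += BW
                    M[np.ix_(pres_b, miss_b)] += BW.T
                    M[np.ix_(miss_b, miss_b)] += n * (
                        E0[np.ix_(fm, fm)] - B @ E0[np.ix_(fp, fm)]
                    ) + BW @ B.T
            if n_tot:
                new.E0[np.ix_(blk, blk)] = M / n_tot
        return self._sanitize(new)

    # ---- gradient and average information ---------------------------------

    def gradient(self, stats: dict) -> np.ndarray:
        """Exact gradient of -2logL with respect to the free parameters."""
        kg, N = stats["kg"], stats["N"]
        G0inv, T, Q = stats["G0inv"], stats["T"], stats["Q"]
        Ttil = G0inv @ T @ G0inv
        g = np.zeros(self.pm.n_free)
        for q, (mat, i, j) in enumerate(self.pm.free):
            mult = 1.0 if i == j else 2.0
            if mat == "G":
                g[q] = mult * (N * G0inv[i, j] - Ttil[i, j] - Q[i, j])
            else:
                acc = 0.0
                for st in self.pm_env_patterns(stats, i, j):
                    pat = list(st["pat"])
                    r, s = pat.index(i), pat.index(j)
                    Einv = st["Einv"]
                    EVE = Einv @ st["Vsum"] @ Einv
                    EUE = Einv @ st["uu"] @ Einv
                    acc += st["n"] * Einv[r, s] - EVE[r, s] - EUE[r, s]
                g[q] = mult * acc
        return g

    @staticmethod
    def pm_env_patterns(stats, i, j):
        for st in stats["env"]:
            if i in st["pat"] and j in st["pat"]:
                yield st

    def average_information(self, stats: dict) -> np.ndarray:
        """AI matrix via working variates solved against the same MME."""
        d = self.design
        sol: Solution = stats["sol"]
        kg, N = stats["kg"], stats["N"]
        G0inv, U_hat = stats["G0inv"], stats["U_hat"]
        nq = self.pm.n_free
        F = np.zeros((d.n_records, nq))
        for q, (mat, i, j) in enumerate(self.pm.free):
            if mat == "G":
                E_ij = np.zeros((kg, kg))
                E_ij[i, j] = E_ij[j, i] = 1.0
                w = (U_hat @ (G0inv @ E_ij)).ravel()  # animal-major
                F[:, q] = d.Z @ w
            else:
                g = np.zeros(d.n_env)
                for st in self.pm_env_patterns(stats, i, j):
                    pat = list(st["pat"])
                    r, s = pat.index(i), pat.index(j)
                    lev = st["lev"]
                    t = st["t"]
                    if r == s:
                        np.add.at(g, lev[:, r], t[:, r])
                    else:
                        np.add.at(g, lev[:, r], t[:, s])
                        np.add.at(g, lev[:, s], t[:, r])
                F[:, q] = d.U @ g
        lam = 1.0 / stats["vcm"].sigma2_dummy
        W = sol.system.W
        rhs = (W.T @ F) * lam
        sols = sol.factor.solve(rhs)
        PF = lam * (F - W @ sols)
        AI = 0.5 * (F.T @ PF)
        return 0.5 * (AI + AI.T)

    def ai_update(self, vc: VarianceComponents, stats: dict, step: float = 1.0):
        """Propose a (possibly damped) AI-REML Newton step."""
        g = self.gradient(stats)
        AI = self.average_information(stats)
        H = 2.0 * AI
        ridge = 1e-10 * max(np.trace(H) / max(len(g), 1), 1.0)
        delta = np.linalg.solve(H + ridge * np.eye(len(g)), -g)
        theta = self.pm.get_free(vc) + step * delta
        # a proposal outside the PD cone is rejected (caller halves the
        # step) rather than projected: projection destroys the descent
        # property of the AI direction
        new = self.pm.mask(self.pm.set_free(vc, theta))
        self._require_pd(new)
        return new, g, AI

    def _require_pd(self, vc: VarianceComponents) -> None:
        for M, blocks in ((vc.G0, self.pm.g_blocks), (vc.E0, self.pm.e_blocks)):
            for b in blocks:
                w = np.linalg.eigvalsh(M[np.ix_(b, b)])
                if w[0] <= 1e-12 * max(w[-1], 1.0):
                    raise NotPositiveDefiniteError("proposal left the PD cone")

    def _sanitize(self, vc: VarianceComponents) -> VarianceComponents:
        new = self.pm.mask(vc)
        new.G0 = bend(new.G0, self.pm.g_blocks)
        new.E0 = bend(new.E0, self.pm.e_blocks)
        return self.pm.mask(new)


def restricted_log_likelihood(
    vc: VarianceComponents,
    dataset: DataSet,
    ped: Pedigree,
    config: ModelConfig,
) -> float:
    """-2 restricted log-likelihood of a component set (sparse path)."""
    return REMLProblem(dataset, ped, config).fit(vc).minus2logl


def em_step(vc: VarianceComponents, solution: Solution, problem: REMLProblem) -> VarianceComponents:
    """One EM update of the free components given a solved system."""
    return problem.em_update(problem.statistics(solution))


def ai_step(vc: VarianceComponents, solution: Solution, problem: REMLProblem) -> VarianceComponents:
    """One AI-REML update with step halving and EM fallback.

    A proposal that leaves the PD cone or fails to decrease -2logL is step
    halved; if no damped AI step is acceptable the EM update is returned
    for this iteration.
    """
    stats = problem.statistics(solution)
    m2ll = solution.minus2logl
    noise = 1e-7 * (1.0 + abs(m2ll))
    step = 1.0
    for _ in range(6):
        try:
            new, _, _ = problem.ai_update(vc, stats, step)
            if problem.fit(new).minus2logl <= m2ll + noise:
                return new
        except (NotPositiveDefiniteError, np.linalg.LinAlgError):
            pass
        step *= 0.5
    return problem.em_update(stats)


def estimate(
    dataset: DataSet,
    ped: Pedigree,
    config: ModelConfig,
    init: VarianceComponents | None = None,
    *,
    sigma2_dummy: float = 1.0,
    tol_param: float = 1e-8,
    tol_logl: float = 1e-6,
    max_iter: int = 200,
    max_halvings: int = 6,
    use_inbreeding: bool = True,
    keep_solution: bool = True,
) -> REMLResult:
    """AI-REML with EM fallback for one of the five maternal models.

    Starting values default to a split of the raw phenotypic variance
    (40% residual, 30% direct genetic, 10% each maternal genetic and
    permanent environmental, zero covariances).  An AI proposal that
    leaves the positive-definite cone or fails to decrease -2logL is step
    halved and finally replaced by an EM step for that iteration; -2logL
    never increases across accepted iterations.
    """
    problem = REMLProblem(dataset, ped, config, use_inbreeding=use_inbreeding)
    if init is None:
        pv = _phenotypic_variance(problem.design, config)
        vc = initial_components(config, pv, sigma2_dummy)
        vc = problem._sanitize(vc)
    else:
        vc = problem._sanitize(init)

    sol = problem.fit(vc)
    m2ll = sol.minus2logl
    trace = [(0, m2ll, "init")]
    status = "max_iterations"
    n_iter = 0
    best = (m2ll, vc, sol)
    quiet = 0  # consecutive iterations at the numerical noise floor
    for it in range(1, max_iter + 1):
        n_iter = it
        # -2logL is recomputed through a fresh sparse factorization each
        # evaluation; its reproducibility is limited to ~1e-7 relative
        noise = 1e-7 * (1.0 + abs(m2ll))
        stats = problem.statistics(sol)
        accepted = None
        step = 1.0
        for _ in range(max_halvings):
            try:
                vc_try, g, AI = problem.ai_update(vc, stats, step)
                sol_try = problem.fit(vc_try)
            except (NotPositiveDefiniteError, np.linalg.LinAlgError):
                step *= 0.5
                continue
            if sol_try.minus2logl <= m2ll + noise:
                accepted = (vc_try, sol_try, "ai" if step == 1.0 else "ai-halved")
                break
            step *= 0.5
        if accepted is None:
            try:
                vc_try = problem.em_update(stats)
                sol_try = problem.fit(vc_try)
            except (NotPositiveDefiniteError, np.linalg.LinAlgError):
                status = "boundary"
                break
            if sol_try.minus2logl > m2ll + 10.0 * noise:
                status = "boundary"
                break
            accepted = (vc_try, sol_try, "em")

        vc_new, sol_new, kind = accepted
        d_theta = np.max(np.abs(problem.pm.get_free(vc_new) - problem.pm.get_free(vc))
                         / (np.abs(problem.pm.get_free(vc)) + 1.0))
        d_ll = m2ll - sol_new.minus2logl
        vc, sol, m2ll = vc_new, sol_new, sol_new.minus2logl
        trace.append((it, m2ll, kind))
        if m2ll < best[0]:
            best = (m2ll, vc, sol)
        if d_theta < tol_param and abs(d_ll) < tol_logl:
            status = "converged"
            break
        # at the numerical noise floor only when the likelihood is flat AND
        # the parameters have stopped moving (EM can crawl with tiny
        # likelihood gains per step but real cumulative movement)
        quiet = quiet + 1 if (abs(d_ll) <= max(tol_logl, noise)
                              and d_theta < 1e-4) else 0
        if quiet >= 2:
            status = "converged"
            break
    if best[0] < m2ll:
        m2ll, vc, sol = best

    # asymptotic covariance from the AI matrix at the final estimate
    stats = problem.statistics(sol)
    AI = problem.average_information(stats)
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov = np.full((problem.pm.n_free,) * 2, np.nan)
        se = np.full(problem.pm.n_free, np.nan)

    return REMLResult(
        vc=vc, minus2logl=m2ll,
        converged=(status == "converged"),
        status=status, n_iter=n_iter, trace=trace,
        se=se, covariance=cov, pm=problem.pm,
        solution=sol if keep_solution else None,
    )


def _phenotypic_variance(design: DesignSet, config: ModelConfig):
    if config.n_traits == 1:
        return float(np.var(design.y, ddof=1))
    return [
        float(np.var(design.y[design.record_trait == t], ddof=1)) if
        np.any(design.record_trait == t) else 1.0
        for t in range(2)
    ]


def lrt(result_nested: REMLResult, result_full: REMLResult) -> dict:
    """Likelihood-ratio test between nested component models on one dataset.

    The degrees of freedom are the plain difference in free-parameter
    counts; no boundary mixture correction is applied, so tests involving
    a variance fixed at zero are conservative in the usual way.
    """
    free_n = set(result_nested.pm.free)
    free_f = set(result_full.pm.free)
    # compare by parameter names: factor sets differ between moda and the rest
    names_n = {_param_name(result_nested.pm, q) for q in range(result_nested.pm.n_free)}
    names_f = {_param_name(result_full.pm, q) for q in range(result_full.pm.n_free)}
    if not names_n <= names_f:
        raise ValueError("models are not nested")
    stat = result_nested.minus2logl - result_full.minus2logl
    df = len(names_f) - len(names_n)
    out = {"statistic": float(stat), "df": df, "convergence_ok": stat >= -1e-4}
    return out
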