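"""Flat-file formats: pedigree, phenotypes, truth tables, reports.

Everything is comma-separated text with a header row, the conventional
exchange format for pedigree and phenotype data in animal breeding.
Unknown parents are coded ``0`` (or empty).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mme import DataSet, Solution
from .pedigree import Pedigree, load_and_sort
from .reml import REMLResult
from .varmodels import ModelConfig, VarianceComponents

log = logging.getLogger("willham")

PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "sr"]
PHENOTYPE_COLUMNS = ["animal", "sr", "hatch", "sex", "dam_age", "bw"]
DEFAULT_FIXED_EFFECTS = (("sr", "hatch"), "sex", "dam_age")


def read_pedigree(path) -> Pedigree:
    """Read ``animal,sire,dam,sex,sr`` (0/empty = unknown parent)."""
    tbl = pd.read_csv(path)
    missing = [c for c in PEDIGREE_COLUMNS[:3] if c not in tbl.columns]
    if missing:
        raise ValueError(f"pedigree file {path} lacks columns {missing}")
    for c in ("sex", "sr"):
        if c not in tbl.columns:
            tbl[c] = "" if c == "sex" else 0
    ped = load_and_sort(tbl[PEDIGREE_COLUMNS])
    log.info("read %d pedigree records from %s", ped.n, path)
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_phenotypes(path, fixed_effects=DEFAULT_FIXED_EFFECTS, trait_col="bw") -> DataSet:
    tbl = pd.read_csv(path)
    if "animal" not in tbl.columns or trait_col not in tbl.columns:
        raise ValueError(f"phenotype file {path} needs 'animal' and {trait_col!r} columns")
    n0 = len(tbl)
    tbl = tbl.dropna(subset=[trait_col]).reset_index(drop=True)
    if len(tbl) < n0:
        log.info("dropped %d rows without phenotype", n0 - len(tbl))
    dup = tbl["animal"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate phenotype for animal {tbl['animal'][dup].iloc[0]!r} "
            f"(line {int(np.flatnonzero(dup)[0]) + 2})"
        )
    log.info("read %d phenotype records from %s", len(tbl), path)
    return DataSet(tbl, trait_col=trait_col, fixed_effects=tuple(
        tuple(f) if isinstance(f, (list, tuple)) else f for f in fixed_effects
    ))


def write_phenotypes(data: DataSet, path) -> None:
    data.table.to_csv(path, index=False)


def read_model_config(path) -> dict:
    """Model/variance configuration: model name, trait count, dummy value,
    initial values per parameter, convergence settings (all optional but
    the model name)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "model" not in cfg:
        raise ValueError(f"config {path} must name a 'model'")
    return cfg


def components_from_config(cfg: dict, config: ModelConfig) -> VarianceComponents | None:
    """Build initial VarianceComponents from a config's ``initial`` block
    (keys like ``var_a``, ``cov_am``, ``var_e``, ``cov_epe``, ``var_pe``)."""
    init = cfg.get("initial")
    if not init:
        return None
    gf, ef = config.genetic_factors, config.env_factors
    G0 = np.zeros((len(gf),) * 2)
    E0 = np.zeros((len(ef),) * 2)
    def put(M, factors, key, value):
        parts = key.split("_", 1)[1]
        if key.startswith("var_"):
            i = factors.index(parts)
            M[i, i] = value
        else:
            a, b = parts.split(".") if "." in parts else (parts[0], parts[1:])
            i, j = factors.index(a), factors.index(b)
            M[i, j] = M[j, i] = value
    for key, value in init.items():
        target = G0 if key.split("_")[-1].replace(".", "")[0] in ("a", "m") else E0
        factors = gf if target is G0 else ef
        put(target, factors, key, float(value))
    return VarianceComponents(gf, G0, ef, E0, float(cfg.get("dummy", 1.0)))


def write_reml_report(result: REMLResult, path, *, lrt_vs: dict | None = None) -> None:
    """Estimation report: parameter table with SEs, -2logL, convergence
    trace, optional LRT against a named reference model."""
    path = Path(path)
    est = result.free_estimates()
    lines = ["parameter,estimate,se"]
    for (name, value), se in zip(est.items(), result.se):
        lines.append(f"{name},{value:.6g},{se:.6g}")
    lines.append(f"minus2logl,{result.minus2logl:.10g},")
    lines.append(f"dummy_variance,{result.vc.sigma2_dummy},fixed")
    lines.append(f"status,{result.status},{result.n_iter} iterations")
    if lrt_vs:
        lines.append(f"lrt_vs_{lrt_vs['reference']},{lrt_vs['statistic']:.6g},df={lrt_vs['df']}")
    path.write_text("\n".join(lines) + "\n")
    trace_path = path.with_suffix(".trace.csv")
    with open(trace_path, "w") as fh:
        fh.write("iteration,minus2logl,step\n")
        for it, ll, kind in result.trace:
            fh.write(f"{it},{ll:.10g},{kind}\n")


def write_solutions(solution: Solution, path) -> None:
    """All effect estimates as ``effect,level,estimate`` rows."""
    sys = solution.system
    rows = []
    for (t, name, lv), b in zip(sys.design.fixed_labels, solution.b):
        rows.append(("fixed", f"trait{t}:{name}:{lv}", b))
    for k, f in enumerate(sys.vc.genetic_factors):
        for i, a in enumerate(sys.ped.ids):
            rows.append((f, a, solution.genetic[k, i]))
    ef = sys.vc.env_factors
    for lev, (owner, fac) in enumerate(zip(sys.design.env_owner, sys.design.env_factor)):
        rows.append((ef[fac], sys.ped.ids[owner], solution.env[lev]))
    pd.DataFrame(rows, columns=["effect", "level", "estimate"]).to_csv(path, index=False)


def write_summary(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def read_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def write_variance_table(results: dict, path) -> None:
    """Per-model variance-component table (models as column groups)."""
    rows = {}
    for model, res in results.items():
        est = res.free_estimates()
        for (name, value), se in zip(est.items(), res.se):
            rows.setdefault(name, {})[model] = f"{value:.6g} ({se:.3g})"
        rows.setdefault("minus2logl", {})[model] = f"{res.minus2logl:.8g}"
    frame = pd.DataFrame(rows).T
    frame.index.name = "parameter"
    frame.to_csv(path)


def write_validation_tables(report, outdir) -> None:
    """Accuracy and inflation tables (models as columns)."""
    outdir = Path(outdir)
    tbl = report.table
    for kind, fname in (("cor", "accuracy.csv"), ("slope", "inflation.csv")):
        sel = tbl[tbl.metric.str.startswith(kind)]
        if len(sel):
            wide = sel.pivot(index="metric", columns="model", values="value")
            wide.to_csv(outdir / fname)
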