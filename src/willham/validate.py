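"""Cross-validation of predicted breeding values under maternal effects.

Two masking strategies are provided.  *Forward prediction* masks every
phenotype of the last selection rounds and predicts those birds from their
ancestors.  *Half-sib prediction* randomly masks half of each paternal
half-sib group in the last rounds and correlates the predicted breeding
value of a masked bird with the corrected phenotype of a paternal half-sib
from a different dam — a reference that shares no maternal effect with the
prediction, which is what makes the comparison fair when models differ in
how much maternal signal leaks into the direct breeding value.

All correlations and regression slopes are computed on values corrected
for the genetic trend: both variables are centred within selection round,
so the statistics use (co)variances conditional on the round means.
Variance components are always taken from a full-data fit of the same
model; only the phenotypes of validation birds are removed when
predicting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mme import DataSet, Solution, solve_model
from .pedigree import Pedigree
from .varmodels import ModelConfig, VarianceComponents

__all__ = [
    "SplitPlan",
    "ValidationReport",
    "forward_split",
    "halfsib_split_and_pair",
    "trend_correct",
    "corrected_phenotype",
    "accuracy_and_inflation",
    "crossval",
]


@dataclass
class SplitPlan:
    """Masking plan: which records keep phenotypes, who is validated."""

    mode: str                      # forward | halfsib
    train_mask: np.ndarray         # bool per record of the full DataSet
    validation_animals: np.ndarray  # external identifiers
    pairings: list = field(default_factory=list)  # halfsib: list of (i, j) arrays
    seed: int | None = None


def forward_split(data: DataSet, n_last: int = 5) -> SplitPlan:
    """Mask all records of the last ``n_last`` selection rounds."""
    sr = data.table["sr"].to_numpy()
    rounds = np.unique(sr)
    if len(rounds) < n_last + 1:
        raise ValueError(f"need more than {n_last} selection rounds, have {len(rounds)}")
    cut = rounds[-n_last]
    mask = sr < cut
    if mask.all():
        raise ValueError("validation set is empty")
    return SplitPlan(
        mode="forward",
        train_mask=mask,
        validation_animals=data.table.loc[~mask, "animal"].to_numpy(),
    )


def halfsib_split_and_pair(
    data: DataSet,
    ped: Pedigree,
    seed: int = 1,
    *,
    n_last: int = 5,
    n_resamples: int = 50,
    within_sex: bool = False,
) -> SplitPlan:
    """Mask half of each paternal half-sib group and build validation pairs.

    Within each sire's offspring in the last ``n_last`` rounds, a random
    half is masked; the extra animal of odd groups stays in training.
    Pairs are drawn among masked half-sibs with *different dams* (full sibs
    share the dam's maternal effects and are excluded), without
    replacement within one resample; ``n_resamples`` independent pairings
    are generated from substreams of ``seed``.
    """
    tbl = data.table
    sr = tbl["sr"].to_numpy()
    rounds = np.unique(sr)
    if len(rounds) < n_last + 1:
        raise ValueError(f"need more than {n_last} selection rounds")
    cut = rounds[-n_last]
    codes = ped.code(tbl["animal"])
    sires = ped.sire[codes]
    dams = ped.dam[codes]
    recent = (sr >= cut) & (sires >= 0)

    rng = np.random.default_rng(seed)
    train_mask = np.ones(len(tbl), dtype=bool)
    masked_rows: list = []
    for s in np.unique(sires[recent]):
        rows = np.flatnonzero(recent & (sires == s))
        if len(rows) < 2 or len(np.unique(dams[rows])) < 2:
            continue  # full sibs only: no maternally-independent pair exists
        rows = rng.permutation(rows)
        masked = rows[: len(rows) // 2]
        train_mask[masked] = False
        masked_rows.append(masked)
    if not masked_rows:
        raise ValueError("no paternal half-sib group allows a valid pair")

    sex = tbl["sex"].to_numpy() if "sex" in tbl.columns else np.full(len(tbl), "")
    pairings = []
    for k in range(n_resamples):
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        pairs_i, pairs_j = [], []
        for masked in masked_rows:
            order = sub.permutation(masked)
            used = np.zeros(len(order), dtype=bool)
            for ai in range(len(order)):
                if used[ai]:
                    continue
                for aj in range(ai + 1, len(order)):
                    if used[aj]:
                        continue
                    ri, rj = order[ai], order[aj]
                    if dams[ri] == dams[rj]:
                        continue
                    if within_sex and sex[ri] != sex[rj]:
                        continue
                    used[ai] = used[aj] = True
                    pairs_i.append(ri)
                    pairs_j.append(rj)
                    break
        pairings.append((np.array(pairs_i, dtype=int), np.array(pairs_j, dtype=int)))
    return SplitPlan(
        mode="halfsib",
        train_mask=train_mask,
        validation_animals=tbl.loc[~train_mask, "animal"].to_numpy(),
        pairings=pairings,
        seed=seed,
    )


def trend_correct(values: np.ndarray, sr_labels: np.ndarray) -> np.ndarray:
    """Deviations from the within-selection-round means."""
    values = np.asarray(values, dtype=float)
    out = values.copy()
    for r in np.unique(sr_labels):
        sel = sr_labels == r
        out[sel] -= values[sel].mean()
    return out


def corrected_phenotype(data: DataSet, solution: Solution) -> np.ndarray:
    """Phenotypes minus the fitted fixed part, y_c = y - Xb, aligned with
    the records of ``data`` (which must be the dataset the solution was
    built from)."""
    return data.table[data.trait_col].to_numpy(dtype=float) - solution.fitted_fixed()


def _cor_slope(response: np.ndarray, predictor: np.ndarray):
    vp = np.var(predictor)
    if vp <= 0 or np.var(response) <= 0:
        return np.nan, np.nan
    cov = np.cov(response, predictor)[0, 1]
    return cov / np.sqrt(np.var(response, ddof=1) * np.var(predictor, ddof=1)), \
        cov / np.var(predictor, ddof=1)


def accuracy_and_inflation(
    predictor: np.ndarray,
    responses: dict,
    sr_labels: np.ndarray,
) -> dict:
    """Trend-corrected correlation and regression slope (response on
    predictor) for each named response; NaN flags degenerate inputs."""
    pred_c = trend_correct(predictor, sr_labels)
    out = {}
    for name, resp in responses.items():
        resp_c = trend_correct(np.asarray(resp, dtype=float), sr_labels)
        cor, slope = _cor_slope(resp_c, pred_c)
        out[f"cor({name})"] = cor
        out[f"slope({name})"] = slope
    return out


@dataclass
class ValidationReport:
    """Per-model accuracies and inflation slopes, tidy format."""

    table: pd.DataFrame

    def metric(self, model: str, name: str) -> float:
        sel = self.table[(self.table.model == model) & (self.table.metric == name)]
        return float(sel.value.iloc[0])

    def ranking(self, metric: str, descending: bool = True) -> list:
        sel = self.table[self.table.metric == metric].sort_values(
            "value", ascending=not descending
        )
        return list(sel.model)


def crossval(
    data: DataSet,
    ped: Pedigree,
    components: dict,
    *,
    truth: pd.DataFrame | None = None,
    seed: int = 1,
    n_last: int = 5,
    halfsib: bool = True,
    n_resamples: int = 50,
    within_sex: bool = False,
) -> ValidationReport:
    """Forward and half-sib validation for several fitted models.

    ``components`` maps model name to its full-data REML
    :class:`VarianceComponents`.  ``truth`` (simulation only) adds
    cor/slope against true breeding values.  Returns a tidy report with
    one row per model and metric (half-sib metrics carry the SD over
    pairings).
    """
    fwd = forward_split(data, n_last)
    rows = []
    sr_all = data.table["sr"].to_numpy()
    val_rows = ~fwd.train_mask
    sr_val = sr_all[val_rows]
    if truth is not None:
        tmap = truth.set_index("animal")["a"]
        tbv_val = tmap.loc[data.table.loc[val_rows, "animal"]].to_numpy()

    hs = None
    if halfsib:
        hs = halfsib_split_and_pair(
            data, ped, seed, n_last=n_last,
            n_resamples=n_resamples, within_sex=within_sex,
        )

    for model, vc in components.items():
        config = ModelConfig(model, 1)
        full = None
        if hasattr(vc, "vc"):  # a REMLResult: reuse its full-data solution
            full = vc.solution
            vc = vc.vc
        if full is None:
            full = solve_model(data, ped, config, vc)
        y_c = corrected_phenotype(data, full)
        codes = ped.code(data.table["animal"])
        ebv_full = full.ebv("a")[codes]

        reduced = solve_model(data.subset(fwd.train_mask), ped, config, vc)
        ebv_red = reduced.ebv("a")[codes]

        responses = {"y_c": y_c[val_rows], "ebv_full": ebv_full[val_rows]}
        if truth is not None:
            responses["tbv"] = tbv_val
        stats = accuracy_and_inflation(ebv_red[val_rows], responses, sr_val)
        for k, v in stats.items():
            rows.append(dict(model=model, metric=k, value=v, sd=np.nan))

        if hs is not None:
            red_hs = solve_model(data.subset(hs.train_mask), ped, config, vc)
            ebv_hs = red_hs.ebv("a")[codes]
            cors = []
            for pi, pj in hs.pairings:
                if len(pi) == 0:
                    continue
                resp = trend_correct(y_c[pi], sr_all[pi])
                pred = trend_correct(ebv_hs[pj], sr_all[pj])
                c, _ = _cor_slope(resp, pred)
                cors.append(c)
            rows.append(dict(
                model=model, metric="cor(halfsib)",
                value=float(np.nanmean(cors)), sd=float(np.nanstd(cors, ddof=1)),
            ))
    return ValidationReport(pd.DataFrame(rows))
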