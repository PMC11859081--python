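"""Hyperparameter tuning over regularization multiplier x feature
combination, with small-sample AICc model selection.

Candidate models are fitted on the full presence set for every
(FC, RM) pair; the information criterion uses the landscape-normalized
raw likelihood (Warren-Seifert): raw predictions are renormalized to
sum to 1 over the whole valid grid, lnL is the summed log probability
at the presence cells, k counts nonzero coefficients, and

    AICc = 2k - 2 lnL + 2k(k+1) / (n - k - 1).

Candidates with n - k - 1 <= 0 are flagged invalid and excluded from
the delta computation.  The selected model is the (unique) delta
AICc = 0 row; exact ties break by smaller k, then smaller RM, then FC
grid order.  Replicate test AUC is computed for the winner only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_COMBINATIONS, build_features
from .grids import EnvStack
from .maxent import (
    MAX_BACKGROUND,
    MaxentModel,
    background_matrix,
    fit_maxent,
    predict,
    presence_matrix,
    replicate_auc,
)
from .occurrences import OccurrenceSet

__all__ = ["DEFAULT_RM_GRID", "TuningResult", "aicc_formula", "aicc", "tune"]

#: RM 0.5 to 4.0 in steps of 0.5 (8 values).
DEFAULT_RM_GRID = tuple(np.arange(0.5, 4.01, 0.5))


def aicc_formula(ln_l: float, k: int, n: int) -> tuple[float, bool]:
    """AICc value and validity flag (invalid when n - k - 1 <= 0)."""
    if n - k - 1 <= 0:
        return float("nan"), False
    return 2.0 * k - 2.0 * ln_l + 2.0 * k * (k + 1) / (n - k - 1), True


def aicc(
    model: MaxentModel, stack: EnvStack, occ: OccurrenceSet
) -> tuple[float, int, float, bool]:
    """(lnL, k, AICc, valid) for a fitted model on its landscape.

    Raw predictions over the full valid grid are renormalized to sum to
    1; lnL sums their logs at the presence cells.
    """
    if len(occ) < 2:
        raise ValueError("need at least 2 presences for AICc")
    raw_map = predict(model, stack, transform="raw")
    raw = raw_map.values
    total = raw[raw_map.mask].sum()
    cells = []
    for lon, lat in occ.records:
        cell = stack.grid.cell_of(lon, lat)
        if cell is None or not raw_map.mask[cell]:
            raise ValueError(f"presence ({lon}, {lat}) outside the valid grid")
        cells.append(cell)
    p = np.array([raw[c] for c in cells]) / total
    if np.any(p <= 0):
        return float("-inf"), model.k, float("nan"), False
    ln_l = float(np.log(p).sum())
    k = model.k
    value, valid = aicc_formula(ln_l, k, len(occ))
    return ln_l, k, value, valid


@dataclass
class TuningResult:
    """Tuning table plus the selected model."""

    table: pd.DataFrame  # fc, rm, k, lnL, aicc, valid, delta_aicc, mean_test_auc
    chosen_index: int
    chosen_model: MaxentModel

    @property
    def chosen(self) -> pd.Series:
        return self.table.loc[self.chosen_index]


def tune(
    occ: OccurrenceSet,
    stack: EnvStack,
    rm_grid=DEFAULT_RM_GRID,
    fc_grid=FEATURE_COMBINATIONS,
    seed: int = 0,
    n_background_max: int = MAX_BACKGROUND,
    replicate_winner_auc: bool = True,
    **fit_kwargs,
) -> TuningResult:
    """Fit the full RM x FC grid and select the delta-AICc = 0 model."""
    rm_grid = list(rm_grid)
    fc_grid = list(fc_grid)
    if not rm_grid or not fc_grid:
        raise ValueError("rm_grid and fc_grid must be non-empty")

    bg_X = background_matrix(stack, n_max=n_background_max, seed=seed)
    rows = []
    models = []
    for fc in fc_grid:
        bg_F, expansion = build_features(bg_X, stack.names, fc)
        pres_X = presence_matrix(occ, stack, expansion.var_names)
        pres_F = expansion.transform(pres_X, clamp=True)
        # solve the RM path from sparsest down, warm-starting each fit
        by_rm = {}
        lam0 = None
        for rm in sorted(rm_grid, reverse=True):
            model = fit_maxent(
                pres_F, bg_F, expansion, rm=rm, seed=seed, lam0=lam0, **fit_kwargs
            )
            lam0 = model.lambdas
            by_rm[float(rm)] = model
        for rm in rm_grid:
            model = by_rm[float(rm)]
            ln_l, k, value, valid = aicc(model, stack, occ)
            rows.append(
                {"fc": fc, "rm": float(rm), "k": k, "lnL": ln_l,
                 "aicc": value, "valid": valid}
            )
            models.append(model)
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError("all tuning candidates invalid (k >= n - 1 everywhere)")
    best = float(valid["aicc"].min())
    table["delta_aicc"] = np.where(table["valid"], table["aicc"] - best, np.nan)
    # winner: delta 0; ties -> smaller k, smaller rm, fc grid order
    zero = valid[np.isclose(valid["aicc"], best, rtol=0, atol=1e-12)]
    fc_order = {fc: i for i, fc in enumerate(fc_grid)}
    chosen_index = int(
        min(
            zero.index,
            key=lambda i: (table.at[i, "k"], table.at[i, "rm"], fc_order[table.at[i, "fc"]]),
        )
    )
    table["mean_test_auc"] = np.nan
    if replicate_winner_auc:
        mean_auc, _ = replicate_auc(
            occ, stack,
            fc=table.at[chosen_index, "fc"],
            rm=float(table.at[chosen_index, "rm"]),
            seed=seed, n_background_max=n_background_max,
        )
        table.at[chosen_index, "mean_test_auc"] = mean_auc
    return TuningResult(
        table=table, chosen_index=chosen_index, chosen_model=models[chosen_index]
    )
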