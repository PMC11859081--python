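"""Two-stage environmental-variable screening.

Stage 1 drops variables with zero percent contribution in a
preliminary model fit; stage 2 prunes collinear pairs (Pearson
|r| > 0.80), keeping the higher-contribution member of each pair.
Both stages are deterministic: pairs are processed in decreasing |r|
order with alphabetical tie-breaks, so the retained set does not
depend on input variable order.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grids import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_matrix",
    "drop_zero_contribution",
    "prune_collinear",
    "screen_variables",
]

#: Contributions below this are treated as exactly zero.
ZERO_CONTRIB_TOL = 1e-9


def pearson_matrix(
    stack: EnvStack,
    sample: str = "all_valid_cells",
    n_background: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlation matrix between stack layers.

    ``sample`` is ``"all_valid_cells"`` (default, deterministic) or
    ``"background_sample"`` (a seeded uniform subsample of at most
    ``n_background`` valid cells).  Constant layers get r = 0
    off-diagonal, with a warning.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 variables for a correlation matrix")
    X = stack.valid_values()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sample cells")
    if sample == "background_sample" and X.shape[0] > n_background:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], n_background, replace=False)]
    elif sample not in ("all_valid_cells", "background_sample"):
        raise ValueError(f"unknown sample mode {sample!r}")
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant variable(s) {list(np.array(stack.names)[constant])}: "
            "correlations set to 0", stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=stack.names, columns=stack.names)


def drop_zero_contribution(contrib: pd.Series) -> list[str]:
    """Retain variables whose percent contribution is nonzero.

    ``contrib`` maps variable name -> percent contribution (summing to
    100 over variables).  Order is preserved.
    """
    contrib = pd.Series(contrib, dtype=float)
    if (contrib < -1e-9).any():
        raise ValueError("contributions must be non-negative")
    retained = [v for v in contrib.index if contrib[v] >= ZERO_CONTRIB_TOL]
    if not retained:
        raise ValueError("all contributions are zero: degenerate preliminary model")
    dropped = [v for v in contrib.index if v not in retained]
    if dropped:
        logger.info("zero-contribution drop: removed %s", dropped)
    return retained


def prune_collinear(
    corr: pd.DataFrame,
    contrib: pd.Series,
    threshold: float = 0.80,
) -> tuple[list[str], list[tuple[str, str, float, str]]]:
    """Greedy collinearity pruning.

    Pairs with |r| strictly above ``threshold`` are visited in
    decreasing |r| order (alphabetical tie-break); in each pair still
    fully retained, the lower-contribution member is dropped
    (contribution ties broken alphabetically: the later name drops).
    Returns (retained names in input order, dropped (a, b, r, dropped)
    records).  Never drops both members of a pair.
    """
    names = list(corr.index)
    if set(names) != set(contrib.index):
        raise ValueError("corr and contrib must cover the same variables")
    contrib = pd.Series(contrib, dtype=float)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) > threshold:
                key = tuple(sorted((a, b)))
                pairs.append((-abs(r), key[0], key[1], r))
    pairs.sort()
    dropped: set[str] = set()
    report = []
    for _, a, b, r in pairs:
        if a in dropped or b in dropped:
            continue
        ca, cb = contrib[a], contrib[b]
        if ca > cb:
            loser = b
        elif cb > ca:
            loser = a
        else:  # tie: alphabetically later name drops
            loser = max(a, b)
        dropped.add(loser)
        report.append((a, b, r, loser))
        logger.info("collinear pair (%s, %s, r=%.3f): dropped %s", a, b, r, loser)
    retained = [v for v in names if v not in dropped]
    return retained, report


def screen_variables(
    occ,
    stack: EnvStack,
    threshold: float = 0.80,
    rm: float = 1.0,
    fc: str = "LQ",
    seed: int = 0,
):
    """Full screening pass: preliminary fit -> zero-drop -> Pearson prune.

    The preliminary model (FC = LQ, RM = 1 by default) only supplies
    percent contributions; its predictions are discarded.  Returns
    (screened EnvStack, contributions Series, correlation DataFrame,
    prune report).
    """
    from .maxent import fit_occurrence_model, percent_contribution

    model = fit_occurrence_model(occ, stack, fc=fc, rm=rm, seed=seed, trace=True)
    contrib = percent_contribution(model)
    retained = drop_zero_contribution(contrib)
    sub = stack.subset(retained)
    if len(retained) >= 2:
        corr = pearson_matrix(sub)
        retained, report = prune_collinear(corr, contrib[retained], threshold)
    else:
        corr = pd.DataFrame(np.ones((1, 1)), index=retained, columns=retained)
        report = []
    return stack.subset(retained), contrib, corr, report
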