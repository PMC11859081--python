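"""Presence-background maximum-entropy model (MaxEnt).

The model is the Gibbs distribution over background cells

    P(x) = exp(lambda . f(x)) / Z

whose L1-penalized log-likelihood of the presence sample is maximal:

    F(lambda) = mean_presence(lambda . f) - ln Z(lambda)
                - sum_j beta_j |lambda_j|,

with Z(lambda) = sum_background exp(lambda . f).  The per-feature
penalty beta_j = RM * beta_class(m) * s_j / sqrt(m) follows the
published MaxEnt defaults: m is the presence count, s_j the feature's
standard deviation over presences (floored at 5% of its background
range), and beta_class(m) is interpolated from a per-class table.

Fitting is cyclic coordinate descent with one-dimensional
soft-threshold (Newton) updates and backtracking, so the penalized
gain is non-decreasing; coordinates that are provably optimal at zero
(KKT check |gradient| <= beta) are skipped.  The regularized training
gain is G = ln(n_background) + F(lambda), zero for the null model.

Outputs: ``raw`` (sums to 1 over the training background),
``cloglog`` = 1 - exp(-e^H * raw) (the modern default habitat
suitability index) and ``logistic``; H is the entropy of the raw
distribution over the background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import rankdata

from .features import FeatureExpansion, FeatureSpec, build_features
from .grids import EnvStack, GridSpec
from .occurrences import OccurrenceSet

__all__ = [
    "MaxentModel",
    "SuitabilityMap",
    "fit_maxent",
    "fit_occurrence_model",
    "predict",
    "percent_contribution",
    "jackknife_importance",
    "response_curve",
    "auc",
    "replicate_auc",
    "presence_matrix",
    "background_matrix",
    "penalized_gain",
]

#: Background size cap: all valid cells if fewer, else a seeded sample.
MAX_BACKGROUND = 10_000

#: lambda magnitudes below this count as zero (k-counting, sparsity).
ZERO_LAMBDA_TOL = 1e-12

# beta_class(m): interpolation nodes (presence count -> multiplier),
# clamped outside the node range.
_BETA_NODES = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "product": ([10, 30, 100], [0.5, 0.3, 0.1]),
    "hinge": ([10, 100], [0.5, 0.5]),
    "threshold": ([10, 30, 100], [2.0, 1.5, 1.0]),
}


def _beta_class(kind: str, m: int) -> float:
    xs, ys = _BETA_NODES[kind]
    return float(np.interp(m, xs, ys))


@dataclass
class SuitabilityMap:
    """Continuous habitat suitability on a grid.

    ``values`` is full-grid float; only cells under ``mask`` are
    meaningful.  ``transform`` is raw / cloglog / logistic."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    transform: str = "cloglog"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError("suitability values/mask shape must match grid")
        if self.transform in ("cloglog", "logistic"):
            v = self.values[self.mask]
            if v.size and (v.min() < -1e-9 or v.max() > 1.0 + 1e-9):
                raise ValueError(f"{self.transform} values must lie in [0, 1]")

    def valid(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model."""

    expansion: FeatureExpansion
    lambdas: np.ndarray
    fc: str
    rm: float
    ln_z: float
    entropy: float
    n_presence: int
    n_background: int
    gain: float
    seed: int = 0
    converged: bool = True
    betas: np.ndarray | None = None
    trace: list[tuple[int, float]] | None = None
    cycle_gains: list[float] = field(default_factory=list)

    @property
    def var_names(self) -> list[str]:
        return self.expansion.var_names

    @property
    def z(self) -> float:
        return float(np.exp(self.ln_z))

    @property
    def k(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.sum(np.abs(self.lambdas) > ZERO_LAMBDA_TOL))

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        exp = self.expansion
        payload = {
            "fc": self.fc,
            "rm": self.rm,
            "ln_z": self.ln_z,
            "entropy": self.entropy,
            "gain": self.gain,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "seed": self.seed,
            "converged": self.converged,
            "lambdas": self.lambdas.tolist(),
            "var_names": exp.var_names,
            "anchors": {k: list(v) for k, v in exp.anchors.items()},
            "bg_means": exp.bg_means,
            "features": [
                {
                    "kind": s.kind,
                    "variables": list(s.variables),
                    "knot": s.knot,
                    "anchors": [list(a) for a in s.anchors],
                }
                for s in exp.specs
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "MaxentModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        specs = [
            FeatureSpec(
                kind=f["kind"],
                variables=tuple(f["variables"]),
                knot=f["knot"],
                anchors=tuple(tuple(a) for a in f["anchors"]),
            )
            for f in payload["features"]
        ]
        exp = FeatureExpansion(
            fc=payload["fc"],
            var_names=payload["var_names"],
            specs=specs,
            anchors={k: tuple(v) for k, v in payload["anchors"].items()},
            bg_means=payload["bg_means"],
        )
        return cls(
            expansion=exp,
            lambdas=np.asarray(payload["lambdas"], dtype=float),
            fc=payload["fc"],
            rm=payload["rm"],
            ln_z=payload["ln_z"],
            entropy=payload["entropy"],
            n_presence=payload["n_presence"],
            n_background=payload["n_background"],
            gain=payload["gain"],
            seed=payload["seed"],
            converged=payload["converged"],
        )


def compute_betas(
    pres_F: np.ndarray, bg_F: np.ndarray, specs: list[FeatureSpec], rm: float
) -> np.ndarray:
    """Per-feature L1 penalties beta_j (see module docstring)."""
    m = pres_F.shape[0]
    s = pres_F.std(axis=0)
    rng = bg_F.max(axis=0) - bg_F.min(axis=0)
    s = np.maximum(s, 0.05 * rng)
    s = np.maximum(s, 1e-6)  # fully degenerate features still get a penalty
    cls = np.array([_beta_class(sp.beta_class, m) for sp in specs])
    return rm * cls * s / np.sqrt(m)


def penalized_gain(
    lambdas: np.ndarray,
    pres_F: np.ndarray,
    bg_F: np.ndarray,
    betas: np.ndarray,
) -> float:
    """Regularized training gain G(lambda) = ln(n_bg) + F(lambda).

    Reference implementation of the objective (used directly by the
    fitter's oracles); the fitter itself tracks it incrementally.
    """
    eta = bg_F @ lambdas
    ln_z = float(logsumexp(eta))
    f_obj = float(pres_F.mean(axis=0) @ lambdas) - ln_z - float(betas @ np.abs(lambdas))
    return np.log(bg_F.shape[0]) + f_obj


def _soft_threshold(x: float, t: float) -> float:
    return float(np.sign(x) * max(abs(x) - t, 0.0))


def fit_maxent(
    pres_F: np.ndarray,
    bg_F: np.ndarray,
    expansion: FeatureExpansion,
    rm: float = 1.0,
    tol: float = 1e-5,
    max_cycles: int = 500,
    seed: int = 0,
    trace: bool = False,
    lam0: np.ndarray | None = None,
) -> MaxentModel:
    """Fit lambda by cyclic coordinate descent with soft-threshold updates.

    ``pres_F``/``bg_F`` are feature matrices from :func:`build_features`
    (same expansion).  Each cycle starts with a KKT screen (one
    matrix-vector product): coordinates at zero whose gradient
    magnitude is within their penalty are provably optimal and are
    skipped; the remainder get exact one-dimensional updates.
    Terminates when the penalized-gain improvement over a full cycle
    drops below ``tol``; non-convergence at ``max_cycles`` sets
    ``converged=False`` on the model (no exception).  ``lam0`` warm
    starts the solve (same optimum, fewer cycles).
    """
    pres_F = np.asarray(pres_F, dtype=float)
    bg_F = np.asarray(bg_F, dtype=float)
    if not (np.all(np.isfinite(pres_F)) and np.all(np.isfinite(bg_F))):
        raise ValueError("non-finite feature values")
    if pres_F.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    if bg_F.shape[0] < 10:
        raise ValueError("need at least 10 background points")
    n_bg, n_feat = bg_F.shape
    if pres_F.shape[1] != n_feat or n_feat != len(expansion.specs):
        raise ValueError("feature matrices do not match the expansion")

    betas = compute_betas(pres_F, bg_F, expansion.specs, rm)
    mp = pres_F.mean(axis=0)
    bg_Fsq = bg_F**2
    bgT = np.asfortranarray(bg_F)  # fast column access

    if lam0 is None:
        lam = np.zeros(n_feat)
        w = np.ones(n_bg)  # unnormalized exp(eta - c)
        c_off = 0.0  # log offset so that exp(eta) = w * e^c
    else:
        lam = np.asarray(lam0, dtype=float).copy()
        eta0 = bg_F @ lam
        c_off = float(eta0.max())
        w = np.exp(eta0 - c_off)
    s_sum = float(w.sum())
    lin = float(lam @ mp)  # lambda . mp
    pen = float(betas @ np.abs(lam))  # sum beta |lambda|
    obj = lin - (np.log(s_sum) + c_off) - pen  # = F(lambda)
    trace_log: list[tuple[int, float]] = [] if trace else None  # type: ignore[assignment]
    cycle_gains = [np.log(n_bg) + obj]
    converged = False

    for _cycle in range(max_cycles):
        obj_start = obj
        # KKT screen at cycle start: zero coordinates whose gradient is
        # inside the penalty stay zero this cycle.
        g_all = mp - (w @ bg_F) / s_sum
        candidates = np.nonzero((lam != 0.0) | (np.abs(g_all) > betas))[0]
        for j in candidates:
            fj = bgT[:, j]
            ef = float(w @ fj) / s_sum
            g = mp[j] - ef
            if lam[j] == 0.0 and abs(g) <= betas[j]:
                continue  # KKT-optimal at zero
            ef2 = float(w @ bg_Fsq[:, j]) / s_sum
            h = max(ef2 - ef * ef, 1e-10)
            target = _soft_threshold(lam[j] + g / h, betas[j] / h)
            delta = np.clip(target - lam[j], -5.0, 5.0)
            if delta == 0.0:
                continue
            # backtracking: accept only non-decreasing penalized gain
            accepted = False
            for _ in range(30):
                lam_j_new = lam[j] + delta
                w_new = w * np.exp(delta * fj)
                s_new = float(w_new.sum())
                lin_new = lin + delta * mp[j]
                pen_new = pen + betas[j] * (abs(lam_j_new) - abs(lam[j]))
                obj_new = lin_new - (np.log(s_new) + c_off) - pen_new
                if obj_new >= obj - 1e-13:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-13:
                    break
            if not accepted:
                continue
            if trace and obj_new > obj:
                trace_log.append((j, obj_new - obj))
            lam[j] = lam_j_new
            w, s_sum, lin, pen, obj = w_new, s_new, lin_new, pen_new, obj_new
            if s_sum > 1e250 or s_sum < 1e-250:  # renormalize offset
                c_off += np.log(s_sum)
                w = w / s_sum
                s_sum = 1.0
        cycle_gains.append(np.log(n_bg) + obj)
        if obj - obj_start < tol:
            converged = True
            break

    eta = bg_F @ lam
    ln_z = float(logsumexp(eta))
    log_p = eta - ln_z
    p = np.exp(log_p)
    entropy = float(-(p @ log_p))
    gain = np.log(n_bg) + float(mp @ lam) - ln_z - float(betas @ np.abs(lam))
    return MaxentModel(
        expansion=expansion,
        lambdas=lam,
        fc=expansion.fc,
        rm=rm,
        ln_z=ln_z,
        entropy=entropy,
        n_presence=pres_F.shape[0],
        n_background=n_bg,
        gain=gain,
        seed=seed,
        converged=converged,
        betas=betas,
        trace=trace_log,
        cycle_gains=cycle_gains,
    )


# ---------------------------------------------------------------------------
# Occurrence/stack plumbing
# ---------------------------------------------------------------------------

def presence_matrix(
    occ: OccurrenceSet, stack: EnvStack, names: list[str] | None = None
) -> np.ndarray:
    """Environmental values at the cells containing each record.

    Records outside the grid or on invalid cells raise — thin first.
    """
    names = names or stack.names
    rows, cols = [], []
    for lon, lat in occ.records:
        cell = stack.grid.cell_of(lon, lat)
        if cell is None or not stack.joint_mask[cell]:
            raise ValueError(
                f"{occ.species}: record ({lon}, {lat}) outside grid or on nodata cell"
            )
        rows.append(cell[0])
        cols.append(cell[1])
    rows, cols = np.asarray(rows), np.asarray(cols)
    return np.column_stack([stack[n].values[rows, cols] for n in names])


def background_matrix(
    stack: EnvStack,
    names: list[str] | None = None,
    n_max: int = MAX_BACKGROUND,
    seed: int = 0,
) -> np.ndarray:
    """Background sample: all jointly valid cells, or a seeded uniform
    subsample of ``n_max`` if there are more."""
    names = names or stack.names
    X = stack.valid_values(names)
    if X.shape[0] > n_max:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], n_max, replace=False)]
    return X


def fit_occurrence_model(
    occ: OccurrenceSet,
    stack: EnvStack,
    fc: str = "LQ",
    rm: float = 1.0,
    seed: int = 0,
    trace: bool = False,
    n_background_max: int = MAX_BACKGROUND,
    **fit_kwargs,
) -> MaxentModel:
    """Convenience: background + features + fit, from occurrences and a stack."""
    bg_X = background_matrix(stack, n_max=n_background_max, seed=seed)
    bg_F, expansion = build_features(bg_X, stack.names, fc)
    pres_X = presence_matrix(occ, stack, expansion.var_names)
    pres_F = expansion.transform(pres_X, clamp=True)
    return fit_maxent(pres_F, bg_F, expansion, rm=rm, seed=seed, trace=trace, **fit_kwargs)


def predict(
    model: MaxentModel, stack: EnvStack, transform: str = "cloglog"
) -> SuitabilityMap:
    """Project a fitted model onto a stack.

    Features are clamped to the training background range, so
    predictions beyond the training range equal the boundary response.
    On the training grid, ``raw`` values sum to 1.
    """
    for v in model.var_names:
        if v not in stack:
            raise KeyError(f"stack lacks model variable {v!r}")
    X = stack.valid_values(model.var_names)
    F = model.expansion.transform(X, clamp=True)
    eta = F @ model.lambdas
    raw = np.exp(eta - model.ln_z)
    if transform == "raw":
        out = raw
    elif transform == "cloglog":
        out = 1.0 - np.exp(-np.exp(model.entropy) * raw)
    elif transform == "logistic":
        t = np.exp(model.entropy) * raw
        out = t / (1.0 + t)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    values = np.zeros(stack.grid.shape)
    values[stack.joint_mask] = np.clip(out, 0.0, 1.0) if transform != "raw" else out
    return SuitabilityMap(
        grid=stack.grid,
        values=values,
        mask=stack.joint_mask.copy(),
        transform=transform,
        label=stack.label,
    )


# ---------------------------------------------------------------------------
# Interpretation
# ---------------------------------------------------------------------------

def percent_contribution(model: MaxentModel) -> "pd.Series":
    """Percent contribution per variable from the training trace.

    Each accepted coordinate update's penalized-gain increase is
    credited to the updated feature's variable(s) (split equally for
    products), floored at 0 and normalized to sum 100.
    """
    import pandas as pd

    if model.trace is None:
        raise ValueError("model was fitted without trace=True")
    credit = {v: 0.0 for v in model.var_names}
    for j, dgain in model.trace:
        vars_ = model.expansion.specs[j].variables
        for v in vars_:
            credit[v] += dgain / len(vars_)
    vals = np.array([max(c, 0.0) for c in credit.values()])
    total = vals.sum()
    if total > 0:
        vals = 100.0 * vals / total
    return pd.Series(vals, index=list(credit), name="percent_contribution")


def jackknife_importance(
    occ: OccurrenceSet,
    stack: EnvStack,
    fc: str = "LQ",
    rm: float = 1.0,
    seed: int = 0,
) -> "pd.DataFrame":
    """Leave-one-variable-out / only-one-variable training gains.

    Refits the model 2V + 1 times and reports regularized training
    gains; per-cell failures are recorded as NaN rather than raised.
    """
    import pandas as pd

    names = stack.names
    if len(names) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    gain_all = fit_occurrence_model(occ, stack, fc=fc, rm=rm, seed=seed).gain
    rows = []
    for v in names:
        row = {"variable": v, "gain_all": gain_all}
        for label, subset in (
            ("gain_with_only", [v]),
            ("gain_without", [n for n in names if n != v]),
        ):
            try:
                row[label] = fit_occurrence_model(
                    occ, stack.subset(subset), fc=fc, rm=rm, seed=seed
                ).gain
            except (ValueError, KeyError):
                row[label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")[
        ["gain_with_only", "gain_without", "gain_all"]
    ]


def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100
) -> "pd.DataFrame":
    """Marginal response: sweep one variable over its background range,
    others held at their background means; cloglog output."""
    import pandas as pd

    if variable not in model.var_names:
        raise KeyError(f"{variable!r} not in model variables {model.var_names}")
    lo, hi = model.expansion.anchors[variable]
    sweep = np.linspace(lo, hi, n_points)
    X = np.tile(
        [model.expansion.bg_means[v] for v in model.var_names], (n_points, 1)
    )
    X[:, model.var_names.index(variable)] = sweep
    F = model.expansion.transform(X, clamp=True)
    raw = np.exp(F @ model.lambdas - model.ln_z)
    cloglog = np.clip(1.0 - np.exp(-np.exp(model.entropy) * raw), 0.0, 1.0)
    return pd.DataFrame({variable: sweep, "response": cloglog})


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of presence vs background scores;
    ties count one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def replicate_auc(
    occ: OccurrenceSet,
    stack: EnvStack,
    fc: str,
    rm: float,
    n_replicates: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
    n_background_max: int = MAX_BACKGROUND,
) -> tuple[float, list[float]]:
    """Mean test-side AUC over random presence subsample splits.

    Each replicate i trains on a 75% subsample (split seeded i, on top
    of the run seed) and scores the held-out 25% against the background.
    """
    bg_X = background_matrix(stack, n_max=n_background_max, seed=seed)
    bg_F, expansion = build_features(bg_X, stack.names, fc)
    pres_X = presence_matrix(occ, stack, expansion.var_names)
    pres_F = expansion.transform(pres_X, clamp=True)
    n = pres_F.shape[0]
    n_train = max(2, int(round(train_fraction * n)))
    if n_train >= n:
        n_train = n - 1
    if n_train < 2:
        raise ValueError("too few presences for a train/test split")
    aucs = []
    for i in range(n_replicates):
        rng = np.random.default_rng((seed, i))
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = fit_maxent(pres_F[train], bg_F, expansion, rm=rm, seed=seed)
        eta_bg = bg_F @ model.lambdas
        eta_te = pres_F[test] @ model.lambdas
        aucs.append(auc(eta_te, eta_bg))
    return float(np.mean(aucs)), aucs
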