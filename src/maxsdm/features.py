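"""Feature expansion for the maximum-entropy model.

Raw environmental variables are min-max scaled to [0, 1] using their
background range, then expanded into the classic MaxEnt feature
classes: Linear, Quadratic, Product (pairwise), Hinge (forward and
reverse, knots at background quantiles) and Threshold (step functions).
A feature combination (FC) label such as ``"LQH"`` selects which
classes enter the model; all expanded features lie in [0, 1], which
keeps the L1 penalty comparable across classes.

When projecting onto new data (e.g. a future climate stack), base
variables are clamped to the training background range before
expansion, so extrapolated cells receive the boundary response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FEATURE_COMBINATIONS", "FeatureSpec", "FeatureExpansion", "build_features"]

FEATURE_COMBINATIONS = ("L", "H", "LQ", "LQH", "LQPH", "LQPHT")

_KINDS = ("linear", "quadratic", "product", "hinge_fwd", "hinge_rev", "threshold")


@dataclass(frozen=True)
class FeatureSpec:
    """One expanded feature.

    ``variables`` holds 1 name (2 for products); ``knot`` lives on the
    scaled [0, 1] axis and is None except for hinge/threshold;
    ``anchors`` is the background (min, max) of each base variable, the
    scaling and clamping range.
    """

    kind: str
    variables: tuple[str, ...]
    knot: float | None
    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "product" and len(set(self.variables)) != 2:
            raise ValueError("product feature needs exactly 2 distinct variables")
        if self.kind in ("hinge_fwd", "hinge_rev", "threshold"):
            if self.knot is None or not 0.0 < self.knot < 1.0:
                raise ValueError(
                    f"{self.kind} knot must lie strictly inside the scaled range"
                )

    @property
    def beta_class(self) -> str:
        """Regularization class this feature belongs to."""
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return "hinge"
        return self.kind


class FeatureExpansion:
    """A fitted feature map: raw variable matrix -> feature matrix."""

    def __init__(
        self,
        fc: str,
        var_names: list[str],
        specs: list[FeatureSpec],
        anchors: dict[str, tuple[float, float]],
        bg_means: dict[str, float],
    ):
        self.fc = fc
        self.var_names = list(var_names)
        self.specs = specs
        self.anchors = anchors
        self.bg_means = bg_means
        self._index = {n: i for i, n in enumerate(self.var_names)}

    def __len__(self) -> int:
        return len(self.specs)

    def scale(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Min-max scale columns of raw ``X`` to [0, 1] by the anchors."""
        X = np.asarray(X, dtype=float)
        Z = np.empty_like(X)
        for i, name in enumerate(self.var_names):
            lo, hi = self.anchors[name]
            Z[:, i] = (X[:, i] - lo) / (hi - lo)
        if clamp:
            np.clip(Z, 0.0, 1.0, out=Z)
        return Z

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Evaluate all features on raw variable matrix ``X`` (n, V)."""
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature input")
        Z = self.scale(X, clamp=clamp)
        out = np.empty((X.shape[0], len(self.specs)))
        for j, spec in enumerate(self.specs):
            cols = [self._index[v] for v in spec.variables]
            z = Z[:, cols[0]]
            k = spec.knot
            if spec.kind == "linear":
                out[:, j] = z
            elif spec.kind == "quadratic":
                out[:, j] = z * z
            elif spec.kind == "product":
                out[:, j] = z * Z[:, cols[1]]
            elif spec.kind == "hinge_fwd":
                out[:, j] = np.maximum(0.0, (z - k) / (1.0 - k))
            elif spec.kind == "hinge_rev":
                out[:, j] = np.maximum(0.0, (k - z) / k)
            else:  # threshold
                out[:, j] = (z > k).astype(float)
        return out


def _quantile_knots(z: np.ndarray, n_knots: int) -> np.ndarray:
    """Equally spaced quantiles of background scaled values, strictly
    inside (0, 1); duplicates and boundary values are dropped."""
    qs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(z, qs)
    knots = np.unique(np.clip(knots, 1e-9, 1 - 1e-9))
    return knots[(knots > 1e-9) & (knots < 1 - 1e-9)]


def build_features(
    bg_X: np.ndarray,
    var_names: list[str],
    fc: str,
    n_hinge_knots: int = 10,
    n_threshold_knots: int = 10,
) -> tuple[np.ndarray, FeatureExpansion]:
    """Build the feature expansion from background values.

    Returns the background feature matrix and the reusable
    :class:`FeatureExpansion`.  Constant variables are excluded from
    the expansion with a warning.
    """
    if fc not in FEATURE_COMBINATIONS:
        raise ValueError(f"fc must be one of {FEATURE_COMBINATIONS}, got {fc!r}")
    bg_X = np.asarray(bg_X, dtype=float)
    if bg_X.ndim != 2 or bg_X.shape[1] != len(var_names):
        raise ValueError("bg_X must be (n_background, n_variables)")

    keep, anchors, bg_means = [], {}, {}
    for i, name in enumerate(var_names):
        lo, hi = float(bg_X[:, i].min()), float(bg_X[:, i].max())
        if lo == hi:
            warnings.warn(
                f"variable {name!r} is constant over the background; excluded",
                stacklevel=2,
            )
            continue
        keep.append(name)
        anchors[name] = (lo, hi)
        bg_means[name] = float(bg_X[:, i].mean())
    if not keep:
        raise ValueError("no non-constant variable to expand")
    col = {n: i for i, n in enumerate(var_names)}
    Z = {
        n: (bg_X[:, col[n]] - anchors[n][0]) / (anchors[n][1] - anchors[n][0])
        for n in keep
    }

    specs: list[FeatureSpec] = []

    def anchor_of(*names: str) -> tuple[tuple[float, float], ...]:
        return tuple(anchors[n] for n in names)

    if "L" in fc:
        for n in keep:
            specs.append(FeatureSpec("linear", (n,), None, anchor_of(n)))
    if "Q" in fc:
        for n in keep:
            specs.append(FeatureSpec("quadratic", (n,), None, anchor_of(n)))
    if "P" in fc:
        for i, a in enumerate(keep):
            for b in keep[i + 1 :]:
                specs.append(FeatureSpec("product", (a, b), None, anchor_of(a, b)))
    if "H" in fc:
        for n in keep:
            for k in _quantile_knots(Z[n], n_hinge_knots):
                specs.append(FeatureSpec("hinge_fwd", (n,), float(k), anchor_of(n)))
                specs.append(FeatureSpec("hinge_rev", (n,), float(k), anchor_of(n)))
    if "T" in fc:
        for n in keep:
            for k in _quantile_knots(Z[n], n_threshold_knots):
                specs.append(FeatureSpec("threshold", (n,), float(k), anchor_of(n)))

    expansion = FeatureExpansion(fc, keep, specs, anchors, bg_means)
    F_bg = expansion.transform(bg_X[:, [col[n] for n in keep]], clamp=False)
    return F_bg, expansion
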