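"""Niche breadth and overlap metrics on suitability surfaces.

* Schoener's D: normalize each species' suitability to sum 1 over the
  jointly valid cells (P_ia, P_ja); D = 1 - 1/2 sum_a |P_ia - P_ja|.
  1 for identical surfaces, 0 for disjoint support.
* Levins standardized breadth B2: Shannon entropy of the normalized
  surface divided by ln(number of cells) — 1 for a uniform generalist,
  0 for a single-cell specialist, invariant to uniform rescaling.
* Range overlap: binarize at an HSI threshold (default 0.4);
  |A intersect B| / min(|A|, |B|) (symmetric min-denominator form).

All metrics are computed on the cloglog HSI scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxent import SuitabilityMap

__all__ = [
    "schoener_d",
    "levins_b2",
    "range_overlap",
    "NicheMetrics",
    "niche_metrics",
]

DEFAULT_RANGE_THRESHOLD = 0.4


def _joint_valid(map_a: SuitabilityMap, map_b: SuitabilityMap) -> np.ndarray:
    if map_a.grid != map_b.grid:
        raise ValueError("suitability maps are on different grids")
    joint = map_a.mask & map_b.mask
    if not joint.any():
        raise ValueError("no jointly valid cell")
    return joint


def schoener_d(map_a: SuitabilityMap, map_b: SuitabilityMap) -> float:
    """Schoener's D niche overlap in [0, 1]."""
    joint = _joint_valid(map_a, map_b)
    pa = map_a.values[joint].astype(float)
    pb = map_b.values[joint].astype(float)
    if pa.sum() <= 0 or pb.sum() <= 0:
        raise ValueError("cannot normalize an all-zero suitability map")
    pa /= pa.sum()
    pb /= pb.sum()
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def levins_b2(smap: SuitabilityMap) -> float:
    """Standardized Levins niche breadth in [0, 1]."""
    v = smap.values[smap.mask].astype(float)
    r = v.size
    if r < 2:
        raise ValueError("need at least 2 valid cells for niche breadth")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero suitability map")
    p = v / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return entropy / np.log(r)


def range_overlap(
    map_a: SuitabilityMap,
    map_b: SuitabilityMap,
    threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> float:
    """Binary range overlap at an HSI threshold; 0 (flagged via 0
    return) when either range is empty."""
    joint = _joint_valid(map_a, map_b)
    ra = (map_a.values >= threshold) & joint
    rb = (map_b.values >= threshold) & joint
    na, nb = int(ra.sum()), int(rb.sum())
    if na == 0 or nb == 0:
        return 0.0
    return float((ra & rb).sum() / min(na, nb))


@dataclass
class NicheMetrics:
    """Pairwise D and range overlap plus per-species B2."""

    species: list[str]
    d_matrix: pd.DataFrame
    range_matrix: pd.DataFrame
    b2: pd.Series
    threshold: float

    def to_table(self) -> pd.DataFrame:
        """Compact report: D above the diagonal, range overlap below,
        B2 as a final column."""
        n = len(self.species)
        out = pd.DataFrame(
            np.ones((n, n)), index=self.species, columns=self.species
        )
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                if i < j:
                    out.loc[a, b] = self.d_matrix.loc[a, b]
                elif i > j:
                    out.loc[a, b] = self.range_matrix.loc[a, b]
        out["B2"] = self.b2
        return out.round(3)


def niche_metrics(
    maps: dict[str, SuitabilityMap], threshold: float = DEFAULT_RANGE_THRESHOLD
) -> NicheMetrics:
    """All pairwise metrics for a set of species suitability maps."""
    species = list(maps)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    n = len(species)
    d = pd.DataFrame(np.eye(n), index=species, columns=species)
    r = pd.DataFrame(np.eye(n), index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            d.loc[a, b] = d.loc[b, a] = schoener_d(maps[a], maps[b])
            r.loc[a, b] = r.loc[b, a] = range_overlap(maps[a], maps[b], threshold)
    b2 = pd.Series({s: levins_b2(maps[s]) for s in species}, name="B2")
    return NicheMetrics(
        species=species, d_matrix=d, range_matrix=r, b2=b2, threshold=threshold
    )
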