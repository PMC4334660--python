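"""Occurrence thinning and maximum uncorrelated variable-subset selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..io_core import Raster


@dataclass
class OccurrenceSet:
    species: str
    points: np.ndarray  # (n, 2) of (lon, lat)

    def __len__(self) -> int:
        return len(self.points)


def grid_thin(species: str, points: np.ndarray, cell: float,
              origin: tuple[float, float] = (0.0, 0.0),
              seed: int = 0) -> OccurrenceSet:
    """Keep one uniformly random point per occupied grid cell.

    The grid of ``cell`` degrees is anchored at ``origin`` (the raster
    lower-left corner).  The retained count equals the number of occupied
    cells for any seed.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        warnings.warn(f"no occurrence points for {species!r}")
        return OccurrenceSet(species, pts)
    ix = np.floor((pts[:, 0] - origin[0]) / cell).astype(int)
    iy = np.floor((pts[:, 1] - origin[1]) / cell).astype(int)
    rng = np.random.default_rng(seed)
    by_cell: dict[tuple[int, int], list[int]] = {}
    for idx, key in enumerate(zip(ix, iy)):
        by_cell.setdefault(key, []).append(idx)
    chosen = sorted(int(rng.choice(members)) for members in
                    (by_cell[k] for k in sorted(by_cell)))
    return OccurrenceSet(species, pts[chosen])


def select_uncorrelated(stack: dict[str, Raster], n_sample: int = 10000,
                        r_max: float = 0.8, seed: int = 0,
                        report=None) -> list[str]:
    """Largest variable subset with all pairwise |Pearson r| below ``r_max``.

    Correlations are computed on ``n_sample`` randomly sampled cells valid
    in every layer.  The maximum-cardinality subset is found exactly by
    branch-and-bound clique search over the compatibility graph; ties are
    broken by lower mean absolute correlation, then input order.  Constant
    layers are excluded with a warning.
    """
    names = list(stack)
    if not names:
        raise ValueError("empty raster stack")
    first = stack[names[0]]
    valid = np.ones((first.nrows, first.ncols), dtype=bool)
    for r in stack.values():
        valid &= r.mask_valid()
    rows, cols = np.nonzero(valid)
    if len(rows) < 2:
        raise ValueError("fewer than 2 cells valid in all layers")
    rng = np.random.default_rng(seed)
    take = min(n_sample, len(rows))
    pick = rng.choice(len(rows), size=take, replace=False)
    data = np.column_stack([stack[n].values[rows[pick], cols[pick]]
                            for n in names])

    keep_idx = []
    for i, n in enumerate(names):
        if data[:, i].std() == 0:
            warnings.warn(f"layer {n!r} is constant over the sample; excluded")
        else:
            keep_idx.append(i)
    names = [names[i] for i in keep_idx]
    data = data[:, keep_idx]
    k = len(names)
    if k == 0:
        raise ValueError("all layers constant")
    corr = np.corrcoef(data, rowvar=False).reshape(k, k)
    compat = np.abs(corr) < r_max
    np.fill_diagonal(compat, False)

    best: list[tuple[int, ...]] = []
    best_size = 0

    def extend(clique: tuple[int, ...], candidates: list[int]):
        nonlocal best, best_size
        if len(clique) + len(candidates) < best_size:
            return
        if len(clique) > best_size:
            best, best_size = [clique], len(clique)
        elif len(clique) == best_size and best_size > 0:
            best.append(clique)
        for idx, c in enumerate(candidates):
            extend(clique + (c,),
                   [x for x in candidates[idx + 1:] if compat[c, x]])

    extend(tuple(), list(range(k)))
    if best_size == 0:  # k >= 1 means a single variable is always a clique
        best = [(i,) for i in range(k)]

    # per-variable mean |r| against all other candidates, for tie-breaking
    abs_corr = np.abs(corr).copy()
    np.fill_diagonal(abs_corr, 0.0)
    var_score = abs_corr.sum(axis=1) / max(1, k - 1)

    def tie_key(subset: tuple[int, ...]):
        return (float(var_score[list(subset)].mean()), subset)

    chosen = min(best, key=tie_key)
    selected = [names[i] for i in sorted(chosen)]
    if report is not None:
        report.log("select_uncorrelated", n_sample=take, r_max=r_max,
                   n_candidates=k, selected=selected,
                   n_tied_maximum_subsets=len(best))
    return selected
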