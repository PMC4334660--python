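"""Ecological niche modeling: thinning, variable selection, maximum-entropy
models, evaluation, and the cryptic-peer hull layer.

High-level entry points:

* :func:`grid_thin`, :func:`select_uncorrelated` - data preparation
* :func:`run_model` - fit + replicate evaluation + importance for one species
* :func:`biotic_model` - refit with the peer species' alpha-hull layer
* :func:`alpha_hull_layer`, :func:`predict_to_raster`
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io_core import Raster
from ._evaluate import (ImportanceTables, ReplicateResult, auc,
                        maxsss_threshold, replicate_runs, variable_importance)
from ._features import DEFAULT_BETAS, Feature, FeatureSpec, build_features
from ._hull import alpha_hull_layer, alpha_shape
from ._maxent import MaxentError, MaxentModel, fit_maxent
from ._select import OccurrenceSet, grid_thin, select_uncorrelated

__all__ = [
    "OccurrenceSet", "grid_thin", "select_uncorrelated", "build_features",
    "FeatureSpec", "Feature", "DEFAULT_BETAS", "fit_maxent", "MaxentModel",
    "MaxentError", "auc", "replicate_runs", "maxsss_threshold",
    "variable_importance", "ImportanceTables", "ReplicateResult",
    "alpha_hull_layer", "alpha_shape", "extract_values", "background_cells",
    "predict_to_raster", "run_model", "biotic_model", "SdmResult",
]


def extract_values(stack: dict[str, Raster], lon: np.ndarray,
                   lat: np.ndarray) -> dict[str, np.ndarray]:
    """Raster values at point locations, one array per variable."""
    out = {}
    for name, r in stack.items():
        row, col = r.cell_index(np.asarray(lon), np.asarray(lat))
        if ((row < 0) | (row >= r.nrows) | (col < 0) | (col >= r.ncols)).any():
            raise ValueError(f"points fall outside raster {name!r}")
        out[name] = r.values[row, col]
    return out


def background_cells(stack: dict[str, Raster], cap: int = 10000,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Centers of cells valid in every layer, subsampled to ``cap``."""
    first = next(iter(stack.values()))
    valid = np.ones((first.nrows, first.ncols), dtype=bool)
    for r in stack.values():
        valid &= r.mask_valid()
    lon, lat = first.cell_centers()
    blon, blat = lon[valid], lat[valid]
    if len(blon) > cap:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(blon), size=cap, replace=False)
        blon, blat = blon[pick], blat[pick]
    return blon, blat


@dataclass
class SdmResult:
    species: str
    class_set: str
    spec: FeatureSpec
    model: MaxentModel
    replicates: ReplicateResult
    threshold: float
    importance: ImportanceTables
    single_models: dict[str, MaxentModel] = field(default_factory=dict)


def _fit_single_variable(var: str, values_p: dict, values_b: dict,
                         class_set: str, n_knots: int, betas, tol, max_iter,
                         categorical: list[str]) -> MaxentModel:
    cat = [var] if var in categorical else []
    sub_b = {var: values_b[var]}
    sub_p = {var: values_p[var]}
    spec, X_b = build_features(sub_b, class_set=class_set, n_knots=n_knots,
                               categorical=cat)
    X_p = spec.transform(sub_p)
    return fit_maxent(X_p, X_b, spec, betas=betas, tol=tol, max_iter=max_iter)


def run_model(occ: OccurrenceSet, stack: dict[str, Raster],
              class_set: str = "H", n_knots: int = 30,
              betas: dict[str, float] | None = None,
              n_rep: int = 100, train_frac: float = 0.75, seed: int = 0,
              background_cap: int = 10000, tol: float = 1e-5,
              max_iter: int = 500, categorical: list[str] | None = None,
              report=None) -> SdmResult:
    """Full per-species analysis on a raster stack.

    Scaling ranges come from the background cells (clipped for presences
    outside them); the headline model is fitted on all presences, the AUC
    comes from replicate subsampling, the threshold is max sensitivity plus
    specificity on the training data, and single-variable models provide
    the jackknife gains.
    """
    categorical = list(categorical or [])
    blon, blat = background_cells(stack, cap=background_cap, seed=seed)
    values_b = extract_values(stack, blon, blat)
    values_p = extract_values(stack, occ.points[:, 0], occ.points[:, 1])

    spec, X_b = build_features(values_b, class_set=class_set, n_knots=n_knots,
                               categorical=categorical)
    X_p = spec.transform(values_p)

    model = fit_maxent(X_p, X_b, spec, betas=betas, tol=tol, max_iter=max_iter)
    reps = replicate_runs(X_p, X_b, spec, n_rep=n_rep, train_frac=train_frac,
                          seed=seed, betas=betas, tol=tol, max_iter=max_iter)
    thr = maxsss_threshold(model.predict_logistic(X_p),
                           model.predict_logistic(X_b))
    singles = {
        v: _fit_single_variable(v, values_p, values_b, class_set, n_knots,
                                betas, tol, max_iter, categorical)
        for v in spec.variables + spec.categorical
    }
    imp = variable_importance(model, singles)
    if report is not None:
        report.log("sdm_run", species=occ.species, class_set=class_set,
                   n_presences=len(occ), n_background=X_b.shape[0],
                   n_features=X_b.shape[1], n_knots=n_knots,
                   betas={**DEFAULT_BETAS, **(betas or {})},
                   mean_auc=reps.mean_auc, threshold=thr,
                   gain=model.gain, converged=model.converged,
                   percent_contribution=imp.percent_contribution,
                   jackknife_gain=imp.jackknife_gain)
    return SdmResult(species=occ.species, class_set=class_set, spec=spec,
                     model=model, replicates=reps, threshold=thr,
                     importance=imp, single_models=singles)


def predict_to_raster(model: MaxentModel, stack: dict[str, Raster]) -> Raster:
    """Logistic suitability raster; cells invalid in any layer get nodata."""
    missing = [v for v in model.spec.variables + model.spec.categorical
               if v not in stack]
    if missing:
        raise MaxentError(f"variables missing from stack: {missing}")
    first = next(iter(stack.values()))
    valid = np.ones((first.nrows, first.ncols), dtype=bool)
    for v in model.spec.variables + model.spec.categorical:
        valid &= stack[v].mask_valid()
    values = {v: stack[v].values[valid]
              for v in model.spec.variables + model.spec.categorical}
    feats = model.spec.transform(values)
    out = np.full((first.nrows, first.ncols), first.nodata, dtype=float)
    out[valid] = model.predict_logistic(feats)
    return first.copy_with(out)


def biotic_model(occ: OccurrenceSet, stack: dict[str, Raster],
                 peer_hull: Raster, climatic_result: SdmResult,
                 hull_name: str = "peer_hull", report=None,
                 **fit_kwargs) -> SdmResult:
    """Refit with the peer species' range hull as a categorical variable.

    The climatic model's least important variable (lowest percent
    contribution, ties by input order) is dropped so the variable count
    stays constant; the 0/1 hull layer takes its place.
    """
    contrib = climatic_result.importance.percent_contribution
    order = climatic_result.spec.variables
    drop = min(order, key=lambda v: (contrib.get(v, 0.0), order.index(v)))
    keep = [v for v in order if v != drop]
    new_stack = {v: stack[v] for v in keep}
    new_stack[hull_name] = peer_hull
    if report is not None:
        report.log("biotic_model", species=occ.species, dropped=drop,
                   kept=keep, hull_variable=hull_name)
    return run_model(occ, new_stack, categorical=[hull_name],
                     class_set=climatic_result.class_set, report=report,
                     **fit_kwargs)
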