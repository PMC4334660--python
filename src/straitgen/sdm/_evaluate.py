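"""Model evaluation: AUC, replicate subsampling, thresholding and
variable-importance tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from ._maxent import MaxentModel, fit_maxent


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC (Mann-Whitney), ties counted 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty score set")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


@dataclass
class ReplicateResult:
    mean_auc: float
    std_auc: float
    aucs: list[float]
    models: list[MaxentModel]


def replicate_runs(pres_features: np.ndarray, bg_features: np.ndarray, spec,
                   n_rep: int = 100, train_frac: float = 0.75, seed: int = 0,
                   betas=None, tol: float = 1e-5, max_iter: int = 500,
                   keep_models: bool = False) -> ReplicateResult:
    """Repeated subsample evaluation: random train/test presence splits.

    Each replicate trains on ``train_frac`` of the presences and scores the
    held-out presences against the full background.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    m = pres_features.shape[0]
    n_train = int(round(train_frac * m))
    if n_train < 1 or n_train >= m:
        raise ValueError(
            f"{m} presences cannot be split {train_frac:.0%}/{1 - train_frac:.0%}"
        )
    rng = np.random.default_rng(seed)
    aucs, models = [], []
    for _ in range(n_rep):
        perm = rng.permutation(m)
        train, test = perm[:n_train], perm[n_train:]
        model = fit_maxent(pres_features[train], bg_features, spec,
                           betas=betas, tol=tol, max_iter=max_iter)
        aucs.append(auc(model.predict_logistic(pres_features[test]),
                        model.predict_logistic(bg_features)))
        if keep_models:
            models.append(model)
    arr = np.array(aucs)
    return ReplicateResult(float(arr.mean()), float(arr.std()), aucs, models)


def maxsss_threshold(presence_scores: np.ndarray,
                     background_scores: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity; ties take the lowest.

    Sensitivity = fraction of presences scoring >= t; specificity =
    fraction of background scoring < t.  Candidates are the sorted unique
    observed scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    candidates = np.unique(np.concatenate([p, b]))
    best_t, best_v = None, -np.inf
    for t in candidates:  # ascending, so ties keep the lowest threshold
        sens = float((p >= t).mean())
        spec = float((b < t).mean())
        if sens + spec > best_v + 1e-12:
            best_v, best_t = sens + spec, float(t)
    return best_t


@dataclass
class ImportanceTables:
    percent_contribution: dict[str, float]
    jackknife_gain: dict[str, float]


def variable_importance(model: MaxentModel,
                        single_variable_models: dict[str, MaxentModel]
                        ) -> ImportanceTables:
    """Percent contribution from the gain trace plus single-variable gains.

    Contributions are the per-variable cumulative gain increments of the
    coordinate-descent path, normalized to sum to 100.  The jackknife table
    reports the regularized training gain of each with-only-this-variable
    model.
    """
    trace = model.gain_trace
    total = sum(trace.values())
    if total <= 0:
        contrib = {v: float("nan") for v in trace}
    else:
        contrib = {v: 100.0 * g / total for v, g in trace.items()}
    jack = {v: m.gain for v, m in single_variable_models.items()}
    return ImportanceTables(percent_contribution=contrib, jackknife_gain=jack)
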