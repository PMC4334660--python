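"""L1-regularized Gibbs (maximum-entropy) presence-background model.

The fitted distribution over background cells is raw(x) = exp(lambda.f(x))/Z.
Coordinate descent maximizes the regularized training gain

    G = mean_presence(eta) - ln(mean_background(exp(eta)))
        - sum_j beta_j * s_j * |lambda_j|

where s_j is the sample standard deviation of feature j at the presences.
The null model (all lambda zero) has G = 0 by construction.  Each coordinate
update is a soft-thresholded Newton step with backtracking, so the gain is
non-decreasing across updates; the absolute gain change of every update is
accumulated per parent variable into ``gain_trace``, which later yields
percent contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._features import DEFAULT_BETAS, FeatureSpec


class MaxentError(ValueError):
    pass


@dataclass
class MaxentModel:
    spec: FeatureSpec
    lambdas: np.ndarray
    log_z: float              # ln sum_background exp(eta)
    n_background: int
    entropy: float            # nats, of the fitted background distribution
    gain: float               # regularized training gain
    raw_gain: float           # gain without the L1 penalty
    gain_trace: dict[str, float] = field(default_factory=dict)
    n_iter: int = 0
    converged: bool = False

    def eta(self, features: np.ndarray) -> np.ndarray:
        return features @ self.lambdas

    def predict_raw(self, features: np.ndarray) -> np.ndarray:
        """Gibbs density normalized over the training background."""
        return np.exp(self.eta(features) - self.log_z)

    def predict_logistic(self, features: np.ndarray) -> np.ndarray:
        """Entropy-calibrated logistic output in (0, 1)."""
        t = np.exp(self.eta(features) + self.entropy - self.log_z)
        return t / (1.0 + t)


def _log_mean_exp(x: np.ndarray) -> float:
    m = float(x.max())
    return m + float(np.log(np.mean(np.exp(x - m))))


def fit_maxent(pres_features: np.ndarray, bg_features: np.ndarray,
               spec: FeatureSpec,
               betas: dict[str, float] | None = None,
               tol: float = 1e-5, max_iter: int = 500) -> MaxentModel:
    """Fit by cyclic coordinate descent with soft-thresholding.

    The coordinate order is fixed at initialization (descending absolute
    gradient under the uniform distribution) for determinism.
    """
    X_p = np.asarray(pres_features, dtype=float)
    X_b = np.asarray(bg_features, dtype=float)
    if X_p.ndim != 2 or X_b.ndim != 2 or X_p.shape[1] != X_b.shape[1]:
        raise MaxentError("presence/background feature matrices do not align")
    m, n_feat = X_p.shape
    n_bg = X_b.shape[0]
    if m < 1 or n_bg < 2:
        raise MaxentError("need >= 1 presence and >= 2 background cells")
    if not (np.isfinite(X_p).all() and np.isfinite(X_b).all()):
        bad = np.flatnonzero(~np.isfinite(X_p).all(axis=0) |
                             ~np.isfinite(X_b).all(axis=0))
        names = [spec.features[i].name for i in bad[:5]]
        raise MaxentError(f"non-finite feature values in {names}")

    betas = {**DEFAULT_BETAS, **(betas or {})}
    beta_j = np.array([betas[f.reg_class] for f in spec.features])
    s_j = X_p.std(axis=0, ddof=1) if m > 1 else np.zeros(n_feat)
    # floor keeps the penalty active for near-constant features, as in the
    # reference implementation's lower bound on feature spread
    s_j = np.maximum(s_j, 1e-3)
    penalty_w = beta_j * s_j

    p_mean = X_p.mean(axis=0)
    lam = np.zeros(n_feat)
    eta_b = np.zeros(n_bg)

    def penalized_gain(lam_vec, eta_bg):
        raw = float(p_mean @ lam_vec) - _log_mean_exp(eta_bg)
        return raw - float(penalty_w @ np.abs(lam_vec))

    # fixed deterministic coordinate cycle
    grad0 = p_mean - X_b.mean(axis=0)
    order = np.argsort(-np.abs(grad0), kind="stable")

    gain_trace: dict[str, float] = {}
    cur_gain = penalized_gain(lam, eta_b)  # = 0
    n_pass = 0
    converged = False
    for n_pass in range(1, max_iter + 1):
        max_improve = 0.0
        for j in order:
            f_b = X_b[:, j]
            shifted = eta_b - eta_b.max()
            w = np.exp(shifted)
            w /= w.sum()
            e_j = float(w @ f_b)
            v_j = float(w @ (f_b * f_b)) - e_j * e_j
            grad = p_mean[j] - e_j
            h = max(v_j, 1e-12)
            z = lam[j] + grad / h
            lam_new = np.sign(z) * max(0.0, abs(z) - penalty_w[j] / h)
            delta = lam_new - lam[j]
            if delta == 0.0:
                continue
            # backtracking keeps the ascent monotone
            for _ in range(40):
                trial_lam = lam[j] + delta
                trial_eta = eta_b + delta * f_b
                lam_try = lam.copy()
                lam_try[j] = trial_lam
                g = penalized_gain(lam_try, trial_eta)
                if g >= cur_gain - 1e-12:
                    break
                delta *= 0.5
            else:
                continue
            if g <= cur_gain:
                continue
            improve = g - cur_gain
            lam[j] = trial_lam
            eta_b = trial_eta
            cur_gain = g
            max_improve = max(max_improve, improve)
            for var in spec.features[j].variables:
                gain_trace[var] = gain_trace.get(var, 0.0) + \
                    improve / len(spec.features[j].variables)
        if max_improve < tol:
            converged = True
            break

    log_z = _log_mean_exp(eta_b) + np.log(n_bg)
    shifted = eta_b - eta_b.max()
    p = np.exp(shifted)
    p /= p.sum()
    entropy = float(-(p * np.log(np.maximum(p, 1e-300))).sum())
    raw_gain = float(p_mean @ lam) - _log_mean_exp(eta_b)
    return MaxentModel(
        spec=spec, lambdas=lam, log_z=log_z, n_background=n_bg,
        entropy=entropy, gain=cur_gain, raw_gain=raw_gain,
        gain_trace=gain_trace, n_iter=n_pass, converged=converged,
    )
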