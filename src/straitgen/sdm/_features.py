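"""Feature construction for the maximum-entropy niche model.

Raw variables are min-max scaled to [0,1]; every derived feature also maps
into [0,1].  The H class uses linear plus forward/reverse hinge features at
equally spaced interior knots; the HQP class adds quadratic and pairwise
product terms.  Categorical variables (the peer-range hull) enter unscaled
as 0/1 under the linear regularization class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Flat regularization defaults per feature class.
DEFAULT_BETAS = {"linear": 0.1, "quadratic": 0.1, "product": 0.2,
                 "hinge": 0.5, "categorical": 0.1}


@dataclass
class Feature:
    name: str
    kind: str            # linear | hinge_fwd | hinge_rev | quadratic | product | categorical
    variables: tuple[str, ...]
    knot: float | None = None

    @property
    def reg_class(self) -> str:
        if self.kind in ("hinge_fwd", "hinge_rev"):
            return "hinge"
        if self.kind in ("linear", "quadratic", "product", "categorical"):
            return {"linear": "linear", "quadratic": "quadratic",
                    "product": "product", "categorical": "categorical"}[self.kind]
        raise ValueError(self.kind)


@dataclass
class FeatureSpec:
    class_set: str                       # "H" or "HQP"
    variables: list[str]
    var_range: dict[str, tuple[float, float]]
    n_knots: int
    features: list[Feature]
    categorical: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def scale(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.var_range[name]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def transform(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Feature matrix (n_points, n_features) from raw variable values."""
        scaled = {v: self.scale(v, values[v]) for v in self.variables}
        for c in self.categorical:
            scaled[c] = np.asarray(values[c], dtype=float)
        cols = []
        for f in self.features:
            if f.kind == "linear":
                cols.append(scaled[f.variables[0]])
            elif f.kind == "categorical":
                cols.append(scaled[f.variables[0]])
            elif f.kind == "quadratic":
                cols.append(scaled[f.variables[0]] ** 2)
            elif f.kind == "product":
                cols.append(scaled[f.variables[0]] * scaled[f.variables[1]])
            elif f.kind == "hinge_fwd":
                k = f.knot
                cols.append(np.maximum(0.0, scaled[f.variables[0]] - k) / (1.0 - k))
            elif f.kind == "hinge_rev":
                k = f.knot
                cols.append(np.maximum(0.0, k - scaled[f.variables[0]]) / k)
            else:
                raise ValueError(f.kind)
        return np.column_stack(cols)


def build_features(values: dict[str, np.ndarray], class_set: str = "H",
                   n_knots: int = 30,
                   categorical: list[str] | None = None,
                   ) -> tuple[FeatureSpec, np.ndarray]:
    """Build a feature spec from observed variable values and transform them.

    ``values`` maps variable name to the raw values used to set each
    variable's scaling range (normally presence + background together).
    Zero-range variables are dropped with a warning.  Knots are at
    ``i / (n_knots + 1)`` for i = 1..n_knots, strictly inside (0, 1).
    """
    if class_set not in ("H", "HQP"):
        raise ValueError(f"unknown class set {class_set!r}")
    categorical = list(categorical or [])
    names, ranges = [], {}
    for name, vals in values.items():
        if name in categorical:
            continue
        vals = np.asarray(vals, dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"variable {name!r} has non-finite values")
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            warnings.warn(f"variable {name!r} has zero range; dropped")
            continue
        names.append(name)
        ranges[name] = (lo, hi)

    knots = [(i + 1) / (n_knots + 1) for i in range(n_knots)]
    feats: list[Feature] = []
    for v in names:
        feats.append(Feature(f"{v}:linear", "linear", (v,)))
        for k in knots:
            feats.append(Feature(f"{v}:hinge_fwd@{k:.4f}", "hinge_fwd", (v,), k))
            feats.append(Feature(f"{v}:hinge_rev@{k:.4f}", "hinge_rev", (v,), k))
    if class_set == "HQP":
        for v in names:
            feats.append(Feature(f"{v}:quadratic", "quadratic", (v,)))
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                feats.append(Feature(f"{names[a]}*{names[b]}", "product",
                                     (names[a], names[b])))
    for c in categorical:
        feats.append(Feature(f"{c}:categorical", "categorical", (c,)))

    spec = FeatureSpec(class_set=class_set, variables=names, var_range=ranges,
                       n_knots=n_knots, features=feats, categorical=categorical)
    return spec, spec.transform(values)
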