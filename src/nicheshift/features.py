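"""Feature expansion for the maximum-entropy model.

Raw predictors are min-max scaled to [0, 1] over the training rows, then
expanded into the five classical feature classes:

* ``linear``    — the scaled variable itself
* ``quadratic`` — its square
* ``product``   — pairwise products of scaled variables
* ``threshold`` — step indicators 1{u > t} at equally spaced knots
* ``hinge``     — forward max(0, u - t)/(1 - t) and reverse max(0, t - u)/t

Scaling constants and knots are frozen at fit time and reused at prediction,
optionally with clamping of out-of-range values (the standard guard against
extrapolation when projecting onto future climate layers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["FeatureCombo", "FeatureDef", "FeatureExpander", "build_features", "FEATURE_CLASSES"]

FEATURE_CLASSES = ("linear", "quadratic", "product", "threshold", "hinge")


@dataclass(frozen=True)
class FeatureCombo:
    """A non-empty subset of feature classes plus the knot count for step/hinge."""

    classes: frozenset[str]
    n_knots: int = 15

    def __init__(self, classes, n_knots: int = 15):
        classes = frozenset(classes)
        if not classes:
            raise ValueError("feature combo must be non-empty")
        unknown = classes - set(FEATURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if classes & {"threshold", "hinge"} and n_knots < 2:
            raise ValueError("n_knots must be >= 2 when threshold or hinge is used")
        object.__setattr__(self, "classes", classes)
        object.__setattr__(self, "n_knots", n_knots)

    @property
    def code(self) -> str:
        """Compact label, e.g. 'lqh' for linear+quadratic+hinge."""
        order = {"linear": "l", "quadratic": "q", "product": "p", "threshold": "t", "hinge": "h"}
        return "".join(order[c] for c in FEATURE_CLASSES if c in self.classes)

    @classmethod
    def from_code(cls, code: str, n_knots: int = 15) -> "FeatureCombo":
        rev = {"l": "linear", "q": "quadratic", "p": "product", "t": "threshold", "h": "hinge"}
        return cls({rev[ch] for ch in code}, n_knots=n_knots)

    def __str__(self) -> str:
        return self.code


@dataclass(frozen=True)
class FeatureDef:
    """One expanded feature: its class, source variable(s) and optional knot."""

    name: str
    feature_class: str
    variables: tuple[str, ...]
    knot: float | None = None


class FeatureExpander:
    """Frozen recipe mapping raw variable rows to the model's feature matrix."""

    def __init__(self, variable_names: list[str], combo: FeatureCombo, mins: np.ndarray, maxs: np.ndarray):
        self.combo = combo
        span = maxs - mins
        keep = span > 0
        if not keep.all():
            dropped = [v for v, k in zip(variable_names, keep) if not k]
            logger.warning("excluding constant variable(s) from features: %s", dropped)
        self.variable_names = [v for v, k in zip(variable_names, keep) if k]
        if not self.variable_names:
            raise ValueError("all variables are constant; nothing to expand")
        self.mins = mins[keep]
        self.maxs = maxs[keep]
        self.feature_defs = self._enumerate_features()

    @classmethod
    def fit(cls, values: np.ndarray, variable_names: list[str], combo: FeatureCombo) -> "FeatureExpander":
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("non-finite values in training rows")
        return cls(variable_names, combo, values.min(axis=0), values.max(axis=0))

    def _knots(self) -> np.ndarray:
        # interior knots, equally spaced in (0, 1)
        return np.linspace(0.0, 1.0, self.combo.n_knots + 2)[1:-1]

    def _enumerate_features(self) -> list[FeatureDef]:
        defs: list[FeatureDef] = []
        cls_ = self.combo.classes
        if "linear" in cls_:
            defs += [FeatureDef(v, "linear", (v,)) for v in self.variable_names]
        if "quadratic" in cls_:
            defs += [FeatureDef(f"{v}^2", "quadratic", (v,)) for v in self.variable_names]
        if "product" in cls_:
            defs += [
                FeatureDef(f"{a}*{b}", "product", (a, b))
                for a, b in combinations(self.variable_names, 2)
            ]
        if "threshold" in cls_:
            defs += [
                FeatureDef(f"{v}>{t:.4g}", "threshold", (v,), knot=float(t))
                for v in self.variable_names
                for t in self._knots()
            ]
        if "hinge" in cls_:
            for v in self.variable_names:
                for t in self._knots():
                    defs.append(FeatureDef(f"hinge({v},{t:.4g})", "hinge", (v,), knot=float(t)))
                    defs.append(FeatureDef(f"hinge'({v},{t:.4g})", "hinge", (v,), knot=float(t)))
        return defs

    @property
    def n_features(self) -> int:
        return len(self.feature_defs)

    @property
    def feature_classes(self) -> np.ndarray:
        return np.array([d.feature_class for d in self.feature_defs])

    def transform(self, values: np.ndarray, variable_names: list[str] | None = None, clamp: bool = False) -> np.ndarray:
        """Expand raw variable rows (n, n_vars) into the feature matrix (n, n_features)."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if variable_names is None:
            if values.shape[1] != len(self.variable_names):
                raise ValueError("column count does not match expander variables")
            cols = {v: i for i, v in enumerate(self.variable_names)}
        else:
            cols = {v: variable_names.index(v) for v in self.variable_names}
        u = np.empty((values.shape[0], len(self.variable_names)))
        for k, v in enumerate(self.variable_names):
            u[:, k] = (values[:, cols[v]] - self.mins[k]) / (self.maxs[k] - self.mins[k])
        if clamp:
            u = np.clip(u, 0.0, 1.0)
        uidx = {v: k for k, v in enumerate(self.variable_names)}
        out = np.empty((values.shape[0], self.n_features))
        for j, d in enumerate(self.feature_defs):
            if d.feature_class == "linear":
                out[:, j] = u[:, uidx[d.variables[0]]]
            elif d.feature_class == "quadratic":
                out[:, j] = u[:, uidx[d.variables[0]]] ** 2
            elif d.feature_class == "product":
                out[:, j] = u[:, uidx[d.variables[0]]] * u[:, uidx[d.variables[1]]]
            elif d.feature_class == "threshold":
                out[:, j] = (u[:, uidx[d.variables[0]]] > d.knot).astype(float)
            else:  # hinge: forward then reverse, alternating by name
                x = u[:, uidx[d.variables[0]]]
                t = d.knot
                if d.name.startswith("hinge("):
                    out[:, j] = np.maximum(0.0, x - t) / (1.0 - t)
                else:
                    out[:, j] = np.maximum(0.0, t - x) / t
        return out


def build_features(
    values: np.ndarray, variable_names: list[str], combo: FeatureCombo
) -> tuple[np.ndarray, FeatureExpander]:
    """Fit an expander on training rows and return (feature matrix, expander)."""
    exp = FeatureExpander.fit(values, variable_names, combo)
    names = list(variable_names)
    return exp.transform(values, variable_names=names), exp
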