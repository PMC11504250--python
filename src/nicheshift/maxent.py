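"""Presence-background maximum-entropy model: fitting, prediction, serialization.

The model is the Gibbs density q(x) = exp(lambda . f(x)) / Z over a finite
background sample of the landscape, with features f built by
:mod:`nicheshift.features`. Coefficients minimize the L1-penalized negative
log-likelihood evaluated at presence points,

    J(lambda) = -mean_presence[lambda . f] + ln Z_background
                + sum_j beta_j |lambda_j|,

which is the classical equivalence between maximum-entropy density estimation
subject to soft feature-expectation constraints and L1-regularized Gibbs
fitting. Per-feature penalties are beta_j = rm * beta_class * s_j / sqrt(m),
with s_j the feature's standard deviation over presences and m the presence
count; ``rm`` is the global regularization multiplier tuned by AICc.

The optimizer is deterministic cyclic coordinate descent: each coordinate
takes a damped prox-Newton step with soft-thresholding, and the objective
decrease of every step is recorded so percent-contribution can attribute the
fit path to variables.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .features import FeatureCombo, FeatureExpander
from .grids import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundSample",
    "MaxEntModel",
    "DEFAULT_BETA_CLASS",
    "sample_background",
    "fit_maxent",
    "train_maxent",
    "predict_raw",
    "predict_logistic",
    "write_model",
    "read_model",
]

#: per-class base penalties; a coarse rendition of the MaxEnt defaults
DEFAULT_BETA_CLASS = {
    "linear": 1.0,
    "quadratic": 1.0,
    "product": 1.0,
    "threshold": 2.0,
    "hinge": 0.5,
}

_COEF_CAP = 100.0  # divergence guard for separable data


@dataclass
class BackgroundSample:
    """Uniform sample of valid cell centers with their extracted variable rows."""

    lon: np.ndarray
    lat: np.ndarray
    values: np.ndarray  # (n, n_variables)
    variable_names: list[str]
    seed: int

    @property
    def n(self) -> int:
        return len(self.lon)


def sample_background(stack: EnvStack, n: int = 10_000, seed: int = 0) -> BackgroundSample:
    """Sample ``n`` valid cell centers uniformly without replacement."""
    r, c = stack.valid_rc()
    n_valid = len(r)
    if n_valid == 0:
        raise ValueError("stack has an empty valid mask")
    if n > n_valid:
        warnings.warn(f"requested {n} background points but only {n_valid} valid cells; using all")
        n = n_valid
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_valid, size=n, replace=False)
    r, c = r[idx], c[idx]
    lon, lat = stack.grid.cell_center(r, c)
    values = np.column_stack([stack.layers[name][r, c] for name in stack.layer_names])
    return BackgroundSample(lon=lon, lat=lat, values=values, variable_names=stack.layer_names, seed=seed)


@dataclass
class MaxEntModel:
    """A fitted model: feature recipe, coefficients and normalization constants."""

    expander: FeatureExpander
    coefficients: np.ndarray
    log_normalizer: float
    entropy: float
    rm: float
    beta: np.ndarray
    converged: bool
    n_presence: int
    n_background: int
    feature_credits: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def combo(self) -> FeatureCombo:
        return self.expander.combo

    @property
    def variable_names(self) -> list[str]:
        return self.expander.variable_names

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def scores_from_values(self, values: np.ndarray, variable_names: list[str] | None = None,
                           clamp: bool = False) -> np.ndarray:
        """Raw (normalized Gibbs) output for arbitrary variable rows."""
        F = self.expander.transform(values, variable_names=variable_names, clamp=clamp)
        return np.exp(F @ self.coefficients - self.log_normalizer)

    def logistic_from_values(self, values: np.ndarray, variable_names: list[str] | None = None,
                             clamp: bool = False) -> np.ndarray:
        q = self.scores_from_values(values, variable_names=variable_names, clamp=clamp)
        return _logistic(q, self.entropy)


def _logistic(q: np.ndarray, entropy: float) -> np.ndarray:
    # tau = 0.5 calibration: a cell with q = exp(-H) scores exactly 0.5
    qe = q * np.exp(entropy)
    return qe / (1.0 + qe)


def _objective(lam, F_norm, pbar, beta):
    return float(-pbar @ lam + logsumexp(F_norm @ lam) + beta @ np.abs(lam))


def fit_maxent(
    F_presence: np.ndarray,
    F_background: np.ndarray,
    feature_classes: np.ndarray | None = None,
    rm: float = 1.0,
    beta_defaults: dict[str, float] | None = None,
    beta_override: np.ndarray | float | None = None,
    tol: float = 1e-7,
    max_sweeps: int = 5000,
) -> dict:
    """Fit penalized coefficients on prebuilt feature matrices.

    ``F_background`` is the normalization set: Z, the entropy and all model
    expectations are computed over exactly these rows (append presence rows
    before calling if they should contribute, as :func:`train_maxent` does).
    ``beta_override`` bypasses the rm * class * s/sqrt(m) recipe with explicit
    per-feature penalties.

    Returns a dict with coefficients, lnZ, entropy, per-feature objective
    credits and a convergence flag.
    """
    F_p = np.asarray(F_presence, dtype=float)
    F_b = np.asarray(F_background, dtype=float)
    if F_p.shape[0] < 2 or F_b.shape[0] < 2:
        raise ValueError("need at least 2 presence and 2 background rows")
    if rm < 0:
        raise ValueError("rm must be >= 0")
    m, J = F_p.shape
    pbar = F_p.mean(axis=0)

    if beta_override is not None:
        beta = np.broadcast_to(np.asarray(beta_override, dtype=float), (J,)).copy()
    else:
        if feature_classes is None:
            raise ValueError("feature_classes required unless beta_override is given")
        bd = beta_defaults or DEFAULT_BETA_CLASS
        s = F_p.std(axis=0)
        beta = rm * np.array([bd[c] for c in feature_classes]) * s / np.sqrt(m)

    nb = F_b.shape[0]
    Fc = np.asfortranarray(F_b)  # fast column slices in the sweep
    F2 = np.asfortranarray(F_b * F_b)
    lam = np.zeros(J)
    # maintain the normalized Gibbs weights w over the background incrementally:
    # a step delta on coordinate j rescales w by exp(delta f_j) / denom
    w = np.full(nb, 1.0 / nb)
    obj = _objective(lam, F_b, pbar, beta)
    credits = np.zeros(J)
    converged = False

    def sweep_over(indices) -> float:
        nonlocal obj, w
        max_delta = 0.0
        for j in indices:
            fj = Fc[:, j]
            Eq = w @ fj
            grad = Eq - pbar[j]
            hess = max(w @ F2[:, j] - Eq * Eq, 1e-12)
            z = lam[j] * hess - grad
            target = np.sign(z) * max(abs(z) - beta[j], 0.0) / hess
            target = min(max(target, -_COEF_CAP), _COEF_CAP)
            delta = target - lam[j]
            if abs(delta) < 1e-15:
                continue
            # damped prox-Newton step: halve until the objective does not increase
            t = np.exp(delta * fj)
            for _ in range(25):
                denom = w @ t
                new_obj = (
                    obj - pbar[j] * delta + np.log(denom)
                    + beta[j] * (abs(lam[j] + delta) - abs(lam[j]))
                )
                if new_obj <= obj + 1e-12:
                    break
                delta *= 0.5
                t = np.sqrt(t)
            else:
                continue
            w = w * t / denom
            credits[j] += max(obj - new_obj, 0.0)
            lam[j] += delta
            obj = new_obj
            max_delta = max(max_delta, abs(delta))
        w /= w.sum()  # guard against incremental drift
        return max_delta

    # glmnet-style active-set cycling: full sweeps alternate with cheap
    # sweeps over the current nonzero set until the full sweep is stable.
    # Besides the coefficient-change tol, an objective plateau across a full
    # outer cycle also counts as converged: near-collinear hinge/threshold
    # features can trade mass indefinitely at no objective gain.
    sweeps_left = max_sweeps
    all_idx = range(J)
    plateau = lambda before: before - obj < 1e-9 * (1.0 + abs(obj))
    while sweeps_left > 0:
        sweeps_left -= 1
        obj_before = obj
        if sweep_over(all_idx) < tol:
            converged = True
            break
        while sweeps_left > 0:
            sweeps_left -= 1
            active = np.nonzero(lam)[0]
            inner_before = obj
            if len(active) == 0 or sweep_over(active) < tol or plateau(inner_before):
                break
        if plateau(obj_before):
            converged = True
            break
    if not converged:
        # the sweep budget ran out; accept the solution anyway if it satisfies
        # the KKT optimality conditions of the L1 problem to modest precision
        grad = F_b.T @ w - pbar
        viol = np.where(
            lam != 0.0,
            np.abs(grad + beta * np.sign(lam)),
            np.maximum(np.abs(grad) - beta, 0.0),
        )
        kkt = float(viol.max())
        if kkt < 1e-4:
            converged = True
        else:
            logger.warning(
                "maxent fit did not converge after %d sweeps (max KKT violation %.3g)",
                max_sweeps, kkt,
            )
    eta = F_b @ lam
    lnZ = float(logsumexp(eta))
    logq = eta - lnZ
    entropy = float(-(np.exp(logq) @ logq))
    return {
        "coefficients": lam,
        "log_normalizer": lnZ,
        "entropy": entropy,
        "beta": beta,
        "converged": converged,
        "feature_credits": credits,
    }


def train_maxent(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    combo: FeatureCombo,
    rm: float = 1.0,
    beta_defaults: dict[str, float] | None = None,
    include_presences_in_background: bool = True,
    tol: float = 1e-7,
    max_sweeps: int = 5000,
) -> MaxEntModel:
    """Fit a model from raw variable rows.

    Feature scaling ranges come from the pooled presence + background rows;
    presence rows are appended to the background for normalization (standard
    presence-background practice) unless disabled.
    """
    P = np.asarray(presence_values, dtype=float)
    B = np.asarray(background_values, dtype=float)
    pooled = np.vstack([B, P])
    expander = FeatureExpander.fit(pooled, list(variable_names), combo)
    F_p = expander.transform(P, variable_names=list(variable_names))
    F_b = expander.transform(pooled if include_presences_in_background else B,
                             variable_names=list(variable_names))
    res = fit_maxent(
        F_p, F_b,
        feature_classes=expander.feature_classes,
        rm=rm, beta_defaults=beta_defaults, tol=tol, max_sweeps=max_sweeps,
    )
    return MaxEntModel(
        expander=expander,
        coefficients=res["coefficients"],
        log_normalizer=res["log_normalizer"],
        entropy=res["entropy"],
        rm=rm,
        beta=res["beta"],
        converged=res["converged"],
        n_presence=P.shape[0],
        n_background=F_b.shape[0],
        feature_credits=res["feature_credits"],
    )


def predict_raw(model: MaxEntModel, stack: EnvStack, clamp: bool = False) -> np.ndarray:
    """Raw Gibbs output per cell (normalized by the training lnZ); NaN off-mask.

    With ``clamp`` on, variable values outside the training range are clipped
    before feature expansion — the recommended mode when projecting onto
    future-scenario layers.
    """
    missing = set(model.variable_names) - set(stack.layer_names)
    if missing:
        raise KeyError(f"stack lacks model variables: {sorted(missing)}")
    r, c = stack.valid_rc()
    values = np.column_stack([stack.layers[v][r, c] for v in model.variable_names])
    q = model.scores_from_values(values, variable_names=model.variable_names, clamp=clamp)
    out = np.full((stack.grid.n_rows, stack.grid.n_cols), np.nan)
    out[r, c] = q
    return out


def predict_logistic(model: MaxEntModel, stack: EnvStack, clamp: bool = True) -> np.ndarray:
    """Logistic suitability in (0, 1) per cell: q e^H / (1 + q e^H)."""
    q = predict_raw(model, stack, clamp=clamp)
    out = np.full_like(q, np.nan)
    ok = np.isfinite(q)
    out[ok] = _logistic(q[ok], model.entropy)
    return out


def write_model(model: MaxEntModel, path: str | Path) -> Path:
    """Serialize a model to a plain-text coefficient table with a JSON header line."""
    path = Path(path)
    meta = {
        "combo": model.combo.code,
        "n_knots": model.combo.n_knots,
        "log_normalizer": model.log_normalizer,
        "entropy": model.entropy,
        "rm": model.rm,
        "converged": model.converged,
        "n_presence": model.n_presence,
        "n_background": model.n_background,
        "variables": {
            v: [float(model.expander.mins[k]), float(model.expander.maxs[k])]
            for k, v in enumerate(model.expander.variable_names)
        },
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("feature\tclass\tknot\tlambda\n")
        for d, lam in zip(model.expander.feature_defs, model.coefficients):
            knot = "" if d.knot is None else repr(float(d.knot))
            fh.write(f"{d.name}\t{d.feature_class}\t{knot}\t{float(lam)!r}\n")
    return path


def read_model(path: str | Path) -> MaxEntModel:
    """Load a model written by :func:`write_model`."""
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        fh.readline()  # column header
        lams = [float(line.rstrip("\n").split("\t")[3]) for line in fh if line.strip()]
    combo = FeatureCombo.from_code(meta["combo"], n_knots=meta["n_knots"])
    names = list(meta["variables"])
    mins = np.array([meta["variables"][v][0] for v in names])
    maxs = np.array([meta["variables"][v][1] for v in names])
    expander = FeatureExpander(names, combo, mins, maxs)
    coef = np.asarray(lams)
    if len(coef) != expander.n_features:
        raise ValueError(f"{path}: coefficient count {len(coef)} != {expander.n_features} features")
    return MaxEntModel(
        expander=expander,
        coefficients=coef,
        log_normalizer=meta["log_normalizer"],
        entropy=meta["entropy"],
        rm=meta["rm"],
        beta=np.zeros_like(coef),
        converged=meta["converged"],
        n_presence=meta["n_presence"],
        n_background=meta["n_background"],
    )
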