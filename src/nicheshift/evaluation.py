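"""Model evaluation and variable importance.

AUC is the presence-background ROC area in its Mann-Whitney form (background
points stand in for absences, so "AUC" here measures how well the model ranks
presences above random landscape points, not above true absences). Variable
importance comes in three flavors, mirroring standard niche-modelling
reports: jackknife training gains (model with only / without each variable),
percent contribution (attribution of the optimizer's objective improvements
along the fit path) and permutation importance (AUC drop when a predictor's
values are shuffled). The selection rule retains variables whose contribution
or permutation importance reaches a threshold (default 5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .features import FeatureCombo
from .maxent import MaxEntModel, train_maxent

__all__ = [
    "compute_auc",
    "roc_points",
    "grade_auc",
    "jackknife_gains",
    "percent_contribution",
    "permutation_importance",
    "VariableSelection",
    "select_variables",
]


def compute_auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence score > background score) + 0.5 P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def roc_points(presence_scores, background_scores):
    """Empirical ROC curve as a DataFrame (threshold, fpr, tpr) for plotting.

    One point per distinct score, descending, plus the (0, 0) origin;
    trapezoidal integration of these points equals :func:`compute_auc`.
    """
    import pandas as pd

    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([p, b]))[::-1]
    tpr = (p[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (b[None, :] >= thresholds[:, None]).mean(axis=1)
    return pd.DataFrame({
        "threshold": np.r_[np.inf, thresholds],
        "fpr": np.r_[0.0, fpr],
        "tpr": np.r_[0.0, tpr],
    })


def grade_auc(auc: float) -> str:
    """Conventional qualitative bands for niche-model AUC (half-open intervals)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc < 0.6:
        return "Fails"
    if auc < 0.7:
        return "Poor"
    if auc < 0.8:
        return "Moderate"
    if auc < 0.9:
        return "Good"
    return "Excellent"


def _training_gain(model: MaxEntModel, presence_values: np.ndarray, variable_names: list[str]) -> float:
    # gain of q over the uniform background distribution, in nats
    q = model.scores_from_values(presence_values, variable_names=variable_names)
    return float(np.mean(np.log(np.maximum(q, 1e-300)))) + np.log(model.n_background)


def jackknife_gains(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    combo: FeatureCombo,
    rm: float = 1.0,
    max_sweeps: int = 2000,
) -> dict:
    """Training gain with only, and without, each variable, plus the full-model gain.

    Returns ``{"full": g, "with_only": {v: g}, "without": {v: g}}``. With a
    single variable the with-only gain trivially equals the full gain (the
    result is still returned so callers can flag it).
    """
    variable_names = list(variable_names)
    P = np.asarray(presence_values, dtype=float)
    B = np.asarray(background_values, dtype=float)

    def gain_for(cols: list[int]) -> float:
        names = [variable_names[i] for i in cols]
        model = train_maxent(P[:, cols], B[:, cols], names, combo, rm=rm, max_sweeps=max_sweeps)
        return _training_gain(model, P[:, cols], names)

    full = gain_for(list(range(len(variable_names))))
    with_only = {v: gain_for([i]) for i, v in enumerate(variable_names)}
    without = {}
    if len(variable_names) > 1:
        without = {
            v: gain_for([j for j in range(len(variable_names)) if j != i])
            for i, v in enumerate(variable_names)
        }
    return {"full": full, "with_only": with_only, "without": without}


def percent_contribution(model: MaxEntModel) -> dict[str, float]:
    """Attribute the fit path's objective improvements to variables, in percent.

    Each coordinate-descent step's objective decrease was credited to the
    feature that moved; features map to their source variable (product
    features split evenly between the pair). Credits are non-negative by
    construction and normalized to sum to 100.
    """
    if model.feature_credits is None:
        raise ValueError("model carries no optimizer trace (loaded from disk?)")
    credit: dict[str, float] = {v: 0.0 for v in model.variable_names}
    for d, c in zip(model.expander.feature_defs, model.feature_credits):
        share = c / len(d.variables)
        for v in d.variables:
            credit[v] += share
    total = sum(credit.values())
    if total <= 0:
        # null model: spread evenly rather than divide by zero
        return {v: 100.0 / len(credit) for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}


def permutation_importance(
    model: MaxEntModel,
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    seed: int = 0,
    n_shuffles: int = 10,
) -> dict[str, float]:
    """AUC drop per shuffled variable, floored at 0 and normalized to sum to 100.

    The shuffle permutes the variable's values jointly across presence and
    background rows, so a variable the model ignores (all its coefficients
    zero) scores exactly 0 before normalization.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    variable_names = list(variable_names)
    P = np.asarray(presence_values, dtype=float)
    B = np.asarray(background_values, dtype=float)
    rng = np.random.default_rng(seed)

    def auc_of(Pv, Bv) -> float:
        return compute_auc(
            model.scores_from_values(Pv, variable_names=variable_names),
            model.scores_from_values(Bv, variable_names=variable_names),
        )

    base = auc_of(P, B)
    used = {v for d, lam in zip(model.expander.feature_defs, model.coefficients)
            if lam != 0 for v in d.variables}
    drops = {}
    n_p = P.shape[0]
    for i, v in enumerate(variable_names):
        if v not in used:
            drops[v] = 0.0
            continue
        col = np.concatenate([P[:, i], B[:, i]])
        d = 0.0
        for _ in range(n_shuffles):
            perm = rng.permutation(col)
            Pv, Bv = P.copy(), B.copy()
            Pv[:, i] = perm[:n_p]
            Bv[:, i] = perm[n_p:]
            d += base - auc_of(Pv, Bv)
        drops[v] = max(d / n_shuffles, 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


@dataclass
class VariableSelection:
    threshold: float
    retained: list[str]
    dropped: list[str]


def select_variables(
    contribution: dict[str, float],
    permutation: dict[str, float],
    threshold: float = 5.0,
    rule: str = "or",
) -> VariableSelection:
    """Retain variables whose contribution or permutation importance meets the threshold.

    ``rule="or"`` (default) keeps a variable passing either metric — the
    inclusive reading; ``rule="and"`` requires both.
    """
    if set(contribution) != set(permutation):
        raise ValueError("contribution and permutation maps must share keys")
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    op = (lambda a, b: a or b) if rule == "or" else (lambda a, b: a and b)
    retained = [v for v in contribution if op(contribution[v] >= threshold, permutation[v] >= threshold)]
    dropped = [v for v in contribution if v not in set(retained)]
    return VariableSelection(threshold=threshold, retained=retained, dropped=dropped)
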