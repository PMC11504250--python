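"""Hyperparameter tuning by AICc over a regularization x feature-combo grid,
and the replicated train/test ensemble that produces the final averaged map.

The candidate grid is the Cartesian product of regularization multipliers
(default 0.5, 1, ..., 4) and feature-class combinations. Every candidate is
fit on the full presence set; its likelihood is the sum over presences of the
log of the raw output (the Gibbs density normalized over background plus
presence cells), its parameter count k is the number of nonzero coefficients,
and the candidate minimizing small-sample-corrected AIC wins (delta AICc = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd

from .evaluation import compute_auc
from .features import FEATURE_CLASSES, FeatureCombo
from .grids import EnvStack
from .maxent import BackgroundSample, MaxEntModel, predict_logistic, train_maxent

logger = logging.getLogger(__name__)

__all__ = [
    "TuningResult",
    "ReplicateEnsemble",
    "aicc",
    "feature_combos",
    "tune",
    "replicate_fit",
    "DEFAULT_RM_GRID",
]

DEFAULT_RM_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: 2k - 2 lnL + 2k(k+1)/(n-k-1).

    Undefined (raises) when n - k - 1 <= 0; callers flag such candidates
    invalid instead of ranking them.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for k={k}, n={n}")
    return 2 * k - 2 * log_likelihood + 2 * k * (k + 1) / (n - k - 1)


def feature_combos(scheme: str = "30", n_knots: int = 15) -> list[FeatureCombo]:
    """Enumerate feature-class combinations.

    ``"31"`` — every non-empty subset of {linear, quadratic, product,
    threshold, hinge}. ``"30"`` (default) — the 31 minus the quadratic-only
    singleton, which no practitioner fits without its linear term. ``"29"`` —
    additionally drops the product-only singleton.
    """
    subsets = [
        frozenset(s)
        for s in chain.from_iterable(combinations(FEATURE_CLASSES, r) for r in range(1, 6))
    ]
    if scheme == "31":
        pass
    elif scheme == "30":
        subsets = [s for s in subsets if s != frozenset({"quadratic"})]
    elif scheme == "29":
        subsets = [s for s in subsets if s not in (frozenset({"quadratic"}), frozenset({"product"}))]
    else:
        raise ValueError(f"unknown combo scheme {scheme!r} (use '29', '30' or '31')")
    return [FeatureCombo(s, n_knots=n_knots) for s in subsets]


@dataclass
class TuningResult:
    rm: float
    combo: FeatureCombo
    k: int
    log_likelihood: float
    aicc: float | None  # None = invalid (k too large for n)
    delta_aicc: float | None = None


def _presence_log_likelihood(model: MaxEntModel, presence_values: np.ndarray) -> float:
    q = model.scores_from_values(presence_values, variable_names=model.variable_names)
    return float(np.sum(np.log(np.maximum(q, 1e-300))))


def tune(
    presence_values: np.ndarray,
    background: BackgroundSample,
    variable_names: list[str],
    rm_grid=DEFAULT_RM_GRID,
    combos: list[FeatureCombo] | None = None,
    beta_defaults: dict[str, float] | None = None,
    max_sweeps: int = 500,
) -> tuple[list[TuningResult], TuningResult]:
    """Fit every (rm, combo) candidate and select the minimum-AICc model.

    Ties break toward fewer parameters, then lower rm, then combo order.
    Returns (all results with delta AICc filled in, the selected result).
    """
    if combos is None:
        combos = feature_combos()
    if len(rm_grid) == 0 or len(combos) == 0:
        raise ValueError("rm_grid and combos must be non-empty")
    n = presence_values.shape[0]
    results: list[TuningResult] = []
    for combo in combos:
        for rm in rm_grid:
            model = train_maxent(
                presence_values, background.values, variable_names, combo,
                rm=rm, beta_defaults=beta_defaults, max_sweeps=max_sweeps,
            )
            k = model.n_nonzero
            ll = _presence_log_likelihood(model, presence_values)
            try:
                a = aicc(ll, k, n)
            except ValueError:
                a = None
                logger.warning("candidate rm=%.2g combo=%s invalid: k=%d vs n=%d", rm, combo, k, n)
            results.append(TuningResult(rm=rm, combo=combo, k=k, log_likelihood=ll, aicc=a))
    valid = [r for r in results if r.aicc is not None]
    if not valid:
        raise ValueError("all tuning candidates invalid (k >= n - 1 everywhere)")
    best_aicc = min(r.aicc for r in valid)
    for r in valid:
        r.delta_aicc = r.aicc - best_aicc
    combo_order = {c.code: i for i, c in enumerate(combos)}
    selected = min(valid, key=lambda r: (r.aicc, r.k, r.rm, combo_order[r.combo.code]))
    return results, selected


def tuning_table(results: list[TuningResult]) -> pd.DataFrame:
    """Results as a DataFrame (rm, combo, k, logLik, AICc, deltaAICc)."""
    return pd.DataFrame(
        {
            "rm": [r.rm for r in results],
            "combo": [r.combo.code for r in results],
            "k": [r.k for r in results],
            "logLik": [r.log_likelihood for r in results],
            "AICc": [r.aicc for r in results],
            "deltaAICc": [r.delta_aicc for r in results],
        }
    )


@dataclass
class ReplicateEnsemble:
    """Models and held-out evaluations from replicated 75/25 presence splits."""

    models: list[MaxEntModel]
    test_indices: list[np.ndarray]
    train_auc: list[float]
    test_auc: list[float]
    averaged_logistic: np.ndarray
    replicate_logistic: list[np.ndarray]
    split_fraction: float

    @property
    def n_replicates(self) -> int:
        return len(self.models)

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean(self.test_auc))

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_auc))


def replicate_fit(
    presence_values: np.ndarray,
    background: BackgroundSample,
    variable_names: list[str],
    stack: EnvStack,
    rm: float,
    combo: FeatureCombo,
    n_replicates: int = 10,
    split_fraction: float = 0.75,
    seed: int = 0,
    beta_defaults: dict[str, float] | None = None,
    max_sweeps: int = 2000,
) -> ReplicateEnsemble:
    """Train ``n_replicates`` models on random subsample splits and average maps.

    Each replicate draws floor(split_fraction * n) training presences without
    replacement from a fresh state of the seeded stream; the rest are the test
    set. AUC uses the background sample as the negative class. The ensemble
    map is the cellwise mean of replicate logistic rasters.
    """
    n = presence_values.shape[0]
    n_train = int(np.floor(split_fraction * n))
    if n_train < 2:
        raise ValueError(f"split leaves {n_train} training presences; need >= 2")
    rng = np.random.default_rng(seed)
    models, test_idx_list, rasters = [], [], []
    train_aucs, test_aucs = [], []
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        model = train_maxent(
            presence_values[train_idx], background.values, variable_names, combo,
            rm=rm, beta_defaults=beta_defaults, max_sweeps=max_sweeps,
        )
        bg_scores = model.scores_from_values(background.values, variable_names=variable_names)
        train_scores = model.scores_from_values(presence_values[train_idx], variable_names=variable_names)
        train_aucs.append(compute_auc(train_scores, bg_scores))
        if len(test_idx):
            test_scores = model.scores_from_values(presence_values[test_idx], variable_names=variable_names)
            test_aucs.append(compute_auc(test_scores, bg_scores))
        models.append(model)
        test_idx_list.append(test_idx)
        rasters.append(predict_logistic(model, stack))
    averaged = np.mean(np.stack(rasters), axis=0)
    return ReplicateEnsemble(
        models=models,
        test_indices=test_idx_list,
        train_auc=train_aucs,
        test_auc=test_aucs or train_aucs,
        averaged_logistic=averaged,
        replicate_logistic=rasters,
        split_fraction=split_fraction,
    )
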