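"""End-to-end analysis pipeline and demo-study generator.

Stages (mirroring a standard climate-suitability workflow): thin occurrences
to the grid -> screen variables by contribution/permutation importance ->
tune (rm, feature combo) by AICc -> fit the replicated ensemble and average
its logistic maps -> project onto each future scenario with clamping ->
classify, measure class areas and area ratios -> compute centroid shifts.
All randomness derives from one master seed via spawned child seeds, so a
re-run with the same config is bit-identical; a JSON manifest records config,
output hashes and wall-clock per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo
from .evaluation import (
    compute_auc,
    grade_auc,
    jackknife_gains,
    percent_contribution,
    permutation_importance,
    roc_points,
    select_variables,
)
from .features import FeatureCombo
from .grids import EnvStack, write_ascii_grid
from .maxent import predict_logistic, sample_background, train_maxent, write_model
from .occurrences import OccurrenceSet, read_occurrences, thin_to_grid, write_samples_csv
from .selection import DEFAULT_RM_GRID, replicate_fit, tune, tuning_table
from .synthetic import (
    SyntheticTruth,
    default_grid,
    make_env_stack,
    make_future_stack,
    sample_presences,
    true_suitability,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "generate_demo", "make_demo_study"]

#: desk-scale combo codes used when no explicit grid is configured; the full
#: tuned product (8 rm x 30 combos) is available via combo_scheme="30"
DESK_COMBOS = ("l", "lq", "lqp", "lqh")


@dataclass
class PipelineConfig:
    occurrences: str
    baseline_dir: str
    scenario_dirs: dict[str, str]
    out_dir: str
    seed: int = 0
    rm_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    combos: tuple[str, ...] = DESK_COMBOS
    n_knots: int = 15
    n_background: int = 2000
    n_replicates: int = 5
    split_fraction: float = 0.75
    selection_threshold: float = 5.0
    selection_rule: str = "or"
    class_thresholds: tuple[float, ...] = geo.CLASS_THRESHOLDS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.occurrences).exists():
            raise FileNotFoundError(self.occurrences)
        for d in [self.baseline_dir, *self.scenario_dirs.values()]:
            if not Path(d).is_dir():
                raise FileNotFoundError(d)
        t = self.class_thresholds
        if list(t) != sorted(t) or t[0] <= 0 or t[-1] >= 1:
            raise ValueError("class thresholds must be strictly increasing within (0, 1)")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, float] = field(default_factory=dict)  # wall-clock seconds
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all artifacts under ``config.out_dir``."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    t0 = time.perf_counter()

    def stage_done(name: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        manifest.stages[name] = round(now - t0, 3)
        logger.info("stage %s finished in %.2fs", name, now - t0)
        t0 = now

    # -- thin ---------------------------------------------------------------
    baseline = EnvStack.read_dir(config.baseline_dir)
    occ_raw = read_occurrences(config.occurrences)
    occ = thin_to_grid(occ_raw, baseline.grid)
    logger.info("occurrences: %d -> %d after thinning", len(occ_raw), len(occ))
    write_samples_csv(occ, out / "occurrences_thinned.csv")
    stage_done("thin")

    # -- background + variable screening ------------------------------------
    background = sample_background(baseline, n=config.n_background, seed=int(seeds[0]))
    pres_values = baseline.extract(occ.lon, occ.lat)
    ok = np.isfinite(pres_values).all(axis=1)
    pres_values = pres_values[ok]
    names = baseline.layer_names
    screen_combo = FeatureCombo({"linear", "quadratic"})
    screen = train_maxent(pres_values, background.values, names, screen_combo, rm=1.0)
    contrib = percent_contribution(screen)
    perm = permutation_importance(screen, pres_values, background.values, names,
                                  seed=int(seeds[1]), n_shuffles=5)
    sel = select_variables(contrib, perm, threshold=config.selection_threshold,
                           rule=config.selection_rule)
    retained = sel.retained or names  # never proceed with zero variables
    logger.info("variable screening retained %d/%d: %s", len(retained), len(names), retained)
    kept_idx = [names.index(v) for v in retained]
    pres_kept = pres_values[:, kept_idx]
    bg_kept = background.values[:, kept_idx]
    stage_done("screen")

    # -- tune ---------------------------------------------------------------
    from .maxent import BackgroundSample

    bg_for_tune = BackgroundSample(
        lon=background.lon, lat=background.lat, values=bg_kept,
        variable_names=retained, seed=background.seed,
    )
    combos = [FeatureCombo.from_code(c, n_knots=config.n_knots) for c in config.combos]
    results, selected = tune(pres_kept, bg_for_tune, retained,
                             rm_grid=config.rm_grid, combos=combos)
    tuning_table(results).to_csv(out / "tuning.csv", index=False)
    logger.info("selected rm=%.2g combo=%s (k=%d)", selected.rm, selected.combo, selected.k)
    stage_done("tune")

    # -- replicate ensemble --------------------------------------------------
    sub = EnvStack(grid=baseline.grid,
                   layers={v: baseline.layers[v] for v in retained},
                   mask=baseline.mask)
    ensemble = replicate_fit(
        pres_kept, bg_for_tune, retained, sub, selected.rm, selected.combo,
        n_replicates=config.n_replicates, split_fraction=config.split_fraction,
        seed=int(seeds[2]),
    )
    write_model(ensemble.models[0], out / "model_replicate1.txt")
    jk = jackknife_gains(pres_kept, bg_kept, retained, selected.combo, rm=selected.rm) \
        if len(retained) > 1 else None
    full_model = train_maxent(pres_kept, bg_kept, retained, selected.combo, rm=selected.rm)
    roc_points(
        full_model.scores_from_values(pres_kept, variable_names=retained),
        full_model.scores_from_values(bg_kept, variable_names=retained),
    ).to_csv(out / "roc_points.csv", index=False)
    report = {
        "auc_train": ensemble.train_auc,
        "auc_train_mean": ensemble.mean_train_auc,
        "auc_test": ensemble.test_auc,
        "auc_test_mean": ensemble.mean_test_auc,
        "auc_grade": grade_auc(min(max(ensemble.mean_test_auc, 0.0), 1.0)),
        "percent_contribution": contrib,
        "permutation_importance": perm,
        "jackknife_gains": jk,
        "variables_retained": retained,
        "variables_dropped": sel.dropped,
        "selected_rm": selected.rm,
        "selected_combo": selected.combo.code,
        "selected_k": selected.k,
    }
    (out / "evaluation.json").write_text(json.dumps(report, indent=2))
    stage_done("fit")

    # -- project + classify --------------------------------------------------
    rasters = {"current": ensemble.averaged_logistic}
    for scen, d in config.scenario_dirs.items():
        stack = EnvStack.read_dir(d)
        sub_f = EnvStack(grid=stack.grid,
                         layers={v: stack.layers[v] for v in retained},
                         mask=stack.mask)
        reps = [predict_logistic(m, sub_f, clamp=True) for m in ensemble.models]
        rasters[scen] = np.mean(np.stack(reps), axis=0)
    classified = {}
    for scen, arr in rasters.items():
        write_ascii_grid(out / f"{scen}_logistic.asc", baseline.grid,
                         np.where(np.isfinite(arr), arr, baseline.grid.nodata_value))
        cls = geo.classify(arr, baseline.grid)
        classified[scen] = cls
        write_ascii_grid(out / f"{scen}_classes.asc", baseline.grid, cls.classes)
    stage_done("project")

    # -- areas + shifts -------------------------------------------------------
    reports = {scen: geo.class_areas(cls, scenario=scen) for scen, cls in classified.items()}
    rows = []
    for scen, rep in reports.items():
        row = {"scenario": scen, **rep.rounded(),
               "total_suitable": int(round(rep.total_suitable_km2))}
        if scen != "current":
            row["highly_ratio_vs_current"] = round(
                geo.area_ratio(rep, reports["current"], "highly"), 2)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "areas.csv", index=False)

    shift_rows = []
    for scen in config.scenario_dirs:
        for label, cls_set in (("total_suitable", geo.SUITABLE_CLASSES), ("highly", "highly")):
            s = geo.centroid_shift(classified["current"], classified[scen], cls_set,
                                   from_scenario="current", to_scenario=scen)
            shift_rows.append({
                "from": s.from_scenario, "to": s.to_scenario, "class": label,
                "displacement_km": round(s.distance_km, 2),
                "direction": s.direction,
                "angle_deg": None if s.theta_deg is None else round(s.theta_deg, 2),
            })
    shifts = pd.DataFrame(shift_rows)
    shifts.to_csv(out / "shifts.csv", index=False)
    stage_done("shift")

    manifest.summary = {
        "n_occurrences_raw": len(occ_raw),
        "n_occurrences_thinned": len(occ),
        "n_candidates": len(results),
        "auc_test_mean": ensemble.mean_test_auc,
        "selected": {"rm": selected.rm, "combo": selected.combo.code},
        "areas": {s: r.rounded() for s, r in reports.items()},
        "shifts": shift_rows,
    }
    for p in sorted(out.iterdir()):
        if p.is_file() and p.suffix in {".csv", ".asc", ".json", ".txt"}:
            manifest.outputs[p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest


# ---------------------------------------------------------------------------
# demo study
# ---------------------------------------------------------------------------

def make_demo_study(
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size: float = 0.05,
    n_layers: int = 23,
    n_presences: int = 194,
    duplicate_fraction: float = 0.2,
    seed: int = 0,
    scenarios: dict[str, tuple[float, float]] | None = None,
    bump_sigma_cells: float = 10.0,
):
    """Build a complete in-memory synthetic study with known ground truth.

    The active variable ``env01`` is a smooth suitability "climate envelope":
    a Gaussian bump centered slightly south of the grid center (so northward
    scenario shifts stay interior) blended with an autocorrelated noise
    field. All other layers are pure autocorrelated noise. Future stacks are
    exact translations of the baseline, so the true range shift is known.

    Returns a dict with the baseline stack, truth, truth raster, occurrence
    set and per-scenario future stacks.
    """
    if scenarios is None:
        # northward shifts of 8 and 15 cells at the default 0.05 degree cell
        scenarios = {"2050s": (0.0, 8 * cell_size), "2070s": (0.0, 15 * cell_size)}
    grid = default_grid(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size)
    stack = make_env_stack(grid, n_layers=n_layers, autocorr_length=8.0, seed=seed)
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    center_r, center_c = 0.55 * n_rows, 0.5 * n_cols
    bump = np.exp(-((rr - center_r) ** 2 + (cc - center_c) ** 2) / (2 * bump_sigma_cells**2))
    noisy = bump + 0.10 * stack.layers["env01"]
    stack.layers["env01"] = (noisy - noisy.mean()) / noisy.std()
    truth = SyntheticTruth(
        coefficients={"env01": (4.0, 0.0)},
        intercept=-5.0,
        shift_per_scenario=scenarios,
    )
    truth_raster = true_suitability(stack, truth)
    occ = sample_presences(truth_raster, grid, n=n_presences, seed=seed + 1,
                           duplicate_fraction=duplicate_fraction)
    futures = {name: make_future_stack(stack, truth, name) for name in scenarios}
    return {
        "grid": grid,
        "stack": stack,
        "truth": truth,
        "truth_raster": truth_raster,
        "occurrences": occ,
        "futures": futures,
    }


def generate_demo(out_dir: str | Path, seed: int = 0, **overrides) -> Path:
    """Write a complete demo study (stacks, occurrences, truth record) to disk.

    Creates ``baseline/``, one directory per scenario, ``occurrences.csv``,
    ``truth.json`` and a ready-to-run ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = make_demo_study(seed=seed, **overrides)
    study["stack"].write_dir(out / "baseline")
    for name, stack in study["futures"].items():
        stack.write_dir(out / name)
    write_samples_csv(study["occurrences"], out / "occurrences.csv")
    truth = study["truth"]
    (out / "truth.json").write_text(json.dumps({
        "coefficients": {k: list(v) for k, v in truth.coefficients.items()},
        "intercept": truth.intercept,
        "shift_per_scenario": {k: list(v) for k, v in truth.shift_per_scenario.items()},
        "seed": seed,
    }, indent=2))
    cfg = PipelineConfig(
        occurrences=str(out / "occurrences.csv"),
        baseline_dir=str(out / "baseline"),
        scenario_dirs={name: str(out / name) for name in study["futures"]},
        out_dir=str(out / "results"),
        seed=seed,
    )
    (out / "config.yaml").write_text(yaml.safe_dump(json.loads(json.dumps(asdict(cfg)))))
    return out
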