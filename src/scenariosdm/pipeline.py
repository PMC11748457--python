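"""End-to-end orchestration of the two-scenario habitat analysis.

One master seed drives every stage; per-stage seeds are derived
deterministically from it (and logged in the run manifest), so a run is
fully reproducible from its config file. Stages: synthetic landscape (or a
user-provided raster stack), occurrence thinning, collinearity filtering,
repeated fits of the learner registry per scenario, top-k ensembles,
suitability prediction for the current and any declared future periods,
Jenks classification, area/centroid reports, and (optionally) the pairing
experiment with its G-test.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .habitat import (
    area_report,
    centroid_displacement,
    change_analysis,
    jenks_classify,
    mean_center,
)
from .models import (
    fit_single_model,
    metrics_frame,
    predict_suitability,
    select_and_ensemble,
    variable_importance,
)
from .pairing import RubricConfig, g_test_from_tallies, score_repetition, tally_repetitions
from .preprocess import (
    build_model_table,
    pearson_filter,
    sample_pseudo_absences,
    split_rows,
    thin_occurrences,
)
from .stack import EnvStack
from .synthetic import default_landscape, default_niche, generate_occurrences

log = logging.getLogger("scenariosdm")

SCENARIOS = ("scenario1_natural", "scenario2_disturbance")


def derive_seed(master: int, *keys) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    material = [int(master)] + [
        k if isinstance(k, int) else zlib.crc32(str(k).encode()) for k in keys
    ]
    return int(np.random.SeedSequence(material).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Whole-run configuration (YAML-serializable)."""

    seed: int = 0
    out_dir: str = "results"
    # landscape
    n_rows: int = 100
    n_cols: int = 100
    cell_size_km: float = 10.0
    stack_dir: str | None = None  # ingest user rasters instead of simulating
    n_raw_presences: int = 82
    # preprocessing
    thinning_radius_km: float = 30.0
    correlation_threshold: float = 0.8
    n_pseudo_absence: int = 500
    split: tuple[float, float] = (0.8, 0.2)
    redraw_pseudo_absences_per_repetition: bool = True
    # modelling
    algorithms: tuple[str, ...] = (
        "GLM", "GBM", "RF", "CTA", "ANN", "FDA", "MARS", "MAXENT", "XGBOOST",
    )
    n_repetitions: int = 10
    ensemble_k: int = 5
    ensemble_metric: str = "auc"  # the optimal committee used for maps
    quality_gate_tss: float = 0.7
    run_scenario2: bool = True
    lucc_var: str = "lucc"
    # futures: period name -> {variable: additive delta in layer units}
    future_periods: dict = field(default_factory=dict)
    # pairing experiment
    run_pairing: bool = False
    fragmentation_radius_km: float = 50.0
    fragmentation_margin: float = 0.10
    # importance
    n_permutations: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.split = tuple(cfg.split)
        cfg.algorithms = tuple(cfg.algorithms)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["split"] = list(self.split)
        d["algorithms"] = list(self.algorithms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class RunManifest:
    """Record of one pipeline run: config, derived seeds, artifacts, counts."""

    config: dict
    version: str = __version__
    stage_seeds: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)
    model_counts: dict = field(default_factory=dict)
    wall_times: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def perturb_stack(stack: EnvStack, deltas: dict[str, float]) -> EnvStack:
    """Future-period stack: additive per-variable deltas on continuous layers."""
    out = EnvStack(
        geometry=stack.geometry,
        variable_meta=dict(stack.variable_meta),
        class_table=dict(stack.class_table),
        categorical_layers=dict(stack.categorical_layers),
    )
    for name, grid in stack.layers.items():
        out.layers[name] = grid + deltas.get(name, 0.0)
    return out


def _scenario_variables(stack: EnvStack, cfg: PipelineConfig, scenario: str) -> list[str]:
    selected = pearson_filter(stack, threshold=cfg.correlation_threshold)
    if scenario == "scenario1_natural":
        selected = [v for v in selected if v not in stack.categorical_layers]
    return selected


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> RunManifest:
    """Execute the full analysis; writes reports under ``out_dir`` and
    returns the manifest. See module docstring for the stage list."""
    t0 = time.time()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(cfg))

    def stage_seed(*keys):
        s = derive_seed(cfg.seed, *keys)
        manifest.stage_seeds["/".join(map(str, keys))] = s
        return s

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        manifest.artifacts.append(str(path))

    # ----------------------------------------------------------- landscape
    if cfg.stack_dir:
        stack = EnvStack.read(cfg.stack_dir)
        log.info("loaded stack from %s", cfg.stack_dir)
    else:
        stack = default_landscape(
            stage_seed("landscape"), cfg.n_rows, cfg.n_cols, cfg.cell_size_km
        )
    niche = default_niche(stack)
    occ_raw = generate_occurrences(stack, niche, cfg.n_raw_presences, stage_seed("occurrences"))
    occ = thin_occurrences(occ_raw, cfg.thinning_radius_km, stage_seed("thinning"))
    log.info("thinned %d raw presences to %d", len(occ_raw), len(occ))
    occ.write_csv(out / "occurrences_thinned.csv")
    manifest.artifacts.append(str(out / "occurrences_thinned.csv"))

    scenarios = [SCENARIOS[0]] + ([SCENARIOS[1]] if cfg.run_scenario2 else [])
    all_metrics = []
    ensembles: dict[str, object] = {}
    tables: dict[str, object] = {}
    surfaces: dict[tuple[str, str], np.ndarray] = {}
    reports: dict[tuple[str, str], object] = {}
    classified: dict[tuple[str, str], object] = {}
    importances = []

    for scenario in scenarios:
        t_sc = time.time()
        variables = _scenario_variables(stack, cfg, scenario)
        log.info("%s: %d predictors selected", scenario, len(variables))
        fits = []
        pa_seed = stage_seed(scenario, "pa")
        absences = sample_pseudo_absences(stack, occ, cfg.n_pseudo_absence, seed=pa_seed)
        for rep in range(1, cfg.n_repetitions + 1):
            if cfg.redraw_pseudo_absences_per_repetition and rep > 1:
                absences = sample_pseudo_absences(
                    stack, occ, cfg.n_pseudo_absence, seed=stage_seed(scenario, "pa", rep)
                )
            table = build_model_table(stack, occ, absences, variables)
            table = split_rows(table, cfg.split, seed=stage_seed(scenario, "split", rep))
            for algo in cfg.algorithms:
                fit = fit_single_model(
                    algo, table, seed=stage_seed(scenario, algo, rep), repetition=rep
                )
                fits.append(fit)
                if fit.failed:
                    log.warning("%s rep %d %s failed: %s", scenario, rep, algo, fit.fail_reason)
            tables[scenario] = table  # last repetition's table, used for ensembling
        n_ok = sum(not f.failed for f in fits)
        manifest.model_counts[scenario] = {
            "attempted": len(fits), "succeeded": n_ok, "failed": len(fits) - n_ok,
        }
        all_metrics.append(metrics_frame(fits, scenario=scenario))
        gate = cfg.quality_gate_tss if cfg.ensemble_metric.lower() == "tss" else None
        ens = select_and_ensemble(
            fits, metric=cfg.ensemble_metric, k=cfg.ensemble_k,
            quality_gate=gate, table=tables[scenario],
        )
        ensembles[scenario] = ens
        imp = variable_importance(
            ens, tables[scenario], cfg.n_permutations, seed=stage_seed(scenario, "importance")
        )
        importances.append(pd.DataFrame([{"scenario": scenario, **imp}]))

        periods = {"current": stack, **{
            name: perturb_stack(stack, deltas) for name, deltas in cfg.future_periods.items()
        }}
        for period, pstack in periods.items():
            surf = predict_suitability(ens, pstack, variables)
            surfaces[(scenario, period)] = surf
            cmap = jenks_classify(surf, stack.geometry, scenario=scenario, period=period)
            classified[(scenario, period)] = cmap
            reports[(scenario, period)] = area_report(cmap, scenario=scenario, period=period)
        manifest.wall_times[scenario] = round(time.time() - t_sc, 2)

    # ------------------------------------------------------------- reports
    metrics_df = pd.concat(all_metrics, ignore_index=True)
    save(metrics_df, "model_metrics.csv")
    save(pd.concat(importances, ignore_index=True), "variable_importance.csv")

    area_rows, change_rows, centroid_rows = [], [], []
    for (scenario, period), rep in reports.items():
        for _, row in rep.to_frame().iterrows():
            area_rows.append({"scenario": scenario, "period": period, **row.to_dict()})
    save(pd.DataFrame(area_rows), "area_reports.csv")

    base = reports.get(("scenario1_natural", "current"))
    for key, rep in reports.items():
        if key == ("scenario1_natural", "current") or base is None:
            continue
        ch = change_analysis(base, rep, label=f"{key[0]}/{key[1]} vs scenario1/current")
        change_rows.append(
            {"comparison": ch.label, "total_delta_1e4_km2": ch.total_delta,
             "pct_change": ch.pct_change}
        )
    if change_rows:
        save(pd.DataFrame(change_rows), "change_analysis.csv")

    cents = {}
    for key, cmap in classified.items():
        try:
            cents[key] = mean_center(cmap)
        except ValueError:
            continue
    ref = cents.get(("scenario1_natural", "current"))
    for key, c in cents.items():
        row = {"scenario": key[0], "period": key[1], "lon": c.lon, "lat": c.lat}
        if ref is not None and key != ("scenario1_natural", "current"):
            d, b = centroid_displacement(ref, c)
            row.update({"displacement_km": d, "bearing_deg": b})
        centroid_rows.append(row)
    save(pd.DataFrame(centroid_rows), "centroids.csv")

    # ------------------------------------------------- pairing experiment
    if cfg.run_pairing and cfg.run_scenario2:
        rub = RubricConfig(
            fragmentation_radius_km=cfg.fragmentation_radius_km,
            fragmentation_margin=cfg.fragmentation_margin,
        )
        control = classified[("scenario1_natural", "current")]
        test = classified[("scenario2_disturbance", "current")]
        tallies, traces = [], []
        for rep in range(1, cfg.n_repetitions + 1):
            vseed = stage_seed("pairing", rep)
            rng = np.random.default_rng(vseed)
            n_val = max(3, len(occ) // 4)
            idx = rng.choice(len(occ), size=n_val, replace=False)
            pts = list(zip(occ.lons[idx], occ.lats[idx]))
            score, trace = score_repetition(pts, control, test, rub, repetition=rep)
            trace.insert(0, "repetition", rep)
            tallies.append(score)
            traces.append(trace)
        save(tally_repetitions(tallies), "pairing_tally.csv")
        save(pd.concat(traces, ignore_index=True), "pairing_trace.csv")
        g = g_test_from_tallies(tallies)
        (out / "g_test.yaml").write_text(
            yaml.safe_dump({"G": g.G, "df": g.df, "p_value": g.p_value})
        )
        manifest.artifacts.append(str(out / "g_test.yaml"))

    manifest.wall_times["total"] = round(time.time() - t0, 2)
    manifest.write(out / "manifest.yaml")
    return manifest
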