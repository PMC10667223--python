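"""End-to-end orchestration: preprocess -> network -> phenogroups -> survival -> classifier.

Each run writes a self-contained run directory (network GraphML/JSON,
phenogroup assignments, survival tables, fitted ensemble, metrics, plots
and a markdown report), stamped with the configuration hash and all seeds,
so reruns with the same configuration are bit-identical except timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, mapper, phenogroup, preprocessing, survival, synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    input_csv: str | None = None
    output_dir: str = "phenomapper_run"
    cover: mapper.CoverConfig = field(default_factory=mapper.CoverConfig)
    target_groups: int = 14
    balance_cap: float = 1.4
    louvain_seed: int = 0
    cv: classify.NestedCVConfig = field(default_factory=classify.NestedCVConfig)
    simulation: synthetic.SimulationConfig = field(default_factory=synthetic.SimulationConfig)
    km_horizons: tuple[float, ...] = (5.0, 10.0)
    train_classifier: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # model grids hold estimator objects; record names only
        if d["cv"].get("models"):
            d["cv"]["models"] = sorted(d["cv"]["models"])
        d["simulation"]["feature_profiles"] = {
            k: dataclasses.asdict(v) for k, v in self.simulation.feature_profiles.items()
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("input_csv", "output_dir", "target_groups", "balance_cap",
                    "louvain_seed", "train_classifier"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "km_horizons" in raw:
            cfg.km_horizons = tuple(raw["km_horizons"])
        for key in ("resolution", "gain", "equalized"):
            if key in raw.get("cover", {}):
                setattr(cfg.cover, key, raw["cover"][key])
        for key in ("outer_folds", "inner_folds", "seed"):
            if key in raw.get("cv", {}):
                setattr(cfg.cv, key, raw["cv"][key])
        sim = raw.get("simulation", {})
        for key in ("n_patients", "seed", "admin_censor_years", "competing_censor_rate"):
            if key in sim:
                setattr(cfg.simulation, key, sim[key])
        if "group_weights" in sim:
            cfg.simulation.group_weights = tuple(sim["group_weights"])
        if "baseline_hazard_per_group" in sim:
            cfg.simulation.baseline_hazard_per_group = tuple(sim["baseline_hazard_per_group"])
        if "device_log_hazard_per_group" in sim:
            cfg.simulation.device_log_hazard_per_group = tuple(sim["device_log_hazard_per_group"])
        return cfg


@dataclass
class RunResult:
    """Handles to everything a finished run produced."""

    run_dir: Path
    graph: mapper.MapperGraph
    partition: phenogroup.PhenogroupPartition
    survival_summary: dict
    ensemble: classify.EnsembleClassifier | None
    metrics: classify.MetricsReport | None


def simulate(config: PipelineConfig, out_csv, latent_csv=None) -> synthetic.SyntheticCohort:
    """Generate a synthetic cohort and write it to CSV."""
    cohort = synthetic.generate_cohort(config.simulation)
    cohort.write(out_csv, latent_csv)
    return cohort


def run_pipeline(config: PipelineConfig, cohort: pd.DataFrame | None = None) -> RunResult:
    """Execute all stages in order and populate the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(),
             "louvain_seed": config.louvain_seed, "cv_seed": config.cv.seed,
             "simulation_seed": config.simulation.seed}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("preprocess")
        if cohort is None:
            if config.input_csv is None:
                raise FileNotFoundError("no input cohort: set input_csv or pass a table")
            cohort = preprocessing.read_cohort_csv(config.input_csv)
        features = preprocessing.preprocess(cohort)
        events_all = cohort["event"].to_numpy(dtype=float)
        times_all = cohort["time_years"].to_numpy(dtype=float)
    except Exception as exc:
        _abort(run_dir, "preprocess", exc)

    try:
        _stage("mapper")
        graph = mapper.build_mapper(features.values, config.cover, events=events_all)
        graph.write_graphml(run_dir / "graph.graphml")
        graph.write_json(run_dir / "graph.json")
    except Exception as exc:
        _abort(run_dir, "mapper", exc)

    try:
        _stage("phenogroup")
        partition = phenogroup.phenogroup_pipeline(
            graph, events_all, target_groups=config.target_groups,
            seed=config.louvain_seed, balance_cap=config.balance_cap)
        assign = partition.to_frame()
        assign["patient_id"] = cohort["patient_id"].to_numpy()[assign["patient_id"].to_numpy()]
        assign.to_csv(run_dir / "phenogroups.csv", index=False)
        partition.write_trace_json(run_dir / "merge_trace.json")
    except Exception as exc:
        _abort(run_dir, "phenogroup", exc)

    try:
        _stage("survival")
        retained = sorted(partition.patient_to_group)
        labels = np.array([partition.patient_to_group[i] for i in retained])
        t = times_all[retained]
        e = events_all[retained].astype(int)
        summary: dict = {"followup": survival.reverse_km_followup(t, e),
                         "outliers_removed": len(graph.outliers),
                         "groups": {}, **stamp}
        lr = survival.logrank(t, e, labels)
        summary["logrank"] = {"statistic": lr["statistic"], "df": lr["df"], "p": lr["p"]}
        for g in phenogroup.PHENOGROUP_LABELS:
            sel = labels == g
            curve = survival.km_estimate(t[sel], e[sel])
            summary["groups"][g] = {
                "n": int(sel.sum()), "events": int(e[sel].sum()),
                "mortality_at": {str(h): float(1 - curve.survival_at(h))
                                 for h in config.km_horizons},
            }
        # phenogroup HRs vs low, and device HR within each phenogroup
        dummies = np.column_stack([(labels == "intermediate").astype(float),
                                   (labels == "high").astype(float)])
        fit = survival.cox_fit(t, e, dummies, names=["intermediate", "high"])
        summary["phenogroup_hr_vs_low"] = {
            name: {"hr": float(fit.hr[j]), "ci": [float(fit.ci_lower[j]), float(fit.ci_upper[j])],
                   "p": float(fit.p[j])}
            for j, name in enumerate(fit.names)}
        device = cohort["device_type"].to_numpy(dtype=float)[retained]
        summary["device_hr_by_group"] = {}
        for g in phenogroup.PHENOGROUP_LABELS:
            sel = (labels == g) & ~np.isnan(device)
            try:
                dfit = survival.cox_fit(t[sel], e[sel], device[sel, None], names=["device"])
                summary["device_hr_by_group"][g] = {
                    "hr": float(dfit.hr[0]),
                    "ci": [float(dfit.ci_lower[0]), float(dfit.ci_upper[0])],
                    "p": float(dfit.p[0])}
            except ValueError as err:
                summary["device_hr_by_group"][g] = {"hr": None, "error": str(err)}
        sub = cohort.iloc[retained].copy()
        forest = survival.subgroup_forest(sub)
        forest.to_csv(run_dir / "subgroup_forest.csv", index=False)
        with open(run_dir / "survival.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        from . import viz

        viz.km_plot(t, e, labels, run_dir / "km_phenogroups.svg")
        viz.forest_plot(forest, run_dir / "forest.svg")
        viz.network_plot(graph, run_dir / "network.svg",
                         node_to_group=partition.node_to_group)
    except Exception as exc:
        _abort(run_dir, "survival", exc)

    ensemble = metrics = None
    if config.train_classifier:
        try:
            _stage("classifier")
            raw = preprocessing.encode_features(cohort)
            X = raw.values[retained]
            ensemble, metrics = classify.nested_cv_train(X, labels, config.cv)
            ensemble.save(run_dir / "model.joblib")
            metrics.to_frame().to_csv(run_dir / "metrics.csv", index=False)
            with open(run_dir / "metrics.json", "w") as fh:
                json.dump({"aggregate": {k: list(v) for k, v in metrics.aggregate.items()},
                           "per_fold": metrics.per_fold,
                           "member_configs": ensemble.member_configs, **stamp},
                          fh, indent=1, default=str)
            np.savetxt(run_dir / "confusion_matrices.csv",
                       np.vstack(metrics.confusion_matrices), fmt="%d", delimiter=",")
        except Exception as exc:
            _abort(run_dir, "classifier", exc)

    with open(run_dir / "run_stamp.json", "w") as fh:
        json.dump(stamp, fh, indent=1)
    return RunResult(run_dir=run_dir, graph=graph, partition=partition,
                     survival_summary=summary, ensemble=ensemble, metrics=metrics)


def _abort(run_dir: Path, stage: str, exc: Exception):
    record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
    with open(run_dir / "error.json", "w") as fh:
        json.dump(record, fh, indent=1)
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


REPORT_ARTIFACTS = ("graph.json", "phenogroups.csv", "survival.json")


def report(run_dir, out_name: str = "report.md") -> Path:
    """Render a markdown summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    missing = [a for a in REPORT_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    with open(run_dir / "survival.json") as fh:
        surv = json.load(fh)
    groups = pd.read_csv(run_dir / "phenogroups.csv")
    lines = ["# Phenomapper run report", "",
             f"Config hash: `{surv.get('config_hash', '?')}`", "",
             "## Phenogroups", ""]
    counts = groups["phenogroup"].value_counts()
    lines += [f"- {g}: {counts.get(g, 0)} patients" for g in ("low", "intermediate", "high")]
    lines += ["",
             f"Outliers removed with minor network components: {surv['outliers_removed']}",
             "",
             "## Survival", "",
             f"Median follow-up (reverse KM): {surv['followup']['median']:.2f} years",
             f"Log-rank across phenogroups: chi2 = {surv['logrank']['statistic']:.2f}, "
             f"df = {surv['logrank']['df']}, p = {surv['logrank']['p']:.2e}", ""]
    for name, d in surv["phenogroup_hr_vs_low"].items():
        lines.append(f"- {name} vs low: HR {d['hr']:.3f} "
                     f"({d['ci'][0]:.3f}-{d['ci'][1]:.3f}), p = {d['p']:.3g}")
    lines.append("")
    lines.append("## Device effect (CRT-D vs CRT-P) within phenogroups")
    for g, d in surv["device_hr_by_group"].items():
        if d.get("hr") is not None:
            lines.append(f"- {g}: HR {d['hr']:.3f} ({d['ci'][0]:.3f}-{d['ci'][1]:.3f})")
        else:
            lines.append(f"- {g}: undefined ({d.get('error', 'no fit')})")
    metrics_path = run_dir / "metrics.json"
    lines.append("")
    lines.append("## Classifier")
    if metrics_path.exists():
        with open(metrics_path) as fh:
            m = json.load(fh)["aggregate"]
        for key in ("balanced_accuracy", "accuracy", "auc_micro", "auc_macro"):
            if key in m:
                mean, lo, hi = m[key]
                lines.append(f"- {key}: {mean:.3f} ({lo:.3f}-{hi:.3f})")
    else:
        lines.append("- classifier section absent (no model trained in this run)")
    out = run_dir / out_name
    out.write_text("\n".join(lines) + "\n")
    return out
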