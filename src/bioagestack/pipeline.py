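"""End-to-end orchestration: generate → impute-bench → select → train/stack →
associate → report, with seeded reproducibility and a digest manifest.

Each stage writes plain CSV artifacts into the run directory and records a
SHA-256 digest; re-running an unchanged configuration reproduces identical
digests for the deterministic stages.  The report is a Markdown document
summarizing the benchmark curves, the model-metric table, BA distributions by
gender and the association batteries.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .associations import (
    add_risk_indices,
    disease_count_battery,
    per_disease_battery,
    results_frame,
    risk_indicator_battery,
)
from .benchmark import run_benchmark, summarize_benchmark
from .cohort import (
    MissingnessProfile,
    default_cohort_spec,
    default_mnar_profile,
    drop_oracle_columns,
    generate_cohort,
)
from .models import BoostedBioAge, SplitSpec, StackedBioAge, StackingSpec
from .selection import SelectionConfig, select_features

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "render_report"]

ALL_STAGES = ("generate", "impute_bench", "select", "train", "associate", "report")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str
    n_participants: int = 2000
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    mcar_rates: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30)
    include_mnar: bool = True
    imputation_methods: tuple[str, ...] = (
        "mean", "knn", "round_robin_regression", "chained_multiple", "autoencoder")
    folds: int = 10
    train_fraction: float = 0.8
    stacking_folds: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("stages", "mcar_rates", "imputation_methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)   # path -> sha256
    seeds: dict[str, int] = field(default_factory=dict)
    wall_clock: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "artifacts": self.artifacts,
             "seeds": self.seeds, "wall_clock": self.wall_clock},
            indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.artifacts[path.name] = _digest(path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order; returns the manifest
    (also written to ``manifest.json`` in the run directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=vars(config) | {
        "stages": list(config.stages), "mcar_rates": list(config.mcar_rates),
        "imputation_methods": list(config.imputation_methods)})
    manifest.seeds["root"] = config.seed
    stages = config.stages
    cohort = None
    ba_sets: dict[str, np.ndarray] = {}

    def _stage_cohort() -> pd.DataFrame:
        nonlocal cohort
        if cohort is None:
            cohort_path = out / "cohort.csv"
            if not cohort_path.exists():
                raise RuntimeError("stage requires a generated cohort; "
                                   "enable the 'generate' stage or keep cohort.csv")
            cohort = pd.read_csv(cohort_path)
        return cohort

    if "generate" in stages:
        t0 = time.perf_counter()
        spec = default_cohort_spec(config.n_participants, seed=config.seed)
        cohort = generate_cohort(spec)
        _write(cohort, out / "cohort.csv", manifest)
        (out / "cohort.meta.json").write_text(json.dumps(
            {"seed": config.seed, "n_participants": config.n_participants}))
        manifest.artifacts["cohort.meta.json"] = _digest(out / "cohort.meta.json")
        manifest.wall_clock["generate"] = time.perf_counter() - t0

    if "impute_bench" in stages:
        t0 = time.perf_counter()
        c = drop_oracle_columns(_stage_cohort())
        profiles: list[MissingnessProfile] = [
            MissingnessProfile("MCAR", global_rate=r) for r in config.mcar_rates]
        if config.include_mnar:
            profiles.append(default_mnar_profile())
        scores = run_benchmark(c, profiles, list(config.imputation_methods),
                               folds=config.folds,
                               train_fraction=config.train_fraction,
                               seed=config.seed)
        # wall-clock timing is informational and machine-dependent; keep it
        # out of the deterministic artifacts
        _write(scores[["method", "mechanism", "rate", "fold", "seconds"]],
               out / "imputation_timing.csv", manifest)
        _write(scores.drop(columns="seconds"),
               out / "imputation_scores.csv", manifest)
        _write(summarize_benchmark(scores).drop(columns="seconds"),
               out / "imputation_summary.csv", manifest)
        manifest.wall_clock["impute_bench"] = time.perf_counter() - t0

    if "select" in stages:
        t0 = time.perf_counter()
        c = drop_oracle_columns(_stage_cohort())
        report = select_features(c, config=SelectionConfig(seed=config.seed))
        _write(report.table, out / "selection_report.csv", manifest)
        manifest.wall_clock["select"] = time.perf_counter() - t0

    if "train" in stages:
        t0 = time.perf_counter()
        c = drop_oracle_columns(_stage_cohort())
        split = SplitSpec(train_fraction=config.train_fraction,
                          stacking_folds=config.stacking_folds, seed=config.seed)
        features = _selected_features(out, c)
        stk = StackedBioAge(c, features=features, split=split,
                            stacking=StackingSpec()).fit()
        moderate = BoostedBioAge(c, features=features, split=split,
                                 mode="moderate").fit()
        overfit = BoostedBioAge(c, features=features, split=split,
                                mode="overfit").fit()
        preds = pd.concat([stk.predictions, moderate.predictions,
                           overfit.predictions], ignore_index=True)
        metrics = pd.concat([stk.metrics_frame(), moderate.metrics_frame(),
                             overfit.metrics_frame()], ignore_index=True)
        _write(preds, out / "ba_predictions.csv", manifest)
        _write(metrics, out / "ba_metrics.csv", manifest)
        _write(stk.importance, out / "feature_importance.csv", manifest)
        for tag, res in (("STK", stk), ("boost_moderate", moderate),
                         ("boost_overfit", overfit)):
            ba_sets[tag] = res.ba
        manifest.wall_clock["train"] = time.perf_counter() - t0

    if "associate" in stages:
        t0 = time.perf_counter()
        c = add_risk_indices(drop_oracle_columns(_stage_cohort()))
        if not ba_sets:
            preds = pd.read_csv(out / "ba_predictions.csv")
            for tag, g in preds.groupby("model_tag"):
                ba_sets[tag] = g.sort_values("participant_id")["ba"].to_numpy()
        for tag, ba in sorted(ba_sets.items()):
            for adj in ("model1", "model2"):
                risk = (risk_indicator_battery(ba, c, "absi", adj, ba_tag=tag)
                        + risk_indicator_battery(ba, c, "whtr", adj, ba_tag=tag))
                counts = disease_count_battery(ba, c, adj, ba_tag=tag)
                per_dis = per_disease_battery(ba, c, adj, ba_tag=tag)
                for name, block in (("risk", risk), ("counts", counts),
                                    ("diseases", per_dis)):
                    _write(results_frame(block),
                           out / f"assoc_{tag}_{name}_{adj}.csv", manifest)
        manifest.wall_clock["associate"] = time.perf_counter() - t0

    if "report" in stages:
        t0 = time.perf_counter()
        report_md = render_report(manifest, out)
        (out / "report.md").write_text(report_md)
        manifest.artifacts["report.md"] = _digest(out / "report.md")
        manifest.wall_clock["report"] = time.perf_counter() - t0

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _selected_features(out: Path, cohort: pd.DataFrame) -> list[str] | None:
    path = out / "selection_report.csv"
    if not path.exists():
        return None
    table = pd.read_csv(path)
    kept = table.loc[table["kept"], "feature"].tolist()
    return [f for f in kept if f in cohort.columns] or None


def render_report(manifest: RunManifest, out: Path) -> str:
    """Markdown report assembled from whatever stage artifacts exist."""
    out = Path(out)
    lines = ["# Biological-age pipeline report", ""]

    p = out / "imputation_summary.csv"
    if p.exists():
        lines += ["## Imputation benchmark (masked-entry MSE / R², fold mean ± SD)",
                  "", pd.read_csv(p).round(4).to_markdown(index=False), ""]

    p = out / "selection_report.csv"
    if p.exists():
        t = pd.read_csv(p)
        lines += ["## Feature selection",
                  f"", f"kept {int(t['kept'].sum())} of {len(t)} candidates", "",
                  t.round(4).to_markdown(index=False), ""]

    p = out / "ba_metrics.csv"
    if p.exists():
        lines += ["## BA model metrics (RMSE / R² / MAE / Pearson r)", "",
                  pd.read_csv(p).round(4).to_markdown(index=False), ""]

    pred_path = out / "ba_predictions.csv"
    cohort_path = out / "cohort.csv"
    if pred_path.exists() and cohort_path.exists():
        preds = pd.read_csv(pred_path)
        cohort = pd.read_csv(cohort_path)
        lines += ["## BA distribution by gender", "",
                  _ba_distribution_table(preds, cohort).round(3)
                  .to_markdown(index=False), ""]

    assoc = sorted(out.glob("assoc_*.csv"))
    if assoc:
        lines += ["## Association batteries", ""]
        for path in assoc:
            lines += [f"### {path.stem}", "",
                      pd.read_csv(path).round(4).to_markdown(index=False), ""]

    p = out / "feature_importance.csv"
    if p.exists():
        lines += ["## Aggregate feature importance (stacked model)", "",
                  pd.read_csv(p).round(4).to_markdown(index=False), ""]

    return "\n".join(lines)


def _ba_distribution_table(preds: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    gender = cohort.set_index("participant_id")["gender"]
    ca = cohort.set_index("participant_id")["chronological_age"]
    rows = []
    for tag, g in preds.groupby("model_tag"):
        g = g.set_index("participant_id")
        for label, sel in (("male", gender == 0), ("female", gender == 1),
                           ("total", gender.notna())):
            ids = gender.index[sel]
            ba = g.loc[g.index.intersection(ids), "ba"]
            r = float(np.corrcoef(ca.loc[ba.index], ba)[0, 1]) if len(ba) > 2 else np.nan
            rows.append({"model_tag": tag, "group": label, "n": len(ba),
                         "min": ba.min(), "max": ba.max(), "median": ba.median(),
                         "mean": ba.mean(), "sd": ba.std(),
                         "correlation_with_ca": r})
    return pd.DataFrame(rows)
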