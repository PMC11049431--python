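"""End-to-end experiment orchestration.

One run executes simulate -> render -> split -> oversample -> train ->
predict -> evaluate -> shelf-life regression -> loss/KDE analysis for a
selection of dataset x index combinations ("general" pools all storage
groups; each group also forms its own dataset; each may be labeled on the
5- or 10-stage index — up to eight datasets), writing every artifact under
a run directory and recording paths, seeds and headline metrics in a JSON
manifest.  All randomness descends from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalmetrics, shelflife
from .fruitdb import LabeledImageDatabase, annotate_days_left, summarize_counts
from .ripenet import AugmentationConfig, TrainingConfig, predict, train_classifier
from .splitting import grouped_stratified_split, oversample_training
from .synthetic_orchard import CohortConfig, RenderConfig, render_cohort, simulate_cohort

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment", "compare_models"]


@dataclass
class ExperimentConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    datasets: tuple[tuple[str, int], ...] = (("general", 5), ("general", 10))
    epochs: int = 30
    minibatch: int = 128
    backbone: str = "small_cnn"
    input_size: int = 32
    lr_init: float = 0.01
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "cohort" in raw:
            kw["cohort"] = CohortConfig(**raw.pop("cohort"))
        if "render" in raw:
            kw["render"] = RenderConfig(**raw.pop("render"))
        if "augmentation" in raw:
            kw["augmentation"] = AugmentationConfig(**raw.pop("augmentation"))
        if "datasets" in raw:
            kw["datasets"] = tuple((d, int(i)) for d, i in raw.pop("datasets"))
        if "fractions" in raw:
            kw["fractions"] = tuple(raw.pop("fractions"))
        kw.update(raw)
        return cls(**kw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    run_dir: str
    datasets: dict                      # name -> artifact paths + metrics
    cohort_summary: dict
    elapsed_s: float

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["render"]["stage_palette"] = np.asarray(d["render"]["stage_palette"]).tolist()
    return d


def run_experiment(config: ExperimentConfig, run_dir) -> RunManifest:
    """Execute every stage for the configured dataset x index combinations."""
    t0 = time.time()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    trajectories, records = _stage("simulate")(simulate_cohort)(config.cohort, seed)
    images = _stage("render")(render_cohort)(trajectories, records, config.render, seed + 1)
    db = LabeledImageDatabase(records=records, images=images)
    db = annotate_days_left(db)
    db.records.to_csv(run_dir / "metadata.csv", index=False)

    datasets: dict[str, dict] = {}
    for dname, index in config.datasets:
        tag = f"{dname}_{index}"
        ddir = run_dir / tag
        ddir.mkdir(exist_ok=True)
        sub_records = (db.records if dname == "general"
                       else db.records[db.records["group"] == dname])
        if sub_records.empty:
            raise RuntimeError(f"pipeline stage 'dataset' failed: no records for {dname!r}")
        sub_db = LabeledImageDatabase(records=sub_records.reset_index(drop=True),
                                      images=images)

        split = _stage("split")(grouped_stratified_split)(
            sub_db, fractions=config.fractions, seed=seed + 2, index=index)
        split.assignments().to_csv(ddir / "split.csv", index=False)
        _stage("oversample")(oversample_training)(split, sub_db, seed=seed + 3, index=index)
        summarize_counts(sub_db, split, index=index).to_csv(ddir / "stage_counts.csv")

        tcfg = TrainingConfig(num_classes=index, epochs=config.epochs,
                              minibatch=config.minibatch, backbone=config.backbone,
                              input_size=config.input_size, lr_init=config.lr_init,
                              seed=seed + 4)
        model = _stage("train")(train_classifier)(split, sub_db, tcfg,
                                                  config.augmentation, index=index)
        model.history.to_csv(ddir / "history.csv", index=False)

        test_rows = sub_db.records[sub_db.records["sample_id"].isin(split.test_ids)]
        preds = _stage("predict")(predict)(model, sub_db, test_rows, index=index)
        preds.to_csv(ddir / "predictions.csv", index=False)

        metrics = {
            "picture_accuracy": evalmetrics.accuracy(preds, "picture", 0),
            "sample_accuracy": evalmetrics.accuracy(preds, "sample", 0),
            "picture_accuracy_margin1": evalmetrics.accuracy(preds, "picture", 1),
            "sample_accuracy_margin1": evalmetrics.accuracy(preds, "sample", 1),
            "per_stage_picture": evalmetrics.per_stage_accuracy(preds, "picture"),
        }
        cm = evalmetrics.confusion_matrix(preds, n_stages=index)
        cm.to_frame().to_csv(ddir / "confusion_matrix.csv")

        models = _stage("shelflife")(shelflife.fit_group_models)(sub_db.records, index)
        pd.DataFrame([{"group": g, **m.summary()} for g, m in models.items()]) \
            .to_csv(ddir / "regression.csv", index=False)

        dcol = "days_left5" if index == 5 else "days_left9"
        joined = preds.merge(
            sub_db.records[["sample_id", "side", "day", dcol, "censored"]],
            on=["sample_id", "side", "day"])
        joined = joined[~joined["censored"] & joined[dcol].notna()]
        joined = joined.rename(columns={dcol: "actual_days_left"})
        loss_rows = {}
        for agg in ("by_picture", "by_sample"):
            lrec, lavg = shelflife.loss_table(joined, models, aggregation=agg)
            lavg.to_csv(ddir / f"loss_{agg}.csv", index=False)
            loss_rows[agg] = {r["group"]: r["mean_abs_loss"]
                              for r in lavg.to_dict("records")}
        _, attr_avg = shelflife.loss_table(joined, models, aggregation="by_picture",
                                           stage_col="true_stage")
        attr_avg.to_csv(ddir / "loss_attributed.csv", index=False)
        grid, dens = shelflife.kde_loss(lrec["loss"].to_numpy())
        pd.DataFrame({"loss_days": grid, "density": dens}).to_csv(
            ddir / "loss_kde.csv", index=False)

        datasets[tag] = {
            "dir": str(ddir),
            "index_system": index,
            "n_train": len(split.train_ids), "n_val": len(split.val_ids),
            "n_test": len(split.test_ids),
            "metrics": metrics,
            "loss": loss_rows,
            "regression": {g: m.alpha for g, m in models.items()},
            "artifacts": sorted(p.name for p in ddir.iterdir()),
        }

    manifest = RunManifest(
        config=_config_dict(config), seed=seed, run_dir=str(run_dir),
        datasets=datasets,
        cohort_summary={"n_fruits": len(trajectories), "n_images": len(db.records),
                        "n_censored": int(db.records["censored"].sum() // 2)},
        elapsed_s=time.time() - t0,
    )
    manifest.save(run_dir / "manifest.json")
    return manifest


def compare_models(manifest_a: RunManifest | str, manifest_b: RunManifest | str) -> dict:
    """Error-overlap and side-by-side accuracy report across two runs.

    Both runs must have evaluated the same test records for each shared
    dataset tag (e.g. the same cohort/split seeds with different training
    seeds or backbones).
    """
    if not isinstance(manifest_a, RunManifest):
        manifest_a = RunManifest.load(manifest_a)
    if not isinstance(manifest_b, RunManifest):
        manifest_b = RunManifest.load(manifest_b)
    report = {}
    shared = sorted(set(manifest_a.datasets) & set(manifest_b.datasets))
    if not shared:
        raise ValueError("runs share no dataset tags")
    for tag in shared:
        pa = pd.read_csv(Path(manifest_a.datasets[tag]["dir"]) / "predictions.csv")
        pb = pd.read_csv(Path(manifest_b.datasets[tag]["dir"]) / "predictions.csv")
        ov = evalmetrics.error_overlap(pa, pb)
        report[tag] = {
            "overlap": dataclasses.asdict(ov),
            "overlap_fraction_of_errors": ov.overlap_fraction_of_errors,
            "accuracy_a": evalmetrics.accuracy(pa, "picture", 0),
            "accuracy_b": evalmetrics.accuracy(pb, "picture", 0),
            "n_test_records": ov.total,
        }
    return report
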