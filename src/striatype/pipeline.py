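"""End-to-end pipeline composition.

``run_pipeline`` drives the whole chain on simulated populations: simulate
-> QC -> feature extraction -> PCA/clustering -> classifier training on the
synthetic benchmark -> per-cell classification and one explanation, writing
every stage artifact plus the effective configuration and a provenance log
into a run directory.  Deterministic for fixed seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adex import jittered_params, preset, simulate_population
from .classifier import classify_table, save_model, train_classifier
from .cluster import export_dendrogram, fit_pca, hierarchical_cluster, select_components, silhouette_sweep
from .ephys import FEATURE_NAMES, extract_features, features_table
from .exceptions import StriatypeError, ValidationError
from .explain import explain_lime
from .feature_tables import CLASS_LABELS, benchmark_specs, sample_feature_table
from .io import write_internal
from .qc import QCRules, apply_qc, qc_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("striatype")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized verbatim into the run directory."""

    out_dir: str = "striatype_run"
    seed: int = 0
    cells_per_class: int = 30
    noise_sd: float = 0.3  # mV measurement noise on simulated sweeps
    sampling_rate: float = 20_000.0
    qc_max_rs: float = 25.0
    qc_rmp_ceiling: float = -50.0
    qc_max_fluctuation: float = 0.10
    dvdt_threshold: float = 20.0
    n_components: int = 3
    linkage_method: str = "ward"
    linkage_metric: str = "euclidean"
    k_min: int = 2
    k_max: int = 10
    hidden_units: int = 13
    cv_folds: int = 10
    benchmark_n_per_class: int = 50
    missing_policy: str = "impute_median"  # or "exclude"
    save_recordings: bool = False
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.cells_per_class < 1:
            raise ValidationError("cells_per_class must be >= 1")
        if self.qc_max_rs <= 0:
            raise ValidationError("qc_max_rs must be positive")
        if not 0 < self.qc_max_fluctuation < 1:
            raise ValidationError("qc_max_fluctuation must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if not 2 <= self.k_min <= self.k_max:
            raise ValidationError("need 2 <= k_min <= k_max")
        if self.missing_policy not in ("impute_median", "exclude"):
            raise ValidationError("missing_policy must be impute_median or exclude")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StriatypeError as exc:
                raise StriatypeError(f"[stage {name}] {exc}") from exc
            log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure halts with a stage-tagged error; artifacts written by
    earlier stages are retained.
    """
    config.validate()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (run_dir / "config.yaml").write_text(config.to_yaml())
        log.info("striatype %s, seed %d", __version__, config.seed)
        _run_stages(config, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return run_dir


def _run_stages(config: PipelineConfig, run_dir: Path) -> None:
    from .recording import StepProtocol

    protocol = StepProtocol(sampling_rate=config.sampling_rate)
    rng = np.random.default_rng(config.seed)

    @_stage("simulate")
    def simulate():
        params, ids, labels = [], [], []
        for label in CLASS_LABELS:
            base = preset(label.lower())
            for i in range(config.cells_per_class):
                params.append(jittered_params(base, rng))
                ids.append(f"{label.lower()}_{i:03d}")
                labels.append(label)
        recs = simulate_population(
            params, protocol, noise_sd=config.noise_sd,
            seed=int(rng.integers(2**31 - 1)), cell_ids=ids,
        )
        if config.save_recordings:
            rec_dir = run_dir / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec in recs:
                write_internal(rec, rec_dir / f"{rec.cell_id}.json")
        return recs, labels

    recs, labels = simulate()

    @_stage("qc")
    def qc():
        rules = QCRules(
            max_series_resistance=config.qc_max_rs,
            rmp_ceiling=config.qc_rmp_ceiling,
            max_fluctuation=config.qc_max_fluctuation,
        )
        reports = [apply_qc(rec, rules) for rec in recs]
        qc_table(reports).to_csv(run_dir / "qc_report.csv", index=False)
        return reports

    qc()

    @_stage("extract")
    def extract():
        feats = [extract_features(rec, config.dvdt_threshold) for rec in recs]
        table = features_table(feats)
        table["true_label"] = labels
        table.to_csv(run_dir / "features.csv")
        return table

    table = extract()

    @_stage("cluster")
    def cluster():
        numeric = table[list(FEATURE_NAMES)]
        if config.missing_policy == "impute_median":
            numeric = numeric.fillna(numeric.median())
        else:
            numeric = numeric.dropna()
        model = fit_pca(numeric)
        scores, cum = select_components(model, n=min(config.n_components, numeric.shape[1]))
        pd.DataFrame(
            model.loadings, index=model.feature_names,
            columns=[f"PC{i + 1}" for i in range(model.loadings.shape[1])],
        ).to_csv(run_dir / "pca_loadings.csv")
        pd.DataFrame(
            {"variance_explained": model.variance_explained}
        ).to_csv(run_dir / "pca_variance.csv", index_label="component")
        result = hierarchical_cluster(
            scores, method=config.linkage_method, metric=config.linkage_metric,
            k_range=range(config.k_min, config.k_max + 1),
        )
        result = silhouette_sweep(scores, result)
        labels_df = pd.DataFrame(
            {f"k{k}": v for k, v in result.labels_for_k.items()},
            index=numeric.index,
        )
        labels_df.to_csv(run_dir / "cluster_labels.csv")
        pd.Series(result.silhouette_by_k, name="mean_silhouette").to_csv(
            run_dir / "silhouette.csv", index_label="k"
        )
        export_dendrogram(
            result, str(run_dir / "dendrogram.nwk"),
            leaf_names=[str(i) for i in numeric.index],
            render=str(run_dir / "dendrogram.png"),
        )
        log.info("cumulative variance of %d PCs: %.3f; optimal k: %d",
                 scores.shape[1], cum, result.optimal_k)
        return result

    cluster()

    @_stage("train")
    def train():
        bench = sample_feature_table(
            benchmark_specs(config.benchmark_n_per_class), seed=config.seed
        )
        model, cv = train_classifier(
            bench, hidden=config.hidden_units, folds=config.cv_folds, seed=config.seed
        )
        save_model(model, str(run_dir / "model.json"))
        with open(run_dir / "cv_results.json", "w") as fh:
            json.dump(
                {
                    "fold_accuracies": cv.fold_accuracies,
                    "mean_accuracy": cv.mean_accuracy,
                    "pooled_accuracy": cv.pooled_accuracy,
                    "confusion": cv.confusion.tolist(),
                    "classes": list(cv.classes),
                },
                fh, indent=2,
            )
        return model

    model = train()

    @_stage("classify")
    def classify():
        feature_cols = table[list(FEATURE_NAMES)]
        if config.missing_policy == "impute_median":
            feature_cols = feature_cols.fillna(feature_cols.median())
        preds = classify_table(model, feature_cols)
        preds.insert(0, "true_label", labels)
        preds.to_csv(run_dir / "predictions.csv", index_label="cell_id")
        return preds, feature_cols

    preds, feature_cols = classify()

    @_stage("explain")
    def explain():
        row = feature_cols.iloc[0].to_numpy(dtype=float)
        expl = explain_lime(
            model, row, seed=config.seed, instance_id=str(feature_cols.index[0])
        )
        with open(run_dir / "explanation.json", "w") as fh:
            json.dump(
                {
                    "instance_id": expl.instance_id,
                    "predicted_class": expl.predicted_class,
                    "weights": dict(zip(expl.feature_names, expl.weights.tolist())),
                    "intercept": expl.intercept,
                    "local_fit_quality": expl.local_fit_quality,
                    "kernel_width": expl.kernel_width,
                    "n_perturbations": expl.n_perturbations,
                    "seed": expl.seed,
                },
                fh, indent=2,
            )

    explain()
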