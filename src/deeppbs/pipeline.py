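"""End-to-end driver: simulate -> preprocess/impute -> train -> evaluate ->
baselines, with a manifest that records seeds, configs, and content hashes
so any stage can be re-executed bit-identically from its predecessor's
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .evaluation import DNNConfig, crib2_alert_rule, compute_metrics, dnn_baseline
from .imputation import ImputationMethod, make_imputer
from .model import DeepPBSMonitor, ModelConfig, save_checkpoint
from .preprocessing import SegmentedSample, preprocess_cohort
from .synthetic_cohort import SyntheticSpec, generate_cohort, write_cohort
from .training import TrainConfig, train_model

__all__ = ["RunConfig", "run_pipeline", "save_samples", "load_samples"]


@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    imputation: str = "bayesian_ridge"
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    dnn: DNNConfig = field(default_factory=DNNConfig)
    threshold: float = 0.5
    seed: int = 0
    run_baselines: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw: dict = {}
        if "synthetic" in d:
            kw["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "model" in d:
            kw["model"] = ModelConfig(**d["model"])
        if "train" in d:
            kw["train"] = TrainConfig(**d["train"])
        if "dnn" in d:
            kw["dnn"] = DNNConfig(**{k: tuple(v) if k == "hidden_sizes" else v
                                     for k, v in d["dnn"].items()})
        for k in ("imputation", "threshold", "seed", "run_baselines"):
            if k in d:
                kw[k] = d[k]
        cfg = cls(**kw)
        ImputationMethod(cfg.imputation)  # validate early
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_samples(samples: list[SegmentedSample], out_dir: str | Path) -> None:
    """One array container for all samples plus a JSON id/label sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "samples.npz",
        X=np.stack([s.X for s in samples]).astype(np.float32),
        pad_mask=np.stack([s.pad_mask for s in samples]),
        labels=np.stack([s.labels for s in samples]),
        turning_point=np.array([s.turning_point for s in samples]),
        end_times=np.stack([s.segment_end_times for s in samples]),
        G=np.stack([s.global_features for s in samples]),
    )
    (out_dir / "samples.json").write_text(json.dumps({
        "infant_ids": [s.infant_id for s in samples],
        "S": int(samples[0].X.shape[0]), "n_v": int(samples[0].X.shape[1]),
    }, indent=2))


def load_samples(in_dir: str | Path) -> list[SegmentedSample]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "samples.json").read_text())
    with np.load(in_dir / "samples.npz") as z:
        return [SegmentedSample(
            infant_id=iid, X=z["X"][i].astype(np.float64),
            pad_mask=z["pad_mask"][i], labels=z["labels"][i],
            turning_point=int(z["turning_point"][i]),
            segment_end_times=z["end_times"][i],
            global_features=z["G"][i],
        ) for i, iid in enumerate(meta["infant_ids"])]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}

    def record(stage: str, directory: Path, **extra) -> None:
        files = sorted(p for p in directory.rglob("*") if p.is_file())
        manifest["stages"][stage] = dict(
            path=str(directory.relative_to(out_dir)),
            files={str(p.relative_to(directory)): _sha256(p) for p in files},
            **extra)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # 1. simulate
        cohort_dir = out_dir / "cohort"
        spec = config.synthetic
        recordings, clinical = generate_cohort(spec)
        write_cohort(recordings, clinical, cohort_dir)
        record("simulate", cohort_dir, spec=asdict(spec))

        # 2. preprocess + impute
        samples_dir = out_dir / "samples"
        method = ImputationMethod(config.imputation, seed=config.seed)
        samples = preprocess_cohort(
            recordings, clinical, imputer=make_imputer(method),
            target_hours=spec.recording_hours)
        save_samples(samples, samples_dir)
        record("preprocess", samples_dir, imputation=config.imputation)

        # 3. train
        run_dir = out_dir / "train"
        run_dir.mkdir(exist_ok=True)
        folds = train_model(samples, config.train, config.model)
        import csv as _csv
        for fr in folds:
            fold_dir = run_dir / f"fold{fr.fold_index}"
            fold_dir.mkdir(exist_ok=True)
            model = DeepPBSMonitor(config.model, seed=0)
            model.load_parameter_arrays(fr.best_params)
            model.bn_state = fr.bn_state
            save_checkpoint(model, fold_dir / "checkpoint.npz")
            np.savez(fold_dir / "standardizer.npz",
                     x_mean=fr.standardizer.x_mean, x_std=fr.standardizer.x_std,
                     g_mean=fr.standardizer.g_mean, g_std=fr.standardizer.g_std)
            (fold_dir / "best_metrics.json").write_text(
                json.dumps(fr.best_metrics, indent=2))
            (fold_dir / "details.json").write_text(json.dumps(
                {k: fr.best_details[k]
                 for k in ("infant_id", "selected_tp", "true_tp")}, indent=2))
            np.savez(fold_dir / "trajectories.npz",
                     **fr.best_details["trajectories"])
            if fr.history:
                with open(fold_dir / "log.csv", "w", newline="") as fh:
                    keys = sorted({k for rec in fr.history for k in rec})
                    w = _csv.DictWriter(fh, fieldnames=keys)
                    w.writeheader()
                    w.writerows(fr.history)
        record("train", run_dir, config=asdict(config.train))

        # 4. evaluate
        eval_dir = out_dir / "evaluate"
        eval_dir.mkdir(exist_ok=True)
        by_id = {s.infant_id: s for s in samples}
        pooled_scores, pooled_labels = [], []
        fold_rows = []
        for fr in folds:
            fold_scores, fold_labels = [], []
            for iid in fr.best_details["infant_id"]:
                s = by_id[iid]
                keep = ~s.pad_mask
                fold_scores.append(fr.best_details["trajectories"][iid][keep])
                fold_labels.append(s.labels[keep])
            pooled_scores.append(np.concatenate(fold_scores))
            pooled_labels.append(np.concatenate(fold_labels))
            fold_rows.append(dict(fr.best_metrics, fold=fr.fold_index))
        rep = compute_metrics(np.concatenate(pooled_scores),
                              np.concatenate(pooled_labels),
                              threshold=config.threshold)
        summary = {
            "per_fold": fold_rows,
            "pooled": {"accuracy": rep.accuracy, "recall": rep.recall,
                       "auc": rep.auc,
                       "accuracy_times_recall": rep.accuracy_times_recall,
                       "confusion": {"TP": rep.tp, "FN": rep.fn,
                                     "FP": rep.fp, "TN": rep.tn}},
        }
        (eval_dir / "metrics.json").write_text(json.dumps(summary, indent=2))
        record("evaluate", eval_dir, threshold=config.threshold)

        # 5. baselines
        if config.run_baselines:
            base_dir = out_dir / "baselines"
            base_dir.mkdir(exist_ok=True)
            scored = [c for c in clinical if c.crib2_score is not None]
            alerts = crib2_alert_rule([c.crib2_score for c in scored])
            died = np.array([c.died for c in scored])
            crib_rep = compute_metrics(alerts.astype(float), died.astype(int))
            from sklearn.metrics import roc_auc_score
            raw_auc = float(roc_auc_score(
                died, [c.crib2_score for c in scored])) \
                if died.any() and not died.all() else None
            _, dnn_rep, _ = dnn_baseline(samples, config.dnn, seed=config.seed,
                                         folds=config.train.folds)
            (base_dir / "baselines.json").write_text(json.dumps({
                "crib2": {"accuracy": crib_rep.accuracy,
                          "recall": crib_rep.recall,
                          "auc_binary_rule": crib_rep.auc,
                          "auc_raw_score": raw_auc,
                          "n_scored": len(scored)},
                "dnn": {"accuracy": dnn_rep.accuracy, "recall": dnn_rep.recall,
                        "auc": dnn_rep.auc,
                        "accuracy_times_recall": dnn_rep.accuracy_times_recall},
            }, indent=2))
            record("baselines", base_dir)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    return manifest
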