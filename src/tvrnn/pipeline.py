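"""End-to-end orchestration: cross-validated training runs, checkpoints,
run manifests, and the model-comparison summary (Final Accuracy / EDT /
AUAC per model)."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import _transformer as _tf  # noqa: F401  (checkpoint round-trip)
from .data import TrialSet, ValidationError, read_trials
from .metrics import auac, earliest_decoding_time, temporal_accuracy
from .models import RNNParams, TVWeights, rnn_forward, tvrnn_forward
from .simulate import ChirpSpec, generate_chirp_trials
from .training import (
    TrainConfig,
    train_model,
    train_sliding_baselines,
)

MODEL_KINDS = (
    "rnn_s1", "rnn_s2", "tvrnn", "transformer",
    "sliding_rnn_s1", "sliding_rnn_s2", "sliding_svm",
)

PRESETS = {
    # 300-point trials sampled at 30 Hz, weight switch every second
    "wfci-like": {"hidden_size": 64, "epochs": 1000, "learning_rate": 1e-4,
                  "batch_size": 64, "window_size": 30, "n_folds": 5,
                  "validation_rate": 0.2},
    # 12-point trials, weight switch every 2 points
    "fmri-like": {"hidden_size": 64, "epochs": 1000, "learning_rate": 1e-4,
                  "batch_size": 64, "window_size": 2, "n_folds": 5,
                  "validation_rate": 0.2},
}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path, meta: dict | None = None) -> Path:
    """One NPZ archive of all parameter arrays + a JSON sidecar."""
    path = Path(path)
    meta = dict(meta or {})
    if isinstance(model, RNNParams):
        arrays = {"W_x": model.W_x, "W_h": model.W_h, "W_y": model.W_y,
                  "b_h": model.b_h, "b_y": np.array([model.b_y])}
        meta.update(kind="rnn", N=model.n_hidden, R=model.n_channels)
    elif isinstance(model, TVWeights):
        arrays = {}
        for k, w in enumerate(model.windows):
            arrays.update({f"W_x@{k}": w.W_x, f"W_h@{k}": w.W_h, f"W_y@{k}": w.W_y,
                           f"b_h@{k}": w.b_h, f"b_y@{k}": np.array([w.b_y])})
        meta.update(kind="tvrnn", w=model.window_size, T=model.T,
                    N=model.n_hidden, R=model.n_channels,
                    n_windows=model.n_windows)
    elif isinstance(model, dict):
        arrays = dict(model)
        meta.update(kind="transformer")
    else:
        raise ValidationError(f"cannot checkpoint {type(model).__name__}")
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
    return path


def load_checkpoint(path: str | Path):
    """Rebuild the model object saved by :func:`save_checkpoint`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as f:
        arrays = {k: f[k] for k in f.files}
    kind = meta["kind"]
    if kind == "rnn":
        return RNNParams(arrays["W_x"], arrays["W_h"], arrays["W_y"],
                         arrays["b_h"], float(arrays["b_y"][0])), meta
    if kind == "tvrnn":
        windows = [
            RNNParams(arrays[f"W_x@{k}"], arrays[f"W_h@{k}"], arrays[f"W_y@{k}"],
                      arrays[f"b_h@{k}"], float(arrays[f"b_y@{k}"][0]))
            for k in range(meta["n_windows"])
        ]
        return TVWeights(windows, meta["w"], meta["T"]), meta
    if kind == "transformer":
        return arrays, meta
    raise ValidationError(f"unknown checkpoint kind {kind!r}")


# ---------------------------------------------------------------------------
# cross-validated fit of one model kind
# ---------------------------------------------------------------------------

def _forward_any(model, X):
    if isinstance(model, RNNParams):
        return rnn_forward(model, X, return_hidden=False).y
    if isinstance(model, TVWeights):
        return tvrnn_forward(model, X, return_hidden=False).y
    if isinstance(model, dict):
        return _tf.transformer_forward(model, X)[0]
    return model.predict_proba_trajectory(X)  # sliding baseline


def fit_cv(kind: str, trials: TrialSet, split, settings: dict, seed: int = 0):
    """Train one model kind on every fold; returns per-fold models, test
    probabilities and test labels."""
    if kind not in MODEL_KINDS:
        raise ValidationError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    strategy = {"rnn_s1": "s1", "rnn_s2": "s2", "tvrnn": "tv",
                "transformer": "transformer"}.get(kind)
    models, probas, labels, traces = [], [], [], []
    for i, fold in enumerate(split.folds):
        if strategy is not None:
            cfg = TrainConfig(
                strategy=strategy,
                epochs=settings.get("epochs", 1000),
                learning_rate=settings.get("learning_rate", 1e-4),
                batch_size=settings.get("batch_size", 64),
                seed=seed + i,
                hidden_size=settings.get("hidden_size", 64),
                window_size=settings.get("window_size", 30),
                warm_start=settings.get("warm_start", False),
                d_model=settings.get("d_model", 64),
                n_layers=settings.get("n_layers", 2),
                n_heads=settings.get("n_heads", 4),
                d_ff=settings.get("d_ff", 128),
                dropout=settings.get("dropout", 0.1),
            )
            res = train_model(cfg, trials, train_idx=fold["train"], val_idx=fold["val"])
            model = res.params
            traces.append(res.trace)
        else:
            sliding_kind = {"sliding_rnn_s1": "independent_rnn_s1",
                            "sliding_rnn_s2": "independent_rnn_s2",
                            "sliding_svm": "svm"}[kind]
            cfg = TrainConfig(
                epochs=settings.get("epochs", 200),
                learning_rate=settings.get("learning_rate", 1e-4),
                batch_size=settings.get("batch_size", 64),
                seed=seed + i,
                hidden_size=settings.get("hidden_size", 32),
            )
            model = train_sliding_baselines(
                sliding_kind, trials, train_idx=fold["train"], val_idx=fold["val"],
                window_len=settings.get("window_size", 30), config=cfg,
                svm_kernel=settings.get("svm_kernel", "rbf"),
            )
            traces.append(None)
        models.append(model)
        probas.append(_forward_any(model, trials.data[fold["test"]]))
        labels.append(trials.labels[fold["test"]])
    return models, probas, labels, traces


def evaluate_cv(trials: TrialSet, probas, labels) -> dict:
    """Temporal accuracy + summary numbers from per-fold test predictions."""
    curve = temporal_accuracy(
        probas, labels, time_axis_seconds=trials.time_seconds
    )
    edr = earliest_decoding_time(curve, t_zero_index=trials.t_zero_index)
    return {
        "curve": curve,
        "edr": edr,
        "final_accuracy": float(curve.accuracy[trials.t_zero_index]),
        "edt_seconds": edr.edt_seconds,
        "edt_index": edr.edt_index,
        "auac": auac(curve),
    }


# ---------------------------------------------------------------------------
# run directory
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunManifest:
    config: dict
    seed: int
    data_checksum: str
    version: str
    created: str
    artifacts: dict = dataclasses.field(default_factory=dict)
    status: str = "complete"
    failed_stage: str | None = None

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


def data_checksum(trials: TrialSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(trials.data).tobytes())
    h.update(np.ascontiguousarray(trials.labels).tobytes())
    return h.hexdigest()


def _load_or_simulate(config: dict, seed: int) -> TrialSet:
    data_cfg = dict(config.get("data", {}))
    path = data_cfg.pop("path", None)
    if path:
        return read_trials(path)
    data_cfg.setdefault("seed", seed)
    return generate_chirp_trials(ChirpSpec(**data_cfg))


def run_experiment(config: dict, out_dir: str | Path, seed: int | None = None) -> pd.DataFrame:
    """Full pipeline on one dataset: simulate/load, CV-train every requested
    model, evaluate, and write the comparison table.

    ``config`` keys: ``data`` (ChirpSpec fields or ``{"path": ...}``),
    ``models`` (list of kinds), ``train`` (settings or ``{"preset": name}``),
    ``seed``.  Returns the comparison DataFrame (one row per model with
    Final Accuracy, EDT, AUAC); artifacts land in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    kinds = list(config.get("models", ["rnn_s1", "rnn_s2", "tvrnn", "transformer"]))
    for k in kinds:
        if k not in MODEL_KINDS:
            raise ValidationError(f"unknown model kind {k!r}; choose from {MODEL_KINDS}")
    settings = dict(config.get("train", {}))
    preset = settings.pop("preset", None)
    if preset:
        merged = dict(PRESETS[preset])
        merged.update(settings)
        settings = merged

    from .training import make_cv_splits  # local import avoids cycle at module load

    trials = _load_or_simulate(config, seed)
    manifest = RunManifest(
        config=config, seed=seed, data_checksum=data_checksum(trials),
        version=__version__, created=datetime.datetime.now().isoformat(),
    )
    rows = []
    try:
        split = make_cv_splits(
            trials.labels, n_folds=settings.get("n_folds", 5),
            validation_rate=settings.get("validation_rate", 0.2), seed=seed,
        )
        folds_json = out_dir / "folds.json"
        folds_json.write_text(json.dumps(
            [{k: v.tolist() for k, v in f.items()} for f in split.folds], indent=2))
        manifest.artifacts["folds"] = folds_json.name
        (out_dir / "time_axis.json").write_text(json.dumps({
            "time_seconds": trials.time_seconds.tolist(),
            "t_zero_index": int(trials.t_zero_index),
            "sampling_rate": trials.sampling_rate,
        }))
        np.savez(out_dir / "labels.npz",
                 **{f"fold{i}": trials.labels[f["test"]] for i, f in enumerate(split.folds)})
        for kind in kinds:
            manifest.failed_stage = f"train:{kind}"
            models, probas, labels, traces = fit_cv(kind, trials, split, settings, seed)
            kind_dir = out_dir / kind
            kind_dir.mkdir(exist_ok=True)
            for i, m in enumerate(models):
                if kind.startswith("sliding"):
                    continue  # per-window baseline lists are not checkpointed
                save_checkpoint(m, kind_dir / f"fold{i}.npz",
                                {"model": kind, "fold": i, "seed": seed + i,
                                 "strategy": kind, "train": settings})
            np.savez(kind_dir / "test_proba.npz",
                     **{f"fold{i}": p for i, p in enumerate(probas)})
            for i, tr in enumerate(traces):
                if tr is not None and tr.epochs:
                    pd.DataFrame({
                        "epoch": tr.epochs, "train_loss": tr.train_loss,
                        "val_loss": tr.val_loss, "grad_example": tr.grad_example,
                        "n_vanishing": tr.n_vanishing, "n_exploding": tr.n_exploding,
                    }).to_csv(kind_dir / f"gradient_trace_fold{i}.csv", index=False)
            ev = evaluate_cv(trials, probas, labels)
            pd.DataFrame({
                "time_s": ev["curve"].time_axis_seconds,
                "accuracy": ev["curve"].accuracy,
                "p_value": ev["edr"].p_values,
                "significant": ev["edr"].significant,
            }).to_csv(kind_dir / "temporal_accuracy.csv", index=False)
            rows.append({"Model": kind,
                         "Final Accuracy": ev["final_accuracy"],
                         "EDT": ev["edt_seconds"],
                         "AUAC": ev["auac"]})
        manifest.failed_stage = None
    except Exception:
        manifest.status = "failed"
        manifest.write(out_dir)
        raise
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "comparison.csv", index=False)
    (out_dir / "summary.json").write_text(
        table.to_json(orient="records", double_precision=10))
    manifest.artifacts.update(comparison="comparison.csv", summary="summary.json")
    manifest.write(out_dir)
    return table
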