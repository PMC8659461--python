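"""End-to-end experiment orchestration.

``run_experiment`` wires the stages together — simulate a two-class study,
derive the degraded "camera" channel, (optionally) render and re-extract a
small vision-leg subset, segment events, build feature tables, cross-validate
the model bank, and write the evaluation artifacts: a metric grid in the
study's report layout (model rows x channels), an optional window-size grid,
cumulative-percentage and correlation comparisons between channels, and
significance-test JSON.  A manifest records every derived seed and parameter
so the classical pipeline is reproducible from the manifest alone.
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

from . import synthetic
from .classifiers import ALGORITHMS, CVScheme, ModelConfig, cross_validate
from .events import compute_velocity, segment_events
from .evaluation import (
    confusion_from_predictions,
    cumulative_percentage,
    delong_test,
    feature_correlations,
    metrics_from_counts,
    roc_auc,
    wilcoxon_signed_rank,
)
from .features import WindowSpec, build_feature_table
from .synthetic import FrameRenderSpec, GazeSimSpec
from .trace import LabeledSegment

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "stage_seed",
    "config_from_manifest",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class ExperimentConfig:
    sim: GazeSimSpec = field(default_factory=GazeSimSpec)
    camera_noise_sd: float = 2.0
    camera_dropout: float = 0.02
    velocity_threshold: float | None = None  # None -> per-recording Otsu
    min_fixation: float = 0.1
    min_saccade: float = 0.02
    window: WindowSpec = field(default_factory=WindowSpec)
    models: tuple[str, ...] = ALGORITHMS
    cv: CVScheme = field(default_factory=CVScheme)
    include_deep: bool = True
    include_window_study: bool = False
    deep_target_len: int = 120  # decimated window length for CPU-scale nets
    deep_lstm_target_len: int = 60  # shorter still: BPTT cost grows with S
    deep_epochs: int = 15
    cump_threshold_pct: float = 15.0
    vision_leg: bool = False
    vision_frames: int = 100
    render: FrameRenderSpec = field(default_factory=FrameRenderSpec)
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)


def _segment_channel(segments, config, stage: str):
    """Velocity + I-VT events for every segment of one channel."""
    out = []
    for seg in segments:
        vel = compute_velocity(seg.trace)
        out.append(
            segment_events(
                vel,
                threshold=config.velocity_threshold,
                min_fixation=config.min_fixation,
                min_saccade=config.min_saccade,
            )
        )
    return out


def _classify_all(table: pd.DataFrame, config: ExperimentConfig, channel: str):
    """Classical + deep predictions for one channel's feature table / segments."""
    preds = {}
    for name in config.models:
        model = ModelConfig(algorithm=name, seed=config.stage_seed(f"model:{name}"))
        preds[name] = cross_validate(table, model, config.cv)
    return preds


def _deep_predictions(segments, config: ExperimentConfig):
    from .deep import (
        AEConfig,
        CNNConfig,
        LSTMConfig,
        ae_svm_hybrid,
        cnn_svm_hybrid,
        prepare_raw_windows,
        train_cnn,
        train_lstm,
    )

    data = prepare_raw_windows(
        segments,
        fs=config.sim.fs,
        window_s=config.window.length,
        target_len=config.deep_target_len,
    )
    flat = prepare_raw_windows(
        segments,
        fs=config.sim.fs,
        window_s=config.window.length,
        flatten=True,
        target_len=config.deep_target_len,
    )
    preds = {}
    cnn_cfg = CNNConfig(epochs=config.deep_epochs, seed=config.stage_seed("cnn"))
    cnn, preds["cnn"] = train_cnn(data.X, data.y, cnn_cfg, config.cv)
    preds["cnn_svm"] = cnn_svm_hybrid(cnn, data.X, data.y, config.cv)
    lstm_data = prepare_raw_windows(
        segments,
        fs=config.sim.fs,
        window_s=config.window.length,
        target_len=config.deep_lstm_target_len,
    )
    lstm_cfg = LSTMConfig(
        hidden_units=32, epochs=config.deep_epochs, seed=config.stage_seed("lstm")
    )
    _, preds["lstm"] = train_lstm(lstm_data.X, lstm_data.y, lstm_cfg, config.cv)
    ae_cfg = AEConfig(seed=config.stage_seed("ae"))
    preds["ae_svm"] = ae_svm_hybrid(flat.X, flat.y, ae_cfg, config.cv)
    return preds


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Run the full experiment and write a report bundle to ``outdir``.

    Returns a summary dict (paths and headline numbers).  Any stage error
    is re-raised annotated with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"outdir": str(outdir)}
    stage = "simulate"
    try:
        sim = dataclasses.replace(config.sim, seed=config.stage_seed("simulate"))
        segments = synthetic.simulate_study(sim)

        stage = "degrade"
        camera_segments = [
            LabeledSegment(
                synthetic.degrade_trace(
                    s.trace,
                    config.camera_noise_sd,
                    config.camera_dropout,
                    seed=config.stage_seed(f"degrade:{s.subject_id}:{s.segment_id}"),
                ),
                s.label,
                s.subject_id,
                s.segment_id,
            )
            for s in segments
        ]
        channels = {"eyeT": segments, "camera": camera_segments}

        stage = "segment"
        events_by_channel = {
            ch: _segment_channel(segs, config, ch) for ch, segs in channels.items()
        }

        stage = "featurize"
        labels = [s.label for s in segments]
        subject_ids = [s.subject_id for s in segments]
        tables = {}
        for ch, seg_events in events_by_channel.items():
            tables[ch] = build_feature_table(
                seg_events,
                config.window,
                labels,
                subject_ids,
                segment_duration=config.sim.segment_duration,
            )
            tables[ch].to_csv(outdir / f"features_{ch}.csv", index=False)

        stage = "classify"
        preds_by_channel = {}
        for ch, table in tables.items():
            preds_by_channel[ch] = _classify_all(table, config, ch)
        if config.include_deep:
            for ch, segs in channels.items():
                preds_by_channel[ch].update(_deep_predictions(segs, config))
        for ch, model_preds in preds_by_channel.items():
            for name, p in model_preds.items():
                p.to_frame().to_csv(outdir / f"preds_{ch}_{name}.csv", index=False)

        stage = "evaluate"
        rows = []
        for ch, model_preds in preds_by_channel.items():
            for name, p in model_preds.items():
                c = confusion_from_predictions(p)
                m = metrics_from_counts(c).rounded()
                rows.append(
                    {
                        "channel": ch,
                        "model": name,
                        "TP": c.tp,
                        "FN": c.fn,
                        "FP": c.fp,
                        "TN": c.tn,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "precision": m.precision,
                        "f1": m.f1,
                        "accuracy": m.accuracy,
                        "auc": roc_auc(p.y_true, p.score).auc,
                    }
                )
        metric_grid = pd.DataFrame(rows)
        metric_grid.to_csv(outdir / "metric_grid.csv", index=False)
        summary["metric_grid"] = str(outdir / "metric_grid.csv")

        if config.include_window_study:
            from .classifiers import compare_window_sizes

            grid = compare_window_sizes(
                events_by_channel,
                labels,
                subject_ids,
                config.sim.segment_duration,
                seed=config.stage_seed("window_study"),
            )
            grid.to_csv(outdir / "window_grid.csv", index=False)
            summary["window_grid"] = str(outdir / "window_grid.csv")

        # channel agreement: cumP on raw co-registered samples + feature correlations
        cump_rows = []
        for s, c in zip(segments, camera_segments):
            ok = s.trace.valid & c.trace.valid
            for axis in ("x", "y"):
                ref = getattr(s.trace, axis)[ok]
                tst = getattr(c.trace, axis)[ok]
                res = cumulative_percentage(ref, tst, config.cump_threshold_pct)
                cump_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "segment_id": s.segment_id,
                        "axis": axis,
                        "final_cump": res.final,
                    }
                )
        cump = pd.DataFrame(cump_rows)
        cump.to_csv(outdir / "cump.csv", index=False)
        summary["mean_final_cump"] = float(cump["final_cump"].mean())

        corr = feature_correlations(tables["eyeT"], tables["camera"])
        corr.to_csv(outdir / "feature_correlations.csv", index=False)
        summary["min_feature_r"] = float(corr["r"].min())

        sig: dict = {}
        best = {
            ch: max(mp, key=lambda k: roc_auc(mp[k].y_true, mp[k].score).auc)
            for ch, mp in preds_by_channel.items()
        }
        for ch, model_preds in preds_by_channel.items():
            sig[ch] = {}
            for name, p in model_preds.items():
                w = wilcoxon_signed_rank(p.y_true, p.y_pred)
                entry = {"wilcoxon": w.to_dict()}
                if name != best[ch]:
                    d = delong_test(model_preds[best[ch]], p)
                    entry["delong_vs_best"] = d.to_dict()
                sig[ch][name] = entry
        with open(outdir / "significance.json", "w") as fh:
            json.dump(sig, fh, indent=2)

        if config.vision_leg:
            stage = "vision"
            summary["vision_leg"] = _run_vision_leg(segments[0], config, outdir)

        stage = "manifest"
        manifest = {
            "master_seed": config.master_seed,
            "stage_seeds": {
                s: config.stage_seed(s) for s in ("simulate", "window_study")
            },
            "config": _config_dict(config),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        summary["manifest"] = str(outdir / "manifest.json")
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc
    return summary


def _run_vision_leg(segment, config: ExperimentConfig, outdir: Path) -> dict:
    """Render a short subset and verify the vision stage recovers the trace."""
    from .vision import extract_pupil_positions

    n = min(config.vision_frames, len(segment.trace))
    sub = segment.trace.copy()
    sub.t, sub.x, sub.y, sub.valid = (
        sub.t[:n],
        sub.x[:n],
        sub.y[:n],
        sub.valid[:n],
    )
    mapped = synthetic.map_trace_to_frame(sub, config.render)
    frames, centers = synthetic.render_frames(mapped, config.render)
    rec = extract_pupil_positions(frames, fps=config.sim.fs)
    ok = rec.valid
    mae = float(
        np.mean(np.hypot(rec.x[ok] - centers[ok, 0], rec.y[ok] - centers[ok, 1]))
    )
    return {"frames": int(n), "recovered_fraction": float(ok.mean()), "mae_px": mae}


def config_from_manifest(path) -> ExperimentConfig:
    """Rebuild an :class:`ExperimentConfig` from a written manifest, so the
    classical pipeline can be reproduced from the manifest alone."""
    with open(path) as fh:
        manifest = json.load(fh)
    cfg = dict(manifest["config"])
    sim = dict(cfg.pop("sim"))
    sim["class0"] = synthetic.ClassParams(**sim["class0"])
    sim["class1"] = synthetic.ClassParams(**sim["class1"])
    cfg["sim"] = GazeSimSpec(**sim)
    cfg["window"] = WindowSpec(**cfg.pop("window"))
    cfg["cv"] = CVScheme(**cfg.pop("cv"))
    cfg["render"] = FrameRenderSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.pop("render").items()
        }
    )
    cfg["models"] = tuple(cfg["models"])
    return ExperimentConfig(**cfg)


def _config_dict(config: ExperimentConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    return enc(config)
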