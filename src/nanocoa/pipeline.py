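"""End-to-end orchestration: simulate -> detect -> train -> classify -> quantify.

Every stage writes its outputs plus a provenance manifest (config hash,
seed, output checksums) into the run directory, so a run is regenerable
from its manifest alone and reruns with identical configuration produce
identical event tables.
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

from . import classify as clf
from . import io as nio
from . import quantify as qt
from . import sigproc as sp
from .simulate import (
    DEFAULT_CLASSES,
    ClassParams,
    SimulationConfig,
    annotations_to_frame,
    simulate_trace,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "detect", "train", "classify", "quantify")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the workflow's
    standard acquisition and training settings."""

    outdir: str = "nanocoa_run"
    seed: int = 0
    # acquisition / simulation
    sampling_rate: float = 500e3  # Hz
    acquisition_filter: float = 100e3  # Hz
    open_pore_current: float = 580.0  # pA
    baseline_noise_sd: float = 30.0  # pA
    voltage: float = 120.0  # mV
    train_trace_duration: float = 10.0  # s per monodisperse training trace
    train_traces_per_class: int = 2
    mixture_trace_duration: float = 10.0  # s
    # name -> ClassParams kwargs; defaults to the calibrated class set at 10 uM
    classes: dict = field(
        default_factory=lambda: {
            name: dataclasses.asdict(params) for name, params in DEFAULT_CLASSES.items()
        }
    )
    # mixture trace composition (name -> uM); empty dict disables the sample trace
    mixture_concentrations: dict = field(
        default_factory=lambda: {"cA3/4": 5.0, "cA5": 5.0, "cA6": 5.0}
    )
    # signal processing
    filter_cutoff: float = 80e3  # Hz, digital low-pass before decimation
    decimate_to: float = 80e3  # Hz
    threshold_frac: float = 0.65
    min_event_samples: int = 2
    flank: int = 47
    width: int = 250
    # training
    epochs: int = 100
    learning_rate: float = 1e-3
    restarts: int = 5
    batch_size: int = 32
    # quantification
    dilution: float = 1.0
    complex_concentration: float = 0.0625  # uM

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def class_params(self) -> dict[str, ClassParams]:
        return {name: ClassParams(**kw) for name, kw in self.classes.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _update_manifest(outdir: Path, config: RunConfig, stage: str, outputs: list[Path]) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    manifest["stages"][stage] = {
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs}
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, stage_needed: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing upstream artifact {path.name!r}; run the {stage_needed!r} stage first"
        )
    return path


def _seed_for(config: RunConfig, stage: str, index: int = 0) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _process_trace(trace, config: RunConfig):
    """filter -> decimate -> open-pore estimate -> threshold detection."""
    filtered = sp.lowpass_filter(trace, config.filter_cutoff)
    decimated = sp.decimate_median(filtered, config.decimate_to)
    open_pore = sp.estimate_open_pore(decimated)
    events = sp.detect_events(
        decimated, open_pore,
        threshold_frac=config.threshold_frac,
        min_event_samples=config.min_event_samples,
    )
    return decimated, open_pore, events


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages; returns a dict of in-memory artifacts."""
    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {ALL_STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "traces").mkdir(exist_ok=True)
    artifacts: dict = {}

    if "simulate" in stages:
        outputs = []
        params = config.class_params()
        idx = 0
        for name in sorted(params):
            for i in range(config.train_traces_per_class):
                cfg = SimulationConfig(
                    classes={name: params[name]},
                    sampling_rate=config.sampling_rate,
                    duration=config.train_trace_duration,
                    open_pore_current=config.open_pore_current,
                    baseline_noise_sd=config.baseline_noise_sd,
                    voltage=config.voltage,
                    filter_cutoff=config.acquisition_filter,
                    seed=_seed_for(config, "simulate", idx),
                    metadata={"analyte": name, "role": "train"},
                )
                trace, ann = simulate_trace(cfg)
                trace.trace_id = f"train_{idx:03d}"
                path = outdir / "traces" / f"{trace.trace_id}.h5"
                nio.write_trace(path, trace)
                ann_path = outdir / "traces" / f"{trace.trace_id}.annotations.tsv"
                annotations_to_frame(ann).to_csv(ann_path, sep="\t", index=False)
                outputs += [path, ann_path]
                idx += 1
        if config.mixture_concentrations:
            mix_classes = {
                name: dataclasses.replace(params[name], concentration=conc)
                for name, conc in config.mixture_concentrations.items()
            }
            cfg = SimulationConfig(
                classes=mix_classes,
                sampling_rate=config.sampling_rate,
                duration=config.mixture_trace_duration,
                open_pore_current=config.open_pore_current,
                baseline_noise_sd=config.baseline_noise_sd,
                voltage=config.voltage,
                filter_cutoff=config.acquisition_filter,
                seed=_seed_for(config, "simulate-mixture"),
                metadata={"analyte": "mixture", "role": "sample"},
            )
            trace, ann = simulate_trace(cfg)
            trace.trace_id = "mixture_000"
            path = outdir / "traces" / "mixture_000.h5"
            nio.write_trace(path, trace)
            ann_path = outdir / "traces" / "mixture_000.annotations.tsv"
            annotations_to_frame(ann).to_csv(ann_path, sep="\t", index=False)
            outputs += [path, ann_path]
        _update_manifest(outdir, config, "simulate", outputs)

    if "detect" in stages:
        trace_files = sorted((outdir / "traces").glob("*.h5"))
        if not trace_files:
            raise PipelineError("missing upstream artifact 'traces/*.h5'; run the 'simulate' stage first")
        frames = []
        meta_rows = []
        for path in trace_files:
            trace = nio.read_trace(path)
            decimated, open_pore, events = _process_trace(trace, config)
            frame = nio.events_to_frame(events)
            frame["trace_id"] = trace.trace_id
            frames.append(frame)
            meta_rows.append(
                {
                    "trace_id": trace.trace_id,
                    "analyte": trace.metadata.get("analyte"),
                    "role": trace.metadata.get("role"),
                    "open_pore_pA": open_pore,
                    "duration_s": decimated.duration,
                    "n_events": len(events),
                }
            )
        events_path = outdir / "events.tsv"
        pd.concat(frames, ignore_index=True).to_csv(events_path, sep="\t", index=False)
        meta_path = outdir / "trace_summary.tsv"
        pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
        _update_manifest(outdir, config, "detect", [events_path, meta_path])

    if "train" in stages:
        events_path = _require(outdir / "events.tsv", "detect")
        meta = pd.read_csv(_require(outdir / "trace_summary.tsv", "detect"), sep="\t")
        events = pd.read_csv(events_path, sep="\t")
        analyte_of = dict(zip(meta.trace_id, meta.analyte))
        role_of = dict(zip(meta.trace_id, meta.role))
        train_events = events[[role_of.get(t) == "train" for t in events.trace_id]]
        class_order = tuple(sorted({analyte_of[t] for t in train_events.trace_id}))
        duration_stats = sp.log_duration_stats(train_events.duration_s.to_numpy())
        X, y = _tensorize(outdir, config, train_events, analyte_of, class_order, duration_stats)
        model = clf.build_classifier(len(class_order), input_width=config.width + 1)
        model, _log = clf.train(
            model, X, y,
            epochs=config.epochs, learning_rate=config.learning_rate,
            restarts=config.restarts, batch_size=config.batch_size,
            seed=_seed_for(config, "train"), class_names=class_order,
        )
        model_path = outdir / "model.npz"
        clf.save_model(model_path, model, class_order, duration_stats)
        _update_manifest(outdir, config, "train", [model_path])
        artifacts["model"] = model

    if "classify" in stages:
        model_path = _require(outdir / "model.npz", "train")
        events_path = _require(outdir / "events.tsv", "detect")
        meta = pd.read_csv(outdir / "trace_summary.tsv", sep="\t")
        model, manifest = clf.load_model(model_path)
        class_order = tuple(manifest["class_order"])
        duration_stats = tuple(manifest["duration_stats"])
        events = pd.read_csv(events_path, sep="\t")
        role_of = dict(zip(meta.trace_id, meta.role))
        sample_events = events[[role_of.get(t) == "sample" for t in events.trace_id]]
        if sample_events.empty:
            raise PipelineError("no sample-role events to classify; configure mixture_concentrations")
        X, kept = _tensorize_unlabeled(outdir, config, sample_events, duration_stats)
        probs = model.predict_proba(X)
        pred = pd.DataFrame(probs, columns=[f"p_{c}" for c in class_order])
        pred.insert(0, "predicted_class", [class_order[i] for i in probs.argmax(axis=1)])
        pred.insert(0, "event_id", kept.event_id.to_numpy())
        pred.insert(0, "trace_id", kept.trace_id.to_numpy())
        pred_path = outdir / "predictions.tsv"
        pred.to_csv(pred_path, sep="\t", index=False)
        _update_manifest(outdir, config, "classify", [pred_path])
        artifacts["predictions"] = pred

    if "quantify" in stages:
        pred_path = _require(outdir / "predictions.tsv", "classify")
        meta = pd.read_csv(_require(outdir / "trace_summary.tsv", "detect"), sep="\t")
        pred = pd.read_csv(pred_path, sep="\t")
        cfs = qt.CorrectionFactors(
            values={name: kw["correction_factor"] for name, kw in config.classes.items()}
        )
        sample_meta = meta[meta.role == "sample"]
        recording_time = float(sample_meta.duration_s.sum())
        counts = {c: int((pred.predicted_class == c).sum()) for c in cfs.values}
        composition = qt.estimate_composition(counts, recording_time, cfs)
        rows = [
            {"class": c, "fraction": composition.fractions[c], "count": counts[c]}
            for c in sorted(counts)
        ]
        comp_path = outdir / "composition.tsv"
        pd.DataFrame(rows).to_csv(comp_path, sep="\t", index=False)
        summary_path = outdir / "composition_summary.txt"
        lines = [f"total event rate r_e = {composition.event_rate:.4f} /s"]
        for r in rows:
            lines.append(f"{r['class']}: {100 * r['fraction']:.1f}% ({r['count']} events)")
        summary_path.write_text("\n".join(lines) + "\n")
        _update_manifest(outdir, config, "quantify", [comp_path, summary_path])
        artifacts["composition"] = composition

    return artifacts


def _tensorize(outdir, config, events_frame, analyte_of, class_order, duration_stats):
    class_index = {c: i for i, c in enumerate(class_order)}
    X_parts, y_parts = [], []
    for trace_id, sub in events_frame.groupby("trace_id"):
        trace = nio.read_trace(outdir / "traces" / f"{trace_id}.h5")
        decimated, _, _ = _process_trace(trace, config)
        evs = nio.frame_to_events(sub)
        X, kept, _ = sp.events_to_tensors(
            decimated, evs, flank=config.flank, width=config.width, duration_stats=duration_stats
        )
        X_parts.append(X)
        y_parts.append(np.full(len(kept), class_index[analyte_of[trace_id]]))
    return np.vstack(X_parts), np.concatenate(y_parts).astype(int)


def _tensorize_unlabeled(outdir, config, events_frame, duration_stats):
    X_parts, kept_rows = [], []
    for trace_id, sub in events_frame.groupby("trace_id"):
        trace = nio.read_trace(outdir / "traces" / f"{trace_id}.h5")
        decimated, _, _ = _process_trace(trace, config)
        evs = nio.frame_to_events(sub)
        for row, ev in zip(sub.itertuples(), evs):
            t = sp.to_event_tensor(
                decimated, ev, flank=config.flank, width=config.width, duration_stats=duration_stats
            )
            if t is not None:
                X_parts.append(t)
                kept_rows.append(row)
    return np.vstack(X_parts), pd.DataFrame(kept_rows)
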