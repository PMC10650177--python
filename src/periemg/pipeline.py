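"""End-to-end orchestration: simulate -> preprocess -> ICA -> features -> classify.

A :class:`PipelineConfig` (typically loaded from YAML) validates every
stage's parameters up front — unknown keys are rejected — and a single
global seed fans out to per-stage seeds through a documented derivation
(``SeedSequence([global_seed, stage_index])``), so each stage is
independently reproducible. :func:`run_pipeline` writes all intermediate
artifacts plus a manifest with SHA-256 hashes; re-running the same config
reproduces every hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .codec import Recording, write_recording
from .classify import SplitSpec, run_benchmark
from .features import extract_feature_matrix, slice_epochs
from .preprocess import PreprocessConfig, preprocess_chain
from .simulate import (
    NoiseSpec,
    ProtocolSpec,
    build_mixing_matrix,
    default_geometry,
    simulate_session,
    write_labels,
)
from .unmix import fit_ica

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
    "load_config",
]

STAGES = ("simulate", "preprocess", "ica", "features", "classify")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolBlock(_Strict):
    reps_per_block: int = 5
    blocks: int = 3
    action_duration_s: float = 2.0
    rest_duration_s: float = 3.0
    interblock_rest_s: float = 30.0
    cue_duration_s: float = 2.0


class NoiseBlock(_Strict):
    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.2
    dc_offset: float = 0.5
    white_noise_sd: float = 0.05


class FilterBlock(_Strict):
    notch_freq: float = 50.0
    notch_quality: float = 30.0
    band_low: float = 20.0
    band_high: float = 350.0
    band_order: int = 4
    envelope_cutoff: float = 10.0
    envelope_order: int = 2
    zero_phase: bool = True


class IcaBlock(_Strict):
    n_components: int = 8
    max_iter: int = 200
    tol: float = 1e-4


class ClassifyBlock(_Strict):
    classifiers: list[str] = Field(default_factory=lambda: ["svm", "rf", "bpnn"])
    tasks: list[str] = Field(default_factory=lambda: ["five_class", "ten_class"])
    train_fraction: float = 0.8
    stratified: bool = True


class PipelineConfig(_Strict):
    """Validated parameters for every pipeline stage plus the global seed."""

    seed: int = 0
    rate: float = 1000.0
    amplitude_jitter_sd: float = 0.2
    protocol: ProtocolBlock = Field(default_factory=ProtocolBlock)
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    filters: FilterBlock = Field(default_factory=FilterBlock)
    ica: IcaBlock = Field(default_factory=IcaBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)

    def validate_cross_stage(self, n_channels: int = 16) -> None:
        if self.ica.n_components > n_channels:
            raise ValueError(
                f"ICA components ({self.ica.n_components}) cannot exceed "
                f"channel count ({n_channels})"
            )
        if self.filters.band_high >= self.rate / 2:
            raise ValueError("bandpass upper corner must be below Nyquist")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31)
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path, verbose: bool = False) -> Path:
    """Run all five stages, writing artifacts and a manifest to ``outdir``.

    Artifacts: recording.txt, labels.tsv, clean.txt, comps.txt, W.txt,
    features.tsv, report.json, manifest.json. Returns the run directory.
    """
    import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_mixing_matrix(default_geometry())
    config.validate_cross_stage(n_channels=model.n_electrodes)

    manifest: dict = {
        "periemg_version": __version__,
        "config": config.model_dump(),
        "stages": [],
        "artifacts": {},
    }

    def _log(msg: str) -> None:
        if verbose:
            print(msg)

    def _stage(name: str, started: float, outputs: dict[str, Path]) -> None:
        for key, path in outputs.items():
            manifest["artifacts"][key] = {
                "path": path.name,
                "sha256": _sha256(path),
            }
        manifest["stages"].append(
            {
                "name": name,
                "seed": stage_seed(config.seed, name),
                "elapsed_s": round(time.perf_counter() - started, 3),
                "outputs": sorted(outputs),
            }
        )
        _log(f"[{name}] done in {time.perf_counter() - started:.2f}s")

    # simulate
    t0 = time.perf_counter()
    protocol = ProtocolSpec(**config.protocol.model_dump())
    noise = NoiseSpec(
        **config.noise.model_dump(), seed=stage_seed(config.seed, "simulate") + 1
    )
    recording, epochs = simulate_session(
        protocol=protocol,
        model=model,
        noise=noise,
        rate=config.rate,
        seed=stage_seed(config.seed, "simulate"),
        amplitude_jitter_sd=config.amplitude_jitter_sd,
    )
    rec_path = outdir / "recording.txt"
    labels_path = outdir / "labels.tsv"
    write_recording(recording, rec_path)
    write_labels(epochs, labels_path)
    _stage("simulate", t0, {"recording": rec_path, "labels": labels_path})

    # preprocess
    t0 = time.perf_counter()
    clean = preprocess_chain(recording, PreprocessConfig(**config.filters.model_dump()))
    clean_path = outdir / "clean.txt"
    write_recording(clean, clean_path)
    _stage("preprocess", t0, {"clean": clean_path})

    # ica
    t0 = time.perf_counter()
    result = fit_ica(
        clean,
        n_components=config.ica.n_components,
        seed=stage_seed(config.seed, "ica"),
        max_iter=config.ica.max_iter,
        tol=config.ica.tol,
    )
    comps_path = outdir / "comps.txt"
    w_path = outdir / "W.txt"
    np.savetxt(comps_path, result.components.T, fmt="%.9e")
    np.savetxt(w_path, result.W, fmt="%.9e")
    _stage("ica", t0, {"components": comps_path, "w_matrix": w_path})

    # features
    t0 = time.perf_counter()
    blocks = slice_epochs(result.components, epochs)
    feature_df = extract_feature_matrix(blocks, config.rate, labels=epochs)
    features_path = outdir / "features.tsv"
    feature_df.to_csv(features_path, sep="\t", index=False)
    _stage("features", t0, {"features": features_path})

    # classify
    t0 = time.perf_counter()
    report: dict = {"metrics": [], "confusion_matrices": {}, "averaging": "macro"}
    spec = SplitSpec(
        train_fraction=config.classify.train_fraction,
        seed=stage_seed(config.seed, "classify"),
        stratified=config.classify.stratified,
    )
    for task in config.classify.tasks:
        table, task_reports = run_benchmark(
            feature_df,
            task=task,
            classifiers=config.classify.classifiers,
            spec=spec,
            seed=stage_seed(config.seed, "classify"),
        )
        report["metrics"].extend(table.to_dict(orient="records"))
        for name, rep in task_reports.items():
            report["confusion_matrices"][f"{task}/{name}"] = {
                "labels": list(rep.confusion.index),
                "matrix": rep.confusion.to_numpy().tolist(),
            }
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    _stage("classify", t0, {"report": report_path})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
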