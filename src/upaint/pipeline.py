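"""End-to-end runs: simulate -> prepare -> train -> predict -> evaluate.

A run is described by a single YAML/JSON config with nested stage sections;
every stochastic stage derives its own random stream from the global seed
and the stage name (SHA-256 of ``"{seed}:{stage}"``, reduced below 2^31), so
altering one stage's workload never perturbs another stage's stream.  Each
run writes a JSON manifest with content hashes of every emitted file, the
effective config, and the derived seeds, enabling exact replay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import metrics as mmod
from .errors import ConfigurationError, UPaintError
from .network import TrainConfig, UNet, UNetSpec, predict, save_checkpoint, train
from .prep import split_dataset
from .simulate import SimulationConfig, generate_dataset, save_triplets

__all__ = ["RunConfig", "validate_config", "run_pipeline", "stage_seed"]

log = logging.getLogger("upaint")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stage-decoupled seed: SHA-256 of '{seed}:{stage}', below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Top-level configuration for a reproducible pipeline run."""

    seed: int = 0
    output_root: str = "runs/demo"
    log_level: str = "INFO"
    n_sets: int = 20
    test_fraction: float = 0.15
    variant: str = "3000"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    unet: UNetSpec = field(default_factory=UNetSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    c1: float = mmod.DEFAULT_C1
    c2: float = mmod.DEFAULT_C2
    save_images: bool = False

    def __post_init__(self):
        if self.unet.tile_size != self.simulation.tile_size:
            raise ConfigurationError(
                f"unet.tile_size ({self.unet.tile_size}) must equal "
                f"simulation.tile_size ({self.simulation.tile_size})"
            )


_SECTION_TYPES = {
    "simulation": SimulationConfig,
    "unet": UNetSpec,
    "training": TrainConfig,
}


def validate_config(path: str) -> RunConfig:
    """Load and validate a YAML/JSON run config, reporting every problem at once."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    kwargs: dict = {}
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in top_fields:
            problems.append(f"unknown key {key!r}")
            continue
        if key in _SECTION_TYPES:
            cls = _SECTION_TYPES[key]
            sub_fields = {f.name for f in dataclasses.fields(cls)}
            bad = set(value) - sub_fields
            problems.extend(f"unknown key {key}.{k!r}" for k in sorted(bad))
            if not bad:
                try:
                    kwargs[key] = cls(**value)
                except UPaintError as exc:
                    problems.append(f"{key}: {exc}")
        else:
            kwargs[key] = value
    cfg = None
    if not problems:
        try:
            cfg = RunConfig(**kwargs)
        except UPaintError as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigurationError(
            "invalid run config:\n  " + "\n  ".join(problems)
        )
    return cfg


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage sequence and write a replayable manifest.

    Returns the manifest dict.  Any stage failure aborts with the stage name;
    the partial manifest (stages completed so far) is persisted first.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    root = config.output_root
    os.makedirs(root, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "seeds": {},
        "stages": {},
        "files": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    current_stage = "init"

    def record(path: str) -> None:
        manifest["files"][os.path.relpath(path, root)] = _hash_file(path)

    try:
        # --- simulate -------------------------------------------------
        current_stage = "simulate"
        seed = stage_seed(config.seed, current_stage)
        manifest["seeds"][current_stage] = seed
        sim_cfg = dataclasses.replace(config.simulation, seed=seed)
        log.info("simulate: %d triplet sets at tile %d", config.n_sets, sim_cfg.tile_size)
        triplets = generate_dataset(sim_cfg, config.n_sets)
        if config.save_images:
            save_triplets(triplets, os.path.join(root, "triplets"), sim_cfg)
            for f in sorted(os.listdir(os.path.join(root, "triplets"))):
                record(os.path.join(root, "triplets", f))
        manifest["stages"]["simulate"] = {"n_sets": len(triplets)}

        # --- prepare (split) ------------------------------------------
        current_stage = "prepare"
        seed = stage_seed(config.seed, current_stage)
        manifest["seeds"][current_stage] = seed
        train_set, test_set = split_dataset(
            triplets, config.test_fraction, np.random.default_rng(seed))
        manifest["stages"]["prepare"] = {"n_train": len(train_set),
                                         "n_test": len(test_set)}
        log.info("prepare: %d train / %d test", len(train_set), len(test_set))

        # --- train ----------------------------------------------------
        current_stage = "train"
        seed = stage_seed(config.seed, current_stage)
        manifest["seeds"][current_stage] = seed
        train_cfg = dataclasses.replace(config.training, seed=seed)
        model = UNet(config.unet, seed=seed)
        model, history = train(model, train_set, train_cfg, variant=config.variant)
        ckpt = os.path.join(root, "model.npz")
        save_checkpoint(model, ckpt, train_cfg)
        record(ckpt)
        hist_path = os.path.join(root, "loss_history.json")
        with open(hist_path, "w") as fh:
            json.dump(history, fh)
        record(hist_path)
        manifest["stages"]["train"] = {"epochs": train_cfg.epochs,
                                       "final_loss": history[-1]}
        log.info("train: %d epochs, final loss %.3g", train_cfg.epochs, history[-1])

        # --- predict + evaluate ---------------------------------------
        current_stage = "evaluate"
        rows = []
        model_reports, sparse_reports = [], []
        for i, t in enumerate(test_set):
            wf = t.widefield if config.unet.in_channels == 2 or config.variant == "WF" else None
            sp = None if config.variant == "WF" else t.sparse
            recon = predict(model, sparse_tile=sp, widefield_tile=wf)
            rep = mmod.evaluate_pair(t.dense, recon, config.c1, config.c2)
            base = mmod.evaluate_pair(t.dense, t.sparse, config.c1, config.c2)
            model_reports.append(rep)
            sparse_reports.append(base)
            rows.append({"tile": t.source_id, "psnr": rep.psnr, "rmse": rep.rmse,
                         "ssim": rep.ssim, "sparse_psnr": base.psnr,
                         "sparse_rmse": base.rmse, "sparse_ssim": base.ssim})
        import pandas as pd
        csv_path = os.path.join(root, "metrics.csv")
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        record(csv_path)
        summary = {
            "model": mmod.summarize_reports(model_reports),
            "sparse_input": mmod.summarize_reports(sparse_reports),
        }
        summary_path = os.path.join(root, "metrics_summary.json")
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
        record(summary_path)
        manifest["stages"]["evaluate"] = summary
        log.info("evaluate: model PSNR %.2f vs sparse %.2f",
                 summary["model"]["psnr"]["mean"],
                 summary["sparse_input"]["psnr"]["mean"])
    except Exception as exc:
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, root)
        raise UPaintError(f"stage {current_stage!r} failed: {exc}") from exc

    _write_manifest(manifest, root)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_manifest(manifest: dict, root: str) -> None:
    with open(os.path.join(root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
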