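"""End-to-end orchestration: simulate -> preprocess -> encode -> pretrain ->
train -> evaluate, usable in memory (benchmarks, tests) or via the CLI with
artifacts written at every stage."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import classifier, gaf, preprocessing, synthetic_gait, tica_net
from .classifier import EvalReport, GafDataset, ModelSpec
from .preprocessing import SegmentationConfig
from .synthetic_gait import GaitClassParams
from .tica_net import TICAConfig

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "derive_seed"]

logger = logging.getLogger(__name__)


_STAGE_IDS = {"simulate": 0, "preprocess": 1, "encode": 2, "pretrain": 3,
              "train": 4, "split": 5}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (stable
    across processes)."""
    tag = _STAGE_IDS.get(stage, zlib.crc32(stage.encode()))
    ss = np.random.SeedSequence([int(global_seed), int(tag)])
    return int(ss.generate_state(1)[0])


_stage_seed = derive_seed


@dataclass
class ExperimentConfig:
    """Scaled-down but complete end-to-end benchmark configuration."""

    n_alcohol: int = 15
    n_marijuana: int = 15
    n_sober: int = 20
    bouts_per_subject: int = 1
    duration_s: float = 12.0
    fs: float = 50.0
    resample_len: int = 64
    presets: Optional[Dict[str, GaitClassParams]] = None
    subject_effect_scale: float = 1.0
    # model
    n_maps: int = 3
    tile_k: int = 2
    rf_s: int = 8
    pretrain: bool = True
    patch_size: int = 16
    n_patches: int = 400
    pretrain_max_outer: int = 40
    freeze_features: bool = False
    # supervised stage
    split_strategy: str = "subject_wise"
    test_fraction: float = 0.3
    epochs: int = 15
    lr: float = 0.5
    batch_size: int = 16
    seed: int = 0


@dataclass
class ExperimentResult:
    report: EvalReport
    train_report: EvalReport
    loss_history: List[float]
    n_cycles: int
    pretrain_trace: Optional[np.ndarray] = None


def _cycles_to_dataset(cycles, resample_len: int) -> GafDataset:
    images = gaf.encode_cycles(cycles)
    return GafDataset.from_images(images)


def run_experiment(config: Optional[ExperimentConfig] = None,
                   **overrides) -> ExperimentResult:
    """Run the full synthetic pipeline once and return evaluation reports.

    Every stage seed is derived from ``config.seed``; identical configs give
    identical reports.
    """
    if config is None:
        config = ExperimentConfig(**overrides)
    elif overrides:
        config = ExperimentConfig(**{**asdict_shallow(config), **overrides})

    seg = SegmentationConfig(resample_len=config.resample_len)

    # 1. simulate
    recs = synthetic_gait.generate_dataset(
        {"alcohol": config.n_alcohol, "marijuana": config.n_marijuana,
         "sober": config.n_sober if config.pretrain else 0},
        bouts_per_subject=config.bouts_per_subject,
        params_by_class=config.presets,
        seed=_stage_seed(config.seed, "simulate"),
        duration_s=config.duration_s, fs=config.fs,
        subject_effect_scale=config.subject_effect_scale)

    # 2. preprocess + 3. encode
    impaired_cycles, sober_cycles = [], []
    for rec in recs:
        cycles = preprocessing.preprocess_recording(rec, seg)
        (sober_cycles if rec.label == "sober" else impaired_cycles).extend(cycles)
    if not impaired_cycles:
        raise RuntimeError("preprocessing produced no impaired gait cycles")
    dataset = _cycles_to_dataset(impaired_cycles, config.resample_len)
    logger.info("pipeline produced %d impaired cycles, %d sober cycles",
                len(dataset), len(sober_cycles))

    # 4. unsupervised pretraining on sober samples
    weights = None
    pretrain_trace = None
    if config.pretrain:
        if not sober_cycles:
            raise RuntimeError("pretraining requested but no sober cycles")
        sober_images = np.stack(
            [im.pixels for im in gaf.encode_cycles(sober_cycles)])
        patches = tica_net.extract_patches(
            sober_images, config.patch_size, config.n_patches,
            seed=_stage_seed(config.seed, "pretrain"))
        w0 = tica_net.init_tiled_weights(
            config.n_maps, config.tile_k, config.rf_s,
            sober_images.shape[-1], seed=_stage_seed(config.seed, "pretrain"))
        result = tica_net.pretrain_tica(
            patches, w0,
            config=TICAConfig(max_outer=config.pretrain_max_outer,
                              seed=_stage_seed(config.seed, "pretrain")))
        weights = result.weights
        pretrain_trace = result.objective_trace

    # 5. supervised training
    train_set, test_set = classifier.split_dataset(
        dataset, strategy=config.split_strategy,
        test_fraction=config.test_fraction,
        seed=_stage_seed(config.seed, "split"))
    model = classifier.build_model(
        input_shape=train_set.X.shape[1:], weights=weights,
        n_maps=config.n_maps, tile_k=config.tile_k, rf_s=config.rf_s,
        freeze_features=config.freeze_features,
        seed=_stage_seed(config.seed, "train"))
    model, history = classifier.train(
        model, train_set, epochs=config.epochs, lr=config.lr,
        batch_size=config.batch_size, seed=_stage_seed(config.seed, "train"))

    # 6. evaluate
    report = classifier.evaluate(model, test_set)
    train_report = classifier.evaluate(model, train_set)
    return ExperimentResult(report=report, train_report=train_report,
                            loss_history=history, n_cycles=len(dataset),
                            pretrain_trace=pretrain_trace)


def asdict_shallow(config: ExperimentConfig) -> dict:
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
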