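"""End-to-end orchestration: phantom -> cube -> centres -> patches -> model
-> prediction -> metrics, with every artifact written to a run directory.

Each stage derives its own seed from the global one, and every artifact
carries the configuration hash, so re-running with the same configuration
and seed reproduces centre lists and patch archives bit-exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, derive_seed
from .errors import StageError
from .evaluation import (MetricsReport, ROCCurve, aggregate_report,
                         evaluate_pair, roc_optimal_threshold, summarize)
from .inference import binarize, predict_cube, reconstruct_export
from .labeling import SamplingPlan, sample_balanced_centers, samples_to_frame
from .network import VARIANTS, MVSIRClassifier
from .patches import PatchStreams, build_patch_streams
from .phantom import PhantomCase, PhantomParams, generate_phantom, save_phantom
from .preprocess import (NoduleCube, consensus_mask, extract_cube,
                         resample_isotropic, save_cube)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    run_dir: Path
    metrics: MetricsReport
    roc: ROCCurve
    threshold: float
    config_hash: str
    learning_curve: pd.DataFrame | None = None
    model: object | None = None
    extras: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with context
                raise StageError(name, str(exc)) from exc
            logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("phantom")
def _make_phantom(cfg: RunConfig, out: Path) -> PhantomCase:
    params = PhantomParams(**cfg.phantom.model_dump(),
                           seed=derive_seed(cfg.seed, "phantom"))
    case = generate_phantom(params)
    save_phantom(case, out / "phantom")
    return case


@_stage("prepare")
def _prepare(cfg: RunConfig, case: PhantomCase, out: Path) -> tuple[NoduleCube, np.ndarray]:
    vol = resample_isotropic(case.volume, cfg.preprocess.target_spacing)
    cons = consensus_mask(case.annotations, vol.shape,
                          n_readers=cfg.phantom.n_readers)
    cube = extract_cube(vol, cons, pad=cfg.preprocess.pad)
    save_cube(cube, out / "cube")
    sl = tuple(slice(o, o + n) for o, n in zip(cube.offset, cube.shape))
    gt_cube = case.gt_mask[sl]
    return cube, gt_cube


@_stage("sample")
def _sample(cfg: RunConfig, cube: NoduleCube, out: Path):
    plan = SamplingPlan(per_slice_n=cfg.sampling.per_slice_n,
                        balance=cfg.sampling.balance,
                        seed=derive_seed(cfg.seed, "sampling"))
    centers = sample_balanced_centers(cube, plan)
    samples_to_frame(centers).to_csv(out / "centers.csv", index=False)
    return centers


@_stage("patches")
def _patches(cfg: RunConfig, cube: NoduleCube, centers, out: Path) -> PatchStreams:
    streams = build_patch_streams(cube, centers, size=cfg.patches.patch_size,
                                  fill=cfg.patches.fill,
                                  vh_normalize=cfg.patches.vh_normalize)
    streams.save(out / "streams.npz")
    return streams


@_stage("train")
def _train(cfg: RunConfig, streams: PatchStreams, out: Path,
           variant: str | None = None) -> MVSIRClassifier:
    model = MVSIRClassifier(
        variant=variant or cfg.network.variant,
        patch_size=cfg.patches.patch_size,
        stem_channels=cfg.network.stem_channels,
        fc_width=cfg.network.fc_width,
        fusion_width=cfg.network.fusion_width,
        learning_rate=cfg.training.learning_rate,
        weight_decay=cfg.training.weight_decay,
        decay_mode=cfg.training.decay_mode,
        batch_size=cfg.training.batch_size,
        epochs=cfg.training.epochs,
        validation_fraction=cfg.training.validation_fraction,
        random_state=derive_seed(cfg.seed, "training"))
    model.fit(streams.as_array(), streams.labels)
    model.save(out / "model")
    model.learning_curve_.to_csv(out / "learning_curve.csv", index=False)
    return model


@_stage("predict")
def _predict(cfg: RunConfig, model, cube: NoduleCube, gt_cube: np.ndarray,
             out: Path):
    pred = predict_cube(model, cube, stride=cfg.inference.stride,
                        size=cfg.patches.patch_size,
                        batch_size=cfg.inference.batch_size,
                        fill=cfg.patches.fill,
                        vh_normalize=cfg.patches.vh_normalize)
    roc = roc_optimal_threshold(pred.confidence, gt_cube)
    threshold = cfg.inference.threshold
    if threshold is None:
        threshold = float(np.clip(roc.optimal_threshold, 1e-6, 1 - 1e-6))
    result = binarize(pred, threshold)
    reconstruct_export(result, pred, cube, out / "prediction")
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                  "tpr": roc.tpr}).to_csv(out / "roc.csv", index=False)
    (out / "roc.json").write_text(json.dumps(
        {"auc": roc.auc, "optimal_threshold": roc.optimal_threshold}))
    return pred, result, roc, threshold


@_stage("evaluate")
def _evaluate(result, gt_cube: np.ndarray, spacing, out: Path) -> MetricsReport:
    rep = evaluate_pair(result.mask, gt_cube, spacing)
    pd.DataFrame([rep.as_dict()]).to_csv(out / "metrics.csv", index=False)
    return rep


def run_pipeline(cfg: RunConfig, out_dir, model=None) -> PipelineResult:
    """Execute the full chain; ``model`` (anything with ``predict_proba``)
    replaces training when given — used for oracle-stub plumbing checks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "config.json").write_text(json.dumps(
        {"config": cfg.model_dump(mode="json"), "hash": chash}, indent=2))
    case = _make_phantom(cfg, out)
    cube, gt_cube = _prepare(cfg, case, out)
    curve = None
    if model is None:
        centers = _sample(cfg, cube, out)
        streams = _patches(cfg, cube, centers, out)
        model = _train(cfg, streams, out)
        curve = model.learning_curve_
    pred, result, roc, threshold = _predict(cfg, model, cube, gt_cube, out)
    rep = _evaluate(result, gt_cube, cube.spacing, out)
    return PipelineResult(out, rep, roc, threshold, chash,
                          learning_curve=curve, model=model,
                          extras={"gt_cube": gt_cube, "cube": cube,
                                  "prediction": pred, "segmentation": result})


def run_variant_sweep(cfg: RunConfig, out_dir,
                      variants: tuple[str, ...] = VARIANTS) -> pd.DataFrame:
    """Train and evaluate every variant on the same phantom, centres and
    patches; returns the comparison table (ASD, HSD, Dice, PPV, SEN rows)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    case = _make_phantom(cfg, out)
    cube, gt_cube = _prepare(cfg, case, out)
    centers = _sample(cfg, cube, out)
    streams = _patches(cfg, cube, centers, out)
    reports: dict[str, MetricsReport] = {}
    for variant in variants:
        vdir = out / variant
        vdir.mkdir(exist_ok=True)
        model = _train(cfg, streams, vdir, variant=variant)
        pred, result, roc, threshold = _predict(cfg, model, cube, gt_cube, vdir)
        reports[variant] = _evaluate(result, gt_cube, cube.spacing, vdir)
    table = aggregate_report(reports)
    table.to_csv(out / "variant_report.csv")
    summarize(table).to_csv(out / "variant_summary.csv")
    return table
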