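"""Run configuration: schema-validated, preset-aware, reproducible.

Every numeric constant of the method lives here as a named field — the
10-voxel pad, the 30x30 patch, the per-slice centre count, the 32/256
channel widths, the optimizer settings.  Two presets are provided:

* ``desk``  — the package default: 200 centres per slice, batch 64, 10
  epochs, learning rate 1e-3, VH min-max normalisation on, stride-1
  inference.  Sized for a single CPU.
* ``paper`` — the published settings: 4000 centres per slice, batch 2000,
  100 epochs, learning rate 1e-4, no VH normalisation, stride 1.

A single global seed fans out to per-stage seeds by hashing the stage name,
so stages are individually reproducible without seed collisions.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomSection(_Section):
    grid_shape: tuple[int, int, int] = (39, 63, 63)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodule_center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (1.8, 6.0, 5.5)
    radial_bumpiness: float = Field(0.12, ge=0, lt=1)
    nodule_intensity: float = 40.0
    background_intensity: float = -800.0
    noise_sigma: float = Field(20.0, ge=0)
    n_readers: int = Field(4, ge=1)
    reader_jitter: float = Field(0.3, ge=0)
    n_vertices: int = Field(64, ge=16)


class PreprocessSection(_Section):
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad: int = Field(10, ge=0)
    rescale_intensity: bool = False


class SamplingSection(_Section):
    per_slice_n: int = Field(200, ge=2)
    balance: float = Field(0.5, gt=0, lt=1)


class PatchSection(_Section):
    patch_size: int = Field(30, ge=4)
    fill: str | float = "edge"
    vh_normalize: bool = True


class NetworkSection(_Section):
    variant: Literal["MV-SIR", "MV-I-CNN", "MV-CNN"] = "MV-SIR"
    stem_channels: int = Field(32, ge=1)
    fc_width: int = Field(256, ge=1)
    fusion_width: int = Field(256, ge=1)


class TrainingSection(_Section):
    learning_rate: float = Field(1e-3, gt=0)
    weight_decay: float = Field(1e-2, ge=0)
    decay_mode: Literal["l2", "lr"] = "l2"
    batch_size: int = Field(64, ge=1)
    epochs: int = Field(10, ge=1)
    validation_fraction: float = Field(0.10, gt=0, lt=1)


class InferenceSection(_Section):
    stride: int | tuple[int, int, int] = 1
    threshold: float | None = Field(None, gt=0, lt=1)  # None: ROC-optimal
    batch_size: int = Field(512, ge=1)


class RunConfig(_Section):
    seed: int = 0
    scale: Literal["desk", "paper"] = "desk"
    phantom: PhantomSection = PhantomSection()
    preprocess: PreprocessSection = PreprocessSection()
    sampling: SamplingSection = SamplingSection()
    patches: PatchSection = PatchSection()
    network: NetworkSection = NetworkSection()
    training: TrainingSection = TrainingSection()
    inference: InferenceSection = InferenceSection()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


#: values the paper-scale preset injects over the desk defaults
PAPER_PRESET = {
    "sampling": {"per_slice_n": 4000},
    "patches": {"vh_normalize": False},
    "training": {"learning_rate": 1e-4, "batch_size": 2000, "epochs": 100},
    "inference": {"stride": 1},
}


def _deep_update(base: dict, update: dict) -> dict:
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def validate_config(raw: dict | str | None = None,
                    scale: str | None = None,
                    seed: int | None = None) -> RunConfig:
    """Build a RunConfig from raw JSON/dict, filling preset defaults.

    Unknown keys are rejected with the offending path named.  An empty input
    yields the full desk preset; ``scale='paper'`` (from the argument or the
    raw config itself) layers the published values on top before explicit
    user keys are applied.
    """
    if isinstance(raw, str):
        raw = json.loads(raw) if raw.strip() else {}
    raw = dict(raw or {})
    eff_scale = raw.get("scale", scale or "desk")
    merged: dict = {"scale": eff_scale}
    if eff_scale == "paper":
        _deep_update(merged, json.loads(json.dumps(PAPER_PRESET)))
    _deep_update(merged, raw)
    if seed is not None:
        merged["seed"] = seed
    return RunConfig(**merged)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: stage-name CRC folded into the global seed."""
    return (zlib.crc32(stage.encode()) ^ (int(global_seed) & 0x7FFFFFFF)) % (2 ** 31)
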