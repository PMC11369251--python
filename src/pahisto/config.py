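"""Run configuration: validated, round-trippable stage configs + seed fan-out.

A :class:`RunConfig` bundles every stage's options.  Defaults are the
full-scale settings (512 px tiles with 50% overlap, translation training for
400 epochs at lr 2e-4, segmentation at lr 1e-4 / batch 64, classification at
lr 1e-4 / batch 32, saliency thresholds 90/170).  ``desk_profile`` returns
the reduced configuration used by tests and examples on one CPU: 64 px
scenes, narrow networks, tens of epochs.

The single global seed fans out to per-stage seeds through a fixed
SeedSequence derivation, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ecut import ECUTLossConfig, TrainConfig
from .saliency import SaliencyThresholds
from .segmentation import UNetTrainConfig
from .stepff import StepFFTrainConfig
from .synthetic import SceneParams, ClassParams

__all__ = ["RunConfig", "PipelineScale", "validate_config", "load_config",
           "dump_config", "desk_profile", "stage_seed", "config_hash"]

STAGES = ("synth", "stain", "segment", "classify", "metrics")


@dataclass
class PipelineScale:
    """Problem sizes for the end-to-end pipeline run."""

    n_per_class: int = 100
    canvas_size: tuple = (512, 512)
    tile_size: int = 512
    overlap: float = 0.5
    gen_base_width: int = 64
    unet_base_width: int = 64
    stepff_base_width: int = 64
    stepff_downsample: int = 0   # x2 downsampling steps before classification
    include_vhe: bool = True    # drop for the PAH(+seg) ablation pipeline


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "pahisto_run"
    verbosity: int = 1
    scene: SceneParams = field(default_factory=SceneParams)
    scale: PipelineScale = field(default_factory=PipelineScale)
    thresholds: SaliencyThresholds = field(default_factory=SaliencyThresholds)
    ecut_loss: ECUTLossConfig = field(default_factory=ECUTLossConfig)
    ecut_train: TrainConfig = field(default_factory=TrainConfig)
    unet_train: UNetTrainConfig = field(default_factory=UNetTrainConfig)
    stepff_train: StepFFTrainConfig = field(default_factory=StepFFTrainConfig)


def desk_profile(seed: int = 0, out_dir: str = "pahisto_run") -> RunConfig:
    """Reduced-scale configuration that completes in minutes on one CPU."""
    cfg = RunConfig(seed=seed, out_dir=out_dir)
    cfg.scale = PipelineScale(
        n_per_class=8, canvas_size=(64, 64), tile_size=64, overlap=0.0,
        gen_base_width=8, unet_base_width=8, stepff_base_width=2,
        stepff_downsample=1)
    cfg.ecut_loss = ECUTLossConfig(n_patches=64, nce_dim=64,
                                   thresholds=cfg.thresholds)
    cfg.ecut_train = TrainConfig(epochs=6, lr_constant_epochs=3, seed=seed)
    cfg.unet_train = UNetTrainConfig(batch_size=2, epochs=40, patience=8,
                                     seed=seed)
    cfg.stepff_train = StepFFTrainConfig(base_width=2, epochs=40, patience=8,
                                         folds=5, seed=seed)
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------- #
# (de)serialization
# --------------------------------------------------------------------------- #

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize to YAML; returns the text (and writes it when given a path)."""
    import yaml

    text = yaml.safe_dump(_to_plain(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


_TUPLE_FIELDS = {"canvas_size", "betas", "he_nucleus", "he_cytoplasm",
                 "he_background", "modalities"}


def _build(cls, raw: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for name, val in raw.items():
        f = fields[name]
        sub = {SceneParams: ("scene",), ClassParams: ("noncancerous", "cancerous"),
               PipelineScale: ("scale",), SaliencyThresholds: ("thresholds",),
               ECUTLossConfig: ("ecut_loss",), TrainConfig: ("ecut_train",),
               UNetTrainConfig: ("unet_train",), StepFFTrainConfig: ("stepff_train",)}
        target = next((cls_ for cls_, names in sub.items() if name in names), None)
        if target is not None and isinstance(val, dict):
            kwargs[name] = _build(target, val, f"{path}.{name}")
        elif name in _TUPLE_FIELDS and isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def validate_config(raw: dict | None) -> RunConfig:
    """Build a RunConfig from a plain dict, filling every unset field with its
    default and rejecting unknown keys with the offending key named."""
    raw = dict(raw or {})
    return _build(RunConfig, raw, "config")


def load_config(path) -> RunConfig:
    import yaml

    text = Path(path).read_text()
    raw = (json.loads(text) if str(path).endswith(".json")
           else yaml.safe_load(text))
    return validate_config(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash over the semantic config content (output location and
    verbosity do not affect results and are excluded)."""
    plain = _to_plain(cfg)
    plain.pop("out_dir", None)
    plain.pop("verbosity", None)
    return hashlib.sha256(
        json.dumps(plain, sort_keys=True).encode()).hexdigest()[:16]
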