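"""Pipeline configuration: nested stage configs, YAML round-trip, validation
and deterministic per-stage seed derivation from one global seed."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluate import MODEL_NAMES, ModelSpec
from .exceptions import ConfigurationError
from .features import FeatureConfig
from .preprocess import PreprocessConfig
from .synth import SynthConfig

_STAGES = ("synth", "preprocess", "features", "feateng", "evaluate")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: one global seed drives every stage."""
    if stage not in _STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0])


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    retention: float = 0.999
    paper_mode: bool = False
    models: tuple[str, ...] = MODEL_NAMES
    folds: int = 5
    seed: int = 0
    out_dir: str = "results"
    write_intermediates: bool = True

    def validate(self) -> list[str]:
        """Collect every constraint violation; empty list means valid."""
        errors: list[str] = []
        try:
            self.synth.validate()
        except ConfigurationError as exc:
            errors.append(f"synth: {exc}")
        try:
            self.preprocess.validate(self.synth.fs)
        except ConfigurationError as exc:
            errors.append(f"preprocess: {exc}")
        try:
            self.features.validate()
        except ConfigurationError as exc:
            errors.append(f"features: {exc}")
        if not 0.0 < self.retention <= 1.0:
            errors.append(f"retention: must be in (0, 1], got {self.retention}")
        for name in self.models:
            if name not in MODEL_NAMES:
                errors.append(f"models: unknown model {name!r} (choose from {MODEL_NAMES})")
        if self.folds < 2:
            errors.append(f"folds: must be >= 2, got {self.folds}")
        return errors

    def model_specs(self) -> list[ModelSpec]:
        return [ModelSpec(name=n) for n in self.models]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "retention": self.retention,
            "paper_mode": self.paper_mode,
            "models": list(self.models),
            "folds": self.folds,
            "write_intermediates": self.write_intermediates,
            "synth": {
                "n_channels": self.synth.n_channels,
                "fs": self.synth.fs,
                "segment_raw_len": self.synth.segment_raw_len,
                "class_counts": {int(k): int(v) for k, v in self.synth.class_counts.items()},
                "activation_profile": np.asarray(self.synth.activation_profile).tolist(),
                "burst_duration": self.synth.burst_duration,
                "baseline_sd": self.synth.baseline_sd,
                "burst_band": list(self.synth.burst_band),
                "gap_jitter": list(self.synth.gap_jitter),
                "seed": self.synth.seed,
            },
            "preprocess": {
                "band": list(self.preprocess.band),
                "filter_order": self.preprocess.filter_order,
                "zero_phase": self.preprocess.zero_phase,
                "normalization": self.preprocess.normalization,
                "envelope_window": self.preprocess.envelope_window,
                "raw_window": self.preprocess.raw_window,
                "kept_window": self.preprocess.kept_window,
            },
            "features": {
                "wamp_threshold": self.features.wamp_threshold,
                "afb_threshold": self.features.afb_threshold,
                "afb_window": self.features.afb_window,
            },
        }


def _check_keys(section: str, given: dict, allowed: set[str], errors: list[str]) -> None:
    for key in given:
        if key not in allowed:
            errors.append(f"{section}: unknown field {key!r}")
    for key, value in given.items():
        if value is None:
            errors.append(f"{section}: field {key!r} is missing a value")


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig`; raises with the full error list."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    errors: list[str] = []
    _check_keys(
        "config",
        data,
        {"seed", "out_dir", "retention", "paper_mode", "models", "folds",
         "write_intermediates", "synth", "preprocess", "features"},
        errors,
    )
    synth_d = dict(data.get("synth") or {})
    pre_d = dict(data.get("preprocess") or {})
    feat_d = dict(data.get("features") or {})
    _check_keys(
        "synth",
        synth_d,
        {"n_channels", "fs", "segment_raw_len", "class_counts", "activation_profile",
         "burst_duration", "baseline_sd", "burst_band", "gap_jitter", "seed"},
        errors,
    )
    _check_keys(
        "preprocess",
        pre_d,
        {"band", "filter_order", "zero_phase", "normalization", "envelope_window",
         "raw_window", "kept_window"},
        errors,
    )
    _check_keys("features", feat_d, {"wamp_threshold", "afb_threshold", "afb_window"}, errors)
    if errors:
        raise ConfigurationError("; ".join(errors))

    if "class_counts" in synth_d:
        synth_d["class_counts"] = {int(k): int(v) for k, v in synth_d["class_counts"].items()}
    for key in ("burst_band", "gap_jitter"):
        if key in synth_d:
            synth_d[key] = tuple(synth_d[key])
    if "band" in pre_d:
        pre_d["band"] = tuple(pre_d["band"])

    cfg = PipelineConfig(
        synth=SynthConfig(**synth_d),
        preprocess=PreprocessConfig(**pre_d),
        features=FeatureConfig(**feat_d),
        retention=float(data.get("retention", 0.999)),
        paper_mode=bool(data.get("paper_mode", False)),
        models=tuple(data.get("models", MODEL_NAMES)),
        folds=int(data.get("folds", 5)),
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "results")),
        write_intermediates=bool(data.get("write_intermediates", True)),
    )
    errors = cfg.validate()
    if errors:
        raise ConfigurationError("; ".join(errors))
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config file."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
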