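"""Run configuration: one structured YAML file drives the whole pipeline.

Sections mirror the pipeline stages (phantom, network, training, quantify);
every consumed field is validated before any stage runs and unknown keys are
rejected, so a typo fails fast instead of silently using a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

from .augment import AugmentSpec
from .cascade import (
    NetConfig,
    TrainConfig,
    desk_net_config,
    desk_train_config,
    fullscale_net_config,
    fullscale_train_config,
)
from .phantom import PhantomParams

__all__ = ["RunConfig", "load_config", "config_hash"]


def _from_mapping(cls, data: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def _tupled(data: dict, keys: tuple[str, ...]) -> dict:
    out = dict(data)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


@dataclass
class QuantifyOptions:
    k_values: tuple[float, ...] = (1.0, 1.5, 2.0)
    frozen_k: float | None = None
    frozen_from: str | None = None  # path to a sweep.json of another run
    sd_ddof: int = 1


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("runs/out")
    n_hc: int = 8
    n_pd: int = 8
    phantom: PhantomParams = field(default_factory=PhantomParams)
    net: NetConfig = field(default_factory=desk_net_config)
    training: TrainConfig = field(default_factory=desk_train_config)
    quantify: QuantifyOptions = field(default_factory=QuantifyOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["output_dir"] = str(self.output_dir)
        return d


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    known = {"seed", "output_dir", "phantom", "network", "training", "quantify"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config: unknown top-level keys {sorted(unknown)}")

    seed = int(raw.get("seed", 0))
    out_dir = Path(raw.get("output_dir", "runs/out"))

    ph = dict(raw.get("phantom") or {})
    n_hc = int(ph.pop("n_hc", 8))
    n_pd = int(ph.pop("n_pd", 8))
    ph = _tupled(ph, ("image_size", "pixel_spacing", "midbrain_slices", "scale_range"))
    ph.setdefault("seed", seed)
    if "snpc_extent" in ph:
        ph["snpc_extent"] = {k: float(v) for k, v in ph["snpc_extent"].items()}
    phantom = _from_mapping(PhantomParams, ph, "config.phantom")

    net_raw = dict(raw.get("network") or {})
    preset = net_raw.pop("preset", "desk")
    net = fullscale_net_config() if preset == "fullscale" else desk_net_config()
    net = _from_mapping(NetConfig, {**asdict(net), **net_raw}, "config.network")

    tr_raw = dict(raw.get("training") or {})
    preset = tr_raw.pop("preset", "desk")
    base = fullscale_train_config(seed) if preset == "fullscale" else desk_train_config(seed)
    aug_raw = tr_raw.pop("augment", None)
    base_d = asdict(base)
    base_d.pop("augment")
    merged = {**base_d, **tr_raw}
    training = _from_mapping(TrainConfig, merged, "config.training")
    if aug_raw is not None:
        training.augment = _from_mapping(
            AugmentSpec, _tupled(dict(aug_raw), ("A_values", "B_values", "angles", "scales")), "config.training.augment"
        )
    else:
        training.augment = base.augment

    q_raw = _tupled(dict(raw.get("quantify") or {}), ("k_values",))
    quantify = _from_mapping(QuantifyOptions, q_raw, "config.quantify")

    return RunConfig(
        seed=seed,
        output_dir=out_dir,
        n_hc=n_hc,
        n_pd=n_pd,
        phantom=phantom,
        net=net,
        training=training,
        quantify=quantify,
    )
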