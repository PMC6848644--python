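"""The two-stage segmentation cascade.

Net 1 segments midbrain vs. outside on the raw slice; net 2 segments SNpc vs.
background, fed with the raw slice concatenated with net 1's current midbrain
probability map (soft gating).  The two nets are trained simultaneously but
their losses are disconnected: each has its own Adam optimizer and no gradient
flows from net 2's loss into net 1.  Per training iteration a square crop is
drawn at random, both nets take a forward pass, two cross-entropy losses are
computed (net 2's restricted to pixels inside the truth midbrain, where its
task is defined) and two independent Adam updates applied.

Two presets are provided: ``fullscale`` mirrors the original full-resolution recipe
(depth 4, 64 base channels, 256-pixel crops, Adam alpha 1e-4) and is not meant
to be trained on a laptop CPU; ``desk`` is a CPU-trainable configuration for
phantom-scale experiments (depth 3, 8 base channels, 96-pixel crops,
alpha 1e-3, a fixed global input scale of 0.01 for conditioning, and a small
rotation/scale augmentation grid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .augment import AugmentSpec, apply_variant
from .imageio import ImageStack, Label, LabelMask, MaskSource
from .nn.layers import softmax, softmax_cross_entropy
from .nn.unet import UNet

__all__ = [
    "NetConfig",
    "TrainConfig",
    "CascadeModel",
    "build_cascade",
    "compose_second_input",
    "train_cascade",
    "predict",
    "cross_validate",
    "desk_net_config",
    "desk_train_config",
    "fullscale_net_config",
    "fullscale_train_config",
]


@dataclass
class NetConfig:
    """Architecture of one U-net (both nets of the cascade share it by default)."""

    depth: int = 3
    base_channels: int = 8
    classes: int = 2

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the original full-resolution training recipe: 256-pixel random crops, batch size 2,
    mean cross entropy, Adam(alpha=1e-4, beta1=0.5, beta2=0.999), 10 epochs,
    no early stopping, 4 cross-validation folds.  ``input_scale`` is a fixed
    global multiplier applied to intensities before the nets (1.0 = the raw,
    unnormalized signal); ``second_input`` selects soft gating (concatenate
    net 1's probability) or a hard mask.
    """

    crop_size: int = 256
    batch_size: int = 2
    epochs: int = 10
    alpha: float = 1e-4
    beta1: float = 0.5
    beta2: float = 0.999
    folds: int = 4
    seed: int = 0
    input_scale: float = 1.0
    second_input: str = "soft"  # "soft" | "hard"
    augment: AugmentSpec | None = None
    train_slices: str = "all"  # "all" | "midbrain"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.second_input not in ("soft", "hard"):
            raise ValueError("second_input must be 'soft' or 'hard'")


def desk_net_config() -> NetConfig:
    return NetConfig(depth=3, base_channels=8)


def fullscale_net_config() -> NetConfig:
    return NetConfig(depth=4, base_channels=64)


def desk_train_config(seed: int = 0) -> TrainConfig:
    """CPU-trainable settings for 128-pixel phantom cohorts."""
    return TrainConfig(
        crop_size=96,
        epochs=10,
        alpha=1e-3,
        seed=seed,
        input_scale=0.01,
        augment=AugmentSpec(
            A_values=(1.0,),
            B_values=(0.0,),
            angles=(-15.0, 0.0, 15.0),
            scales=(0.95, 1.0, 1.05),
            combine="per_category",
        ),
        train_slices="midbrain",
    )


def fullscale_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(seed=seed, augment=AugmentSpec())


@dataclass
class CascadeModel:
    """The midbrain net, the SNpc net, and their training provenance."""

    net_midbrain: UNet
    net_snpc: UNet
    net_config: NetConfig
    train_config: TrainConfig | None = None
    fold_id: int | None = None
    seed: int = 0

    @property
    def input_scale(self) -> float:
        return self.train_config.input_scale if self.train_config else 1.0

    def save(self, path: str | Path) -> Path:
        """Checkpoint: weights as .npz plus a JSON sidecar with the configs."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for tag, net in (("mb", self.net_midbrain), ("sn", self.net_snpc)):
            for i, v in enumerate(net.state()):
                arrays[f"{tag}_{i}"] = v
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {
            "net_config": asdict(self.net_config),
            "train_config": _train_config_dict(self.train_config),
            "fold_id": self.fold_id,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @staticmethod
    def load(path: str | Path) -> "CascadeModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net_cfg = NetConfig(**sidecar["net_config"])
        train_cfg = _train_config_from_dict(sidecar["train_config"])
        model = build_cascade(net_cfg, seed=sidecar.get("seed", 0), train_config=train_cfg)
        model.fold_id = sidecar.get("fold_id")
        data = np.load(path.with_suffix(".npz"))
        for tag, net in (("mb", model.net_midbrain), ("sn", model.net_snpc)):
            state = [data[f"{tag}_{i}"] for i in range(len(net.params))]
            net.load_state(state)
        return model


def _train_config_dict(cfg: TrainConfig | None) -> dict | None:
    if cfg is None:
        return None
    d = asdict(cfg)
    if cfg.augment is not None:
        d["augment"] = asdict(cfg.augment)
    return d


def _train_config_from_dict(d: dict | None) -> TrainConfig | None:
    if d is None:
        return None
    d = dict(d)
    if d.get("augment") is not None:
        aug = dict(d["augment"])
        for k in ("A_values", "B_values", "angles", "scales"):
            aug[k] = tuple(aug[k])
        d["augment"] = AugmentSpec(**aug)
    return TrainConfig(**d)


def build_cascade(
    cfg: NetConfig | tuple[NetConfig, NetConfig],
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> CascadeModel:
    """Initialize the two nets (net 1: 1 input channel; net 2: 2 channels)."""
    cfg_mb, cfg_sn = cfg if isinstance(cfg, tuple) else (cfg, cfg)
    net_mb = UNet(1, cfg_mb.classes, depth=cfg_mb.depth, base_channels=cfg_mb.base_channels, seed=seed)
    net_sn = UNet(
        2, cfg_sn.classes, depth=cfg_sn.depth, base_channels=cfg_sn.base_channels, seed=seed + 1
    )
    return CascadeModel(net_mb, net_sn, cfg_mb, train_config=train_config, seed=seed)


def compose_second_input(image: np.ndarray, midbrain_prob: np.ndarray, mode: str = "soft") -> np.ndarray:
    """Build net 2's input from the (scaled) image and net 1's midbrain output.

    ``soft``: concatenate the probability map as a second channel.  ``hard``:
    concatenate the thresholded (argmax) mask instead.  Shapes: image and
    probability are (N, H, W); the result is (N, 2, H, W).
    """
    image = np.asarray(image)
    midbrain_prob = np.asarray(midbrain_prob)
    if image.shape != midbrain_prob.shape:
        raise ValueError(f"geometry mismatch: {image.shape} vs {midbrain_prob.shape}")
    gate = midbrain_prob if mode == "soft" else (midbrain_prob > 0.5).astype(image.dtype)
    return np.stack([image, gate], axis=1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _as_subject_arrays(
    subjects: Sequence, loader=None
) -> list[tuple[ImageStack, LabelMask]]:
    """Accept PhantomSubject-like objects, (image, mask) pairs, or a manifest."""
    out = []
    for s in subjects:
        if hasattr(s, "image") and hasattr(s, "truth"):
            out.append((s.image, s.truth))
        else:
            img, msk = s
            out.append((img, msk))
    return out


def _build_samples(
    pairs: list[tuple[ImageStack, LabelMask]], cfg: TrainConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialize (intensity slice, label slice) training samples.

    Augmentation (if configured) is precomputed per subject; slice selection
    keeps either all slices or only midbrain-bearing ones plus one empty slice
    as a negative example.
    """
    samples: list[tuple[np.ndarray, np.ndarray]] = []
    spec = cfg.augment or AugmentSpec.identity()
    for img, msk in pairs:
        msk.check_alignment(img)
        for variant in spec.variants():
            aimg, amsk = apply_variant(img, msk, variant)
            has_mb = amsk.data.reshape(amsk.data.shape[0], -1).max(axis=1) > 0
            if cfg.train_slices == "midbrain":
                keep = list(np.flatnonzero(has_mb))
                empty = np.flatnonzero(~has_mb)
                if empty.size:
                    keep.append(int(empty[0]))
            else:
                keep = range(amsk.data.shape[0])
            for i in keep:
                samples.append(
                    (
                        np.asarray(aimg.data[i], dtype=np.float32),
                        np.asarray(amsk.data[i], dtype=np.int64),
                    )
                )
    return samples


def _random_crop(
    img: np.ndarray, lab: np.ndarray, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    h, w = img.shape
    if size > h or size > w:
        raise ValueError(f"crop {size} larger than image {h}x{w}")
    r = int(rng.integers(0, h - size + 1))
    c = int(rng.integers(0, w - size + 1))
    return img[r : r + size, c : c + size], lab[r : r + size, c : c + size]


def train_cascade(
    subjects: Sequence,
    cfg: TrainConfig,
    net_cfg: NetConfig | None = None,
    model: CascadeModel | None = None,
    train_net1: bool = True,
    train_net2: bool = True,
) -> tuple[CascadeModel, dict[str, list[float]]]:
    """Train both nets simultaneously with disconnected losses.

    Returns the model and per-iteration loss traces ``{"midbrain": [...],
    "snpc": [...]}``.  Fully reproducible for a fixed ``cfg.seed``.  Passing an
    existing ``model`` continues training; ``train_net1``/``train_net2`` allow
    freezing one net (used to verify the disconnected-loss property).
    """
    pairs = _as_subject_arrays(subjects)
    if not pairs:
        raise ValueError("empty training set")
    m = 2 ** ((net_cfg or desk_net_config()).depth - 1)
    if cfg.crop_size % m:
        raise ValueError(f"crop_size {cfg.crop_size} not divisible by 2**(depth-1) = {m}")
    if model is None:
        model = build_cascade(net_cfg or desk_net_config(), seed=cfg.seed, train_config=cfg)
    else:
        model.train_config = cfg

    samples = _build_samples(pairs, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    opt1 = model.net_midbrain.optimizer(cfg.alpha, cfg.beta1, cfg.beta2)
    opt2 = model.net_snpc.optimizer(cfg.alpha, cfg.beta1, cfg.beta2)
    trace: dict[str, list[float]] = {"midbrain": [], "snpc": []}

    n = len(samples)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = [samples[j] for j in order[start : start + cfg.batch_size]]
            imgs, labs = [], []
            for img, lab in batch:
                ci, cl = _random_crop(img, lab, cfg.crop_size, rng)
                imgs.append(ci)
                labs.append(cl)
            x = np.stack(imgs) * cfg.input_scale
            lab = np.stack(labs)
            target_mb = (lab != Label.OUTSIDE).astype(np.int64)
            target_sn = (lab == Label.SNPC).astype(np.int64)
            weight_mb = (lab != Label.OUTSIDE).astype(np.float32)

            logits1 = model.net_midbrain.forward(x[:, None])
            loss1, dlogits1 = softmax_cross_entropy(logits1, target_mb)
            if train_net1:
                model.net_midbrain.zero_grad()
                model.net_midbrain.backward(dlogits1)
                opt1.step()
            trace["midbrain"].append(loss1)

            # net 2 sees net 1's current output but no gradient crosses back
            p_mb = softmax(logits1, axis=1)[:, 1]
            x2 = compose_second_input(x, p_mb, mode=cfg.second_input)
            logits2 = model.net_snpc.forward(x2)
            loss2, dlogits2 = softmax_cross_entropy(logits2, target_sn, weight=weight_mb)
            if train_net2 and weight_mb.sum() > 0:
                model.net_snpc.zero_grad()
                model.net_snpc.backward(dlogits2)
                opt2.step()
            trace["snpc"].append(loss2)
    return model, trace


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _pad_to_multiple(x: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[-2:]
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        x = np.pad(x, [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)], mode="reflect")
    return x, (ph, pw)


def predict(model: CascadeModel, image: ImageStack) -> LabelMask:
    """Segment a full stack: argmax of net 1 gates argmax of net 2.

    The whole image is processed (reflect-padded to the nearest multiple of
    ``2**(depth-1)``, then un-padded); pixels outside the predicted midbrain
    are OUTSIDE.  At exactly equal class probabilities the lower class index
    wins, so inference is deterministic.
    """
    scale = model.input_scale
    x = np.asarray(image.data, dtype=np.float32) * scale
    m = 2 ** (model.net_midbrain.depth - 1)
    xp, (ph, pw) = _pad_to_multiple(x, m)
    labels = np.zeros(xp.shape, dtype=np.uint8)
    for i in range(xp.shape[0]):
        xi = xp[i][None, None]
        p1 = model.net_midbrain.predict_proba(xi)[0]
        mb = np.argmax(p1, axis=0) == 1  # ties -> lower index (outside)
        x2 = compose_second_input(
            xp[i][None], p1[1][None], mode=model.train_config.second_input if model.train_config else "soft"
        )
        p2 = model.net_snpc.predict_proba(x2)[0]
        sn = np.argmax(p2, axis=0) == 1
        sl = np.zeros(xp.shape[1:], dtype=np.uint8)
        sl[mb] = Label.BACKGROUND
        sl[mb & sn] = Label.SNPC
        labels[i] = sl
    h, w = image.data.shape[1:]
    labels = labels[:, :h, :w]
    return LabelMask(labels, source=MaskSource.NETWORK, pixel_spacing=image.pixel_spacing)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def assign_folds(groups: Sequence[str], n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold labels with an HC:PD ratio as close to 1:1 as counts allow."""
    groups = np.asarray(groups)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    folds = np.full(len(groups), -1, dtype=int)
    for g in ("HC", "PD"):
        idx = np.flatnonzero(groups == g)
        if len(idx) < n_folds:
            raise ValueError(f"group {g} has {len(idx)} subjects; need >= {n_folds} for {n_folds} folds")
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[i] = j % n_folds
    return folds


def cross_validate(
    subjects: Sequence,
    groups: Sequence[str],
    cfg: TrainConfig,
    net_cfg: NetConfig | None = None,
) -> dict:
    """Stratified k-fold cross-validation of the cascade.

    Each fold is validated on itself after training on the remaining folds.
    Reports train/validation Dice per structure and designates the model of
    fold 1 (index 0) as the deployment model.
    """
    from .evalstats import dice_masks

    pairs = _as_subject_arrays(subjects)
    folds = assign_folds(groups, cfg.folds, cfg.seed)
    report: dict = {"folds": [], "fold_assignment": folds.tolist()}
    deployment = None
    traces: dict[int, dict[str, list[float]]] = {}
    for f in range(cfg.folds):
        val_idx = np.flatnonzero(folds == f)
        train_idx = np.flatnonzero(folds != f)
        model, trace = train_cascade([pairs[i] for i in train_idx], cfg, net_cfg=net_cfg)
        model.fold_id = f
        traces[f] = trace
        entry: dict = {"fold": f, "n_train": len(train_idx), "n_val": len(val_idx)}
        for split, idx in (("train", train_idx), ("val", val_idx)):
            mbs, sns = [], []
            for i in idx:
                img, truth = pairs[i]
                pred = predict(model, img)
                mbs.append(dice_masks(truth, pred, "midbrain"))
                sns.append(dice_masks(truth, pred, "snpc"))
            entry[f"{split}_dice_midbrain"] = float(np.mean(mbs))
            entry[f"{split}_dice_snpc"] = float(np.mean(sns))
        report["folds"].append(entry)
        if f == 0:
            deployment = model
    report["deployment_fold"] = 0
    return {"report": report, "model": deployment, "traces": traces}
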