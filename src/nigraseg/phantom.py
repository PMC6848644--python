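"""Synthetic neuromelanin-MRI midbrain phantoms with ground-truth masks.

Each phantom subject is a short axial stack in which the midbrain appears as a
convex "butterfly" region on two consecutive slices, containing two crescent
shaped SNpc sub-regions.  A controllable fraction of each crescent is rendered
hyperintense (mean ``mu_background + delta_snpc``); the Parkinson's-disease
effect is a reduced hyperintense extent, i.e. fewer suprathreshold SNpc pixels
and hence a smaller hyperintense area — the quantity the threshold statistic
measures.  Shapes are evaluated analytically on a jittered coordinate grid, so
truth masks are exact (no interpolation), and with ``sigma_noise = 0`` the
planted suprathreshold pixel count is recovered exactly downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

from .imageio import (
    CohortManifest,
    ImageStack,
    Label,
    LabelMask,
    MaskSource,
    SubjectRecord,
    save_manifest,
    write_image,
    write_mask,
)

__all__ = ["PhantomParams", "PhantomSubject", "generate_subject", "generate_cohort"]

Group = Literal["HC", "PD"]


@dataclass
class PhantomParams:
    """Generator settings.

    Geometry defaults mimic an oblique-axial neuromelanin acquisition:
    0.43 mm in-plane pixels, the midbrain present on two consecutive slices of
    a four-slice stack.  Intensity means are in arbitrary scanner-like units;
    ``snpc_extent`` is the group-wise fraction of anatomical SNpc pixels that
    are hyperintense (healthy ~0.95, Parkinson ~0.55).
    """

    image_size: tuple[int, int] = (128, 128)
    pixel_spacing: tuple[float, float] = (0.43, 0.43)
    n_slices: int = 4
    midbrain_slices: tuple[int, int] = (1, 2)
    mu_outside: float = 50.0
    mu_background: float = 100.0
    delta_snpc: float = 40.0
    sigma_noise: float = 8.0
    snpc_extent: dict[str, float] = field(default_factory=lambda: {"HC": 0.95, "PD": 0.55})
    extent_sd: float = 0.05  # per-subject spread of the hyperintense fraction
    # per-subject geometry jitter (uniform ranges)
    shift_px: float = 4.0
    rotation_deg: float = 8.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    pd_effect: Literal["extent", "delta"] = "extent"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, e in self.snpc_extent.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"snpc_extent[{g!r}] must be in [0,1], got {e}")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        i0, i1 = self.midbrain_slices
        if not (0 <= i0 and i1 == i0 + 1 and i1 < self.n_slices):
            raise ValueError("midbrain_slices must be two consecutive valid indices")


@dataclass
class PhantomSubject:
    image: ImageStack
    truth: LabelMask
    record: SubjectRecord
    true_hyperintense_fraction: float
    n_hyper_pixels: int  # planted suprathreshold pixels on the midbrain slices


def _subject_seed(cohort_seed: int, group: Group, index: int) -> int:
    """Deterministic per-subject seed from (cohort seed, group, index)."""
    ss = np.random.SeedSequence([int(cohort_seed), 0 if group == "HC" else 1, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def _ellipse(rr: np.ndarray, cc: np.ndarray, center: tuple[float, float],
             semi: tuple[float, float], angle_deg: float = 0.0) -> np.ndarray:
    """Boolean membership of a rotated ellipse on pixel-coordinate grids."""
    th = np.deg2rad(angle_deg)
    dr, dc = rr - center[0], cc - center[1]
    u = np.cos(th) * dr + np.sin(th) * dc
    v = -np.sin(th) * dr + np.cos(th) * dc
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def _render_slice(
    shape: tuple[int, int],
    shift: tuple[float, float],
    rot_deg: float,
    scale: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render (midbrain, snpc, lateral-coordinate) for one slice.

    Shapes are defined in a canonical frame and the pixel grid is pulled back
    through the inverse of the subject's similarity transform, so masks stay
    exact.  Returns the midbrain boolean, the SNpc boolean and, for SNpc
    pixels, a signed medial->lateral coordinate used to carve the hyperintense
    sub-region.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    # pull back to canonical coordinates centred on the midbrain
    rr0, cc0 = rr - (h / 2 + shift[0]), cc - (w / 2 + shift[1])
    th = np.deg2rad(rot_deg)
    r = (np.cos(th) * rr0 + np.sin(th) * cc0) / scale
    c = (-np.sin(th) * rr0 + np.cos(th) * cc0) / scale

    # midbrain: tegmentum body plus two anterior peduncle lobes (butterfly)
    body = _ellipse(r, c, (2.0, 0.0), (17.0, 23.0))
    lobes = _ellipse(r, c, (-10.0, -12.0), (11.0, 11.0)) | _ellipse(r, c, (-10.0, 12.0), (11.0, 11.0))
    midbrain = body | lobes

    # SNpc: one crescent per side = ellipse minus an anteriorly shifted copy
    snpc = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        centre = (-2.0, side * 11.0)
        outer = _ellipse(r, c, centre, (5.5, 10.5), angle_deg=side * 25.0)
        inner = _ellipse(r, c, (centre[0] - 4.5, centre[1]), (5.5, 10.5), angle_deg=side * 25.0)
        snpc |= outer & ~inner
    snpc &= midbrain
    lateral = np.abs(c)  # medial->lateral coordinate in the canonical frame
    return midbrain, snpc, lateral


def _carve_hyper(snpc: np.ndarray, lateral: np.ndarray, extent: float) -> np.ndarray:
    """Keep the medial ``extent`` fraction of SNpc pixels hyperintense.

    Parkinsonian signal loss preferentially involves the lateral SNpc, so the
    retained (hyperintense) pixels are the most medial ones.  Deterministic:
    pixels are ranked by the canonical lateral coordinate.
    """
    hyper = np.zeros_like(snpc)
    n = int(snpc.sum())
    if n == 0 or extent <= 0.0:
        return hyper
    k = min(n, int(round(extent * n)))
    if k == 0:
        return hyper
    idx = np.flatnonzero(snpc)
    order = np.argsort(lateral.ravel()[idx], kind="stable")
    hyper.ravel()[idx[order[:k]]] = True
    return hyper


def generate_subject(
    params: PhantomParams,
    group: Group,
    subject_seed: int,
    subject_id: str | None = None,
) -> PhantomSubject:
    """Generate one phantom subject; deterministic for fixed inputs.

    Jitter draws that leave the SNpc empty are regenerated with the next
    sub-seed, failing after 10 attempts.
    """
    if group not in ("HC", "PD"):
        raise ValueError(f"group must be HC or PD, got {group!r}")
    h, w = params.image_size
    sl0, sl1 = params.midbrain_slices

    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([int(subject_seed), attempt]))
        shift = tuple(rng.uniform(-params.shift_px, params.shift_px, size=2))
        rot = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
        scale = float(rng.uniform(*params.scale_range))
        base_extent = params.snpc_extent[group]
        extent = float(np.clip(rng.normal(base_extent, params.extent_sd), 0.0, 1.0))

        labels = np.zeros((params.n_slices, h, w), dtype=np.uint8)
        hyper = np.zeros((params.n_slices, h, w), dtype=bool)
        ok = True
        for j, sl in enumerate((sl0, sl1)):
            # the second slice is slightly smaller, as at the midbrain's edge
            mb, sn, lat = _render_slice((h, w), shift, rot, scale * (1.0 if j == 0 else 0.92))
            if sn.sum() < 8 or mb.sum() < 64:
                ok = False
                break
            labels[sl][mb] = Label.BACKGROUND
            labels[sl][sn] = Label.SNPC
            hyper[sl] = _carve_hyper(sn, lat, extent)
        if ok:
            break
    else:
        raise RuntimeError(f"empty phantom geometry after 10 attempts (seed {subject_seed})")

    delta = params.delta_snpc
    if params.pd_effect == "delta" and group == "PD":
        # alternative effect model: attenuated contrast over the full SNpc
        hyper = labels == Label.SNPC
        delta = params.delta_snpc * params.snpc_extent["PD"]

    img = np.full((params.n_slices, h, w), params.mu_outside, dtype=np.float64)
    img[labels != Label.OUTSIDE] = params.mu_background
    img[hyper] += delta
    if params.sigma_noise > 0:
        if params.noise_model == "rician":
            a = img + rng.normal(0.0, params.sigma_noise, img.shape)
            b = rng.normal(0.0, params.sigma_noise, img.shape)
            img = np.hypot(a, b)
        else:
            img = img + rng.normal(0.0, params.sigma_noise, img.shape)

    sid = subject_id or f"{group.lower()}{subject_seed:010d}"
    age = float(np.clip(rng.normal(70.0, 5.0), 45.0, 90.0))
    sex = "M" if rng.random() < 0.5 else "F"
    duration = updrs = None
    if group == "PD":
        duration = float(rng.uniform(2.0, 15.0))
        # motor severity tracks hyperintense loss, with clinical scatter
        updrs = float(max(0.0, 60.0 * (1.0 - extent) + rng.normal(0.0, 4.0)))
    record = SubjectRecord(sid, group, age=age, sex=sex, disease_duration=duration, updrs3=updrs)

    image = ImageStack(
        data=img,
        pixel_spacing=params.pixel_spacing,
        slice_thickness=2.5,
        slice_gap=0.5,
        subject_id=sid,
    )
    truth = LabelMask(labels, source=MaskSource.PHANTOM_TRUTH, pixel_spacing=params.pixel_spacing)
    n_snpc = int((labels == Label.SNPC).sum())
    n_hyper = int(hyper.sum())
    return PhantomSubject(
        image=image,
        truth=truth,
        record=record,
        true_hyperintense_fraction=n_hyper / max(n_snpc, 1),
        n_hyper_pixels=n_hyper,
    )


def generate_cohort(
    params: PhantomParams,
    n_hc: int,
    n_pd: int,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
    dataset_tag: str = "synthetic",
) -> tuple[CohortManifest, list[PhantomSubject]]:
    """Generate a cohort of phantom subjects, optionally writing it to disk.

    Per-subject seeds derive from ``params.seed`` and the (group, index) pair,
    so regeneration is order-independent and bit-reproducible.  With
    ``out_dir`` set, NIfTI images/truth masks and a manifest CSV are written;
    an existing non-empty directory requires ``overwrite=True``.
    """
    if n_hc < 1 or n_pd < 1:
        raise ValueError("need at least one subject per group")
    subjects: list[PhantomSubject] = []
    for group, n in (("HC", n_hc), ("PD", n_pd)):
        for i in range(n):
            seed = _subject_seed(params.seed, group, i)
            sid = f"{group.lower()}{i:03d}"
            subjects.append(generate_subject(params, group, seed, subject_id=sid))

    manifest = CohortManifest(records=[s.record for s in subjects], dataset_tag=dataset_tag)
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} exists and is not empty; pass overwrite=True")
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in subjects:
            sid = s.record.subject_id
            img_path = out_dir / f"{sid}_img.nii.gz"
            msk_path = out_dir / f"{sid}_truth.nii.gz"
            write_image(s.image, img_path)
            write_mask(s.truth, msk_path)
            manifest.image_paths[sid] = img_path
            manifest.truth_mask_paths[sid] = msk_path
        save_manifest(manifest, out_dir / "manifest.csv")
        prov = {
            "params": _params_dict(params),
            "n_hc": n_hc,
            "n_pd": n_pd,
            "dataset_tag": dataset_tag,
        }
        prov["config_sha256"] = hashlib.sha256(
            json.dumps(prov, sort_keys=True).encode()
        ).hexdigest()
        (out_dir / "provenance.json").write_text(json.dumps(prov, indent=2))
    return manifest, subjects


def _params_dict(params: PhantomParams) -> dict:
    d = asdict(params)
    d["image_size"] = list(params.image_size)
    return d
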