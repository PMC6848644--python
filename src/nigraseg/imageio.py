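"""Core data model and I/O: NM-MRI image stacks, label masks, cohort manifests.

Conventions
-----------
Arrays are row-major with 0-based indices; axis order is ``(slice, row, col)``
and the slice index increases superior -> inferior.  Masks use a three-letter
label alphabet (OUTSIDE / BACKGROUND / SNPC); the midbrain is by definition
``BACKGROUND | SNPC``.  On disk, masks are unsigned 8-bit NIfTI volumes with
the canonical encoding 0/1/2; other integer dialects are handled through an
explicit ``label_map``.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Label",
    "MaskSource",
    "ImageStack",
    "LabelMask",
    "SubjectRecord",
    "CohortManifest",
    "CANONICAL_LABEL_MAP",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
]


class Label(enum.IntEnum):
    """Per-pixel structure labels."""

    OUTSIDE = 0
    BACKGROUND = 1  # midbrain minus SNpc: the reference tissue
    SNPC = 2


class MaskSource(enum.Enum):
    MANUAL_READER1 = "manual_reader1"
    MANUAL_READER2 = "manual_reader2"
    NETWORK = "network"
    PHANTOM_TRUTH = "phantom_truth"


CANONICAL_LABEL_MAP: dict[int, Label] = {
    0: Label.OUTSIDE,
    1: Label.BACKGROUND,
    2: Label.SNPC,
}


@dataclass
class ImageStack:
    """An ordered stack of axial 2D grayscale slices with geometry metadata.

    Parameters
    ----------
    data:
        Float array of shape ``(n_slices, height, width)``; intensities are in
        arbitrary scanner units and must be finite.
    pixel_spacing:
        In-plane ``(row, col)`` spacing in mm (e.g. the 0.43 x 0.43 mm of a
        neuromelanin-sensitive acquisition).  Enters every area computation.
    slice_thickness, slice_gap:
        Through-plane geometry in mm; informational only.
    """

    data: np.ndarray
    pixel_spacing: tuple[float, float] = (0.43, 0.43)
    slice_thickness: float = 2.5
    slice_gap: float = 0.5
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected 2D or 3D data, got ndim={self.data.ndim}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"image contains {n_bad} non-finite voxel(s)")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    def copy(self, data: np.ndarray | None = None) -> "ImageStack":
        return ImageStack(
            data=self.data.copy() if data is None else data,
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness,
            slice_gap=self.slice_gap,
            subject_id=self.subject_id,
        )


@dataclass
class LabelMask:
    """Per-pixel structure labels aligned to an :class:`ImageStack`.

    The partition invariant holds by construction: every pixel carries exactly
    one of the three labels, and the midbrain region is ``BACKGROUND | SNPC``.
    """

    data: np.ndarray
    source: MaskSource = MaskSource.PHANTOM_TRUTH
    pixel_spacing: tuple[float, float] = (0.43, 0.43)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"expected 2D or 3D mask, got ndim={self.data.ndim}")
        valid = {int(l) for l in Label}
        present = set(np.unique(self.data).tolist())
        unknown = present - valid
        if unknown:
            raise ValueError(f"mask contains unknown label values: {sorted(unknown)}")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def region(self, which: str) -> np.ndarray:
        """Boolean region selector: 'midbrain', 'snpc', 'background' or 'outside'."""
        if which == "midbrain":
            return self.data != Label.OUTSIDE
        if which == "snpc":
            return self.data == Label.SNPC
        if which == "background":
            return self.data == Label.BACKGROUND
        if which == "outside":
            return self.data == Label.OUTSIDE
        raise ValueError(f"unknown region {which!r}")

    def check_alignment(self, image: ImageStack) -> None:
        if self.shape != image.shape:
            raise ValueError(f"mask shape {self.shape} != image shape {image.shape}")


@dataclass
class SubjectRecord:
    """One cohort row: identity, diagnostic group and optional clinical covariates."""

    subject_id: str
    group: str  # "HC" or "PD"
    age: float | None = None
    sex: str | None = None  # "M" / "F"
    disease_duration: float | None = None
    updrs3: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("HC", "PD"):
            raise ValueError(f"group must be 'HC' or 'PD', got {self.group!r}")


@dataclass
class CohortManifest:
    """A cohort: subject records plus image/mask file locations."""

    records: list[SubjectRecord] = field(default_factory=list)
    image_paths: dict[str, Path] = field(default_factory=dict)
    truth_mask_paths: dict[str, Path] = field(default_factory=dict)
    pred_mask_paths: dict[str, Path] = field(default_factory=dict)
    dataset_tag: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate subject ids: {dupes}")

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"HC": 0, "PD": 0}
        for r in self.records:
            counts[r.group] += 1
        return counts

    def subset(self, ids: Sequence[str]) -> "CohortManifest":
        keep = set(ids)
        return CohortManifest(
            records=[r for r in self.records if r.subject_id in keep],
            image_paths={k: v for k, v in self.image_paths.items() if k in keep},
            truth_mask_paths={k: v for k, v in self.truth_mask_paths.items() if k in keep},
            pred_mask_paths={k: v for k, v in self.pred_mask_paths.items() if k in keep},
            dataset_tag=self.dataset_tag,
        )


def _affine(pixel_spacing: tuple[float, float], slice_spacing: float) -> np.ndarray:
    return np.diag([pixel_spacing[0], pixel_spacing[1], slice_spacing, 1.0])


def write_image(image: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a 3D NIfTI volume."""
    path = Path(path)
    # in-memory (slice,row,col) -> on-disk (row,col,slice)
    vol = np.ascontiguousarray(np.transpose(image.data, (1, 2, 0)).astype(np.float32))
    aff = _affine(image.pixel_spacing, image.slice_thickness + image.slice_gap)
    nib.save(nib.Nifti1Image(vol, aff), str(path))
    return path


def read_image(path: str | Path) -> ImageStack:
    """Read a NIfTI image into an :class:`ImageStack`.

    A 2D file is promoted to a 1-slice stack.  Pixel spacing is taken from the
    header zooms; non-finite voxels raise with their count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj).astype(np.float64)
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D image, got shape {arr.shape}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    slice_spacing = float(zooms[2]) if len(zooms) > 2 else 1.0
    data = np.transpose(arr, (2, 0, 1))
    return ImageStack(
        data=data,
        pixel_spacing=spacing,
        slice_thickness=slice_spacing,  # header stores spacing between slices
        slice_gap=0.0,
        subject_id=path.name.split(".")[0],
    )


def write_mask(
    mask: LabelMask,
    path: str | Path,
    label_map: Mapping[int, Label] | None = None,
    reference: ImageStack | None = None,
) -> Path:
    """Write a :class:`LabelMask` as an integer NIfTI volume.

    ``label_map`` maps on-disk integers to labels (canonical 0/1/2 by default);
    an optional ``reference`` image enforces geometric alignment first.
    """
    path = Path(path)
    if reference is not None:
        mask.check_alignment(reference)
    label_map = dict(label_map or CANONICAL_LABEL_MAP)
    inverse = {lab: code for code, lab in label_map.items()}
    missing = [lab for lab in Label if lab not in inverse]
    if missing:
        raise ValueError(f"label_map does not encode labels {missing}")
    out = np.zeros(mask.data.shape, dtype=np.uint8)
    for lab, code in inverse.items():
        out[mask.data == lab] = code
    vol = np.ascontiguousarray(np.transpose(out, (1, 2, 0)))
    aff = _affine(mask.pixel_spacing, 1.0)
    nib.save(nib.Nifti1Image(vol, aff), str(path))
    return path


def read_mask(
    path: str | Path,
    label_map: Mapping[int, Label] | None = None,
    source: MaskSource = MaskSource.PHANTOM_TRUTH,
) -> LabelMask:
    """Read an integer NIfTI mask, translating on-disk codes via ``label_map``.

    Every integer present in the file must be covered by the map; unknown
    values raise and are listed in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded):
            raise ValueError(f"{path}: mask voxels are not integer-valued")
        arr = rounded.astype(np.int64)
    label_map = dict(label_map or CANONICAL_LABEL_MAP)
    present = np.unique(arr)
    unknown = [int(v) for v in present if int(v) not in label_map]
    if unknown:
        raise ValueError(f"{path}: unmapped mask values {unknown}")
    zooms = img.header.get_zooms()
    out = np.zeros(arr.shape, dtype=np.uint8)
    for code, lab in label_map.items():
        out[arr == code] = int(lab)
    data = np.transpose(out, (2, 0, 1))
    return LabelMask(data=data, source=source, pixel_spacing=(float(zooms[0]), float(zooms[1])))


MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "disease_duration",
    "updrs3",
    "image",
    "mask_truth",
    "mask_pred",
]


def save_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    """Write the cohort table as CSV (paths stored relative to the CSV)."""
    path = Path(path)
    base = path.parent
    rows = []
    for r in manifest.records:
        sid = r.subject_id

        def rel(p: Path | None) -> str:
            if p is None:
                return ""
            return os.path.relpath(Path(p).resolve(), base.resolve())

        rows.append(
            {
                "subject_id": sid,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "disease_duration": r.disease_duration,
                "updrs3": r.updrs3,
                "image": rel(manifest.image_paths.get(sid)),
                "mask_truth": rel(manifest.truth_mask_paths.get(sid)),
                "mask_pred": rel(manifest.pred_mask_paths.get(sid)),
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_manifest(path: str | Path, dataset_tag: str = "synthetic") -> CohortManifest:
    """Load and validate a cohort manifest CSV.

    Required columns: subject_id, group, image, mask_truth.  Group tokens must
    be exactly ``HC`` or ``PD``; ids must be unique; referenced paths must
    resolve (relative to the CSV's directory).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = ["subject_id", "group", "image", "mask_truth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    base = path.parent

    records: list[SubjectRecord] = []
    image_paths: dict[str, Path] = {}
    truth_paths: dict[str, Path] = {}
    pred_paths: dict[str, Path] = {}
    for i, row in df.iterrows():
        group = str(row["group"]).strip()
        if group not in ("HC", "PD"):
            raise ValueError(f"{path} row {i}: unknown group token {group!r} (expected HC or PD)")

        def opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        sex = None
        if "sex" in df.columns and not pd.isna(row["sex"]):
            sex = str(row["sex"])
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=group,
            age=opt("age"),
            sex=sex,
            disease_duration=opt("disease_duration"),
            updrs3=opt("updrs3"),
        )
        records.append(rec)
        for col, store in (("image", image_paths), ("mask_truth", truth_paths), ("mask_pred", pred_paths)):
            if col not in df.columns or pd.isna(row[col]) or str(row[col]) == "":
                if col == "mask_pred":
                    continue
                raise ValueError(f"{path} row {i}: empty {col}")
            p = Path(str(row[col]))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"{path} row {i}: {col} path {p} does not exist")
            store[rec.subject_id] = p

    manifest = CohortManifest(
        records=records,
        image_paths=image_paths,
        truth_mask_paths=truth_paths,
        pred_mask_paths=pred_paths,
        dataset_tag=dataset_tag,
    )
    return manifest
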