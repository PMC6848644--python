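"""Training-time augmentation: intensity affine deviation, rotation, rescaling.

The intensity deviation follows the form ``A * (orig + B)`` with gains
A in {0.7, 1.0, 1.3} and offsets B in {-100, 0, 100}; geometric deviations are
in-plane rotations of +/-30 degrees and rescaling to 90/100/110% of the
original size.  Image and mask are always transformed together: bilinear
interpolation for intensities, nearest-neighbour for labels so the label
alphabet is preserved.  Because the gain A is positive, intensity deviation is
monotone on pixels and therefore leaves the background-referenced
suprathreshold set of the quantification stage unchanged.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imageio import ImageStack, Label, LabelMask

__all__ = [
    "AugmentSpec",
    "intensity_transform",
    "rotate_pair",
    "rescale_pair",
    "enumerate_augmentations",
]


@dataclass
class AugmentSpec:
    """The grid of deviations applied to each training subject.

    ``combine='cartesian'`` crosses all four axes (81 variants at defaults);
    ``'per_category'`` applies one axis at a time (13 variants at defaults,
    the identity counted once).
    """

    A_values: tuple[float, ...] = (0.7, 1.0, 1.3)
    B_values: tuple[float, ...] = (-100.0, 0.0, 100.0)
    angles: tuple[float, ...] = (-30.0, 0.0, 30.0)
    scales: tuple[float, ...] = (0.9, 1.0, 1.1)
    combine: str = "cartesian"

    def __post_init__(self) -> None:
        for name, vals in (
            ("A_values", self.A_values),
            ("B_values", self.B_values),
            ("angles", self.angles),
            ("scales", self.scales),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.combine not in ("cartesian", "per_category"):
            raise ValueError(f"unknown combine mode {self.combine!r}")

    @staticmethod
    def identity() -> "AugmentSpec":
        return AugmentSpec(A_values=(1.0,), B_values=(0.0,), angles=(0.0,), scales=(1.0,))

    def variants(self) -> list[tuple[float, float, float, float]]:
        """The (A, B, angle, scale) tuples this spec enumerates."""
        if self.combine == "cartesian":
            return list(itertools.product(self.A_values, self.B_values, self.angles, self.scales))
        out: list[tuple[float, float, float, float]] = [(1.0, 0.0, 0.0, 1.0)]
        for a, b in itertools.product(self.A_values, self.B_values):
            if (a, b) != (1.0, 0.0):
                out.append((a, b, 0.0, 1.0))
        out.extend((1.0, 0.0, ang, 1.0) for ang in self.angles if ang != 0.0)
        out.extend((1.0, 0.0, 0.0, s) for s in self.scales if s != 1.0)
        return out


def intensity_transform(image: ImageStack, A: float, B: float) -> ImageStack:
    """Affine intensity deviation: every pixel becomes ``A * (orig + B)``."""
    if not (math.isfinite(A) and math.isfinite(B)):
        raise ValueError("A and B must be finite")
    return image.copy(data=A * (image.data + B))


def _rotate_arrays(
    img: np.ndarray, msk: np.ndarray, angle: float, img_cval: float
) -> tuple[np.ndarray, np.ndarray]:
    if angle == 0.0:
        return img.copy(), msk.copy()
    img_out = np.empty_like(img)
    msk_out = np.empty_like(msk)
    for i in range(img.shape[0]):
        img_out[i] = ndimage.rotate(
            img[i], angle, reshape=False, order=1, mode="constant", cval=img_cval
        )
        msk_out[i] = ndimage.rotate(
            msk[i], angle, reshape=False, order=0, mode="constant", cval=int(Label.OUTSIDE)
        )
    return img_out, msk_out


def rotate_pair(image: ImageStack, mask: LabelMask, angle: float) -> tuple[ImageStack, LabelMask]:
    """Rotate image (bilinear) and mask (nearest) about the slice centre.

    Pixels rotated in from outside the canvas take the image minimum /
    OUTSIDE, so the label alphabet never grows.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    mask.check_alignment(image)
    cval = float(image.data.min())
    img, msk = _rotate_arrays(image.data, mask.data, angle, cval)
    return image.copy(data=img), LabelMask(msk, source=mask.source, pixel_spacing=mask.pixel_spacing)


def _center_fit(arr: np.ndarray, shape: tuple[int, int], fill) -> np.ndarray:
    """Center-crop or pad a 2D array to ``shape``."""
    out = np.full(shape, fill, dtype=arr.dtype)
    h, w = arr.shape
    H, W = shape
    r0 = max((h - H) // 2, 0)
    c0 = max((w - W) // 2, 0)
    R0 = max((H - h) // 2, 0)
    C0 = max((W - w) // 2, 0)
    hh, ww = min(h, H), min(w, W)
    out[R0 : R0 + hh, C0 : C0 + ww] = arr[r0 : r0 + hh, c0 : c0 + ww]
    return out


def rescale_pair(
    image: ImageStack, mask: LabelMask, factor: float
) -> tuple[ImageStack, LabelMask]:
    """Resize contents by ``factor`` while keeping the canvas size.

    The slice is zoomed (bilinear / nearest) and then centre-cropped or padded
    back to the original height x width.  A factor small enough to erase the
    midbrain only warns.
    """
    if not (math.isfinite(factor) and factor > 0):
        raise ValueError("factor must be positive and finite")
    mask.check_alignment(image)
    if factor == 1.0:
        return image.copy(), LabelMask(
            mask.data.copy(), source=mask.source, pixel_spacing=mask.pixel_spacing
        )
    shape = image.data.shape[1:]
    cval = float(image.data.min())
    img_out = np.empty_like(image.data)
    msk_out = np.empty_like(mask.data)
    for i in range(image.data.shape[0]):
        zi = ndimage.zoom(image.data[i], factor, order=1, mode="constant", cval=cval)
        zm = ndimage.zoom(mask.data[i], factor, order=0, mode="constant", cval=int(Label.OUTSIDE))
        img_out[i] = _center_fit(zi, shape, cval)
        msk_out[i] = _center_fit(zm, shape, np.uint8(Label.OUTSIDE))
    new_mask = LabelMask(msk_out, source=mask.source, pixel_spacing=mask.pixel_spacing)
    if (mask.data != Label.OUTSIDE).any() and not (msk_out != Label.OUTSIDE).any():
        warnings.warn(f"rescale factor {factor} erased the midbrain", stacklevel=2)
    return image.copy(data=img_out), new_mask


def apply_variant(
    image: ImageStack, mask: LabelMask, variant: tuple[float, float, float, float]
) -> tuple[ImageStack, LabelMask]:
    """Apply one (A, B, angle, scale) deviation: intensity, then rotation, then scale."""
    A, B, angle, scale = variant
    img = intensity_transform(image, A, B) if (A, B) != (1.0, 0.0) else image.copy()
    msk = LabelMask(mask.data.copy(), source=mask.source, pixel_spacing=mask.pixel_spacing)
    if angle != 0.0:
        img, msk = rotate_pair(img, msk, angle)
    if scale != 1.0:
        img, msk = rescale_pair(img, msk, scale)
    return img, msk


def enumerate_augmentations(
    image: ImageStack, mask: LabelMask, spec: AugmentSpec
) -> list[tuple[ImageStack, LabelMask]]:
    """Materialize every augmented (image, mask) variant of one subject."""
    mask.check_alignment(image)
    return [apply_variant(image, mask, v) for v in spec.variants()]
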