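"""Image loading, intensity normalization and quadrant patch splitting.

A source micrograph (nominally 512x512) is divided into four non-overlapping
quadrant patches; each patch is the unit of classification.  The on-disk
dataset layout is ``<root>/<modality>/<label>/<source_id>.png`` (PNG or TIFF,
8/16-bit, gray or RGB).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np

from .exceptions import DimensionError, ValidationError

MODALITIES = ("SEM", "AFM")
LABELS = ("normal", "benign", "malignant")

#: ITU-R BT.601 luma coefficients used to collapse RGB to a single channel.
_LUMA = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class ImagePatch:
    """One square grayscale patch with its provenance.

    ``pixels`` are intensities normalized to [0, 1]; the side must be a
    power of two (>= 16) so a 4-level dyadic wavelet decomposition is exact.
    """

    pixels: np.ndarray
    modality: str
    label: Optional[str] = None
    source_id: str = ""
    patch_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise DimensionError(
                f"patch must be square 2-D, got shape {px.shape}"
            )
        if not _is_power_of_two(px.shape[0]) or px.shape[0] < 16:
            raise DimensionError(
                f"patch side must be a power of 2 >= 16, got {px.shape[0]}"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if px.size and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise ValidationError(
                "patch intensities must lie in [0, 1] after normalization"
            )
        self.pixels = px

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def load_image(path: str | Path, modality: str) -> np.ndarray:
    """Read a raster image and return a 2-D float array scaled to [0, 1].

    RGB(A) input is collapsed to luminance before scaling.  Integer images
    are divided by their dtype maximum (not the observed maximum) so that
    absolute brightness differences between images survive normalization.
    """
    if modality not in MODALITIES:
        raise ValidationError(f"unknown modality {modality!r}")
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr[:, :, :3].astype(np.float64) @ _LUMA
        scale = np.float64(np.iinfo(raw.dtype).max) if np.issubdtype(
            raw.dtype, np.integer) else 1.0
        img = arr / scale
    elif arr.ndim == 2:
        if np.issubdtype(arr.dtype, np.integer):
            img = arr.astype(np.float64) / np.iinfo(arr.dtype).max
        else:
            img = arr.astype(np.float64)
    else:
        raise OSError(f"could not read image {path}: unsupported ndim {arr.ndim}")

    img = np.clip(img, 0.0, 1.0)
    if img.size and np.ptp(img) == 0:
        warnings.warn(f"image {path} has zero variance", stacklevel=2)
    return img


def split_image(
    image: np.ndarray,
    patch_side: int = 256,
    *,
    modality: str = "SEM",
    label: Optional[str] = None,
    source_id: str = "",
) -> list[ImagePatch]:
    """Split a square image into 4 quadrant patches, row-major from top-left.

    The image side must equal ``2 * patch_side``.  Quadrant order (top-left,
    top-right, bottom-left, bottom-right) is fixed so ``patch_index`` is
    stable across runs; concatenating the patches back in this order
    reconstructs the image exactly.
    """
    image = np.asarray(image, dtype=np.float64)
    expected = 2 * patch_side
    if image.ndim != 2 or image.shape != (expected, expected):
        raise DimensionError(
            f"expected a {expected}x{expected} image for patch_side="
            f"{patch_side}, got shape {image.shape}"
        )
    patches = []
    for idx, (r, c) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        block = image[
            r * patch_side:(r + 1) * patch_side,
            c * patch_side:(c + 1) * patch_side,
        ]
        patches.append(
            ImagePatch(
                pixels=block.copy(),
                modality=modality,
                label=label,
                source_id=source_id,
                patch_index=idx,
            )
        )
    return patches


def assemble_quadrants(patches: list[ImagePatch]) -> np.ndarray:
    """Inverse of :func:`split_image` (used for round-trip checks)."""
    if len(patches) != 4:
        raise DimensionError(f"need exactly 4 patches, got {len(patches)}")
    ordered = sorted(patches, key=lambda p: p.patch_index)
    top = np.hstack([ordered[0].pixels, ordered[1].pixels])
    bottom = np.hstack([ordered[2].pixels, ordered[3].pixels])
    return np.vstack([top, bottom])


def iter_dataset(
    root: str | Path, patch_side: Optional[int] = None
) -> Iterator[ImagePatch]:
    """Walk ``<root>/<modality>/<label>/<source_id>.{png,tif}`` and yield patches.

    ``patch_side=None`` infers half the image side (the quadrant split).
    """
    root = Path(root)
    for modality in MODALITIES:
        for label in LABELS:
            folder = root / modality / label
            if not folder.is_dir():
                continue
            for path in sorted(folder.iterdir()):
                if path.suffix.lower() not in _IMAGE_SUFFIXES:
                    continue
                image = load_image(path, modality)
                yield from split_image(
                    image,
                    patch_side if patch_side is not None else image.shape[0] // 2,
                    modality=modality,
                    label=label,
                    source_id=path.stem,
                )
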