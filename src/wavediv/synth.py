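"""Seeded generator of SEM-like and AFM-like texture images in three classes.

The generator emulates only the statistical structure the downstream
classifier consumes: a smoothed Gaussian random field (tissue background),
Poisson-placed bright blobs (nuclear enlargement — denser and higher-contrast
in malignant texture), a modality filter (SEM: high-frequency grain; AFM:
low-pass smoothing) and additive sensor noise.  Class parameters are ordered
monotonically normal < benign < malignant in blob density and contrast so
that a scalar malignancy score lands benign between the other two.

``separation`` linearly scales each class's parameter offset from the middle
(benign) class: at ``separation=0`` all three classes are drawn from the same
distribution, which is the null used by the chance-level checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DimensionError, ValidationError
from .imaging import ImagePatch, LABELS, MODALITIES, split_image


@dataclass(frozen=True)
class ClassParams:
    """Texture parameters of one class.

    correlation_length : px, Gaussian-blur sigma of the background field
    contrast           : std of background intensity (intensity units)
    blob_density       : expected blob count per 10^4 px
    noise_sd           : additive Gaussian noise sd (intensity units)
    """

    correlation_length: float
    contrast: float
    blob_density: float
    noise_sd: float


@dataclass(frozen=True)
class ModalityParams:
    """Modality filter: SEM grain gain and/or AFM low-pass radius (px)."""

    grain_gain: float = 0.0
    smooth_radius: float = 0.0


# Frozen defaults: monotone normal < benign < malignant in blob_density and
# contrast; calibrated once for the default pipeline and not revisited.
DEFAULT_CLASS_PARAMS: Dict[str, ClassParams] = {
    "normal": ClassParams(6.0, 0.05, 1.5, 0.02),
    "benign": ClassParams(4.5, 0.09, 4.0, 0.02),
    "malignant": ClassParams(3.0, 0.13, 7.0, 0.02),
}

DEFAULT_MODALITY_PARAMS: Dict[str, ModalityParams] = {
    "SEM": ModalityParams(grain_gain=0.04),
    "AFM": ModalityParams(smooth_radius=1.2),
}

_BLOB_SIGMA = 4.0  # px
_BLOB_AMPLITUDE = 0.25
_BASELINE = 0.45


@dataclass(frozen=True)
class SynthConfig:
    n_per_class_per_modality: int = 30
    image_side: int = 256
    seed: int = 0
    class_params: Dict[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    modality_params: Dict[str, ModalityParams] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_PARAMS)
    )
    separation: float = 1.0

    def effective_class_params(self) -> Dict[str, ClassParams]:
        """Interpolate each class toward the middle (benign) parameters.

        separation=1 returns the configured parameters unchanged;
        separation=0 collapses all classes onto the benign values.
        """
        if self.separation < 0:
            raise ValidationError("separation must be >= 0")
        mid = self.class_params["benign"]
        out = {}
        for label, cp in self.class_params.items():
            out[label] = ClassParams(
                correlation_length=mid.correlation_length
                + self.separation * (cp.correlation_length - mid.correlation_length),
                contrast=mid.contrast + self.separation * (cp.contrast - mid.contrast),
                blob_density=mid.blob_density
                + self.separation * (cp.blob_density - mid.blob_density),
                noise_sd=cp.noise_sd,
            )
        return out


def _render_blobs(img: np.ndarray, rng: np.random.Generator, density: float) -> None:
    """Add Poisson-placed Gaussian bumps in place."""
    side = img.shape[0]
    n_blobs = rng.poisson(density * side * side / 1e4)
    half = int(np.ceil(4 * _BLOB_SIGMA))
    ax = np.arange(-half, half + 1, dtype=np.float64)
    bump = _BLOB_AMPLITUDE * np.exp(
        -(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * _BLOB_SIGMA**2)
    )
    for _ in range(n_blobs):
        cy, cx = rng.integers(0, side, size=2)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, side)
        x0, x1 = max(cx - half, 0), min(cx + half + 1, side)
        img[y0:y1, x0:x1] += bump[
            y0 - (cy - half): y1 - (cy - half),
            x0 - (cx - half): x1 - (cx - half),
        ]


def generate_image(
    rng: np.random.Generator,
    class_params: ClassParams,
    modality_params: ModalityParams,
    side: int,
) -> np.ndarray:
    """One synthetic source image in [0, 1]."""
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((side, side)),
        class_params.correlation_length,
        mode="wrap",
    )
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    img = _BASELINE + class_params.contrast * field_
    _render_blobs(img, rng, class_params.blob_density)

    if modality_params.grain_gain > 0:
        grain = rng.standard_normal((side, side))
        grain -= ndimage.gaussian_filter(grain, 1.0, mode="wrap")
        img = img + modality_params.grain_gain * grain
    if modality_params.smooth_radius > 0:
        img = ndimage.gaussian_filter(img, modality_params.smooth_radius, mode="wrap")

    img = img + rng.normal(0.0, class_params.noise_sd, size=(side, side))
    return np.clip(img, 0.0, 1.0)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


def subject_id(label: str, index: int) -> str:
    return f"{label[0]}{index:03d}"


def source_id(label: str, modality: str, index: int) -> str:
    return f"{label[0]}{modality}{index:03d}"


def generate_dataset(config: SynthConfig) -> List[ImagePatch]:
    """Generate the full labeled patch collection for a config.

    Each of the ``n_per_class_per_modality`` source images per (class,
    modality) cell is rendered at ``image_side`` and quadrant-split into four
    patches of side ``image_side/2``.  Identical config (including seed)
    yields bit-identical arrays: every image gets its own child of
    ``SeedSequence(seed)`` in a fixed iteration order.
    """
    if not _is_power_of_two(config.image_side):
        raise DimensionError(
            f"image_side must be a power of 2, got {config.image_side}"
        )
    if config.n_per_class_per_modality < 1:
        raise ValidationError("n_per_class_per_modality must be >= 1")
    eff = config.effective_class_params()
    n = config.n_per_class_per_modality
    children = np.random.SeedSequence(config.seed).spawn(2 * 3 * n)
    patches: List[ImagePatch] = []
    k = 0
    for modality in MODALITIES:
        mp = config.modality_params[modality]
        for label in LABELS:
            cp = eff[label]
            for i in range(n):
                rng = np.random.default_rng(children[k])
                k += 1
                image = generate_image(rng, cp, mp, config.image_side)
                patches.extend(
                    split_image(
                        image,
                        config.image_side // 2,
                        modality=modality,
                        label=label,
                        source_id=source_id(label, modality, i),
                    )
                )
    return patches


def manifest_frame(config: SynthConfig) -> pd.DataFrame:
    """Source-level manifest: one row per generated image."""
    rows = []
    for modality in MODALITIES:
        for label in LABELS:
            for i in range(config.n_per_class_per_modality):
                rows.append(
                    {
                        "source_id": source_id(label, modality, i),
                        "subject_id": subject_id(label, i),
                        "modality": modality,
                        "label": label,
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows)


def write_dataset(config: SynthConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset layout ``<out>/<modality>/<label>/<source_id>.png``.

    Images are written as 16-bit grayscale PNG plus a ``manifest.csv``;
    returns the manifest frame.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    patches = generate_dataset(config)
    # regroup patches back into source images for writing
    by_source: Dict[str, list] = {}
    for p in patches:
        by_source.setdefault(p.source_id, []).append(p)
    manifest = manifest_frame(config)
    for row in manifest.itertuples():
        quad = sorted(by_source[row.source_id], key=lambda p: p.patch_index)
        top = np.hstack([quad[0].pixels, quad[1].pixels])
        bottom = np.hstack([quad[2].pixels, quad[3].pixels])
        image = np.vstack([top, bottom])
        folder = out_dir / row.modality / row.label
        folder.mkdir(parents=True, exist_ok=True)
        iio.imwrite(
            folder / f"{row.source_id}.png",
            np.round(image * 65535).astype(np.uint16),
        )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
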