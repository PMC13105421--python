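"""4-level 2-D discrete wavelet decomposition and per-subband statistics.

Each patch is decomposed with an orthonormal Daubechies wavelet (db4 by
default) in *periodization* mode.  Periodization is deliberate: it is the
one standard boundary mode that gives exact dyadic subband sizes (an N-side
patch has N/2^l-side bands at level l) and preserves energy (Parseval), so
the normalized-energy feature NE_B = sum(C_B^2) / sum(I^2) of the 13 stored
bands sums to exactly 1.

Stored bands: the approximation at the deepest level (CA4 for 4 levels) and
the horizontal/vertical/diagonal details (CH, CV, CD) at every level —
13 bands for 4 levels.  Seven statistics per band (energy, entropy, mean,
std, skewness, kurtosis, NE) give the 91-attribute feature vector.

Conventions (documented because the literature is ambiguous):

* std is the population standard deviation (divisor n);
* skewness and kurtosis are the standardized 3rd/4th central moments;
  kurtosis is NOT excess (a Gaussian band scores ~3);
* entropy is the Shannon entropy in bits of a 64-bin histogram of the
  band's coefficients over the band's own [min, max];
* zero-variance bands score skewness = kurtosis = entropy = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pywt

from .exceptions import ConfigurationError, DimensionError
from .imaging import ImagePatch

DETAIL_BANDS = ("CH", "CV", "CD")
STATS = ("energy", "entropy", "mean", "std", "skewness", "kurtosis", "NE")
DEFAULT_WAVELET = "db4"
DEFAULT_LEVELS = 4
DEFAULT_ENTROPY_BINS = 64


def band_names(levels: int = DEFAULT_LEVELS) -> List[str]:
    """Fixed band order: CA<levels>, then CH1..CHL, CV1..CVL, CD1..CDL."""
    names = [f"CA{levels}"]
    for b in DETAIL_BANDS:
        names.extend(f"{b}{l}" for l in range(1, levels + 1))
    return names


def attribute_names(levels: int = DEFAULT_LEVELS) -> List[str]:
    """Fixed attribute order (band-major): ``{stat}_{band}{level}``.

    This ordering is load-bearing: divergence weights are indexed by
    position, so it must be stable across runs and serializations.
    """
    return [f"{s}_{b}" for b in band_names(levels) for s in STATS]


@dataclass
class SubbandSet:
    """DWT coefficient arrays keyed by (level, band-kind).

    ``coefficients[(l, "CH")]`` is the level-l horizontal detail;
    ``coefficients[(levels, "CA")]`` is the deepest approximation.
    """

    coefficients: Dict[Tuple[int, str], np.ndarray]
    wavelet_name: str
    boundary_mode: str
    levels: int

    def band(self, name: str) -> np.ndarray:
        """Look up a band by display name, e.g. ``"CH3"`` or ``"CA4"``."""
        kind, level = name[:2], int(name[2:])
        return self.coefficients[(level, kind)]


@dataclass
class FeatureVector:
    """Ordered attribute -> value map for one patch, with provenance."""

    values: Dict[str, float]
    modality: str
    label: Optional[str] = None
    source_id: str = ""
    patch_index: int = 0

    def as_array(self, attributes: Sequence[str]) -> np.ndarray:
        return np.array([self.values[a] for a in attributes], dtype=np.float64)


def dwt_decompose(
    patch: ImagePatch,
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
) -> SubbandSet:
    """Multilevel separable 2-D DWT with periodized boundary handling."""
    side = patch.side
    if side % (2**levels) != 0:
        raise DimensionError(
            f"patch side {side} not divisible by 2^{levels}"
        )
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ConfigurationError(f"unknown wavelet {wavelet_name!r}") from exc

    coeffs = pywt.wavedec2(patch.pixels, wavelet, mode="periodization", level=levels)
    out: Dict[Tuple[int, str], np.ndarray] = {(levels, "CA"): coeffs[0]}
    # pywt orders details coarsest-first: coeffs[k] is level (levels - k + 1)
    for k in range(1, levels + 1):
        level = levels - k + 1
        ch, cv, cd = coeffs[k]
        out[(level, "CH")] = ch
        out[(level, "CV")] = cv
        out[(level, "CD")] = cd
    return SubbandSet(out, wavelet_name, "periodization", levels)


def normalized_energy(band: np.ndarray, patch: ImagePatch | np.ndarray) -> float:
    """NE = sum(|C|^2) / sum(|I|^2): fraction of patch energy in one band.

    ``patch`` may be an ImagePatch or a bare intensity array.
    """
    pixels = patch.pixels if hasattr(patch, "pixels") else np.asarray(patch)
    total = float(np.sum(np.square(pixels)))
    if total == 0.0:
        import warnings

        warnings.warn("all-zero patch: normalized energy defined as 0", stacklevel=2)
        return 0.0
    return float(np.sum(np.square(band)) / total)


def _band_entropy(values: np.ndarray, bins: int) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-np.sum(p * np.log2(p)))


def extract_features(
    subbands: SubbandSet,
    patch: ImagePatch,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
) -> FeatureVector:
    """Seven statistics for each of the 13 stored subbands."""
    patch_energy = float(np.sum(np.square(patch.pixels)))
    values: Dict[str, float] = {}
    for name in band_names(subbands.levels):
        c = subbands.band(name).ravel()
        energy = float(np.sum(np.square(c)))
        mean = float(c.mean())
        std = float(c.std())  # population (divisor n)
        if std > 0:
            centered = c - mean
            skew = float(np.mean(centered**3) / std**3)
            kurt = float(np.mean(centered**4) / std**4)
        else:
            skew = kurt = 0.0
        entropy = _band_entropy(c, entropy_bins)
        ne = 0.0 if patch_energy == 0 else energy / patch_energy
        values[f"energy_{name}"] = energy
        values[f"entropy_{name}"] = entropy
        values[f"mean_{name}"] = mean
        values[f"std_{name}"] = std
        values[f"skewness_{name}"] = skew
        values[f"kurtosis_{name}"] = kurt
        values[f"NE_{name}"] = ne
    return FeatureVector(
        values=values,
        modality=patch.modality,
        label=patch.label,
        source_id=patch.source_id,
        patch_index=patch.patch_index,
    )


METADATA_COLUMNS = ["source_id", "patch_index", "modality", "label"]


def features_dataframe(
    patches: Sequence[ImagePatch],
    wavelet_name: str = DEFAULT_WAVELET,
    levels: int = DEFAULT_LEVELS,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
) -> pd.DataFrame:
    """Feature matrix: one row per patch, metadata + 91 attribute columns."""
    attrs = attribute_names(levels)
    rows = []
    for patch in patches:
        fv = extract_features(dwt_decompose(patch, wavelet_name, levels), patch,
                              entropy_bins)
        row = {
            "source_id": fv.source_id,
            "patch_index": fv.patch_index,
            "modality": fv.modality,
            "label": fv.label,
        }
        row.update({a: fv.values[a] for a in attrs})
        rows.append(row)
    return pd.DataFrame(rows, columns=METADATA_COLUMNS + attrs)
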