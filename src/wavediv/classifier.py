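"""The d-test: weighted divergence from the normal class, banded into
normal / benign / malignant, with likelihood posteriors and SEM+AFM fusion.

A test patch's attribute value is turned into a point-mass distribution on
the attribute's shared bins (same smoothing kernel and floor as training),
and its divergence from the *normal* class reference is averaged with the
trained attribute weights.  Normal patches therefore score low and
malignant patches high.  Because the raw score's scale depends on the data,
a monotone piecewise-linear calibration anchors the training-class median
raw scores at d = 0.2 / 0.5 / 0.8, after which the fixed decision bands

    d in [0, 0.4)  -> normal
    d in [0.4, 0.6) -> benign
    d in [0.6, 1]  -> malignant

are meaningful on any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .distributions import ClassReference, point_mass_columns
from .divergence import DIVERGENCE_KINDS, WeightVector, divergence_rows
from .exceptions import ConfigurationError, ValidationError
from .imaging import LABELS
from .wavelet_features import METADATA_COLUMNS, FeatureVector

BAND_EDGES = (0.4, 0.6)
CALIBRATION_TARGETS = (0.2, 0.5, 0.8)


@dataclass
class CalibrationMap:
    """Monotone piecewise-linear map from raw weighted divergence to [0, 1].

    ``raw_anchors`` are the training-class median raw scores (normal,
    benign, malignant) mapped to ``targets``; the map extends the end
    segments linearly and clips to [0, 1].
    """

    divergence_kind: str
    raw_anchors: np.ndarray
    targets: Tuple[float, float, float] = CALIBRATION_TARGETS

    def __post_init__(self) -> None:
        a = np.asarray(self.raw_anchors, dtype=np.float64)
        if a.shape != (3,):
            raise ConfigurationError("calibration needs 3 raw anchors")
        # Guard against ties/inversions (inseparable classes): nudge each
        # anchor to be strictly greater than its predecessor.
        tiny = 1e-9 * max(float(np.ptp(a)), 1.0)
        a = a.copy()
        for i in (1, 2):
            a[i] = max(a[i], a[i - 1] + tiny)
        self.raw_anchors = a

    def apply(self, raw: np.ndarray | float) -> np.ndarray | float:
        raw_arr = np.atleast_1d(np.asarray(raw, dtype=np.float64))
        a, t = self.raw_anchors, np.asarray(self.targets)
        d = np.interp(raw_arr, a, t)
        lo_slope = (t[1] - t[0]) / (a[1] - a[0])
        hi_slope = (t[2] - t[1]) / (a[2] - a[1])
        below = raw_arr < a[0]
        above = raw_arr > a[2]
        d[below] = t[0] + lo_slope * (raw_arr[below] - a[0])
        d[above] = t[2] + hi_slope * (raw_arr[above] - a[2])
        d = np.clip(d, 0.0, 1.0)
        return float(d[0]) if np.isscalar(raw) or np.asarray(raw).ndim == 0 else d


@dataclass
class DTestResult:
    """Per-patch d scores, posteriors and assignment."""

    d: Dict[str, float]
    posteriors: np.ndarray  # (P(Cn|f), P(Cb|f), P(Cm|f))
    assigned: str
    modality: str
    source_id: str = ""
    patch_index: int = 0
    assigned_per_kind: Dict[str, str] = field(default_factory=dict)


def classify_bands(d: float, edges: Tuple[float, float] = BAND_EDGES) -> str:
    """Half-open decision bands [0, e1) / [e1, e2) / [e2, 1]."""
    if not (0.0 <= d <= 1.0):
        raise ValidationError(f"d must lie in [0, 1], got {d}")
    if d < edges[0]:
        return "normal"
    if d < edges[1]:
        return "benign"
    return "malignant"


def consensus(d_map: Dict[str, float], policy: str = "median"):
    """Combine the three per-divergence d scores.

    ``median`` returns ``(median d, band label)``; ``per_divergence``
    returns a mapping kind -> (d, band label), letting each divergence
    classify independently (the Table-2-style evaluation view).
    """
    if policy == "median":
        d = float(np.median(list(d_map.values())))
        return d, classify_bands(d)
    if policy == "per_divergence":
        return {k: (v, classify_bands(v)) for k, v in d_map.items()}
    raise ConfigurationError(f"unknown consensus policy {policy!r}")


def _bin_indices(values: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Bin index of each attribute value on its own edge row (clipped)."""
    n_bins = bin_edges.shape[1] - 1
    idx = np.empty(values.shape[0], dtype=np.intp)
    for i in range(values.shape[0]):
        idx[i] = np.searchsorted(bin_edges[i], values[i], side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def test_distributions(
    values: np.ndarray, reference: ClassReference, K: Optional[np.ndarray] = None
) -> np.ndarray:
    """Point-mass-smoothed test distribution per attribute, (n_attr, n_bins)."""
    if K is None:
        K = point_mass_columns(reference.n_bins, reference.bandwidth)
    idx = _bin_indices(values, reference.bin_edges)
    return K[:, idx].T


def raw_d_scores(
    values: np.ndarray,
    reference: ClassReference,
    weights: Dict[str, WeightVector],
    K: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Weighted divergence of one patch's test distributions from the
    normal-class reference, per divergence kind (uncalibrated)."""
    T = test_distributions(values, reference, K)
    normal = reference.class_probs["normal"]
    return {
        kind: float(np.dot(wv.weights, divergence_rows(kind, T, normal)))
        for kind, wv in weights.items()
    }


def d_test(
    features: FeatureVector | np.ndarray,
    reference: ClassReference,
    weights: Dict[str, WeightVector],
    calibration: Dict[str, CalibrationMap],
) -> Dict[str, float]:
    """Calibrated d score in [0, 1] per divergence kind for one patch."""
    if not calibration:
        raise ConfigurationError("calibration has not been fitted")
    if hasattr(features, "as_array"):
        values = features.as_array(reference.attributes)
    else:
        values = np.asarray(features, dtype=np.float64)
    raw = raw_d_scores(values, reference, weights)
    return {kind: float(calibration[kind].apply(raw[kind])) for kind in raw}


def fit_calibration(
    training: pd.DataFrame,
    reference: ClassReference,
    weights: Dict[str, WeightVector],
) -> Dict[str, CalibrationMap]:
    """Anchor class median raw scores at 0.2 / 0.5 / 0.8 per divergence."""
    sub = training[training["modality"] == reference.modality]
    X = sub[reference.attributes].to_numpy(dtype=np.float64)
    labels = sub["label"].to_numpy()
    K = point_mass_columns(reference.n_bins, reference.bandwidth)
    raws = {kind: np.empty(len(sub)) for kind in weights}
    for j in range(len(sub)):
        r = raw_d_scores(X[j], reference, weights, K)
        for kind in weights:
            raws[kind][j] = r[kind]
    maps = {}
    for kind in weights:
        anchors = [float(np.median(raws[kind][labels == c])) for c in LABELS]
        maps[kind] = CalibrationMap(kind, np.array(anchors))
    return maps


def posteriors(
    features: FeatureVector | np.ndarray, reference: ClassReference
) -> np.ndarray:
    """Class posteriors from the exponential likelihoods (equal priors).

    Stable softmax of the three joint log-likelihoods; returns
    (P(Cn|f), P(Cb|f), P(Cm|f)) summing to 1.
    """
    if not reference.rates:
        raise ConfigurationError("exponential rates have not been trained")
    if hasattr(features, "as_array"):
        x = features.as_array(reference.attributes)
    else:
        x = np.asarray(features, dtype=np.float64)
    xs = reference.shift(x)
    ll = np.array(
        [float(np.sum(np.log(reference.rates[c]) - reference.rates[c] * xs))
         for c in LABELS]
    )
    ll -= ll.max()
    p = np.exp(ll)
    return p / p.sum()


def fuse_modalities(sem: DTestResult, afm: DTestResult) -> DTestResult:
    """Subject-level fusion: mean d per divergence, product posteriors.

    Requires one SEM and one AFM result for the same subject; the fused
    label comes from the band of the fused median consensus d.
    """
    if {sem.modality, afm.modality} != {"SEM", "AFM"}:
        raise ValidationError(
            f"fusion needs one SEM and one AFM result, got "
            f"{sem.modality}/{afm.modality}"
        )
    d = {k: 0.5 * (sem.d[k] + afm.d[k]) for k in sem.d}
    post = sem.posteriors * afm.posteriors
    total = post.sum()
    post = post / total if total > 0 else np.full(3, 1.0 / 3.0)
    cons_d, label = consensus(d, "median")
    return DTestResult(
        d=d,
        posteriors=post,
        assigned=label,
        modality="SEM+AFM",
        source_id=sem.source_id,
        patch_index=sem.patch_index,
        assigned_per_kind={k: classify_bands(v) for k, v in d.items()},
    )


def classify_patches(
    features: pd.DataFrame,
    reference: ClassReference,
    weights: Dict[str, WeightVector],
    calibration: Dict[str, CalibrationMap],
) -> pd.DataFrame:
    """Batch classification of one modality's feature matrix.

    Returns a results frame with d scores, posteriors and assignments per
    divergence plus the median-consensus assignment.  Inference is fully
    deterministic.
    """
    sub = features[features["modality"] == reference.modality]
    X = sub[reference.attributes].to_numpy(dtype=np.float64)
    K = point_mass_columns(reference.n_bins, reference.bandwidth)
    normal = reference.class_probs["normal"]

    n = len(sub)
    d_cols = {kind: np.empty(n) for kind in DIVERGENCE_KINDS}
    post = np.empty((n, 3))
    for j in range(n):
        T = test_distributions(X[j], reference, K)
        for kind in DIVERGENCE_KINDS:
            raw = float(np.dot(weights[kind].weights,
                               divergence_rows(kind, T, normal)))
            d_cols[kind][j] = calibration[kind].apply(raw)
        post[j] = posteriors(X[j], reference)

    out = sub[METADATA_COLUMNS].copy().reset_index(drop=True)
    for kind in DIVERGENCE_KINDS:
        out[f"d_{kind}"] = d_cols[kind]
        out[f"assigned_{kind}"] = [classify_bands(v) for v in d_cols[kind]]
    out["P_Cn"], out["P_Cb"], out["P_Cm"] = post[:, 0], post[:, 1], post[:, 2]
    out["assigned_consensus"] = [
        consensus({k: out.loc[j, f"d_{k}"] for k in DIVERGENCE_KINDS}, "median")[1]
        for j in range(n)
    ]
    return out
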