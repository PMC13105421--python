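"""Per-attribute class distributions and exponential likelihood models.

Training values of every attribute are discretized onto bin edges shared by
all three classes (the divergences need common support), smoothed with a
Gaussian kernel applied to the binned histogram, floored at a small epsilon
(so downstream divergences never hit log 0), and renormalized.

A second, independent likelihood route models each attribute with an
exponential distribution per class.  Because attributes such as skewness or
band means can be negative while the exponential support is positive, every
attribute is shifted by its pooled training minimum (minus a small delta)
before fitting; the shift parameters are stored with the reference so test
values are shifted identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError, EstimationError
from .imaging import LABELS
from .wavelet_features import METADATA_COLUMNS

PROB_FLOOR = 1e-9
DEFAULT_N_BINS = 64
DEFAULT_BANDWIDTH = 1.0  # in bins
EDGE_MARGIN = 0.05
SHIFT_DELTA_FRACTION = 1e-6


@dataclass
class FeatureDistribution:
    """Discretized probability vector of one attribute for one class."""

    attribute: str
    bin_edges: np.ndarray
    probabilities: np.ndarray
    smoothing_bandwidth: float


def shared_bin_edges(
    values: np.ndarray, n_bins: int = DEFAULT_N_BINS, margin: float = EDGE_MARGIN
) -> np.ndarray:
    """Edges covering the pooled range of an attribute, extended by ``margin``."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EstimationError("cannot build bin edges from empty values")
    lo, hi = float(values.min()), float(values.max())
    span = hi - lo
    if span == 0.0:
        lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = lo - margin * span, hi + margin * span
    return np.linspace(lo, hi, n_bins + 1)


def _smooth_floor_normalize(p: np.ndarray, bandwidth: float) -> np.ndarray:
    if bandwidth > 0:
        # reflect keeps a uniform histogram uniform and conserves mass
        p = ndimage.gaussian_filter1d(p, bandwidth, mode="reflect")
    p = np.maximum(p, PROB_FLOOR)
    return p / p.sum()


def estimate_distribution(
    values: np.ndarray,
    bin_edges: np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    attribute: str = "",
) -> FeatureDistribution:
    """Kernel-smoothed histogram on shared edges, floored and renormalized."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EstimationError(f"no values for attribute {attribute!r}")
    lo, hi = bin_edges[0], bin_edges[-1]
    if values.min() < lo or values.max() > hi:
        warnings.warn(
            f"values of {attribute!r} outside bin edges; clipped into end bins",
            stacklevel=2,
        )
        values = np.clip(values, lo, hi)
    counts, _ = np.histogram(values, bins=bin_edges)
    p = counts.astype(np.float64) / values.size
    p = _smooth_floor_normalize(p, bandwidth)
    return FeatureDistribution(attribute, np.asarray(bin_edges), p, bandwidth)


def point_mass_columns(n_bins: int, bandwidth: float) -> np.ndarray:
    """Matrix K whose column j is the smoothed/floored/normalized point mass
    at bin j — the distribution a single test value in bin j maps to.

    Precomputing K makes per-patch test distributions a single fancy-index.
    """
    K = np.eye(n_bins)
    return np.stack(
        [_smooth_floor_normalize(K[:, j].copy(), bandwidth) for j in range(n_bins)],
        axis=1,
    )


def fit_exponential(values: np.ndarray) -> float:
    """Maximum-likelihood exponential rate: lambda = 1 / mean.

    ``values`` must already be shifted to nonnegative support.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise EstimationError("cannot fit exponential to empty values")
    mean = float(values.mean())
    if mean <= 0:
        raise EstimationError("mean of shifted values must be positive")
    return 1.0 / mean


@dataclass
class ClassReference:
    """Trained per-modality reference: distributions, rates and ranges.

    Arrays are stored attribute-major for speed: ``class_probs[c]`` has shape
    ``(n_attributes, n_bins)`` on the shared ``bin_edges`` row for that
    attribute.  ``pooled_probs`` is the all-class distribution used for the
    entropy normalization of attribute weights.
    """

    modality: str
    attributes: List[str]
    bin_edges: np.ndarray  # (n_attr, n_bins + 1)
    class_probs: Dict[str, np.ndarray]  # label -> (n_attr, n_bins)
    pooled_probs: np.ndarray  # (n_attr, n_bins)
    rates: Dict[str, np.ndarray]  # label -> (n_attr,)
    shift_min: np.ndarray  # (n_attr,) pooled minimum per attribute
    shift_delta: np.ndarray  # (n_attr,)
    stage_ranges: Dict[str, Dict[str, Tuple[float, float]]]
    bandwidth: float
    n_train: int

    @property
    def n_bins(self) -> int:
        return self.class_probs[LABELS[0]].shape[1]

    def get_distribution(self, attribute: str, label: str) -> FeatureDistribution:
        i = self.attributes.index(attribute)
        return FeatureDistribution(
            attribute,
            self.bin_edges[i],
            self.class_probs[label][i],
            self.bandwidth,
        )

    def shift(self, x: np.ndarray) -> np.ndarray:
        """Shift attribute values onto the exponential support (clip at 0)."""
        return np.maximum(np.asarray(x, dtype=np.float64) - self.shift_min
                          + self.shift_delta, 0.0)


def compute_stage_ranges(training: pd.DataFrame) -> Dict[str, Dict[str, Tuple[float, float]]]:
    """Per-attribute class intervals (5th–95th percentile), diagnostic only.

    Stage I/II/III intervals report where each class's attribute values lie;
    the band classifier does not consult them.
    """
    attrs = [c for c in training.columns if c not in METADATA_COLUMNS]
    missing = set(LABELS) - set(training["label"].unique())
    if missing:
        raise ConfigurationError(f"training lacks classes: {sorted(missing)}")
    out: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for attr in attrs:
        out[attr] = {}
        for label in LABELS:
            vals = training.loc[training["label"] == label, attr].to_numpy()
            out[attr][label] = (
                float(np.percentile(vals, 5)),
                float(np.percentile(vals, 95)),
            )
    return out


def train_reference(
    training: pd.DataFrame,
    modality: str,
    n_bins: int = DEFAULT_N_BINS,
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> ClassReference:
    """Fit distributions, exponential rates and stage ranges for one modality."""
    sub = training[training["modality"] == modality]
    missing = set(LABELS) - set(sub["label"].unique())
    if missing:
        raise ConfigurationError(
            f"{modality} training lacks classes: {sorted(missing)}"
        )
    attrs = [c for c in sub.columns if c not in METADATA_COLUMNS]
    n_attr = len(attrs)
    X = sub[attrs].to_numpy(dtype=np.float64)
    labels = sub["label"].to_numpy()

    bin_edges = np.empty((n_attr, n_bins + 1))
    pooled_probs = np.empty((n_attr, n_bins))
    class_probs = {c: np.empty((n_attr, n_bins)) for c in LABELS}
    rates = {c: np.empty(n_attr) for c in LABELS}
    shift_min = X.min(axis=0)
    span = X.max(axis=0) - shift_min
    shift_delta = SHIFT_DELTA_FRACTION * np.where(span > 0, span, 1.0)

    for i, attr in enumerate(attrs):
        edges = shared_bin_edges(X[:, i], n_bins)
        bin_edges[i] = edges
        pooled_probs[i] = estimate_distribution(
            X[:, i], edges, bandwidth, attr
        ).probabilities
        for c in LABELS:
            vals = X[labels == c, i]
            class_probs[c][i] = estimate_distribution(
                vals, edges, bandwidth, attr
            ).probabilities
            shifted = np.maximum(vals - shift_min[i] + shift_delta[i], 0.0)
            rates[c][i] = fit_exponential(shifted)

    return ClassReference(
        modality=modality,
        attributes=attrs,
        bin_edges=bin_edges,
        class_probs=class_probs,
        pooled_probs=pooled_probs,
        rates=rates,
        shift_min=shift_min,
        shift_delta=shift_delta,
        stage_ranges=compute_stage_ranges(sub),
        bandwidth=bandwidth,
        n_train=len(sub),
    )


def class_likelihood(
    features, reference: ClassReference, label: str
) -> float:
    """Joint exponential log-likelihood of a feature vector under one class.

    ``features`` may be a FeatureVector or an array in reference attribute
    order.  Returns sum_i [ log lambda_c,i - lambda_c,i * x'_i ] with x'
    the shifted test values.
    """
    if label not in LABELS:
        raise ConfigurationError(f"unknown class {label!r}")
    if hasattr(features, "as_array"):
        try:
            x = features.as_array(reference.attributes)
        except KeyError as exc:
            raise ConfigurationError(f"attribute mismatch: {exc}") from exc
    else:
        x = np.asarray(features, dtype=np.float64)
        if x.shape != (len(reference.attributes),):
            raise ConfigurationError(
                f"expected {len(reference.attributes)} attributes, got {x.shape}"
            )
    lam = reference.rates[label]
    xs = reference.shift(x)
    return float(np.sum(np.log(lam) - lam * xs))
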