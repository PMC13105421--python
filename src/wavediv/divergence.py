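"""Jensen–Shannon, squared Hellinger and triangular discrimination, plus the
entropy-normalized attribute weighting.

All three measures are symmetric f-divergences mapped onto a common [0, 1]
range so one set of decision bands applies to each:

* ``jsd``      — base-2 Jensen–Shannon divergence (maximum 1 on disjoint
  support).  The "printed" binary-KL variant is kept behind
  ``jsd_variant="printed"`` for comparison only.
* ``hellinger`` — squared Hellinger distance H^2 = 1/2 sum (sqrt p - sqrt q)^2.
* ``triangle``  — triangular discrimination sum (p-q)^2/(p+q), halved from
  its native [0, 2] range.

Attribute weights combine between-class separability (mean divergence over
the three unordered class pairs) with an entropy normalization that
penalizes attributes whose pooled distribution is diffuse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .distributions import ClassReference
from .exceptions import ConfigurationError, ValidationError
from .imaging import LABELS

DIVERGENCE_KINDS = ("JSD", "HD", "TD")
CLASS_PAIRS = (("normal", "benign"), ("normal", "malignant"), ("benign", "malignant"))
ENTROPY_FLOOR = 0.1  # bits


def _validate_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 1:
        raise ValidationError(f"length mismatch: {p.shape} vs {q.shape}")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValidationError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValidationError(f"{name} does not sum to 1 (sum={v.sum():.8f})")
    return p, q


def _jsd_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise base-2 JSD for matrices of distributions (no validation)."""
    M = 0.5 * (P + Q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(P > 0, P * np.log2(np.where(P > 0, P / M, 1.0)), 0.0)
        t2 = np.where(Q > 0, Q * np.log2(np.where(Q > 0, Q / M, 1.0)), 0.0)
    return 0.5 * t1.sum(axis=-1) + 0.5 * t2.sum(axis=-1)


def _hellinger_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return 0.5 * np.sum((np.sqrt(P) - np.sqrt(Q)) ** 2, axis=-1)


def _triangle_rows(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    s = P + Q
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s > 0, (P - Q) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return 0.5 * terms.sum(axis=-1)


_ROW_FUNCS = {"JSD": _jsd_rows, "HD": _hellinger_rows, "TD": _triangle_rows}


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen–Shannon divergence, in [0, 1]."""
    p, q = _validate_pair(p, q)
    return float(_jsd_rows(p, q))


def jsd_printed(p: np.ndarray, q: np.ndarray) -> float:
    """Per-bin binary-KL variant (archaeological; clipped to [0, 1]).

    Treats each bin as a Bernoulli (p_i, 1-p_i) vs (q_i, 1-q_i) and sums the
    asymmetric KLs.  Not a bounded symmetric divergence; provided only for
    side-by-side comparison with :func:`jsd`, never used by default.
    """
    p, q = _validate_pair(p, q)
    pc = np.clip(p, 1e-12, 1 - 1e-12)
    qc = np.clip(q, 1e-12, 1 - 1e-12)
    val = np.sum(pc * np.log2(pc / qc) + (1 - pc) * np.log2((1 - pc) / (1 - qc)))
    return float(np.clip(val, 0.0, 1.0))


def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    """Squared Hellinger distance, in [0, 1]."""
    p, q = _validate_pair(p, q)
    return float(_hellinger_rows(p, q))


def triangle(p: np.ndarray, q: np.ndarray) -> float:
    """Triangular discrimination halved to [0, 1]; 0/0 terms contribute 0."""
    p, q = _validate_pair(p, q)
    return float(_triangle_rows(p, q))


def divergence_rows(kind: str, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Vectorized row-wise divergence of the given kind (internal fast path)."""
    try:
        return _ROW_FUNCS[kind](np.asarray(P), np.asarray(Q))
    except KeyError:
        raise ConfigurationError(f"unknown divergence kind {kind!r}") from None


@dataclass
class WeightVector:
    """Normalized per-attribute weights for one divergence kind."""

    divergence_kind: str
    attributes: List[str]
    weights: np.ndarray
    z: float
    N: int

    def as_map(self) -> Dict[str, float]:
        return dict(zip(self.attributes, self.weights.tolist()))

    def top(self, k: int = 10) -> List[tuple[str, float]]:
        order = np.argsort(self.weights)[::-1][:k]
        return [(self.attributes[i], float(self.weights[i])) for i in order]


def compute_weights(
    training: Optional[pd.DataFrame],
    reference: ClassReference,
    divergence_kind: str,
    entropy_floor: float = ENTROPY_FLOOR,
) -> WeightVector:
    """Entropy-normalized separability weights, summing to 1.

    Per attribute i: W_av(i) is the mean divergence between the class
    distributions over the three unordered class pairs; H(i) is the Shannon
    entropy (bits) of the pooled all-class distribution, floored at
    ``entropy_floor``; W(i) = W_av(i) / (z * H(i)) with z the normalization
    constant making the weights sum to 1.  If no attribute separates the
    classes at all (all W_av = 0), weights fall back to uniform.

    ``training`` is accepted for the record count N; the distributions
    themselves live in the trained reference.
    """
    if divergence_kind not in DIVERGENCE_KINDS:
        raise ConfigurationError(f"unknown divergence kind {divergence_kind!r}")
    present = set(reference.class_probs)
    if set(LABELS) - present:
        raise ConfigurationError("reference must be trained on all three classes")
    n_attr = len(reference.attributes)

    w_av = np.zeros(n_attr)
    for a, b in CLASS_PAIRS:
        w_av += divergence_rows(
            divergence_kind, reference.class_probs[a], reference.class_probs[b]
        )
    w_av /= len(CLASS_PAIRS)

    P = reference.pooled_probs
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.sum(np.where(P > 0, P * np.log2(np.where(P > 0, P, 1.0)), 0.0), axis=1)
    H = np.maximum(H, entropy_floor)

    raw = w_av / H
    total = raw.sum()
    if total <= 0:
        weights = np.full(n_attr, 1.0 / n_attr)
        z = 1.0
    else:
        z = total
        weights = raw / z

    N = len(training) if training is not None else reference.n_train
    return WeightVector(divergence_kind, list(reference.attributes), weights, float(z), N)
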