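"""Per-class correct-classification rates, six-group aggregation and
percentile-bootstrap confidence intervals.

The headline summary mirrors the six-group layout (normal/benign/malignant
x SEM/AFM): per-group percent correct, the total number of correctly
classified regions, and the average success rate per divergence kind.
Confidence intervals use the plain percentile bootstrap (2.5th/97.5th
percentiles of the resampled metric), with numpy's linear-interpolation
percentile definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .divergence import DIVERGENCE_KINDS
from .exceptions import AlignmentError, ValidationError
from .imaging import LABELS

_KEY = ["source_id", "patch_index", "modality"]


@dataclass
class EvaluationReport:
    """Point estimates (and optional bootstrap CIs) per divergence kind."""

    per_kind: Dict[str, dict]
    n_total: int
    bootstrap: Optional[Dict[str, dict]] = None

    def to_dict(self) -> dict:
        out = {"n_total": self.n_total, "per_kind": self.per_kind}
        if self.bootstrap is not None:
            out["bootstrap"] = self.bootstrap
        return out


def _macro_prf(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[float, float, float]:
    """Macro-averaged precision/recall/F1 over the three classes.

    Zero-denominator classes contribute 0 (the convention stated in docs).
    """
    precs, recs, f1s = [], [], []
    for c in LABELS:
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return float(np.mean(precs)), float(np.mean(recs)), float(np.mean(f1s))


def score(predictions: pd.DataFrame, truth: pd.DataFrame) -> EvaluationReport:
    """Point estimates from aligned predictions and truth labels.

    ``predictions`` must carry ``assigned_<kind>`` columns and the key
    columns (source_id, patch_index, modality); ``truth`` carries the same
    keys plus ``label``.  Records must match one-to-one.
    """
    merged = predictions.merge(
        truth[_KEY + ["label"]].rename(columns={"label": "true_label"}),
        on=_KEY,
        how="outer",
        indicator=True,
    )
    bad = merged[merged["_merge"] != "both"]
    if len(bad):
        offenders = bad[_KEY].head(10).to_dict("records")
        raise AlignmentError(f"unmatched records (first 10): {offenders}")
    y_true = merged["true_label"].to_numpy()

    per_kind: Dict[str, dict] = {}
    for kind in DIVERGENCE_KINDS:
        col = f"assigned_{kind}"
        if col not in merged.columns:
            continue
        y_pred = merged[col].to_numpy()
        groups = {}
        total_correct = 0
        for modality in sorted(merged["modality"].unique()):
            for label in LABELS:
                mask = (merged["modality"] == modality) & (y_true == label)
                n_c = int(mask.sum())
                if n_c == 0:
                    continue
                correct = int(np.sum(y_pred[mask.to_numpy()] == label))
                total_correct += correct
                groups[f"{label[0]}{modality}"] = {
                    "rate_percent": 100.0 * correct / n_c,
                    "correct": correct,
                    "n": n_c,
                }
        prec, rec, f1 = _macro_prf(y_true, y_pred)
        per_kind[kind] = {
            "per_group": groups,
            "total_correct": total_correct,
            "total_used": len(merged),
            "average_success_rate": round(100.0 * total_correct / len(merged), 2),
            "macro_precision": prec,
            "macro_recall": rec,
            "macro_f1": f1,
        }
    return EvaluationReport(per_kind=per_kind, n_total=len(merged))


def aggregate_rates(
    per_class_rates: Sequence[float], n_per_class: int
) -> Tuple[int, float]:
    """Total correct count and average success rate from six group rates.

    The printed per-group percentages are themselves rounded, so the implied
    per-group counts can be fractional (98% of 90 = 88.2); the total is
    rounded to the nearest integer and the average reported to 2 decimals.
    """
    rates = np.asarray(per_class_rates, dtype=np.float64)
    if rates.shape != (6,):
        raise ValidationError(f"expected 6 per-class rates, got {rates.shape}")
    if np.any(rates < 0) or np.any(rates > 100):
        raise ValidationError("rates must lie in [0, 100]")
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    total_correct = int(round(float(np.sum(rates * n_per_class / 100.0))))
    average = round(100.0 * total_correct / (6 * n_per_class), 2)
    return total_correct, average


def bootstrap_ci(
    correctness: Sequence[int] | np.ndarray,
    n_resamples: int = 10000,
    level: float = 95.0,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Percentile-bootstrap CI of the accuracy of a binary correctness vector.

    Resamples the vector with replacement ``n_resamples`` times and returns
    (mean, lower, upper) accuracy in percent, bounds at the (100-level)/2
    and (100+level)/2 percentiles.  Deterministic under a fixed seed.
    """
    c = np.asarray(correctness, dtype=np.float64)
    if c.size == 0:
        raise ValidationError("correctness vector is empty")
    if n_resamples < 2:
        raise ValidationError("n_resamples must be >= 2")
    if n_resamples < 100:
        warnings.warn("n_resamples < 100 gives unstable percentile bounds",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, c.size, size=(n_resamples, c.size))
    means = 100.0 * c[idx].mean(axis=1)
    lo_q, hi_q = (100.0 - level) / 2.0, (100.0 + level) / 2.0
    lower, upper = np.percentile(means, [lo_q, hi_q])
    return float(means.mean()), float(lower), float(upper)


def bootstrap_metric_cis(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    n_resamples: int = 10000,
    level: float = 95.0,
    seed: int = 0,
) -> Dict[str, dict]:
    """Percentile-bootstrap CIs for accuracy, macro precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("y_true and y_pred must be equal-length, non-empty")
    if n_resamples < 2:
        raise ValidationError("n_resamples must be >= 2")
    rng = np.random.default_rng(seed)
    n = y_true.size
    acc = np.empty(n_resamples)
    prf = np.empty((n_resamples, 3))
    for b in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        t, p = y_true[idx], y_pred[idx]
        acc[b] = 100.0 * np.mean(t == p)
        prf[b] = _macro_prf(t, p)
    lo_q, hi_q = (100.0 - level) / 2.0, (100.0 + level) / 2.0
    out = {}
    for name, samples in (
        ("accuracy", acc),
        ("precision", prf[:, 0]),
        ("recall", prf[:, 1]),
        ("f1", prf[:, 2]),
    ):
        lower, upper = np.percentile(samples, [lo_q, hi_q])
        out[name] = {
            "mean": float(samples.mean()),
            "lower": float(lower),
            "upper": float(upper),
            "n_resamples": n_resamples,
            "seed": seed,
        }
    return out


def markdown_table(report: EvaluationReport) -> str:
    """Six-group summary table in the usual rates/totals/average layout."""
    kinds = [k for k in DIVERGENCE_KINDS if k in report.per_kind]
    seen: List[str] = []
    for k in kinds:
        for g in report.per_kind[k]["per_group"]:
            if g not in seen:
                seen.append(g)
    # order rows modality-major, normal/benign/malignant within each
    modalities = sorted({g[1:] for g in seen}, reverse=True)  # AFM before SEM*
    groups = [f"{label[0]}{m}" for m in modalities for label in LABELS
              if f"{label[0]}{m}" in seen]
    lines = ["| Group | " + " | ".join(kinds) + " |",
             "|---" * (len(kinds) + 1) + "|"]
    for g in groups:
        cells = [
            f"{report.per_kind[k]['per_group'][g]['rate_percent']:.0f}"
            if g in report.per_kind[k]["per_group"] else "-"
            for k in kinds
        ]
        lines.append(f"| {g} | " + " | ".join(cells) + " |")
    lines.append(
        "| total correct | "
        + " | ".join(str(report.per_kind[k]["total_correct"]) for k in kinds)
        + " |"
    )
    lines.append(
        "| total used | "
        + " | ".join(str(report.per_kind[k]["total_used"]) for k in kinds)
        + " |"
    )
    lines.append(
        "| average success rate (%) | "
        + " | ".join(f"{report.per_kind[k]['average_success_rate']:.2f}"
                     for k in kinds)
        + " |"
    )
    return "\n".join(lines)
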