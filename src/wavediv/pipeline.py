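"""End-to-end glue: train a model from a labeled feature matrix, classify,
fuse modalities and evaluate — plus a seeded synthetic run for experiments.

A *model* bundles, per modality, the trained class reference (distributions,
exponential rates, stage ranges), one weight vector per divergence kind and
one calibration map per kind, and serializes to a single JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    CalibrationMap,
    classify_bands,
    classify_patches,
    fit_calibration,
)
from .config import PipelineConfig
from .distributions import ClassReference, train_reference
from .divergence import DIVERGENCE_KINDS, WeightVector, compute_weights
from .evaluation import EvaluationReport, bootstrap_metric_cis, score
from .exceptions import ConfigurationError, ValidationError
from .imaging import LABELS, MODALITIES
from .synth import SynthConfig, generate_dataset
from .wavelet_features import METADATA_COLUMNS, features_dataframe


@dataclass
class Model:
    config: PipelineConfig
    references: Dict[str, ClassReference]
    weights: Dict[str, Dict[str, WeightVector]]  # modality -> kind -> WV
    calibrations: Dict[str, Dict[str, CalibrationMap]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "package_version": __version__,
            "config": {
                **self.config.__dict__,
                "band_edges": list(self.config.band_edges),
                "calibration_anchors": list(self.config.calibration_anchors),
            },
            "config_hash": self.config.config_hash(),
            "modalities": {},
        }
        for modality, ref in self.references.items():
            payload["modalities"][modality] = {
                "attributes": ref.attributes,
                "bin_edges": ref.bin_edges.tolist(),
                "class_probs": {c: p.tolist() for c, p in ref.class_probs.items()},
                "pooled_probs": ref.pooled_probs.tolist(),
                "rates": {c: r.tolist() for c, r in ref.rates.items()},
                "shift_min": ref.shift_min.tolist(),
                "shift_delta": ref.shift_delta.tolist(),
                "stage_ranges": ref.stage_ranges,
                "bandwidth": ref.bandwidth,
                "n_train": ref.n_train,
                "weights": {
                    kind: {
                        "weights": wv.weights.tolist(),
                        "z": wv.z,
                        "N": wv.N,
                    }
                    for kind, wv in self.weights[modality].items()
                },
                "calibration": {
                    kind: cm.raw_anchors.tolist()
                    for kind, cm in self.calibrations[modality].items()
                },
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Model":
        payload = json.loads(Path(path).read_text())
        cfg = dict(payload["config"])
        cfg["band_edges"] = tuple(cfg["band_edges"])
        cfg["calibration_anchors"] = tuple(cfg["calibration_anchors"])
        config = PipelineConfig(**cfg)
        references, weights, calibrations = {}, {}, {}
        for modality, m in payload["modalities"].items():
            references[modality] = ClassReference(
                modality=modality,
                attributes=m["attributes"],
                bin_edges=np.array(m["bin_edges"]),
                class_probs={c: np.array(p) for c, p in m["class_probs"].items()},
                pooled_probs=np.array(m["pooled_probs"]),
                rates={c: np.array(r) for c, r in m["rates"].items()},
                shift_min=np.array(m["shift_min"]),
                shift_delta=np.array(m["shift_delta"]),
                stage_ranges={
                    a: {c: tuple(v) for c, v in d.items()}
                    for a, d in m["stage_ranges"].items()
                },
                bandwidth=m["bandwidth"],
                n_train=m["n_train"],
            )
            weights[modality] = {
                kind: WeightVector(
                    kind, m["attributes"], np.array(w["weights"]), w["z"], w["N"]
                )
                for kind, w in m["weights"].items()
            }
            calibrations[modality] = {
                kind: CalibrationMap(kind, np.array(anchors))
                for kind, anchors in m["calibration"].items()
            }
        return cls(config, references, weights, calibrations)


def train_model(training: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> Model:
    """Fit references, weights and calibrations for every modality present."""
    modalities = sorted(training["modality"].unique())
    if not modalities:
        raise ConfigurationError("training frame is empty")
    references, weights, calibrations = {}, {}, {}
    for modality in modalities:
        ref = train_reference(training, modality, config.n_bins, config.bandwidth)
        wv = {
            kind: compute_weights(training[training["modality"] == modality],
                                  ref, kind)
            for kind in DIVERGENCE_KINDS
        }
        references[modality] = ref
        weights[modality] = wv
        calibrations[modality] = fit_calibration(training, ref, wv)
    return Model(config, references, weights, calibrations)


def classify(features: pd.DataFrame, model: Model) -> pd.DataFrame:
    """Classify every patch of every modality the model was trained on."""
    frames = []
    for modality, ref in model.references.items():
        sub = features[features["modality"] == modality]
        if len(sub) == 0:
            continue
        frames.append(
            classify_patches(sub, ref, model.weights[modality],
                             model.calibrations[modality])
        )
    if not frames:
        raise ConfigurationError("no patches match the model's modalities")
    return pd.concat(frames, ignore_index=True)


def fuse_results(results: pd.DataFrame) -> pd.DataFrame:
    """Pair SEM and AFM rows of the same subject+patch and fuse them.

    Subjects are matched by stripping the modality token from source_id
    (the synthetic naming convention ``<l><MOD><idx>``); rows without a
    partner are dropped.
    """
    res = results.copy()
    res["subject_id"] = [
        sid.replace(mod, "", 1)
        for sid, mod in zip(res["source_id"], res["modality"])
    ]
    sem = res[res["modality"] == "SEM"]
    afm = res[res["modality"] == "AFM"]
    merged = sem.merge(
        afm,
        on=["subject_id", "patch_index", "label"],
        suffixes=("_sem", "_afm"),
    )
    out = merged[["subject_id", "patch_index", "label"]].copy()
    out["modality"] = "SEM+AFM"
    out["source_id"] = merged["subject_id"]
    for kind in DIVERGENCE_KINDS:
        d = 0.5 * (merged[f"d_{kind}_sem"] + merged[f"d_{kind}_afm"])
        out[f"d_{kind}"] = d
        out[f"assigned_{kind}"] = [classify_bands(v) for v in d]
    post = (
        merged[["P_Cn_sem", "P_Cb_sem", "P_Cm_sem"]].to_numpy()
        * merged[["P_Cn_afm", "P_Cb_afm", "P_Cm_afm"]].to_numpy()
    )
    norm = post.sum(axis=1, keepdims=True)
    post = np.where(norm > 0, post / norm, 1.0 / 3.0)
    out["P_Cn"], out["P_Cb"], out["P_Cm"] = post[:, 0], post[:, 1], post[:, 2]
    med = np.median(out[[f"d_{k}" for k in DIVERGENCE_KINDS]].to_numpy(), axis=1)
    out["assigned_consensus"] = [classify_bands(v) for v in med]
    return out


def split_train_test(
    features: pd.DataFrame, split_by: str = "source"
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic half split, stratified by (modality, label).

    ``source`` keeps all 4 patches of an image on one side (leakage-safe);
    ``patch`` splits at the patch level, replicating per-patch designs.
    """
    train_mask = np.zeros(len(features), dtype=bool)
    for (modality, label), group in features.groupby(["modality", "label"]):
        if split_by == "source":
            sources = sorted(group["source_id"].unique())
            train_sources = set(sources[: len(sources) // 2])
            train_mask[group.index] = group["source_id"].isin(train_sources)
        else:
            idx = group.sort_values(["source_id", "patch_index"]).index
            train_mask[idx[: len(idx) // 2]] = True
    return (
        features[train_mask].reset_index(drop=True),
        features[~train_mask].reset_index(drop=True),
    )


def run_end_to_end(
    config: PipelineConfig = PipelineConfig(),
    synth_config: Optional[SynthConfig] = None,
    seed: int = 1,
    bootstrap: bool = False,
) -> dict:
    """Generate -> split -> train -> classify -> fuse -> evaluate.

    Returns a dict with per-modality and fused evaluation reports plus the
    raw results frames.  Fully determined by the config and seed.
    """
    if synth_config is None:
        synth_config = SynthConfig(seed=seed)
    patches = generate_dataset(synth_config)
    features = features_dataframe(
        patches, config.wavelet_name, config.levels, config.entropy_bins
    )
    train_df, test_df = split_train_test(features, config.split_by)
    model = train_model(train_df, config)
    results = classify(test_df, model)
    truth = test_df[METADATA_COLUMNS]
    report = score(results, truth)
    if bootstrap:
        report.bootstrap = {
            kind: bootstrap_metric_cis(
                results["label"].to_numpy(),
                results[f"assigned_{kind}"].to_numpy(),
                n_resamples=config.bootstrap_n,
                seed=seed,
            )
            for kind in DIVERGENCE_KINDS
        }
    per_modality = {
        modality: score(
            results[results["modality"] == modality],
            truth[truth["modality"] == modality],
        )
        for modality in sorted(results["modality"].unique())
    }
    fused = fuse_results(results)
    fused_truth = fused[["source_id", "patch_index", "modality", "label"]]
    fused_report = score(fused, fused_truth)
    return {
        "report": report,
        "per_modality": per_modality,
        "fused_report": fused_report,
        "results": results,
        "fused_results": fused,
        "model": model,
        "test_features": test_df,
    }
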