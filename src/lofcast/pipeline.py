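"""End-to-end orchestration: configuration, train / predict runs, manifests.

A run is driven by a single :class:`RunConfig` (YAML-serializable).  All
randomness flows from one top-level seed, expanded deterministically per
stage.  Every run writes a manifest (input hashes, seeds, versions) from
which an identical rerun reproduces byte-identical CSV outputs.

Inputs can be real files (feature table + functional table, optionally
an alignment for the evolutionary index) or a synthetic scenario, which
generates the study-shaped table in memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cascade import CascadeClassifier, CascadeResults
from .evolution import VAEConfig, compute_sequence_weights, train_vae_ensemble
from .io import read_alignment, read_variant_table, variants_from_table
from .landscape import enumerate_missense, predict_landscape, MutationalLandscape
from .synthetic import TableScenario, generate_feature_table


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Fully serializable description of a training run."""

    seed: int = 0
    out_dir: str = "lofcast_run"
    label_scheme: str = "JEG3_T4"
    cv_folds: int = 10
    cv_scheme: str = "stratified"
    # real inputs (CSV paths); optional when synthetic is set
    features_path: str | None = None
    functional_path: str | None = None
    alignment_path: str | None = None
    vae: dict = field(default_factory=dict)  # VAEConfig overrides + n_models
    # synthetic scenario (TableScenario kwargs); used when set
    synthetic: dict | None = None
    stage1_features: list[str] | None = None
    stage2_features: list[str] | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    key = f"{seed}:{stage}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2 ** 31)


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.synthetic is not None:
        scenario = TableScenario(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        table, functional, _ = generate_feature_table(scenario)
        return table, functional
    if config.features_path is None or config.functional_path is None:
        raise PipelineError(
            "inputs: neither a synthetic scenario nor both features_path and "
            "functional_path are configured"
        )
    for name, p in (("features", config.features_path), ("functional", config.functional_path)):
        if not Path(p).exists():
            raise PipelineError(f"inputs: missing {name} table {p}")
    features = pd.read_csv(config.features_path, index_col="variant")
    functional = read_variant_table(config.functional_path)
    return features, functional


def _maybe_add_evolutionary_index(
    config: RunConfig, features: pd.DataFrame
) -> pd.DataFrame:
    """Train the VAE ensemble and fill the evolutionary_index column when
    an alignment is configured and the column is absent."""
    if config.alignment_path is None or "evolutionary_index" in features.columns:
        return features
    alignment = read_alignment(config.alignment_path)
    weights = compute_sequence_weights(alignment)
    vae_kwargs = dict(config.vae)
    n_models = vae_kwargs.pop("n_models", 10)
    ensemble = train_vae_ensemble(
        alignment,
        weights,
        n_models=n_models,
        base_seed=_stage_seed(config.seed, "vae"),
        config=VAEConfig(**vae_kwargs) if vae_kwargs else None,
    )
    from .io import parse_variant

    variants = [parse_variant(v) for v in features.index]
    features = features.copy()
    features["evolutionary_index"] = ensemble.indices(variants)
    return features


def run_train(config: RunConfig) -> dict:
    """Execute the full training pipeline; returns the manifest.

    Writes model.json, cv_report.json and manifest.json under
    ``config.out_dir``.  Any stage failure raises :class:`PipelineError`
    naming the stage, and no partial model archive is left behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        features, functional = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"inputs: {exc}") from exc

    try:
        features = _maybe_add_evolutionary_index(config, features)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"evolutionary_model: {exc}") from exc

    try:
        activity = functional.set_index("variant")["relative_activity"]
        model = CascadeClassifier(
            features,
            activity,
            stage1_features=config.stage1_features,
            stage2_features=config.stage2_features,
        )
        results = model.fit(seed=_stage_seed(config.seed, "fit"))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"cascade_fit: {exc}") from exc

    try:
        cv_seed = _stage_seed(config.seed, "cv")
        cv1 = model.crossvalidate_stage1(
            k=config.cv_folds, scheme=config.cv_scheme, seed=cv_seed
        )
        cv2 = model.crossvalidate_stage2(
            k=config.cv_folds, scheme=config.cv_scheme, seed=cv_seed
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"cross_validation: {exc}") from exc

    # all stages succeeded: write outputs
    archive = out / "model.json"
    results.save(archive)
    (out / "cv_report.json").write_text(
        json.dumps({"stage1": cv1.to_dict(), "stage2": cv2.to_dict()}, indent=1),
        encoding="utf-8",
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in ("vae", "fit", "cv")},
        "config": asdict(config),
        "input_hashes": {
            name: _hash_file(p)
            for name, p in (
                ("features", config.features_path),
                ("functional", config.functional_path),
                ("alignment", config.alignment_path),
            )
            if p is not None
        },
        "outputs": {
            "model": archive.name,
            "cv_report": "cv_report.json",
        },
        "metrics": {
            "stage1_cv_auc": cv1.mean_auc,
            "stage2_cv_auc": cv2.mean_auc,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def run_predict(
    archive_path: str | Path,
    features: pd.DataFrame,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Predict variants from a saved model archive and a feature table."""
    results = CascadeResults.load(archive_path)
    pred = results.predict(features)
    pred.index.name = "variant"
    if out_path is not None:
        pred.to_csv(out_path)
    return pred


def run_landscape(
    archive_path: str | Path,
    sequence: str,
    region: tuple[int, int],
    feature_provider,
    out_path: str | Path | None = None,
) -> MutationalLandscape:
    results = CascadeResults.load(archive_path)
    variants = enumerate_missense(sequence, region[0], region[1])
    landscape = predict_landscape(results, feature_provider, variants)
    if out_path is not None:
        landscape.records.to_csv(out_path, index=False)
    return landscape
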