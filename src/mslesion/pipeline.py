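"""End-to-end orchestration: phantoms/ingest -> features -> selection -> report.

Every stage is seeded from one master seed through a fixed fan-out rule
(``numpy.random.SeedSequence(master, spawn_key=(stage_index,))``), so a run is
fully reproducible and any deleted intermediate can be regenerated
bit-identically from the surviving ones. All intermediates are persisted as
CSV/text in the run directory together with an ``artifacts.json`` manifest of
SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bfa, classify, deep_features, handcrafted, image_io, phantom
from .errors import ConfigurationError

# stage indices for the seed fan-out (stable; appending new stages is safe)
_STAGES = {"phantom": 0, "deep": 1, "hcf": 2, "select_deep": 3, "select_hcf": 4, "evaluate": 5}
_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """One configuration object for the whole chain (YAML-serializable)."""

    n_per_class: int = 50
    phantom: phantom.PhantomConfig = field(default_factory=phantom.PhantomConfig)
    backbone: deep_features.BackboneSpec = field(default_factory=deep_features.BackboneSpec)
    lbp: handcrafted.LBPConfig = field(default_factory=handcrafted.LBPConfig)
    phog: handcrafted.PHOGConfig = field(default_factory=handcrafted.PHOGConfig)
    deep_k: int = bfa.DEFAULT_DEEP_K
    hcf_k: int = bfa.DEFAULT_HCF_K
    bfa_population: int = 20
    bfa_iterations: int = 100
    classifiers: tuple[str, ...] = ("RF", "KNN")
    folds: int = 5
    seed: int = 0
    manifest: str | None = None  # ingest an existing dataset instead of phantoms

    def validate(self) -> None:
        self.phantom.validate()
        self.backbone.validate()
        self.lbp.validate()
        self.phog.validate()
        for name in self.classifiers:
            if name not in classify.CLASSIFIERS:
                raise ConfigurationError(f"unknown classifier {name!r}")
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "phantom" in kwargs:
        kwargs["phantom"] = phantom.config_from_dict(kwargs["phantom"])
    if "backbone" in kwargs:
        kwargs["backbone"] = deep_features.BackboneSpec(**kwargs["backbone"])
    if "lbp" in kwargs:
        kwargs["lbp"]["weights"] = tuple(kwargs["lbp"].get("weights", (1, 2, 3, 4)))
        kwargs["lbp"] = handcrafted.LBPConfig(**kwargs["lbp"])
    if "phog" in kwargs:
        kwargs["phog"] = handcrafted.PHOGConfig(**kwargs["phog"])
    if "classifiers" in kwargs:
        kwargs["classifiers"] = tuple(kwargs["classifiers"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def _config_to_dict(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        return obj

    return {f.name: convert(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(path: Path, uids: list[str], matrix: np.ndarray) -> None:
    df = pd.DataFrame(matrix, columns=[f"f{i}" for i in range(matrix.shape[1])])
    df.insert(0, "uid", uids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_matrix(path: Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return df["uid"].tolist(), df.drop(columns="uid").to_numpy(dtype=np.float64)


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> Path:
    """Execute (or resume) the full chain inside ``workdir``; returns the path.

    Stages whose output files already exist are skipped, which both resumes
    interrupted runs and regenerates deleted intermediates bit-identically.
    """
    config.validate()
    run = Path(workdir)
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.yaml").write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))

    # -- stage 1: dataset ---------------------------------------------------
    data_dir = run / "slices"
    manifest_path = data_dir / "manifest.csv"
    if config.manifest is not None:
        manifest = image_io.load_manifest(config.manifest)
        base = Path(config.manifest).parent
        slices = []
        for _, row in manifest.iterrows():
            img = image_io.load_slice(base / row["path"])
            img.label = row["label"]
            img.uid = row["uid"]
            slices.append(image_io.resize_to_standard(img, 224))
    else:
        if not manifest_path.exists():
            phantom.generate_dataset(
                config.phantom, config.n_per_class, stage_seed(config.seed, "phantom"), data_dir
            )
        manifest = image_io.load_manifest(manifest_path)
        slices = []
        for _, row in manifest.iterrows():
            img = image_io.load_slice(data_dir / row["path"])
            img.label = row["label"]
            img.uid = row["uid"]
            slices.append(img)
    uids = [s.uid for s in slices]
    labels = np.array([1 if s.label == phantom.LABEL_MS else 0 for s in slices])
    pd.DataFrame({"uid": uids, "label": labels}).to_csv(run / "labels.csv", index=False)

    # -- stage 2: deep features --------------------------------------------
    deep_path = run / "deep_features.csv"
    if not deep_path.exists():
        spec = dataclasses.replace(config.backbone, seed=stage_seed(config.seed, "deep"))
        block = deep_features.extract_deep(slices, spec)
        _write_matrix(deep_path, uids, block.matrix)
    _, deep_matrix = _read_matrix(deep_path)

    # -- stage 3: hand-crafted features -------------------------------------
    hcf_path = run / "hcf_features.csv"
    if not hcf_path.exists():
        hcf = handcrafted.extract_hcf_block(slices, config.lbp, config.phog)
        _write_matrix(hcf_path, uids, hcf.matrix)
        (run / "hcf_blocks.yaml").write_text(
            yaml.safe_dump({k: list(v) for k, v in handcrafted.HCF_BLOCK_OFFSETS.items()})
        )
    _, hcf_matrix = _read_matrix(hcf_path)

    # -- stage 4: BFA selection per block ------------------------------------
    selections = {}
    for block_name, matrix, k in (
        ("deep", deep_matrix, config.deep_k),
        ("hcf", hcf_matrix, config.hcf_k),
    ):
        mask_path = run / f"mask_{block_name}.txt"
        if not mask_path.exists():
            cfg = bfa.BFAConfig(
                population=config.bfa_population,
                iterations=config.bfa_iterations,
                target_k=k,
                seed=stage_seed(config.seed, f"select_{block_name}"),
            )
            result = bfa.select_features(matrix, labels, cfg)
            np.savetxt(mask_path, result.selected_indices, fmt="%d")
            (run / f"mask_{block_name}.yaml").write_text(
                yaml.safe_dump(
                    {
                        "block": block_name,
                        "target_k": k,
                        "seed": cfg.seed,
                        "final_fitness": result.fitness,
                    }
                )
            )
        selections[block_name] = np.loadtxt(mask_path, dtype=int, ndmin=1)

    # -- stage 5: fusion ------------------------------------------------------
    fused_path = run / "fused_features.csv"
    if not fused_path.exists():
        fused = classify.serial_fuse(
            deep_matrix[:, selections["deep"]], hcf_matrix[:, selections["hcf"]]
        )
        _write_matrix(fused_path, uids, fused)
    _, fused_matrix = _read_matrix(fused_path)

    # -- stage 6: cross-validated evaluation ---------------------------------
    report_path = run / "report.csv"
    if not report_path.exists():
        eval_seed = stage_seed(config.seed, "evaluate")
        results = [
            classify.five_fold_cv(fused_matrix, labels, name, seed=eval_seed, n_folds=config.folds)
            for name in config.classifiers
        ]
        classify.report_tables(results, report_path)
        for r in results:
            points, area = classify.roc_curve_points(r.scores, r.score_labels)
            roc = pd.DataFrame(points, columns=["FPR", "TPR"])
            roc.to_csv(run / f"roc_{r.classifier_name}.csv", index=False, float_format=_FLOAT_FMT)
            (run / f"roc_{r.classifier_name}.auc.txt").write_text(f"{area:.6f}\n")

    artifacts = {
        p.name: _sha256(p)
        for p in sorted(run.iterdir())
        if p.is_file() and p.name != "artifacts.json"
    }
    (run / "artifacts.json").write_text(json.dumps(artifacts, indent=2, sort_keys=True))
    return run
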