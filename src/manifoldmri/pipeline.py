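"""End-to-end orchestration: images -> features -> geometry -> graph -> GNNs.

A single validated config drives every stage; each stage writes its artifact
into the output directory and is skipped on re-run when the artifact already
exists (delete an artifact to regenerate just that stage and its
dependents).  A manifest JSON records the artifacts, the config hash, and
every seed, so runs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import geometry, graph as graph_mod, stats, synthetic
from .nn.models import ModelConfig
from .nn.training import TrainConfig, train_node_classifier
from .preprocess import (
    FeatureMatrix,
    load_image_directory,
    pca_fit_transform,
    resize_flatten,
    smote_oversample,
    standardize,
)

logger = logging.getLogger(__name__)


class SyntheticInputConfig(BaseModel):
    kind: Literal["synthetic"] = "synthetic"
    n_images: int = 400
    latent_dim: int = 8
    image_size: int = 64
    basis_seed: int = 7
    sample_seed: int = 11


class DirectoryInputConfig(BaseModel):
    kind: Literal["directory"] = "directory"
    path: str


class ArrayInputConfig(BaseModel):
    kind: Literal["array"] = "array"
    path: str


class PreprocessConfig(BaseModel):
    size: int = 64
    geometry_pca_variance: float = Field(0.95, gt=0, le=1)
    graph_pca_components: int = Field(128, ge=1)
    smote_targets: Optional[dict] = None
    smote_k: int = 5
    seed: int = 0


class GeometryConfig(BaseModel):
    epsilon: float = 1e-5
    n_permutations: int = 200
    pga_components: int = 2
    seed: int = 0


class GraphConfig(BaseModel):
    per_class: int = 300
    batch: int = 10
    percentile: float = Field(80.0, gt=0, le=100)
    prune_scope: Literal["per_class", "global"] = "per_class"
    adjacency_mode: Literal["binary", "gaussian_kernel"] = "binary"
    seed: int = 0


class TrainingConfig(BaseModel):
    models: list = Field(default_factory=lambda: ["gcn", "gat", "sage"])
    learning_rate: float = 1e-4
    grad_clip_norm: float = 1.0
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 16
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    class_weighting: bool = True
    seed: int = 0


class PipelineConfig(BaseModel):
    input: Union[SyntheticInputConfig, DirectoryInputConfig, ArrayInputConfig] = (
        Field(default_factory=SyntheticInputConfig, discriminator="kind")
    )
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    graph: GraphConfig = Field(default_factory=GraphConfig)
    training: TrainingConfig = Field(default_factory=TrainingConfig)
    out_dir: str = "pipeline_out"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_pixel_features(config: PipelineConfig) -> FeatureMatrix:
    inp = config.input
    if inp.kind == "synthetic":
        study = synthetic.default_study(
            n_images=inp.n_images, latent_dim=inp.latent_dim,
            image_size=inp.image_size, basis_seed=inp.basis_seed,
            sample_seed=inp.sample_seed,
        )
        latents, labels = synthetic.generate_latent_classes(study)
        images = synthetic.render_images(latents, study)
    elif inp.kind == "directory":
        images, labels = load_image_directory(inp.path)
    else:
        with np.load(inp.path, allow_pickle=False) as data:
            images, labels = data["images"], data["labels"]
    return resize_flatten(images, labels, size=config.preprocess.size)


def _derived_features(features: FeatureMatrix, config: PipelineConfig):
    """Standardize once, then branch into the geometry-stage (variance
    target) and graph-stage (fixed component count) PCA spaces."""
    std, _ = standardize(features)
    geo_fm, _ = pca_fit_transform(
        std, variance_target=config.preprocess.geometry_pca_variance
    )
    max_rank = min(std.X.shape[0] - 1, std.X.shape[1])
    n_comp = min(config.preprocess.graph_pca_components, max_rank)
    if n_comp < config.preprocess.graph_pca_components:
        logger.warning("graph PCA reduced to %d components (rank limit)", n_comp)
    graph_fm, _ = pca_fit_transform(std, n_components=n_comp,
                                    random_state=config.preprocess.seed)
    return geo_fm, graph_fm


def write_table1_style_report(pairs, results, path=None) -> pd.DataFrame:
    """Permutation-test table: one row per class pair, in class order."""
    rows = []
    for pair in pairs:
        if pair not in results:
            raise ValueError(f"missing permutation result for pair {pair}")
        r = results[pair]
        rows.append({
            "pair": f"{pair[0]} vs {pair[1]}",
            "observed_distance": r.observed,
            "p_value": r.p_value,
            "n_permutations": r.n_permutations,
            "seed": r.seed,
        })
    frame = pd.DataFrame(rows)
    if path is not None:
        # 17 significant digits so values survive a CSV round trip exactly
        frame.to_csv(path, index=False, float_format="%.17g")
    return frame


def run_full_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute (or resume) every stage; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages_run: list[str] = []

    def path_of(name: str) -> Path:
        return out / name

    # -- stage: features ---------------------------------------------------
    features_path = path_of("features.npz")
    if force or not features_path.exists():
        logger.info("[features] building pixel feature matrix")
        fm = _load_pixel_features(config)
        if config.preprocess.smote_targets:
            fm = smote_oversample(fm, config.preprocess.smote_targets,
                                  k=config.preprocess.smote_k,
                                  seed=config.preprocess.seed)
        fm.save(features_path)
        stages_run.append("features")
    else:
        logger.info("[features] reusing %s", features_path)
        fm = FeatureMatrix.load(features_path)
    artifacts["features"] = str(features_path)

    geo_fm, graph_fm = _derived_features(fm, config)
    class_order = [str(c) for c in fm.class_order()]
    eps = config.geometry.epsilon

    # -- stage: class distance matrix -------------------------------------
    dist_path = path_of("distance_matrix.csv")
    if force or not dist_path.exists():
        logger.info("[geometry] class geodesic distance matrix")
        D = geometry.class_distance_matrix(geo_fm, epsilon=eps)
        D.to_csv(dist_path)
        stages_run.append("distance_matrix")
    artifacts["distance_matrix"] = str(dist_path)

    # -- stage: permutation tests ------------------------------------------
    perm_path = path_of("permutation_tests.csv")
    if force or not perm_path.exists():
        logger.info("[permtest] %d permutations per class pair",
                    config.geometry.n_permutations)
        labels = np.asarray(geo_fm.labels)
        results = {}
        pairs = list(itertools.combinations(class_order, 2))
        for i, pair in enumerate(pairs):
            a, b = pair
            results[pair] = stats.permutation_test(
                geo_fm.X[labels == a], geo_fm.X[labels == b],
                n_permutations=config.geometry.n_permutations,
                epsilon=eps, seed=config.geometry.seed + i,
            )
        write_table1_style_report(pairs, results, perm_path)
        stages_run.append("permutation_tests")
    artifacts["permutation_tests"] = str(perm_path)

    # -- stage: intra-class variability ------------------------------------
    var_path = path_of("variability.csv")
    if force or not var_path.exists():
        logger.info("[variability] average intra-class Mahalanobis distances")
        var = stats.intra_class_variability(geo_fm, epsilon=eps)
        pd.DataFrame(
            [{"class": c, "avg_mahalanobis": var[c]} for c in class_order]
        ).to_csv(var_path, index=False)
        stages_run.append("variability")
    artifacts["variability"] = str(var_path)

    # -- stage: principal geodesic analysis --------------------------------
    pga_path = path_of("pga.csv")
    if force or not pga_path.exists():
        logger.info("[pga] tangent-space whitened PCA per class")
        labels = np.asarray(geo_fm.labels)
        rows = []
        for c in class_order:
            res = stats.pga(geo_fm.X[labels == c], epsilon=eps,
                            n_components=min(config.geometry.pga_components,
                                             geo_fm.X.shape[1]))
            for k in range(res.n_components):
                rows.append({"class": c, "component": k + 1,
                             "explained_variance_ratio":
                                 res.explained_variance_ratio[k]})
        pd.DataFrame(rows).to_csv(pga_path, index=False)
        stages_run.append("pga")
    artifacts["pga"] = str(pga_path)

    # -- stage: manifold graph ---------------------------------------------
    graph_path = path_of("graph.json")
    if force or not graph_path.exists():
        logger.info("[graph] manifold points and pruned geodesic graph")
        points = graph_mod.sample_manifold_points(
            graph_fm, per_class=config.graph.per_class,
            batch=config.graph.batch, epsilon=eps, seed=config.graph.seed,
        )
        W = graph_mod.build_complete_graph(points)
        g = graph_mod.prune_and_connect(W, percentile=config.graph.percentile,
                                        points=points,
                                        scope=config.graph.prune_scope)
        g.to_json(graph_path)
        stages_run.append("graph")
    artifacts["graph"] = str(graph_path)

    # -- stage: GNN training -----------------------------------------------
    report_paths = {}
    missing = [
        arch for arch in config.training.models
        if force or not path_of(f"report_{arch}.csv").exists()
    ]
    if missing:
        if not graph_path.exists():
            raise RuntimeError("cannot resume stage 'train': missing graph artifact")
        g = graph_mod.ManifoldGraph.from_json(graph_path)
        tensors = graph_mod.graph_tensors(
            g, adjacency_mode=config.graph.adjacency_mode
        )
        tcfg = TrainConfig(
            learning_rate=config.training.learning_rate,
            grad_clip_norm=config.training.grad_clip_norm,
            max_epochs=config.training.max_epochs,
            early_stop_patience=config.training.early_stop_patience,
            batch_size=config.training.batch_size,
            test_fraction=config.training.test_fraction,
            val_fraction_of_train=config.training.val_fraction_of_train,
            class_weighting=config.training.class_weighting,
            seed=config.training.seed,
        )
        for arch in missing:
            logger.info("[train] %s", arch)
            mcfg = ModelConfig.for_arch(arch, n_classes=len(class_order))
            params, history, report = train_node_classifier(tensors, mcfg, tcfg)
            report.to_frame().to_csv(path_of(f"report_{arch}.csv"), index=False)
            report.to_json(path_of(f"report_{arch}.json"))
            history.to_csv(path_of(f"history_{arch}.csv"), index=False)
            np.savez_compressed(path_of(f"params_{arch}.npz"), **params)
            stages_run.append(f"train_{arch}")
    for arch in config.training.models:
        report_paths[arch] = str(path_of(f"report_{arch}.csv"))
    artifacts["reports"] = report_paths

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "seeds": {
            "sample_seed": getattr(config.input, "sample_seed", None),
            "basis_seed": getattr(config.input, "basis_seed", None),
            "preprocess": config.preprocess.seed,
            "geometry": config.geometry.seed,
            "graph": config.graph.seed,
            "training": config.training.seed,
        },
        "artifacts": artifacts,
        "stages_run": stages_run,
    }
    path_of("manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
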