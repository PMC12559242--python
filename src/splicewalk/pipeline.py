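"""End-to-end orchestration and the probability-weighted PSI combination.

The final PSI estimate blends the three strategy outputs per event-cell
pair, weighting by the cascade probabilities:

    PSI = P_ND . S1 + (1-P_ND) . (P_BD . S2 + (1-P_BD) .
          (P_TD+Info . S2 + (1-P_TD+Info) . S3))

where ``.`` is the elementwise product.  The telescoping coefficients sum
to 1 per pair, so the result is a convex combination of the strategies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cell_similarity import SimilarityNetwork, cell_network_from_features
from .diffusion import DiffusionConfig, row_normalize, rwr_diffuse, sparsify_topk
from .event_similarity import (
    EventEmbedding,
    EventFeatureMatrix,
    build_event_similarity,
    combine_event_distances,
    compute_rbp_event_correlation,
    embed_features,
    normalized_euclidean,
)
from .events import (
    CountMatrix,
    EventDefinition,
    ExpressionMatrix,
    PsiMatrix,
    compute_raw_psi,
    normalize_by_library_size,
)
from .imputation import ImputationResult, impute_all
from .scenario import (
    MODEL1_STAGE,
    MODEL2_STAGE,
    FeatureContext,
    ScenarioModel,
    ScenarioProbabilities,
    ScenarioThresholds,
    classify_nd_wd,
    extract_scenario_features,
    finetune_scenario_models,
    predict_scenario_probabilities,
    train_cascade,
)

logger = logging.getLogger(__name__)

FEATURE_SOURCES = ("rbp", "raw_rc", "raw_psi")


@dataclass
class PipelineConfig:
    """File-based run configuration for the command-line entry point."""

    data_dir: str
    output_dir: str
    feature_source: str = "rbp"
    diffusion: DiffusionConfig = field(default_factory=DiffusionConfig)
    k_event: int = 10
    embedding_dim: int = 10
    normalization_scale: float = 1e4
    scenario_thresholds: ScenarioThresholds = field(default_factory=ScenarioThresholds)
    conserved_reference: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(f"feature_source must be one of {FEATURE_SOURCES}")


@dataclass
class PipelineResult:
    psi_raw: PsiMatrix
    imputation: ImputationResult
    probabilities: ScenarioProbabilities
    psi_final: PsiMatrix
    cell_network: SimilarityNetwork
    event_network: SimilarityNetwork
    report: dict
    feature_context: FeatureContext | None = None


def combine_estimates(
    p: ScenarioProbabilities, s1: PsiMatrix, s2: PsiMatrix, s3: PsiMatrix
) -> PsiMatrix:
    """Probability-weighted combination of the three strategies."""
    shapes = {s1.values.shape, s2.values.shape, s3.values.shape, p.p_nd.shape}
    if len(shapes) != 1:
        raise ValueError("probability and strategy matrices must share a shape")
    blend = p.p_nd * s1.values + (1 - p.p_nd) * (
        p.p_bd * s2.values
        + (1 - p.p_bd) * (p.p_td_info * s2.values + (1 - p.p_td_info) * s3.values)
    )
    return PsiMatrix(blend, s1.cell_ids, s1.event_ids)


def impute_dataset(
    rc_ijc: CountMatrix,
    rc_ejc: CountMatrix,
    events: list[EventDefinition],
    rbp_expression: ExpressionMatrix,
    event_features: EventFeatureMatrix | None = None,
    event_embedding: EventEmbedding | None = None,
    host_expression: ExpressionMatrix | None = None,
    scenario_labels: pd.DataFrame | None = None,
    scenario_models: tuple[ScenarioModel, ScenarioModel] | None = None,
    conserved_reference: Mapping[str, float] | None = None,
    feature_source: str = "rbp",
    diffusion: DiffusionConfig | None = None,
    k_event: int = 10,
    embedding_dim: int = 10,
    normalization_scale: float = 1e4,
    scenario_thresholds: ScenarioThresholds | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full imputation pipeline on in-memory inputs.

    ``scenario_labels`` (long table with cell_index/event_index/label) trains
    the cascade on this dataset; alternatively pre-trained
    ``scenario_models`` can be supplied and optionally fine-tuned against a
    ``conserved_reference`` of stable events.
    """
    cfg = diffusion or DiffusionConfig()
    if rc_ijc.cell_ids != rc_ejc.cell_ids:
        raise ValueError("count matrices must share cell ids")
    if feature_source not in FEATURE_SOURCES:
        raise ValueError(f"feature_source must be one of {FEATURE_SOURCES}")

    library_sizes = rc_ijc.values.sum(axis=1) + rc_ejc.values.sum(axis=1)
    library_sizes = np.maximum(library_sizes, 1.0)
    norm_ijc = normalize_by_library_size(rc_ijc, library_sizes, normalization_scale)
    norm_ejc = normalize_by_library_size(rc_ejc, library_sizes, normalization_scale)
    psi_raw = compute_raw_psi(norm_ijc, norm_ejc, events)

    if feature_source == "rbp":
        features = rbp_expression.values
    elif feature_source == "raw_rc":
        features = np.hstack([norm_ijc.values, norm_ejc.values])
    else:
        features = psi_raw.values
    cell_kernel = cell_network_from_features(features, node_ids=list(rc_ijc.cell_ids))
    cell_diffused = sparsify_topk(rwr_diffuse(row_normalize(cell_kernel), cfg))

    if event_embedding is None:
        if event_features is None:
            raise ValueError("either event_features or event_embedding is required")
        L = min(embedding_dim, len(events), len(event_features.feature_ids))
        event_embedding = embed_features(event_features, L, seed=seed)
    per = compute_rbp_event_correlation(psi_raw, rbp_expression)
    ned_emb = normalized_euclidean(event_embedding.values)
    ned_per = normalized_euclidean(per.values)
    dis_event = combine_event_distances(ned_emb, ned_per, per)
    event_kernel = build_event_similarity(dis_event, k_event, [e.event_id for e in events])
    event_diffused = sparsify_topk(rwr_diffuse(row_normalize(event_kernel), cfg))

    imputation = impute_all(
        psi_raw, norm_ijc, norm_ejc, events, cell_diffused, event_diffused,
        tol=cfg.tol, max_iter=cfg.max_iter,
    )

    ctx = FeatureContext(
        rc_ijc=norm_ijc,
        rc_ejc=norm_ejc,
        psi_raw=psi_raw,
        events=events,
        cell_network=cell_diffused,
        host_expression=host_expression,
        library_sizes=library_sizes,
        psi_strategy2=imputation.psi_strategy2,
        rc_ijc_imputed=imputation.rc_ijc_imputed,
        rc_ejc_imputed=imputation.rc_ejc_imputed,
    )
    if scenario_models is None:
        if scenario_labels is None:
            raise ValueError(
                "scenario cascade needs either training labels or pre-trained models"
            )
        model1, model2 = train_cascade(ctx, scenario_labels, seed=seed)
    else:
        model1, model2 = scenario_models
        if conserved_reference:
            model1, model2 = finetune_scenario_models(
                (model1, model2), conserved_reference, ctx, seed=seed,
                thresholds=scenario_thresholds,
            )
    p_nd = classify_nd_wd(psi_raw)
    f1 = extract_scenario_features(ctx, MODEL1_STAGE)
    f2 = extract_scenario_features(ctx, MODEL2_STAGE)
    probabilities = predict_scenario_probabilities(model1, model2, f1, f2, p_nd)
    psi_final = combine_estimates(
        probabilities,
        imputation.psi_strategy1,
        imputation.psi_strategy2,
        imputation.psi_strategy3,
    )
    report = {
        "version": __version__,
        "seed": seed,
        "n_cells": len(rc_ijc.cell_ids),
        "n_events": len(events),
        "feature_source": feature_source,
        "diffusion": asdict(cfg),
        "k_event": k_event,
        "cell_network": {
            "converged": cell_diffused.converged,
            "iterations": cell_diffused.iterations,
            "delta_trace": cell_diffused.delta_trace,
            "median_k": float(np.median(cell_diffused.per_node_k)),
        },
        "event_network": {
            "converged": event_diffused.converged,
            "iterations": event_diffused.iterations,
            "delta_trace": event_diffused.delta_trace,
        },
        "imputation_iterations": imputation.iterations_used,
        "imputation_converged": imputation.converged,
    }
    return PipelineResult(
        psi_raw=psi_raw,
        imputation=imputation,
        probabilities=probabilities,
        psi_final=psi_final,
        cell_network=cell_diffused,
        event_network=event_diffused,
        report=report,
        feature_context=ctx,
    )


def run_pipeline(config: PipelineConfig):
    """File-based pipeline: read a dataset directory, impute, write outputs."""
    from .simulation import read_dataset

    data_dir = Path(config.data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"dataset directory does not exist: {data_dir}")
    dataset = read_dataset(data_dir)
    labels_path = data_dir / "truth_labels.tsv"
    labels = pd.read_csv(labels_path, sep="\t") if labels_path.exists() else None
    conserved = None
    if config.conserved_reference:
        ref = pd.read_csv(config.conserved_reference, sep="\t")
        conserved = dict(zip(ref["event_id"], ref["psi_reference"]))
    result = impute_dataset(
        dataset.rc_ijc,
        dataset.rc_ejc,
        dataset.events,
        dataset.rbp_expression,
        event_features=dataset.event_features,
        host_expression=dataset.host_expression,
        scenario_labels=labels,
        conserved_reference=conserved,
        feature_source=config.feature_source,
        diffusion=config.diffusion,
        k_event=config.k_event,
        embedding_dim=config.embedding_dim,
        normalization_scale=config.normalization_scale,
        scenario_thresholds=config.scenario_thresholds,
        seed=config.seed,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result.psi_raw.to_frame().to_csv(out / "psi_raw.tsv", sep="\t")
        result.imputation.psi_strategy1.to_frame().to_csv(out / "psi_strategy1.tsv", sep="\t")
        result.imputation.psi_strategy2.to_frame().to_csv(out / "psi_strategy2.tsv", sep="\t")
        result.imputation.psi_strategy3.to_frame().to_csv(out / "psi_strategy3.tsv", sep="\t")
        result.psi_final.to_frame().to_csv(out / "psi_final.tsv", sep="\t")
        for name in ("p_nd", "p_bd", "p_td_info"):
            pd.DataFrame(
                getattr(result.probabilities, name),
                index=result.probabilities.cell_ids,
                columns=result.probabilities.event_ids,
            ).to_csv(out / f"{name}.tsv", sep="\t")
        write_network_edges(result.cell_network, out / "cell_network.tsv")
        write_network_edges(result.event_network, out / "event_network.tsv")
        (out / "report.json").write_text(json.dumps(result.report, indent=2))
    except Exception:
        for f in out.glob("*"):
            f.unlink()
        raise
    return result


def write_network_edges(network: SimilarityNetwork, path: str | Path) -> None:
    """Weighted edge list plus a per-node k column on the source rows."""
    rows = []
    ids = network.node_ids
    for i, src in enumerate(ids):
        for j in np.nonzero(network.values[i])[0]:
            rows.append((src, ids[j], network.values[i, j], int(network.per_node_k[i])))
    pd.DataFrame(rows, columns=["source", "target", "weight", "source_k"]).to_csv(
        path, sep="\t", index=False
    )
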