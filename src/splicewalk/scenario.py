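"""Cascade classification of event-cell pairs into dropout scenarios.

For every event-cell pair the cascade decides which imputation strategy is
trustworthy.  A rule (Model0) marks pairs with observed PSI strictly between
0 and 1 as non-dropout (ND); all other pairs carry dropout (WD), including
pairs with no supporting reads whose PSI is 0 by convention.  Two logistic
regressions then act on WD pairs: Model1 scores the probability that the
dropout is biological (BD, the cell truly expresses a single isoform) rather
than technical (TD), and Model2 scores whether a technical dropout's
neighborhood still carries usable junction information (TD+Info vs TD-Info).
Features summarize junction read counts and PSI in the target cell and its
network neighbors and are min-max normalized with bounds frozen at training
time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cell_similarity import SimilarityNetwork
from .events import CountMatrix, EventDefinition, ExpressionMatrix, PsiMatrix

logger = logging.getLogger(__name__)

MODEL1_STAGE = "BD_vs_TD"
MODEL2_STAGE = "TDinfo_vs_TDnoinfo"

LABELS = ("ND", "BD", "TD+Info", "TD-Info")

MODEL1_FEATURES = [
    "host_gene_expression",
    "total_reads",
    "inclusion_reads",
    "exclusion_reads",
    "raw_psi",
    "neighborhood_size",
    "neighbor_mean_inclusion",
    "neighbor_var_inclusion",
    "neighbor_mean_exclusion",
    "neighbor_var_exclusion",
    "neighbor_mean_psi",
    "neighbor_var_psi",
    "frac_neighbors_inclusion_support",
    "frac_neighbors_exclusion_support",
    "frac_neighbors_single_isoform",
    "neighbor_mean_host_expression",
    "library_size",
]
MODEL2_EXTRA = ["abs_strategy2_shift", "strategy2_total_reads"]
MODEL2_FEATURES = MODEL1_FEATURES + MODEL2_EXTRA


@dataclass
class ScenarioThresholds:
    """Decision thresholds for reference-based scenario labeling."""

    reference_extreme_tol: float = 0.05  # |ref - {0,1}| tolerance for BD
    bd_neighbor_frac: float = 0.8  # single-isoform same-side neighbor fraction
    info_neighbor_frac: float = 0.5  # neighbors-with-reads fraction for TD+Info


@dataclass
class ScenarioFeatures:
    """Per event-cell pair feature rows (unnormalized; models freeze min-max
    bounds at fit time)."""

    values: np.ndarray
    feature_ids: list[str]
    cell_index: np.ndarray
    event_index: np.ndarray
    cell_ids: list[str]
    event_ids: list[str]
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.cell_index.size, len(self.feature_ids)):
            raise ValueError("feature matrix shape mismatch")


@dataclass
class ScenarioModel:
    """Binary logistic classifier with frozen min-max feature bounds."""

    stage: str
    feature_ids: list[str]
    coef: np.ndarray
    intercept: float
    feature_min: np.ndarray
    feature_max: np.ndarray

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        span = self.feature_max - self.feature_min
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = (X - self.feature_min) / span
        Z[:, span == 0] = 0.0  # constant features map to 0
        return np.clip(Z, 0.0, 1.0)

    def predict_proba(self, features: ScenarioFeatures) -> np.ndarray:
        if features.stage != self.stage:
            raise ValueError(
                f"feature stage {features.stage!r} does not match model stage {self.stage!r}"
            )
        Z = self._normalize(features.values)
        logits = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))

    def save(self, path: str | Path) -> None:
        header = {
            "stage": self.stage,
            "feature_ids": self.feature_ids,
            "intercept": float(self.intercept),
        }
        lines = ["#" + json.dumps(header), "feature\tweight\tmin\tmax"]
        for i, name in enumerate(self.feature_ids):
            lines.append(
                f"{name}\t{float(self.coef[i])!r}\t{float(self.feature_min[i])!r}"
                f"\t{float(self.feature_max[i])!r}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ScenarioModel":
        lines = Path(path).read_text().splitlines()
        header = json.loads(lines[0].lstrip("#"))
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            stage=header["stage"],
            feature_ids=header["feature_ids"],
            coef=table["weight"].to_numpy(float),
            intercept=float(header["intercept"]),
            feature_min=table["min"].to_numpy(float),
            feature_max=table["max"].to_numpy(float),
        )


@dataclass
class ScenarioProbabilities:
    """Eq-style combination coefficients: ND indicator plus BD and TD+Info
    probabilities (meaningful on WD pairs; ignored for ND downstream)."""

    p_nd: np.ndarray
    p_bd: np.ndarray
    p_td_info: np.ndarray
    cell_ids: list[str]
    event_ids: list[str]

    def __post_init__(self) -> None:
        shape = (len(self.cell_ids), len(self.event_ids))
        for name in ("p_nd", "p_bd", "p_td_info"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape mismatch")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{name} outside [0, 1]")
            setattr(self, name, arr)
        if not np.all(np.isin(self.p_nd, (0.0, 1.0))):
            raise ValueError("p_nd must be a binary indicator")


# ---------------------------------------------------------------------------
# Model0: ND vs WD
# ---------------------------------------------------------------------------


def classify_nd_wd(psi_raw: PsiMatrix) -> np.ndarray:
    """Indicator of non-dropout pairs: observed PSI strictly inside (0, 1).

    No-support pairs carry PSI 0 by convention and thus land in WD.  The
    rule depends only on the PSI ratio, so it is invariant to library-size
    rescaling of the counts.
    """
    P = psi_raw.values
    return ((P > 0) & (P < 1)).astype(float)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureContext:
    """Everything feature extraction needs, aligned on cells x events."""

    rc_ijc: CountMatrix
    rc_ejc: CountMatrix
    psi_raw: PsiMatrix
    events: Sequence[EventDefinition]
    cell_network: SimilarityNetwork
    host_expression: ExpressionMatrix | None = None
    library_sizes: np.ndarray | None = None
    psi_strategy2: PsiMatrix | None = None
    rc_ijc_imputed: CountMatrix | None = None
    rc_ejc_imputed: CountMatrix | None = None
    _tensors: dict = field(default_factory=dict, repr=False)


def _event_mean_counts(counts: CountMatrix, events: Sequence[EventDefinition],
                       which: str) -> np.ndarray:
    pos = {j: i for i, j in enumerate(counts.junction_ids)}
    cols = np.zeros((counts.values.shape[0], len(events)))
    for e_idx, event in enumerate(events):
        ids = event.inclusion_ids if which == "incl" else event.exclusion_ids
        cols[:, e_idx] = counts.values[:, [pos[j] for j in ids]].mean(axis=1)
    return cols


def _feature_tensors(ctx: FeatureContext) -> dict[str, np.ndarray]:
    if ctx._tensors:
        return ctx._tensors
    n_cells = len(ctx.psi_raw.cell_ids)
    n_events = len(ctx.psi_raw.event_ids)
    A = _event_mean_counts(ctx.rc_ijc, ctx.events, "incl")
    B = _event_mean_counts(ctx.rc_ejc, ctx.events, "excl")
    P = ctx.psi_raw.values
    # host gene expression per event (0 when the gene is absent)
    H = np.zeros((n_cells, n_events))
    if ctx.host_expression is not None:
        gene_pos = {g: i for i, g in enumerate(ctx.host_expression.gene_ids)}
        for e_idx, event in enumerate(ctx.events):
            g = gene_pos.get(event.gene_id)
            if g is not None:
                H[:, e_idx] = ctx.host_expression.values[:, g]
    lib = (
        np.asarray(ctx.library_sizes, dtype=float)
        if ctx.library_sizes is not None
        else ctx.rc_ijc.values.sum(axis=1) + ctx.rc_ejc.values.sum(axis=1)
    )
    # neighbor sets: nonzero off-diagonal entries of the diffused network rows
    W = ctx.cell_network.values.copy()
    np.fill_diagonal(W, 0.0)
    adj = (W > 0).astype(float)
    counts = adj.sum(axis=1)
    counts[counts == 0] = 1.0
    NB = adj / counts[:, None]  # unweighted neighbor averaging operator
    single = ((P == 0) | (P == 1)).astype(float)
    nb_mean = {name: NB @ X for name, X in (("A", A), ("B", B), ("P", P), ("H", H))}
    tensors = {
        "host_gene_expression": H,
        "total_reads": A + B,
        "inclusion_reads": A,
        "exclusion_reads": B,
        "raw_psi": P,
        "neighborhood_size": np.broadcast_to(
            ctx.cell_network.per_node_k.astype(float)[:, None], (n_cells, n_events)
        ),
        "neighbor_mean_inclusion": nb_mean["A"],
        "neighbor_var_inclusion": NB @ (A**2) - nb_mean["A"] ** 2,
        "neighbor_mean_exclusion": nb_mean["B"],
        "neighbor_var_exclusion": NB @ (B**2) - nb_mean["B"] ** 2,
        "neighbor_mean_psi": nb_mean["P"],
        "neighbor_var_psi": NB @ (P**2) - nb_mean["P"] ** 2,
        "frac_neighbors_inclusion_support": NB @ (A > 0).astype(float),
        "frac_neighbors_exclusion_support": NB @ (B > 0).astype(float),
        "frac_neighbors_single_isoform": NB @ single,
        "neighbor_mean_host_expression": nb_mean["H"],
        "library_size": np.broadcast_to(lib[:, None], (n_cells, n_events)),
    }
    if ctx.psi_strategy2 is not None:
        tensors["abs_strategy2_shift"] = np.abs(ctx.psi_strategy2.values - P)
    if ctx.rc_ijc_imputed is not None and ctx.rc_ejc_imputed is not None:
        Ai = _event_mean_counts(ctx.rc_ijc_imputed, ctx.events, "incl")
        Bi = _event_mean_counts(ctx.rc_ejc_imputed, ctx.events, "excl")
        tensors["strategy2_total_reads"] = Ai + Bi
    ctx._tensors = tensors
    return tensors


def extract_scenario_features(
    ctx: FeatureContext,
    stage: str,
    cell_index: np.ndarray | None = None,
    event_index: np.ndarray | None = None,
) -> ScenarioFeatures:
    """Feature rows for the given event-cell pairs (all pairs by default)."""
    if stage not in (MODEL1_STAGE, MODEL2_STAGE):
        raise ValueError(f"unknown stage {stage!r}")
    names = MODEL1_FEATURES if stage == MODEL1_STAGE else MODEL2_FEATURES
    tensors = _feature_tensors(ctx)
    missing = [n for n in names if n not in tensors]
    if missing:
        raise ValueError(f"stage {stage} needs strategy-2 outputs for features: {missing}")
    n_cells = len(ctx.psi_raw.cell_ids)
    n_events = len(ctx.psi_raw.event_ids)
    if cell_index is None:
        grid_c, grid_e = np.meshgrid(np.arange(n_cells), np.arange(n_events), indexing="ij")
        cell_index, event_index = grid_c.ravel(), grid_e.ravel()
    cell_index = np.asarray(cell_index)
    event_index = np.asarray(event_index)
    if np.any(cell_index >= n_cells) or np.any(event_index >= n_events):
        raise ValueError("pair index references unknown cell or event")
    values = np.column_stack([tensors[n][cell_index, event_index] for n in names])
    return ScenarioFeatures(
        values, list(names), cell_index, event_index,
        list(ctx.psi_raw.cell_ids), list(ctx.psi_raw.event_ids), stage,
    )


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def _fit_bounds(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def train_scenario_model(
    features: ScenarioFeatures,
    labels: np.ndarray,
    stage: str,
    seed: int = 0,
    warm_start_from: ScenarioModel | None = None,
) -> ScenarioModel:
    """Fit the binary logistic stage on min-max normalized features.

    Class imbalance is handled by inverse-frequency weighting; min-max
    bounds are frozen from the training rows.
    """
    y = np.asarray(labels).astype(int)
    if features.stage != stage:
        raise ValueError("features were extracted for a different stage")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    lo, hi = _fit_bounds(features.values)
    model = ScenarioModel(stage, list(features.feature_ids),
                          np.zeros(len(features.feature_ids)), 0.0, lo, hi)
    Z = model._normalize(features.values)
    clf = LogisticRegression(
        class_weight="balanced", random_state=seed, max_iter=2000,
        warm_start=warm_start_from is not None,
    )
    if warm_start_from is not None:
        clf.classes_ = np.array([0, 1])
        clf.coef_ = warm_start_from.coef.reshape(1, -1).copy()
        clf.intercept_ = np.array([warm_start_from.intercept])
    clf.fit(Z, y)
    model.coef = clf.coef_.ravel().copy()
    model.intercept = float(clf.intercept_[0])
    return model


def predict_scenario_probabilities(
    model1: ScenarioModel,
    model2: ScenarioModel,
    features_m1: ScenarioFeatures,
    features_m2: ScenarioFeatures,
    p_nd: np.ndarray,
) -> ScenarioProbabilities:
    """Fill the BD and TD+Info probability matrices for all pairs.

    ND pairs receive values too, but the combination formula zeroes their
    contribution through the (1 - P_ND) factor.
    """
    n_cells = len(features_m1.cell_ids)
    n_events = len(features_m1.event_ids)
    p_bd = np.zeros((n_cells, n_events))
    p_td = np.zeros((n_cells, n_events))
    p_bd[features_m1.cell_index, features_m1.event_index] = model1.predict_proba(features_m1)
    p_td[features_m2.cell_index, features_m2.event_index] = model2.predict_proba(features_m2)
    return ScenarioProbabilities(
        np.asarray(p_nd, dtype=float), p_bd, p_td,
        list(features_m1.cell_ids), list(features_m1.event_ids),
    )


# ---------------------------------------------------------------------------
# Reference-based labeling and fine-tuning
# ---------------------------------------------------------------------------


def label_pairs_from_reference(
    ctx: FeatureContext,
    reference_psi: Mapping[str, float],
    thresholds: ScenarioThresholds | None = None,
) -> pd.DataFrame:
    """Hard scenario labels for WD pairs from a per-event reference PSI.

    A WD pair is BD when the reference says the event is essentially
    single-isoform (reference PSI within tolerance of 0 or 1) and at least
    ``bd_neighbor_frac`` of the cell's neighbors show the same single
    isoform; otherwise it is TD, split into TD+Info / TD-Info by whether at
    least ``info_neighbor_frac`` of the neighbors carry any reads for the
    event.  The rules partition the WD pairs; ND pairs are labeled ND.
    """
    thr = thresholds or ScenarioThresholds()
    event_ids = list(ctx.psi_raw.event_ids)
    ref = np.full(len(event_ids), np.nan)
    for i, e in enumerate(event_ids):
        if e in reference_psi:
            ref[i] = float(reference_psi[e])
    if np.all(np.isnan(ref)):
        raise ValueError("reference PSI missing for every event")
    tensors = _feature_tensors(ctx)
    P = ctx.psi_raw.values
    support = (
        ctx.psi_raw.support
        if ctx.psi_raw.support is not None
        else tensors["total_reads"] > 0
    )
    W = ctx.cell_network.values.copy()
    np.fill_diagonal(W, 0.0)
    adj = (W > 0).astype(float)
    counts = adj.sum(axis=1)
    counts[counts == 0] = 1.0
    NB = adj / counts[:, None]
    frac_nb_zero_side = NB @ ((P == 0) & support).astype(float)
    frac_nb_one_side = NB @ (P == 1).astype(float)
    frac_nb_reads = NB @ support.astype(float)
    nd = classify_nd_wd(ctx.psi_raw).astype(bool)
    rows = []
    for e_idx, event in enumerate(event_ids):
        if np.isnan(ref[e_idx]):
            continue
        near_zero = abs(ref[e_idx]) <= thr.reference_extreme_tol
        near_one = abs(ref[e_idx] - 1.0) <= thr.reference_extreme_tol
        for c_idx, cell in enumerate(ctx.psi_raw.cell_ids):
            if nd[c_idx, e_idx]:
                label = "ND"
            else:
                same_side = (
                    frac_nb_zero_side[c_idx, e_idx] if near_zero
                    else frac_nb_one_side[c_idx, e_idx] if near_one
                    else 0.0
                )
                if (near_zero or near_one) and same_side >= thr.bd_neighbor_frac:
                    label = "BD"
                elif frac_nb_reads[c_idx, e_idx] >= thr.info_neighbor_frac:
                    label = "TD+Info"
                else:
                    label = "TD-Info"
            rows.append((cell, event, c_idx, e_idx, label))
    return pd.DataFrame(rows, columns=["cell_id", "event_id", "cell_index", "event_index", "label"])


def train_cascade(
    ctx: FeatureContext,
    labels: pd.DataFrame,
    seed: int = 0,
    warm_start: tuple[ScenarioModel, ScenarioModel] | None = None,
) -> tuple[ScenarioModel, ScenarioModel]:
    """Train Model1 (BD=1 vs TD=0) and Model2 (TD+Info=1 vs TD-Info=0) from a
    labeled pair table (columns cell_index, event_index, label)."""
    wd = labels[labels["label"] != "ND"]
    m1_rows = wd
    y1 = (m1_rows["label"] == "BD").to_numpy(int)
    td_rows = wd[wd["label"].isin(["TD+Info", "TD-Info"])]
    y2 = (td_rows["label"] == "TD+Info").to_numpy(int)
    f1 = extract_scenario_features(
        ctx, MODEL1_STAGE, m1_rows["cell_index"].to_numpy(), m1_rows["event_index"].to_numpy()
    )
    f2 = extract_scenario_features(
        ctx, MODEL2_STAGE, td_rows["cell_index"].to_numpy(), td_rows["event_index"].to_numpy()
    )
    w1 = warm_start[0] if warm_start else None
    w2 = warm_start[1] if warm_start else None
    model1 = train_scenario_model(f1, y1, MODEL1_STAGE, seed, w1)
    model2 = train_scenario_model(f2, y2, MODEL2_STAGE, seed, w2)
    return model1, model2


def finetune_scenario_models(
    models: tuple[ScenarioModel, ScenarioModel],
    conserved_reference: Mapping[str, float],
    ctx: FeatureContext,
    seed: int = 0,
    min_pairs_per_class: int = 20,
    thresholds: ScenarioThresholds | None = None,
) -> tuple[ScenarioModel, ScenarioModel]:
    """Warm-start refit of the cascade on labels derived from conserved
    events; skipped (originals returned) when any class is under-populated."""
    if not conserved_reference:
        logger.warning("fine-tuning skipped: empty conserved-event reference")
        return models
    present = {e: v for e, v in conserved_reference.items() if e in set(ctx.psi_raw.event_ids)}
    if not present:
        logger.warning("fine-tuning skipped: no conserved events present in the dataset")
        return models
    labels = label_pairs_from_reference(ctx, present, thresholds)
    wd = labels[labels["label"] != "ND"]
    class_counts = wd["label"].value_counts()
    needed = ["BD", "TD+Info", "TD-Info"]
    if any(class_counts.get(k, 0) < min_pairs_per_class for k in needed):
        logger.warning(
            "fine-tuning skipped: fewer than %d labeled pairs in some class (%s)",
            min_pairs_per_class, class_counts.to_dict(),
        )
        return models
    return train_cascade(ctx, labels, seed=seed, warm_start=models)
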