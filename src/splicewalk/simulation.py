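"""Synthetic single-cell splicing data with known ground truth.

The generator emulates the statistical structure the imputation method
assumes: discrete cell groups with group-specific true PSI per event, RBP
expression linearly coupled to the PSI of a regulated event subset,
log-normal library-size variation, negative-binomial sequencing depth per
event-cell pair, binomial splitting of depth into inclusion/exclusion reads,
and the four observation scenarios — non-dropout (ND), biological dropout
(BD: the group truly expresses a single isoform), and technical dropout with
or without neighborhood information (TD+Info: the pair's depth is
suppressed while group neighbors keep reads; TD-Info: depth is suppressed
across the whole group for the event).

Every cell of a group shares the group's true PSI for an event, so network
smoothing has a well-defined target and per-strategy recovery is testable.
A synthetic events-by-features matrix stands in for sequence-feature
embeddings: features are linear read-outs of the event's group-PSI profile
plus noise, so events with similar splicing behavior have nearby features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .event_similarity import EventFeatureMatrix
from .events import CountMatrix, EventDefinition, ExpressionMatrix, Junction

SCENARIOS = ("ND", "BD", "TD+Info", "TD-Info")


@dataclass
class SimulationParams:
    n_cells: int = 200
    n_events: int = 300
    n_groups: int = 3
    n_rbps: int = 30
    group_proportions: tuple[float, ...] | None = None  # uniform when None
    psi_alpha: float = 2.0  # Beta prior of group-level true PSI
    psi_beta: float = 2.0
    regulated_fraction: float = 0.5  # fraction of events coupled to RBPs
    rbp_coupling: float = 1.0  # linear slope of RBP expression on PSI
    rbp_noise_sd: float = 0.1
    rbp_targets: int = 2  # regulated events averaged per RBP
    mean_depth: float = 20.0  # mean junction reads per event-cell pair
    depth_dispersion: float = 2.0  # negative-binomial size parameter
    libsize_sigma: float = 0.3  # log-normal sigma of library factors
    event_depth_sigma: float = 0.5  # log-normal sigma of per-event depth factors
    bd_rate: float = 0.2  # fraction of pairs forced to single-isoform groups
    td_info_rate: float = 0.2  # fraction of pairs with isolated depth suppression
    td_noinfo_rate: float = 0.1  # fraction of pairs with group-wide suppression
    n_event_features: int = 50
    event_feature_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_proportions is not None:
            props = np.asarray(self.group_proportions, dtype=float)
            if props.size != self.n_groups or not np.isclose(props.sum(), 1.0):
                raise ValueError("group proportions must sum to 1, one per group")
        for rate in (self.bd_rate, self.td_info_rate, self.td_noinfo_rate):
            if not 0 <= rate <= 1:
                raise ValueError("scenario rates must lie in [0, 1]")
        if self.bd_rate + self.td_info_rate + self.td_noinfo_rate >= 1:
            raise ValueError("scenario rates must leave room for ND pairs")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")


@dataclass
class SimTruth:
    true_psi: np.ndarray  # cells x events, pair-level truth (after BD forcing)
    group_psi: np.ndarray  # groups x events
    groups: np.ndarray  # group index per cell
    scenario: np.ndarray  # cells x events, values in SCENARIOS
    library_factors: np.ndarray
    rbp_truth: np.ndarray  # cells x rbps noiseless expression
    cell_ids: list[str] = field(default_factory=list)
    event_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    rc_ijc: CountMatrix  # raw integer inclusion-junction counts
    rc_ejc: CountMatrix
    rbp_expression: ExpressionMatrix
    host_expression: ExpressionMatrix
    event_features: EventFeatureMatrix  # synthetic sequence-feature stand-in
    events: list[EventDefinition]
    truth: SimTruth


def _make_events(n_events: int) -> list[EventDefinition]:
    """Skipped-exon style events: two inclusion junctions flanking a cassette
    exon plus one exclusion junction spanning it."""
    events = []
    for i in range(n_events):
        base = 10_000 * (i + 1)
        incl = [
            Junction("chrS", base + 100, base + 200, "+"),
            Junction("chrS", base + 300, base + 400, "+"),
        ]
        excl = [Junction("chrS", base + 100, base + 400, "+")]
        events.append(EventDefinition(f"ev{i:04d}", f"gene{i:04d}", "SE", incl, excl))
    return events


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, np.clip(p, 1e-12, 1.0))


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Draw one synthetic dataset; deterministic given ``params.seed``."""
    par = params or SimulationParams()
    rng = np.random.default_rng(par.seed)
    n_c, n_e, n_g = par.n_cells, par.n_events, par.n_groups
    cell_ids = [f"cell{i:04d}" for i in range(n_c)]
    events = _make_events(n_e)
    event_ids = [e.event_id for e in events]

    props = (
        np.asarray(par.group_proportions, dtype=float)
        if par.group_proportions is not None
        else np.full(n_g, 1.0 / n_g)
    )
    groups = rng.choice(n_g, size=n_c, p=props)

    group_psi = rng.beta(par.psi_alpha, par.psi_beta, size=(n_g, n_e))

    # scenario assignment: BD and TD-Info act on whole (group, event) blocks,
    # TD+Info on individual pairs of the remaining blocks
    u = rng.random((n_g, n_e))
    bd_block = u < par.bd_rate
    td_noinfo_block = (u >= par.bd_rate) & (u < par.bd_rate + par.td_noinfo_rate)
    normal_block = ~(bd_block | td_noinfo_block)
    # BD blocks: the group expresses a single isoform; direction follows the
    # group's underlying PSI so extreme events stay plausible
    single_side = (rng.random((n_g, n_e)) < group_psi).astype(float)
    group_psi = np.where(bd_block, single_side, group_psi)

    true_psi = group_psi[groups]  # cells x events
    scenario = np.full((n_c, n_e), "ND", dtype=object)
    scenario[bd_block[groups]] = "BD"
    scenario[td_noinfo_block[groups]] = "TD-Info"
    remaining_rate = 1.0 - par.bd_rate - par.td_noinfo_rate
    p_td_info = par.td_info_rate / remaining_rate
    td_info_mask = normal_block[groups] & (rng.random((n_c, n_e)) < p_td_info)
    scenario[td_info_mask] = "TD+Info"

    lib = rng.lognormal(mean=0.0, sigma=par.libsize_sigma, size=n_c)
    lib /= lib.mean()
    event_factor = rng.lognormal(mean=0.0, sigma=par.event_depth_sigma, size=n_e)
    event_factor /= event_factor.mean()

    mean_depth = par.mean_depth * np.outer(lib, event_factor)
    depth = _negative_binomial(rng, mean_depth, par.depth_dispersion)
    suppressed = (scenario == "TD+Info") | (scenario == "TD-Info")
    depth = np.where(suppressed, 0, depth)

    # every junction is crossed by its own reads at the event's depth: each
    # inclusion junction draws Binomial(depth, psi), the exclusion junction
    # Binomial(depth, 1 - psi), independently
    n_incl_junc = len(events[0].inclusion_junctions)
    incl_split = np.stack(
        [rng.binomial(depth, true_psi) for _ in range(n_incl_junc)], axis=2
    )
    rc_ijc_values = incl_split.reshape(n_c, n_e * n_incl_junc).astype(float)
    incl_junction_ids = [j for e in events for j in e.inclusion_ids]
    rc_ejc_values = rng.binomial(depth, 1.0 - true_psi).astype(float)
    excl_junction_ids = [e.exclusion_ids[0] for e in events]

    # RBP expression: linear read-out of regulated events' true PSI
    n_reg = max(1, int(round(par.regulated_fraction * n_e)))
    regulated = rng.choice(n_e, size=n_reg, replace=False)
    targets = rng.choice(regulated, size=(par.n_rbps, min(par.rbp_targets, n_reg)), replace=True)
    baseline = rng.gamma(2.0, 0.5, size=par.n_rbps)
    rbp_truth = baseline[None, :] + par.rbp_coupling * true_psi[:, targets].mean(axis=2)
    rbp_values = np.maximum(
        rbp_truth + rng.normal(0.0, par.rbp_noise_sd, size=rbp_truth.shape), 0.0
    )
    rbp_ids = [f"RBP{i:03d}" for i in range(par.n_rbps)]

    # host gene expression tracks the event's depth factor and the library
    host_values = np.maximum(
        np.outer(lib, event_factor) * rng.lognormal(0.0, 0.2, size=(n_c, n_e)), 0.0
    )
    gene_ids = [e.gene_id for e in events]

    # synthetic sequence-feature stand-in: linear read-outs of the group-PSI
    # profile, so regulatory similar events have nearby features
    loadings = rng.normal(size=(n_g, par.n_event_features))
    feat = group_psi.T @ loadings
    feat = feat + rng.normal(0.0, par.event_feature_noise_sd, size=feat.shape)
    feature_ids = [f"synthfeat{i:03d}" for i in range(par.n_event_features)]

    truth = SimTruth(
        true_psi=true_psi,
        group_psi=group_psi,
        groups=groups,
        scenario=scenario,
        library_factors=lib,
        rbp_truth=rbp_truth,
        cell_ids=cell_ids,
        event_ids=event_ids,
    )
    return SimulatedDataset(
        rc_ijc=CountMatrix(rc_ijc_values, cell_ids, incl_junction_ids),
        rc_ejc=CountMatrix(rc_ejc_values, cell_ids, excl_junction_ids),
        rbp_expression=ExpressionMatrix(rbp_values, cell_ids, rbp_ids, unit="library-size-normalized"),
        host_expression=ExpressionMatrix(host_values, cell_ids, gene_ids, unit="library-size-normalized"),
        event_features=EventFeatureMatrix(feat, event_ids, feature_ids),
        events=events,
        truth=truth,
    )


def truth_labels(truth: SimTruth) -> pd.DataFrame:
    """Long-format scenario labels consumable by the cascade trainer."""
    n_c, n_e = truth.scenario.shape
    grid_c, grid_e = np.meshgrid(np.arange(n_c), np.arange(n_e), indexing="ij")
    return pd.DataFrame(
        {
            "cell_id": np.array(truth.cell_ids)[grid_c.ravel()],
            "event_id": np.array(truth.event_ids)[grid_e.ravel()],
            "cell_index": grid_c.ravel(),
            "event_index": grid_e.ravel(),
            "label": truth.scenario.ravel(),
        }
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write the dataset in the plain-text formats the pipeline reads."""
    from .events import write_event_table, write_matrix_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_event_table(dataset.events, out / "events.tsv")
    write_matrix_tsv(dataset.rc_ijc.to_frame(), out / "rc_ijc.tsv")
    write_matrix_tsv(dataset.rc_ejc.to_frame(), out / "rc_ejc.tsv")
    write_matrix_tsv(dataset.rbp_expression.to_frame(), out / "rbp_expression.tsv")
    write_matrix_tsv(dataset.host_expression.to_frame(), out / "host_expression.tsv")
    feat = pd.DataFrame(
        dataset.event_features.values,
        index=dataset.event_features.event_ids,
        columns=dataset.event_features.feature_ids,
    )
    write_matrix_tsv(feat, out / "event_features.tsv")
    truth = dataset.truth
    write_matrix_tsv(
        pd.DataFrame(truth.true_psi, index=truth.cell_ids, columns=truth.event_ids),
        out / "truth_psi.tsv",
    )
    truth_labels(truth).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": truth.cell_ids, "group": truth.groups}).to_csv(
        out / "groups.tsv", sep="\t", index=False
    )


def read_dataset(indir: str | Path) -> SimulatedDataset:
    """Read back a dataset directory written by :func:`write_dataset`."""
    from .events import read_event_table, read_matrix_tsv

    d = Path(indir)
    events = read_event_table(d / "events.tsv")
    rc_ijc = CountMatrix.from_frame(read_matrix_tsv(d / "rc_ijc.tsv"))
    rc_ejc = CountMatrix.from_frame(read_matrix_tsv(d / "rc_ejc.tsv"))
    rbp = ExpressionMatrix.from_frame(read_matrix_tsv(d / "rbp_expression.tsv"))
    host = ExpressionMatrix.from_frame(read_matrix_tsv(d / "host_expression.tsv"))
    feat_frame = read_matrix_tsv(d / "event_features.tsv")
    feat = EventFeatureMatrix(
        feat_frame.to_numpy(float), list(feat_frame.index), list(feat_frame.columns)
    )
    truth_psi = read_matrix_tsv(d / "truth_psi.tsv")
    labels = pd.read_csv(d / "truth_labels.tsv", sep="\t")
    groups = pd.read_csv(d / "groups.tsv", sep="\t")
    scenario = (
        labels.pivot(index="cell_id", columns="event_id", values="label")
        .reindex(index=truth_psi.index, columns=truth_psi.columns)
        .to_numpy()
    )
    truth = SimTruth(
        true_psi=truth_psi.to_numpy(float),
        group_psi=np.zeros((0, len(truth_psi.columns))),
        groups=groups.set_index("cell_id").loc[truth_psi.index, "group"].to_numpy(),
        scenario=scenario,
        library_factors=np.ones(len(truth_psi.index)),
        rbp_truth=np.zeros((len(truth_psi.index), 0)),
        cell_ids=list(truth_psi.index),
        event_ids=list(truth_psi.columns),
    )
    return SimulatedDataset(rc_ijc, rc_ejc, rbp, host, feat, events, truth)
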