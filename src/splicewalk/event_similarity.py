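"""Event-event similarity from sequence features and RBP regulatory profiles.

Two complementary distances are fused: a normalized Euclidean distance (NED)
between low-dimensional embeddings of event sequence features, and a NED
between the events' RBP-regulation profiles (Pearson correlations of event
PSI with each RBP's expression).  The fusion weight ω(e1,e2) is a logistic
function of the p-value of the correlation between the two events'
regulation profiles, with constants a = -2·ln(9999) and b = ln(9999) fixing
ω(0) = 1e-4, ω(0.5) = 1/2 and ω(1) = 0.9999.  The fused distance feeds the
same adaptive-bandwidth KNN Gaussian kernel used for cells, with a fixed
neighbor count k_event (10 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .cell_similarity import SimilarityNetwork, build_knn_kernel
from .events import EventDefinition, ExpressionMatrix, PsiMatrix

logger = logging.getLogger(__name__)

OMEGA_A = -2.0 * np.log(9999.0)
OMEGA_B = np.log(9999.0)

DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class EventFeatureMatrix:
    """Events x features sequence-derived descriptors."""

    values: np.ndarray
    event_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if self.values.shape != (len(self.event_ids), len(self.feature_ids)):
            raise ValueError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")


@dataclass
class EventEmbedding:
    """Events x L latent representation of sequence features."""

    values: np.ndarray
    event_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.event_ids):
            raise ValueError("embedding shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding must be finite")


@dataclass
class RegulatoryCorrelation:
    """Events x RBPs Pearson correlations of PSI with RBP expression."""

    values: np.ndarray
    pvalues: np.ndarray
    event_ids: list[str]
    rbp_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        shape = (len(self.event_ids), len(self.rbp_ids))
        if self.values.shape != shape or self.pvalues.shape != shape:
            raise ValueError("correlation matrix shape mismatch")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values outside [0, 1]")


# ---------------------------------------------------------------------------
# Sequence features
# ---------------------------------------------------------------------------


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [p + b for p in kmers for b in "ACGT"]
    return kmers


def _kmer_frequencies(seq: str, k: int, kmers: list[str]) -> np.ndarray:
    seq = seq.upper()
    counts = dict.fromkeys(kmers, 0)
    total = 0
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in counts:
            counts[kmer] += 1
            total += 1
    freq = np.array([counts[m] for m in kmers], dtype=float)
    return freq / total if total else freq


def _reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


DEFAULT_MOTIFS = ("GT", "AG", "GTAAG", "TACTAAC", "TTTT", "CTCTCT")


def _alternative_region(event: EventDefinition) -> list[tuple[str, int, int]]:
    """Genomic segments spanned by the exclusion junctions but not covered by
    any inclusion junction: the alternative segment of the event."""
    chrom = event.exclusion_junctions[0].chrom
    span_start = min(j.start for j in event.exclusion_junctions)
    span_end = max(j.end for j in event.exclusion_junctions)
    cuts = {span_start, span_end}
    for j in event.inclusion_junctions:
        cuts.add(min(max(j.start, span_start), span_end))
        cuts.add(min(max(j.end, span_start), span_end))
    bounds = sorted(cuts)
    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        covered = any(j.start <= a and b <= j.end for j in event.inclusion_junctions)
        if not covered and b > a:
            segments.append((chrom, a, b))
    return segments


def extract_sequence_features(
    events: list[EventDefinition],
    genome_fasta: str,
    k: int = 4,
    flank: int = 300,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
) -> EventFeatureMatrix:
    """Length, k-mer and motif features of the alternative region and flanks.

    Sequences on the minus strand are reverse-complemented.  A conservation
    column is emitted zero-filled; precomputed conservation scores can be
    appended by the caller.
    """
    from pyfaidx import Fasta

    genome = Fasta(genome_fasta)
    kmers = _all_kmers(k)
    feature_ids = (
        ["len_alt", "len_upstream_flank", "len_downstream_flank"]
        + [f"kmer_{m}" for m in kmers]
        + [f"motif_{m}" for m in motifs]
        + ["conservation"]
    )
    rows = []
    for event in events:
        chrom = event.exclusion_junctions[0].chrom
        if chrom not in genome:
            raise ValueError(f"event {event.event_id}: contig {chrom!r} not in genome")
        contig_len = len(genome[chrom])
        segments = _alternative_region(event)
        if any(seg[2] > contig_len for seg in segments):
            raise ValueError(f"event {event.event_id}: coordinates outside contig {chrom!r}")
        alt_seq = "".join(str(genome[chrom][a:b]) for _, a, b in segments)
        span_start = min(j.start for j in event.exclusion_junctions)
        span_end = max(j.end for j in event.exclusion_junctions)
        up = str(genome[chrom][max(0, span_start - flank) : span_start])
        down = str(genome[chrom][span_end : min(contig_len, span_end + flank)])
        strand = event.exclusion_junctions[0].strand
        if strand == "-":
            alt_seq = _reverse_complement(alt_seq)
            up, down = _reverse_complement(down), _reverse_complement(up)
        full = up + alt_seq + down
        row = [float(len(alt_seq)), float(len(up)), float(len(down))]
        row.extend(_kmer_frequencies(full, k, kmers))
        row.extend(float(full.upper().count(m)) for m in motifs)
        row.append(0.0)  # conservation placeholder
        rows.append(row)
    return EventFeatureMatrix(np.array(rows), [e.event_id for e in events], feature_ids)


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------


def embed_features(features: EventFeatureMatrix, L: int, seed: int = 0) -> EventEmbedding:
    """Deterministic linear embedding of standardized features.

    A truncated singular decomposition of the column-standardized feature
    matrix; the top-L scores are the embedding.  Signs are fixed so the
    largest-magnitude loading of each component is positive, making the
    output reproducible.  Any user-trained E x L embedding can be supplied
    downstream in its place.
    """
    X = features.values
    E, F = X.shape
    if E < 2:
        raise ValueError("need at least 2 events to embed")
    if L > min(E, F):
        raise ValueError(f"embedding dimension L={L} exceeds min(E, F)={min(E, F)}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    if Z.shape[1] == 0:
        raise ValueError("all feature columns are constant")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    L_eff = min(L, s.size)
    scores = U[:, :L_eff] * s[:L_eff]
    # sign convention: dominant loading positive
    for j in range(L_eff):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            scores[:, j] = -scores[:, j]
    if L_eff < L:
        scores = np.hstack([scores, np.zeros((E, L - L_eff))])
    recon = np.linalg.norm(Z - (U[:, :L_eff] * s[:L_eff]) @ Vt[:L_eff], ord="fro")
    logger.debug("embedding reconstruction error (Frobenius): %.4g", recon)
    return EventEmbedding(scores, list(features.event_ids))


# ---------------------------------------------------------------------------
# Regulatory correlation
# ---------------------------------------------------------------------------


def _pearson_pvalue(r: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform."""
    n = np.asarray(n, dtype=float)
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = np.where(df > 0, 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), 1.0)
    p = np.where(np.isclose(np.abs(r), 1.0) & (df > 0), 0.0, p)
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def compute_rbp_event_correlation(
    psi_raw: PsiMatrix, rbp_expression: ExpressionMatrix
) -> RegulatoryCorrelation:
    """Pearson correlation of each event's PSI with each RBP's expression.

    Cells whose pair lacks junction support are excluded pairwise (their
    PSI 0 is a convention, not a measurement).  Constant vectors or fewer
    than 3 usable cells yield correlation 0 with p-value 1.
    """
    if psi_raw.cell_ids != rbp_expression.cell_ids:
        raise ValueError("PSI and RBP expression must share cell ids in order")
    E = len(psi_raw.event_ids)
    B = len(rbp_expression.gene_ids)
    R = np.zeros((E, B))
    P = np.ones((E, B))
    expr = rbp_expression.values
    support = psi_raw.support if psi_raw.support is not None else np.ones_like(psi_raw.values, bool)
    few = 0
    for e in range(E):
        mask = support[:, e]
        n = int(mask.sum())
        if n < 3:
            few += 1
            continue
        y = psi_raw.values[mask, e]
        X = expr[mask]
        y_c = y - y.mean()
        X_c = X - X.mean(axis=0)
        denom = np.sqrt((y_c**2).sum()) * np.sqrt((X_c**2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (X_c * y_c[:, None]).sum(axis=0) / denom
        r = np.nan_to_num(r, nan=0.0)
        R[e] = np.clip(r, -1.0, 1.0)
        P[e] = np.where(denom > 0, _pearson_pvalue(R[e], n), 1.0)
    if few:
        logger.warning("RBP correlation: %d events with <3 supported cells set to r=0, p=1", few)
    return RegulatoryCorrelation(R, P, list(psi_raw.event_ids), list(rbp_expression.gene_ids))


# ---------------------------------------------------------------------------
# Distances and fusion
# ---------------------------------------------------------------------------


def normalized_euclidean(matrix: np.ndarray) -> np.ndarray:
    """Pairwise NED: Euclidean distance with per-column variance weights
    (sample variance, denominator n-1).  Zero-variance columns are dropped."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    var = X.var(axis=0, ddof=1)
    keep = var > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if not keep.all():
        logger.warning("normalized_euclidean: dropping %d zero-variance columns",
                       int((~keep).sum()))
    Z = X[:, keep] / np.sqrt(var[keep])
    return squareform(pdist(Z, metric="euclidean"))


def omega(p: np.ndarray) -> np.ndarray:
    """Fusion coefficient ω(p) = 1 / (1 + exp(a p + b))."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return 1.0 / (1.0 + np.exp(OMEGA_A * p + OMEGA_B))


def profile_correlation_pvalues(per: RegulatoryCorrelation) -> np.ndarray:
    """P-values of the Pearson correlation between every two events'
    RBP-regulation profiles (rows of the correlation matrix)."""
    X = per.values
    B = X.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Xc.T) / np.outer(norms, norms)
    R = np.nan_to_num(R, nan=0.0)
    P = _pearson_pvalue(R, B)
    P[norms == 0, :] = 1.0
    P[:, norms == 0] = 1.0
    np.fill_diagonal(P, 0.0)
    return P


def combine_event_distances(
    ned_emb: np.ndarray,
    ned_per: np.ndarray,
    regulatory_correlation: RegulatoryCorrelation,
) -> np.ndarray:
    """Fused event distance (1-ω)·NED_emb + ω·NED_per with ω from the
    profile-correlation p-values."""
    if ned_emb.shape != ned_per.shape:
        raise ValueError("distance matrices must share a shape")
    P = profile_correlation_pvalues(regulatory_correlation)
    if P.shape != ned_emb.shape:
        raise ValueError("correlation profile count does not match distance matrices")
    w = omega(P)
    return (1.0 - w) * ned_emb + w * ned_per


def build_event_similarity(
    dis_event: np.ndarray, k_event: int = 10, event_ids: list[str] | None = None
) -> SimilarityNetwork:
    """Event KNN Gaussian kernel with a fixed neighbor count."""
    n = dis_event.shape[0]
    if k_event >= n:
        raise ValueError(f"k_event={k_event} must be smaller than the event count {n}")
    return build_knn_kernel(dis_event, k_event, event_ids)
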