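"""Splicing events, junction count matrices and PSI computation.

A splicing event is quantified from split-read (junction) evidence: the set of
inclusion junctions supports the isoform containing the alternative segment,
the set of exclusion junctions supports the isoform skipping it.  The raw PSI
(percent spliced-in) of an event in a cell is the ratio of the mean inclusion
junction read count to the sum of the mean inclusion and mean exclusion
counts; a pair with no supporting reads on either side is set to PSI 0 and
flagged as unsupported.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = {"SE", "A3SS", "A5SS", "RI", "MXE", "AL"}

_JUNCTION_RE = re.compile(r"^([^:]+):(\d+)-(\d+):([+\-.])$")


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction as a 0-based half-open intronic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("junction chrom must be nonempty")
        if self.end <= self.start:
            raise ValueError(
                f"junction end must exceed start, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @classmethod
    def parse(cls, text: str) -> "Junction":
        m = _JUNCTION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"malformed junction coordinate string: {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"


@dataclass
class EventDefinition:
    """One alternative-splicing event with typed junction evidence sets."""

    event_id: str
    gene_id: str
    event_type: str
    inclusion_junctions: list[Junction]
    exclusion_junctions: list[Junction]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_junctions or not self.exclusion_junctions:
            raise ValueError(
                f"event {self.event_id}: needs >=1 inclusion and >=1 exclusion junction"
            )
        if set(self.inclusion_junctions) & set(self.exclusion_junctions):
            raise ValueError(
                f"event {self.event_id}: inclusion/exclusion junction sets overlap"
            )

    @property
    def inclusion_ids(self) -> list[str]:
        return [str(j) for j in self.inclusion_junctions]

    @property
    def exclusion_ids(self) -> list[str]:
        return [str(j) for j in self.exclusion_junctions]


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {what} labels")
    return labels


@dataclass
class CountMatrix:
    """Cells x junctions nonnegative read counts, raw or library-normalized."""

    values: np.ndarray
    cell_ids: list[str]
    junction_ids: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _check_labels(self.cell_ids, "cell")
        self.junction_ids = _check_labels(self.junction_ids, "junction")
        if self.values.shape != (len(self.cell_ids), len(self.junction_ids)):
            raise ValueError("count matrix shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("count matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.junction_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, normalized: bool = False) -> "CountMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), normalized)


@dataclass
class PsiMatrix:
    """Cells x events PSI values in [0, 1].

    ``support`` marks pairs backed by at least one junction read; unsupported
    pairs carry the conventional value 0.
    """

    values: np.ndarray
    cell_ids: list[str]
    event_ids: list[str]
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _check_labels(self.cell_ids, "cell")
        self.event_ids = _check_labels(self.event_ids, "event")
        if self.values.shape != (len(self.cell_ids), len(self.event_ids)):
            raise ValueError("PSI matrix shape does not match labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("PSI values outside [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape:
                raise ValueError("support mask shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.event_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PsiMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


@dataclass
class ExpressionMatrix:
    """Cells x genes nonnegative expression values."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit: str = "raw"  # raw | TPM | library-size-normalized

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _check_labels(self.cell_ids, "cell")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("expression matrix shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("expression matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, unit: str = "raw") -> "ExpressionMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), unit)


# ---------------------------------------------------------------------------
# Event table I/O
# ---------------------------------------------------------------------------

EVENT_TABLE_COLUMNS = [
    "event_id",
    "gene_id",
    "event_type",
    "inclusion_junctions",
    "exclusion_junctions",
]


def read_event_table(path: str | Path) -> list[EventDefinition]:
    """Read a TSV event definition table.

    Junctions are encoded ``chrom:start-end:strand`` and comma-separated
    within the inclusion/exclusion columns.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVENT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns: {missing}")
    events: list[EventDefinition] = []
    seen: set[str] = set()
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            incl = [Junction.parse(t) for t in str(row.inclusion_junctions).split(",")]
            excl = [Junction.parse(t) for t in str(row.exclusion_junctions).split(",")]
            event = EventDefinition(
                str(row.event_id).strip(),
                str(row.gene_id).strip(),
                str(row.event_type).strip(),
                incl,
                excl,
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
        if event.event_id in seen:
            raise ValueError(f"{path} line {lineno}: duplicate event_id {event.event_id!r}")
        seen.add(event.event_id)
        events.append(event)
    return events


def write_event_table(events: Iterable[EventDefinition], path: str | Path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "inclusion_junctions": ",".join(e.inclusion_ids),
            "exclusion_junctions": ",".join(e.exclusion_ids),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrix I/O: TSV and MatrixMarket
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")


def read_count_mtx(mtx_path: str | Path, cells_path: str | Path, cols_path: str | Path,
                   normalized: bool = False) -> CountMatrix:
    from scipy.io import mmread

    values = np.asarray(mmread(str(mtx_path)).todense(), dtype=float)
    cells = Path(cells_path).read_text().split()
    cols = Path(cols_path).read_text().split()
    return CountMatrix(values, cells, cols, normalized)


def write_count_mtx(matrix: CountMatrix, mtx_path: str | Path, cells_path: str | Path,
                    cols_path: str | Path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(matrix.values))
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")
    Path(cols_path).write_text("\n".join(matrix.junction_ids) + "\n")


# ---------------------------------------------------------------------------
# Junction counting from alignments
# ---------------------------------------------------------------------------


def _read_skips(read) -> list[tuple[int, int]]:
    """Reference intervals skipped by N CIGAR operations of one read."""
    skips: list[tuple[int, int]] = []
    if read.cigartuples is None:
        return skips
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op == 3:  # N: skipped region
            skips.append((pos, pos + length))
        if op in (0, 2, 3, 7, 8):  # consume reference: M, D, N, =, X
            pos += length
    return skips


def count_junction_reads(
    alignments: Mapping[str, str | Path] | str | Path,
    junctions: Sequence[Junction],
    barcode_tag: str | None = None,
) -> CountMatrix:
    """Count split reads whose skipped segment matches a junction exactly.

    ``alignments`` is either a mapping cell_id -> SAM/BAM path (plate-style
    data, one file per cell) or a single path combined with ``barcode_tag``
    naming the tag that carries the cell barcode.  A read with several N
    operations contributes once to every matching junction.
    """
    import pysam

    if not junctions:
        raise ValueError("junction list must be nonempty")
    junction_ids = [str(j) for j in junctions]
    lookup: dict[tuple[str, int, int], int] = {
        (j.chrom, j.start, j.end): i for i, j in enumerate(junctions)
    }

    def count_file(path: str | Path, per_cell: dict[str, np.ndarray],
                   fixed_cell: str | None) -> None:
        with pysam.AlignmentFile(str(path), check_sq=False) as handle:
            for read in handle:
                if read.is_unmapped:
                    continue
                if fixed_cell is None:
                    if not read.has_tag(barcode_tag):
                        raise ValueError(
                            f"read {read.query_name} lacks barcode tag {barcode_tag!r}"
                        )
                    cell = str(read.get_tag(barcode_tag))
                else:
                    cell = fixed_cell
                row = per_cell.setdefault(cell, np.zeros(len(junctions)))
                chrom = read.reference_name
                for start, end in _read_skips(read):
                    idx = lookup.get((chrom, start, end))
                    if idx is not None:
                        row[idx] += 1

    per_cell: dict[str, np.ndarray] = {}
    if isinstance(alignments, (str, Path)):
        if barcode_tag is None:
            raise ValueError("single alignment file requires barcode_tag")
        count_file(alignments, per_cell, None)
        cell_ids = sorted(per_cell)
    else:
        cell_ids = list(alignments)
        for cell_id in cell_ids:
            per_cell.setdefault(cell_id, np.zeros(len(junctions)))
            count_file(alignments[cell_id], per_cell, cell_id)
    values = np.vstack([per_cell[c] for c in cell_ids]) if cell_ids else np.zeros((0, len(junctions)))
    return CountMatrix(values, cell_ids, junction_ids, normalized=False)


# ---------------------------------------------------------------------------
# Normalization and PSI
# ---------------------------------------------------------------------------


def normalize_by_library_size(
    counts: CountMatrix, library_sizes: Sequence[float], scale: float = 1e4
) -> CountMatrix:
    """Divide each cell's counts by its library size and multiply by ``scale``."""
    sizes = np.asarray(library_sizes, dtype=float)
    if sizes.shape != (len(counts.cell_ids),):
        raise ValueError("one library size per cell required")
    if np.any(sizes <= 0):
        raise ValueError("library sizes must be strictly positive")
    values = counts.values / sizes[:, None] * scale
    return CountMatrix(values, counts.cell_ids, counts.junction_ids, normalized=True)


def compute_raw_psi(
    rc_ijc: CountMatrix, rc_ejc: CountMatrix, events: Sequence[EventDefinition]
) -> PsiMatrix:
    """Raw PSI per event-cell pair: mean inclusion / (mean inclusion + mean exclusion).

    Pairs with zero support on both junction classes are set to 0 and marked
    unsupported in the ``support`` mask.
    """
    if rc_ijc.cell_ids != rc_ejc.cell_ids:
        raise ValueError("inclusion/exclusion matrices must share cell ids")
    incl_pos = {j: i for i, j in enumerate(rc_ijc.junction_ids)}
    excl_pos = {j: i for i, j in enumerate(rc_ejc.junction_ids)}
    n_cells = len(rc_ijc.cell_ids)
    n_events = len(events)
    psi = np.zeros((n_cells, n_events))
    support = np.zeros((n_cells, n_events), dtype=bool)
    for e_idx, event in enumerate(events):
        try:
            i_cols = [incl_pos[j] for j in event.inclusion_ids]
            j_cols = [excl_pos[j] for j in event.exclusion_ids]
        except KeyError as exc:
            raise ValueError(
                f"event {event.event_id} references unknown junction id {exc.args[0]!r}"
            ) from exc
        mean_incl = rc_ijc.values[:, i_cols].mean(axis=1)
        mean_excl = rc_ejc.values[:, j_cols].mean(axis=1)
        denom = mean_incl + mean_excl
        ok = denom > 0
        psi[ok, e_idx] = mean_incl[ok] / denom[ok]
        support[:, e_idx] = ok
    return PsiMatrix(psi, rc_ijc.cell_ids, [e.event_id for e in events], support)


def tpm_normalize(
    raw_expression: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Standard TPM: per-cell length-normalized rates scaled to sum 1e6."""
    try:
        lengths = np.asarray([float(gene_lengths[g]) for g in raw_expression.gene_ids])
    except KeyError as exc:
        raise ValueError(f"missing gene length for {exc.args[0]!r}") from exc
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rates = raw_expression.values / lengths[None, :]
    totals = rates.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        logger.warning("TPM normalization: %d all-zero cells left as zero", int(zero.sum()))
        totals = np.where(zero, 1.0, totals)
    tpm = rates / totals[:, None] * 1e6
    return ExpressionMatrix(tpm, raw_expression.cell_ids, raw_expression.gene_ids, unit="TPM")
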