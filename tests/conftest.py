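import numpy as np
import pytest

from splicewalk.simulation import SimulationParams, simulate_dataset, truth_labels


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """60-cell, 80-event dataset for fast end-to-end checks."""
    return simulate_dataset(SimulationParams(n_cells=60, n_events=80, n_groups=3, seed=11))


@pytest.fixture(scope="session")
def acceptance_dataset():
    """The scaled-down study conditions: 200 cells x 300 events, 3 groups,
    default scenario rates, seed 7."""
    return simulate_dataset(SimulationParams(n_cells=200, n_events=300, n_groups=3, seed=7))


@pytest.fixture(scope="session")
def acceptance_run(acceptance_dataset):
    """Single shared pipeline run on the acceptance dataset."""
    import splicewalk as sw

    ds = acceptance_dataset
    labels = truth_labels(ds.truth)
    return sw.impute_dataset(
        ds.rc_ijc,
        ds.rc_ejc,
        ds.events,
        ds.rbp_expression,
        event_features=ds.event_features,
        host_expression=ds.host_expression,
        scenario_labels=labels,
        seed=7,
    )


def write_sam(path, reads, contigs=(("chr1", 100000),)):
    """Minimal SAM writer for fixtures.

    ``reads`` are (qname, chrom, pos_1based, cigar) or with a trailing dict of
    extra tags, e.g. {"CB": "cellA"}.
    """
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in contigs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for read in reads:
        name, chrom, pos, cigar = read[:4]
        tags = read[4] if len(read) > 4 else {}
        seq_len = sum(
            int(n) for n, op in _cigar_tokens(cigar) if op in "MIS=X"
        )
        fields = [name, "0", chrom, str(pos), "60", cigar, "*", "0", "0",
                  "A" * seq_len, "I" * seq_len]
        for tag, value in tags.items():
            fields.append(f"{tag}:Z:{value}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def _cigar_tokens(cigar):
    import re

    return [(m.group(1), m.group(2)) for m in re.finditer(r"(\d+)([MIDNSHP=X])", cigar)]
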