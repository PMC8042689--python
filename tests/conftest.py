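import numpy as np
import pandas as pd
import pytest

from splicetransfer.splicing import EventCountTable
from splicetransfer.synthetic import CohortConfig, generate_cohort


def make_table(ic: dict, sc: dict, genes=None) -> EventCountTable:
    """Build a small EventCountTable from {sample: [counts per event]} dicts."""
    ic_df = pd.DataFrame(ic)
    sc_df = pd.DataFrame(sc)
    n = len(ic_df)
    ids = pd.Index([f"ev{i + 1:03d}" for i in range(n)], name="event_id")
    ic_df.index = sc_df.index = ids
    events = pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"G{i + 1}" for i in range(n)],
            "chrom": ["chr1"] * n,
            "start": [1000 * (i + 1) + 1 for i in range(n)],
            "end": [1000 * (i + 1) + 100 for i in range(n)],
            "strand": ["+"] * n,
        },
        index=ids,
    )
    return EventCountTable(events, ic_df.astype(np.int64), sc_df.astype(np.int64))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort with a clear planted structure, shared across tests."""
    cfg = CohortConfig(
        n_cell_a=8, n_cell_b=8, n_patients=30, n_events=40, n_informative=10,
        n_genes=60, n_de_genes=12, depth_mean=150.0, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def cell_groups(small_cohort):
    ann = small_cohort.annotation
    cells = ann[ann["domain"] == "cell_line"]
    return {
        "A": list(cells.index[cells["subtype"] == "A"]),
        "B": list(cells.index[cells["subtype"] == "B"]),
    }
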