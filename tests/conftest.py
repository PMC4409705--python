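import numpy as np
import pandas as pd
import pytest

from coregulation import ParamsTable, WorldConfig, simulate_world


@pytest.fixture
def small_table() -> ParamsTable:
    """Five genes with a mix of present and absent parameters."""
    frame = pd.DataFrame(
        {
            "x": [10.0, 4.0, 6.0, np.nan, 2.0],
            "I": [5.0, 2.0, np.nan, 3.0, 4.0],
            "b": [3.0, np.nan, 1.0, 2.0, 0.0],
            "m": [15.0, np.nan, 8.0, 6.0, 100.0],
        },
        index=pd.Index(["P1", "P2", "P3", "P4", "P5"], name="gene_id"),
    )
    return ParamsTable(frame)


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world shared by read-only tests."""
    return simulate_world(WorldConfig(seed=20))


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path
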