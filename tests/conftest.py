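import numpy as np
import pandas as pd
import pytest

from reactscape import CountTable, make_metadata


def build_table(counts: dict, habitat="soil", season="spring", paired=True) -> CountTable:
    """Build a CountTable from {sample_id: count-list}; DNA/RNA inferred
    from a trailing _DNA/_RNA in the sample id, pair id from the prefix."""
    ids = list(counts)
    n_otu = len(next(iter(counts.values())))
    frame = pd.DataFrame(
        {k: np.asarray(v, dtype=int) for k, v in counts.items()},
        index=[f"otu{i}" for i in range(n_otu)],
    )
    nat = ["RNA" if s.endswith("_RNA") else "DNA" for s in ids]
    pid = [s.rsplit("_", 1)[0] if paired else "" for s in ids]
    meta = make_metadata(ids, habitat, season, nat, pid)
    return CountTable(frame, meta)


@pytest.fixture
def paired_table() -> CountTable:
    """Two DNA/RNA pairs over 4 OTUs, including a phantom (otu3 in p2)."""
    return build_table(
        {
            "p1_DNA": [10, 5, 3, 0],
            "p1_RNA": [8, 0, 3, 0],
            "p2_DNA": [2, 7, 0, 0],
            "p2_RNA": [1, 7, 0, 4],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
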