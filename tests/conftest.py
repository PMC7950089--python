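import numpy as np
import pandas as pd
import pytest

from prosal.formats import (
    GROUP_NEGATIVE,
    GROUP_POSITIVE,
    PeptideQuantTable,
    ProteinRecord,
)


def make_quant(rows: dict, group_map: dict, sequences: dict | None = None,
               proteins: dict | None = None, quality: dict | None = None
               ) -> PeptideQuantTable:
    """Build a quant table from {peptide_id: {sample: intensity-or-None}}."""
    samples = list(group_map)
    data = {}
    for col in ("sequence", "proteins", "quality"):
        data[col] = {}
    for pid, values in rows.items():
        data["sequence"][pid] = (sequences or {}).get(pid, "PEPTIDE".replace("PEPTIDE", "AAAAK"))
        data["proteins"][pid] = (proteins or {}).get(pid, "SYN0001")
        data["quality"][pid] = (quality or {}).get(pid, 10.0)
    frame = pd.DataFrame(data)
    for s in samples:
        frame[s] = [np.nan if rows[pid].get(s) is None else float(rows[pid][s])
                    for pid in rows]
    frame.index = pd.Index(list(rows), name="peptide_id")
    return PeptideQuantTable(data=frame, group_map=dict(group_map))


@pytest.fixture
def two_group_map():
    return {
        "A1": GROUP_NEGATIVE, "A2": GROUP_NEGATIVE, "A3": GROUP_NEGATIVE,
        "B1": GROUP_POSITIVE, "B2": GROUP_POSITIVE, "B3": GROUP_POSITIVE,
    }


@pytest.fixture
def tiny_proteome():
    return [
        ProteinRecord("PR001", "MKAFSVVYAKGH", "hand-checkable example"),
        ProteinRecord("PR002", "AAAFGAAA", "single F|G bond"),
        ProteinRecord("PR003", "MQGPLKAQGSVW", "Q|G sites"),
    ]


def random_quant(n_rows: int, group_map: dict, seed: int = 0,
                 missing_rate: float = 0.2) -> PeptideQuantTable:
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(n_rows):
        pid = f"pep{i:04d}"
        rows[pid] = {
            s: (None if rng.random() < missing_rate
                else float(rng.lognormal(14, 1)))
            for s in group_map
        }
    return make_quant(rows, group_map)
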