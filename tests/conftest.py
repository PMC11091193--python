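import numpy as np
import pandas as pd
import pytest

from holopipe.io import CountMatrix, SampleSheet


@pytest.fixture
def toy_sheet() -> SampleSheet:
    rows = []
    for cond in ("control", "runt_rnai"):
        for tp in ("0hpa", "3hpa"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{tp}_{cond}_r{rep}",
                        "timepoint": tp,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def make_matrix(counts: np.ndarray, sheet: SampleSheet, ids=None) -> CountMatrix:
    ids = ids or [f"g{i:04d}" for i in range(counts.shape[0])]
    return CountMatrix(ids, sheet.sample_ids, np.asarray(counts, dtype=np.int64), sheet)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    rows = [
        {
            "sample_id": f"s{j}",
            "timepoint": "0hpa",
            "condition": "control" if j < 3 else "runt_rnai",
            "replicate": j % 3 + 1,
        }
        for j in range(6)
    ]
    return SampleSheet(pd.DataFrame(rows))
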