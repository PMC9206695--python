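import numpy as np
import pandas as pd
import pytest

from huangjiu_core import load_annotation, load_table1
from huangjiu_core.ha_quant import HATable


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def annotation():
    return load_annotation()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_ha_table(mean: dict, timepoints: list[str]) -> HATable:
    """Build a small HATable from a dict of compound -> values (None = ND)."""
    rows = {c: [np.nan if v is None else float(v) for v in vals]
            for c, vals in mean.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=timepoints)
    nd = frame.isna()
    return HATable(mean=frame, nd_mask=nd)
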