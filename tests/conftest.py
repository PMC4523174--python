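import numpy as np
import pandas as pd
import pytest

from tissuespec import ClassificationConfig, ContingencyTable2x2, ExpressionMatrix

# 2x2 tables as printed in the published marker study, layout
# [[neg&benign, neg&tumor], [pos&benign, pos&tumor]]
TMEM79_TABLE = ContingencyTable2x2(29, 148, 127, 29)
ACOXL_TABLE = ContingencyTable2x2(22, 129, 132, 50)
MEM_VS_CYTO_TABLE = ContingencyTable2x2(105, 73, 126, 29)


@pytest.fixture
def default_cfg() -> ClassificationConfig:
    return ClassificationConfig(target_tissue="prostate")


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples over 2 tissues."""
    values = pd.DataFrame(
        {
            "prostate.1": [2.0, 10.0, 0.0],
            "prostate.2": [4.0, 14.0, 0.0],
            "liver.1": [1.0, 100.0, 0.5],
            "liver.2": [3.0, 120.0, 0.7],
        },
        index=["gA", "gB", "gC"],
    )
    tmap = {s: s.split(".")[0] for s in values.columns}
    return ExpressionMatrix(values=values, tissue_of_sample=tmap)


def random_mean_row(rng: np.random.Generator, n_tissues: int = 10) -> pd.Series:
    """Non-negative tissue-mean vector spanning the FPKM dynamic range."""
    vals = np.where(
        rng.random(n_tissues) < 0.3,
        0.0,
        10 ** rng.uniform(-1, 3, size=n_tissues),
    )
    labels = [f"t{i:02d}" for i in range(n_tissues)]
    return pd.Series(vals, index=labels)
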