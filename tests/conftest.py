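import numpy as np
import pytest
from hypothesis import settings

from igselect import ExpressionDataset, SyntheticSpec, generate, zscore_normalize

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_dataset():
    """4 samples x 3 genes; gene gA separates the classes perfectly."""
    return ExpressionDataset(
        values=np.array([
            [0.1, 5.0, 1.0],
            [0.2, 5.5, -1.0],
            [0.9, 5.2, 0.5],
            [1.0, 4.8, -0.5],
        ]),
        gene_ids=np.array(["gA", "gB", "gC"], dtype=object),
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        labels=np.array([-1, -1, 1, 1]),
        label_names={-1: "normal", 1: "tumor"},
    )


@pytest.fixture
def planted_dataset():
    """Normalized 40-sample, 30-gene dataset with 3 strong planted genes."""
    ds, planted = generate(
        SyntheticSpec(m=40, n=30, n_informative=3, effect=3.0,
                      class_balance=0.5, seed=7)
    )
    return zscore_normalize(ds), planted


def write_tsv(path, frame_text):
    path.write_text(frame_text)
    return str(path)
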