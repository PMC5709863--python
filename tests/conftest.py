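import numpy as np
import pandas as pd
import pytest

from decontree.cart import CLASS_NAMES, PREDICTOR_NAMES
from decontree.simulate import simulate_toy_assembly


def make_frame(values: dict, labels=None) -> pd.DataFrame:
    """Pad a partial predictor dict into a full 8-column table."""
    n = len(next(iter(values.values())))
    data = {c: values.get(c, np.zeros(n)) for c in PREDICTOR_NAMES}
    frame = pd.DataFrame(data, index=[f"s{i}" for i in range(n)])
    frame.index.name = "scaffold_id"
    if labels is not None:
        return frame, pd.Series(list(labels), index=frame.index)
    return frame


@pytest.fixture()
def separable_1d():
    """Four scaffolds split perfectly by gc at 5.5 (values 1,2,9,10)."""
    return make_frame(
        {"gc": np.array([1.0, 2.0, 9.0, 10.0])},
        labels=["target", "target", "contaminant", "contaminant"],
    )


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return simulate_toy_assembly("separable", seed=3, out_dir=out,
                                 n_target=12, n_contam=12)
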