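import numpy as np
import pandas as pd
import pytest

from metasurv.matrix import CATEGORICAL, NUMERIC, OmicsMatrix
from metasurv.network import RiskNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_net(n_features, hidden=(6, 5, 4), seed=0, bias_scale=0.1):
    """Random network with nonzero biases (keeps FD checks off ReLU kinks)."""
    net = RiskNetwork.init(n_features, hidden=hidden, seed=seed)
    rng = np.random.default_rng(seed + 1)
    net.params = [
        (W, b + rng.normal(0, bias_scale, size=b.shape)) for W, b in net.params
    ]
    return net


def simple_matrix(values, columns=None, kinds=None, block="block0"):
    values = np.asarray(values, dtype=object)
    n, p = values.shape
    columns = columns or [f"f{j}" for j in range(p)]
    df = pd.DataFrame(values, index=[f"P{i}" for i in range(n)], columns=columns)
    for c in columns:
        if kinds is None or kinds.get(c, NUMERIC) == NUMERIC:
            df[c] = pd.to_numeric(df[c])
    kind_series = pd.Series(
        [kinds.get(c, NUMERIC) if kinds else NUMERIC for c in columns], index=columns
    )
    return OmicsMatrix(df, pd.Series(block, index=columns), kind_series)


def survival_from(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    return pd.DataFrame(
        {"time": time, "event": event},
        index=[f"P{i}" for i in range(len(time))],
    )
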