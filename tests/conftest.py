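import numpy as np
import pandas as pd
import pytest

from dyskin import synthetic
from dyskin.types import STATES, StateProbSeries


@pytest.fixture(scope="session")
def template():
    return synthetic.make_template_face(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_states(fps=30.0, **traces) -> StateProbSeries:
    """StateProbSeries from keyword traces; unspecified states are 0."""
    n = max(len(np.atleast_1d(v)) for v in traces.values())
    cols = {}
    for s in STATES:
        v = np.atleast_1d(np.asarray(traces.get(s, 0.0), dtype=float))
        cols[s] = np.broadcast_to(v, (n,)).copy()
    return StateProbSeries(fps=fps, probs=pd.DataFrame(cols))
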