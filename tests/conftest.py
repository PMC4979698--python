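import numpy as np
import pytest

from thermnorm.reaction_norms import RegimenObservation, StageSeries
from thermnorm.trees import read_newick_string


def make_series(temps, dev_times, species_id="spA", stage="total", source_id="s1",
                n=None, sex=None):
    obs = tuple(
        RegimenObservation(t, d, n=n, sex=sex) for t, d in zip(temps, dev_times)
    )
    return StageSeries(species_id=species_id, stage=stage, observations=obs,
                       source_id=source_id)


def linear_series(a, b, temps, **kw):
    """Noiseless series on the exact line R = a + bT."""
    return make_series(temps, [1.0 / (a + b * t) for t in temps], **kw)


@pytest.fixture
def balanced_four_tree():
    """((A,B),(C,D)) without branch lengths."""
    return read_newick_string("((A,B),(C,D));")


@pytest.fixture
def three_tip_tree():
    return read_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
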