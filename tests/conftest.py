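import itertools

import numpy as np
import pytest

from dtni.expression import DoseTimeExpressionSet, SampleDescriptor


def grid_samples(compound="C1", doses=(10.0, 100.0, 1000.0), times=(2.0, 8.0, 24.0),
                 replicates=1):
    """Balanced sample list for one compound."""
    out = []
    for (rank, dose), time, rep in itertools.product(
            enumerate(doses, start=1), times, range(1, replicates + 1)):
        out.append(SampleDescriptor(compound=compound, dose=dose, dose_rank=rank,
                                    time=time, replicate=rep))
    return out


def make_ds(genes=("G1", "G2"), values=None, seed=0, **kwargs):
    """Small balanced expression set; values random unless given."""
    samples = grid_samples(**kwargs)
    if values is None:
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, size=(len(genes), len(samples)))
    return DoseTimeExpressionSet(genes=list(genes), samples=samples,
                                 values=np.asarray(values, dtype=float))


@pytest.fixture
def small_ds():
    return make_ds()


@pytest.fixture
def replicated_ds():
    return make_ds(replicates=2)
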