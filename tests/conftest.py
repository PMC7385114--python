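import numpy as np
import pytest

from mea_trainer.types import ElectrodeLayout, SpikeTrainSet, standard_layout


@pytest.fixture
def layout2():
    return ElectrodeLayout(("E1", "E2"), ((0, 0), (0, 1)))


@pytest.fixture
def layout3():
    return ElectrodeLayout(("E1", "E2", "E3"), ((0, 0), (0, 1), (0, 2)))


@pytest.fixture
def layout60():
    return standard_layout(60)


def make_trains(layout, duration_s, **trains):
    """SpikeTrainSet with the named trains and empty trains elsewhere."""
    full = {e: np.asarray(trains.get(e, ()), dtype=float) for e in layout.electrode_ids}
    return SpikeTrainSet(full, duration_s=duration_s, layout=layout)


@pytest.fixture
def trains_factory():
    return make_trains
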