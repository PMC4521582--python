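import numpy as np
import pytest

from dgfilter import StimulationProtocol, immature_cell, mature_cell
from dgfilter.params import TraceRecording
from dgfilter.pipeline import PipelineConfig, run_study

MASTER_SEED = 20160916


@pytest.fixture(scope="session")
def mature():
    return mature_cell(seed=101)


@pytest.fixture(scope="session")
def immature():
    return immature_cell(seed=202)


@pytest.fixture(scope="session")
def study():
    """Full default study grid (8 cells/phenotype, 4 frequencies, 4 conditions),
    shared by the ordinal acceptance tests."""
    return run_study(PipelineConfig(master_seed=MASTER_SEED, n_cells=8))


def make_trace(y, dt=0.05, stim_times=(), mode="loose_patch", **kw):
    y = np.asarray(y, dtype=float)
    t = np.arange(y.size) * dt
    return TraceRecording(
        t=t, y=y, stim_times=np.asarray(stim_times, float), mode=mode, **kw
    )


@pytest.fixture()
def flat_trace():
    return make_trace(np.zeros(20000), stim_times=[100.0], mode="field")
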