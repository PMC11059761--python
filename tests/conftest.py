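import numpy as np
import pytest

from capnodyn import BreathFeatures, BreathPattern, LungTruth, simulate_sequence


@pytest.fixture
def truth():
    return LungTruth()


@pytest.fixture
def truth_no_store():
    return LungTruth(store_fraction=0.0)


@pytest.fixture
def pattern():
    return BreathPattern()


@pytest.fixture
def noiseless_records(truth, pattern):
    """27 noiseless breaths (three full hold cycles) under default truth."""
    return simulate_sequence(truth, pattern, 27, seed=0)


def records_to_features(records, pattern, truth):
    """Solver-ready feature list straight from simulator ground truth."""
    return [
        BreathFeatures(
            faco2=r.faco2, vtco2=r.vtco2, dt=r.dt, vt_exp=pattern.vt,
            vdaw=truth.vdaw, petco2=np.nan, peco2=np.nan,
        )
        for r in records
    ]


@pytest.fixture
def features_of():
    return records_to_features
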