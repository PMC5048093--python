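import numpy as np
import pytest

from viewens.ensemble import SubviewSpec
from viewens.model import MCNNClassifier, tiny_config, tiny_training_config
from viewens.records import Dataset, TimeSeriesRecord
from viewens.synthgen import easy_benchmark

#: subview offsets used throughout for the 160-of-200 easy benchmark crops
EASY_OFFSETS = (1, 6, 11, 16, 21, 26, 31, 36, 41)


def make_record(rec_id="r0", c=2, f=100, rate=100.0, label=0, seed=0):
    rng = np.random.default_rng(seed)
    return TimeSeriesRecord(rec_id, rng.normal(size=(c, f)), rate, label)


def make_dataset(n=6, c=2, f=100, rate=100.0, seed=0):
    rng = np.random.default_rng(seed)
    recs = [
        TimeSeriesRecord(f"r{i}", rng.normal(size=(c, f)), rate, int(i % 2)) for i in range(n)
    ]
    return Dataset(recs)


@pytest.fixture(scope="session")
def easy_sets():
    """The packaged 200/60/200 easy synthetic benchmark."""
    return easy_benchmark(seed=2024)


@pytest.fixture(scope="session")
def fitted_easy(easy_sets):
    """Both trainers fitted once on the easy benchmark (shared across tests)."""
    train, val, test = easy_sets
    cfg = tiny_config()
    tc = tiny_training_config(seed=0, max_epochs=30)
    res_explicit = MCNNClassifier(
        train, val, config=cfg, training=tc, method="explicit", init_seed=0
    ).fit()
    res_implicit = MCNNClassifier(
        train, config=cfg, training=tc, method="implicit", init_seed=1
    ).fit()
    return {
        "explicit": res_explicit,
        "implicit": res_implicit,
        "test": test,
        "spec": SubviewSpec(offsets=EASY_OFFSETS, length=160),
    }
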