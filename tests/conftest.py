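import warnings

import numpy as np
import pytest

from nrcascade.simdata import default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The 474+500 synthetic benchmark at a fixed seed, shared across the
    session (generation is cheap but encoding downstream is not)."""
    return default_benchmark(seed=1)


@pytest.fixture(scope="session")
def benchmark_split(benchmark):
    """(records, cascade_labels, binary_labels, positive_indices)."""
    records = list(benchmark.records)
    labels = list(benchmark.labels)
    binary = ["0" if lab == "non-NR" else "1" for lab in labels]
    pos_idx = [i for i, lab in enumerate(labels) if lab != "non-NR"]
    return records, labels, binary, pos_idx


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(autouse=True)
def _quiet_small_class_warning():
    """Stratified folds on the benchmark's smallest subfamily (7 members,
    k=10) warn by design; keep test output readable."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*least populated class.*", category=UserWarning
        )
        yield


def random_protein(rng, length):
    from nrcascade.alphabets import STANDARD_AA

    return "".join(rng.choice(list(STANDARD_AA), size=length))
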