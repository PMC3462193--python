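import numpy as np
import pandas as pd
import pytest

import territory_coupling as tc


@pytest.fixture(scope="session")
def coupled_dataset():
    """Fully coupled (beta=1) default-size study shared across tests."""
    return tc.generate_study(tc.SimulationConfig(seed=11))


def iad_from_log_activity(log_activity: np.ndarray, labels) -> tc.DistanceMatrix:
    """IAD built directly from a log-activity vector (ground-truth route)."""
    la = np.asarray(log_activity, float)
    return tc.DistanceMatrix(
        labels=tuple(labels),
        values=np.abs(la[:, None] - la[None, :]),
        units="log_activity",
        role="IAD",
    )


def random_metric_matrix(n: int, rng: np.random.Generator, labels=None) -> tc.DistanceMatrix:
    """A Euclidean (hence metric) random distance matrix."""
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import cdist

    labels = labels or tuple(f"chr{i + 1}" for i in range(n))
    return tc.DistanceMatrix(
        labels=tuple(labels), values=cdist(pts, pts), units="dimensionless", role="other"
    )
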