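import numpy as np
import pytest

from caveclass.features import BlobFeaturizer
from caveclass.simulate import SimulationParams, generate_dataset


@pytest.fixture(scope="session")
def full_sim():
    """Full-scale simulated dataset (1000 blobs/class) plus its 28-feature
    matrix; shared across tests that need the study-condition dataset."""
    params = SimulationParams(seed=20)
    blobs = generate_dataset(params)
    points = [b.points for b in blobs]
    y = np.array([b.label for b in blobs])
    featurizer = BlobFeaturizer().fit(points)
    X = featurizer.transform(points)
    return {"params": params, "blobs": blobs, "points": points, "y": y,
            "X": X, "threshold": featurizer.threshold_nm_}


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset (100 blobs/class) for cheap model tests."""
    params = SimulationParams(n_blobs_per_class=100, seed=11)
    blobs = generate_dataset(params)
    points = [b.points for b in blobs]
    y = np.array([b.label for b in blobs])
    featurizer = BlobFeaturizer().fit(points)
    X = featurizer.transform(points)
    return {"params": params, "blobs": blobs, "points": points, "y": y, "X": X}
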