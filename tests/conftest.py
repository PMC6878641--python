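import numpy as np
import pandas as pd
import pytest

import spatialboot as sb


@pytest.fixture
def line_coords():
    """Four units on a line at x = 0, 1, 2, 3."""
    return sb.CoordinateSet(np.array(["a", "b", "c", "d"]),
                            np.array([0.0, 1.0, 2.0, 3.0]),
                            np.zeros(4))


@pytest.fixture
def toy_dataset():
    """Three clusters x two members each, members sharing coordinates."""
    df = pd.DataFrame({
        "obs_id": [1, 2, 3, 4, 5, 6],
        "cluster_id": [1, 1, 2, 2, 3, 3],
        "x": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        "y": [0.0, 0.0, 1.0, 1.0, 2.0, 2.0],
        "outcome": [0.1, 0.4, 1.2, 1.0, 2.3, 2.1],
        "wealth": [1.0, 2.0, 3.0, 4.0, 5.0, 1.0],
    })
    return sb.SurveyDataset(df, ["wealth"])


@pytest.fixture(scope="session")
def small_survey():
    """Synthetic survey at desk scale, reused by read-only tests."""
    ds, truth = sb.generate_survey(sb.SyntheticConfig(
        n_clusters=40, members_per_cluster=5, seed=123))
    return ds, truth


def random_weights(rng, n, normalized=True):
    """Random inverse-distance weights on n distinct random points."""
    pts = rng.uniform(0, 10, size=(n, 2))
    coords = sb.CoordinateSet(np.arange(n), pts[:, 0], pts[:, 1])
    W = sb.build_inverse_distance_matrix(coords)
    return sb.row_normalize(W) if normalized else W
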