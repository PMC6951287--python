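import numpy as np
import pandas as pd
import pytest

from ramclass.io import SpectralDataset


def make_meta(scan_ids, specimens=None, individuals=None, labels=None, reps=None):
    n = len(scan_ids)
    return pd.DataFrame(
        {
            "scan_id": scan_ids,
            "specimen_id": specimens or scan_ids,
            "individual_id": individuals or specimens or scan_ids,
            "class_label": labels or ["a"] * n,
            "replicate_index": reps or [1] * n,
        }
    )


def blob_dataset(rng, n_per_class=8, n_points=30, separation=6.0, noise=1.0, classes=("a", "b")):
    """Two Gaussian blobs in spectrum space with a mean shift along one direction."""
    grid = np.linspace(400.0, 1800.0, n_points)
    direction = np.sin(np.linspace(0, 3 * np.pi, n_points))
    direction /= np.linalg.norm(direction)
    rows, labels = [], []
    for ci, c in enumerate(classes):
        for _ in range(n_per_class):
            rows.append(ci * separation * direction + rng.normal(0, noise, n_points))
            labels.append(c)
    ids = [f"s{i:03d}" for i in range(len(rows))]
    return SpectralDataset(grid, np.vstack(rows), make_meta(ids, labels=labels))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def separated_dataset(rng):
    return blob_dataset(rng, separation=25.0, noise=1.0)
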