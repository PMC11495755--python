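import numpy as np
import pandas as pd
import pytest

import nichemap as nm


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort (4 patients, 5 phenotypes) shared across tests."""
    cfg = nm.small_config(n_patients=4, n_phenotypes=5, seed=42)
    return nm.simulate_cohort(cfg)


@pytest.fixture()
def tiny_cells_csv(tmp_path):
    path = tmp_path / "cells.csv"
    path.write_text(
        "cell_id,image_id,x_um,y_um,CD3,CD20\n"
        "c1,img1,10.0,20.0,5.0,0.1\n"
        "c2,img1,30.0,40.0,0.2,6.0\n"
        "c3,img2,15.0,25.0,4.5,0.3\n"
    )
    return path


def random_labeled_image(seed, n_cells=300, n_clusters=4, side=1000.0):
    """A random labelled point pattern in one image frame."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, side, size=(n_cells, 2))
    labels = rng.choice([f"c{k}" for k in range(n_clusters)], size=n_cells)
    return pd.DataFrame(
        {
            "cell_id": [f"x{i:04d}" for i in range(n_cells)],
            "image_id": "img",
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "phenotype": labels,
        }
    )
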