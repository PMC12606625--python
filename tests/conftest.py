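import numpy as np
import pandas as pd
import pytest

from chemflag.featurize import standardize_structure
from chemflag.synthetic import generate_toy_library


@pytest.fixture(scope="session")
def toy_library():
    """60 standardized, diverse SMILES (deterministic)."""
    return [standardize_structure(s) for s in generate_toy_library(60, seed=7)]


@pytest.fixture(scope="session")
def small_world():
    """A compact feature world used by several flagging tests."""
    from chemflag.synthetic import FeatureWorldSpec, generate_feature_world

    return generate_feature_world(FeatureWorldSpec(
        n_clusters=6, molecules_per_cluster=20, n_features=12,
        class_separation=1.0, noise_sd=0.1, seed=11))


@pytest.fixture(scope="session")
def world_experiments():
    """Ten end-to-end synthetic-world flagging experiments (one per seed)."""
    from chemflag.workflow import run_world_experiment

    return [run_world_experiment(seed=s) for s in range(10)]


def make_predictions(ids, true, pred, proba=None):
    proba = proba if proba is not None else np.full(len(ids), 0.9)
    return pd.DataFrame({
        "molecule_id": [str(i) for i in ids],
        "true_label": np.asarray(true, dtype=int),
        "predicted_label": np.asarray(pred, dtype=int),
        "class_probability": np.asarray(proba, dtype=float),
    })
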