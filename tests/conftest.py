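import numpy as np
import pandas as pd
import pytest

from xdec import (ManifestEntry, MixedDataset, VariableManifest, DECConfig,
                  SyntheticSpec, TrainingConfig, apply_scaler, fit_scaler,
                  generate_cohort)
from xdec.pipeline import make_pipeline_factory


def make_dataset(numeric: dict, binary: dict, ids=None) -> MixedDataset:
    """Build a MixedDataset from plain column dicts."""
    n = len(next(iter({**numeric, **binary}.values())))
    ids = pd.Index(ids if ids is not None else [f"s{i}" for i in range(n)],
                   name="sample_id")
    manifest = VariableManifest(
        [ManifestEntry(c, "numerical") for c in numeric]
        + [ManifestEntry(c, "binary") for c in binary])
    return MixedDataset(pd.DataFrame(numeric, index=ids, dtype=float),
                        pd.DataFrame(binary, index=ids, dtype=float), manifest)


def rows_as_new_samples(ds: MixedDataset, positions) -> MixedDataset:
    """Copy rows (possibly repeated) into a dataset with fresh sample ids."""
    numeric = ds.numeric.iloc[list(positions)].copy()
    binary = ds.binary.iloc[list(positions)].copy()
    ids = pd.Index([f"dup{i}" for i in range(len(positions))], name="sample_id")
    numeric.index = ids
    binary.index = ids
    return MixedDataset(numeric, binary, ds.manifest)


@pytest.fixture
def toy_dataset():
    return make_dataset(
        {"hr": [60.0, 80.0, 100.0, 70.0], "map": [65.0, 85.0, 75.0, 90.0]},
        {"ventilated": [1.0, 0.0, 1.0, 0.0]})


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 3-cluster mixed cohort, z-scaled, with truth labels."""
    coh = generate_cohort(SyntheticSpec(n=210, k=3, p_num=8, p_cat=4,
                                        delta=7.0, binary_contrast=0.4, seed=11))
    scaler = fit_scaler(coh.dataset)
    return apply_scaler(coh.dataset, scaler), coh.true_labels, scaler, coh.outcomes


@pytest.fixture(scope="session")
def quick_train():
    """Short TrainingConfig for unit tests of pipeline mechanics."""
    return TrainingConfig(epochs=60, batch_size=32)


@pytest.fixture(scope="session")
def fitted_small(small_cohort, quick_train):
    ds, truth, scaler, _ = small_cohort
    factory = make_pipeline_factory("xdec", train_config=quick_train,
                                    dec_config=DECConfig(k=3), scaler=scaler)
    return factory(ds, seed=5192)
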