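import numpy as np
import pandas as pd
import pytest

import pgpscreen as pg


@pytest.fixture(scope="session")
def dataset59():
    return pg.load_fixture("dataset59")


@pytest.fixture(scope="session")
def testsets():
    return pg.load_fixture("testsets")


@pytest.fixture(scope="session")
def external47():
    return pg.load_fixture("external47")


@pytest.fixture(scope="session")
def small_noiseless():
    """40 compounds x 20 descriptors, single planted rule per endpoint, no noise."""
    return pg.generate_dataset(pg.SyntheticConfig(
        n_compounds=40, n_descriptors=20, n_constant=2, n_redundant_groups=2,
        label_noise=0.0,
        class_targets={"inhibition": 18, "atpase": 20, "efflux": 22}, seed=5))


@pytest.fixture(scope="session")
def paper_shaped():
    """59 x 696 synthetic dataset with the study's class balances."""
    return pg.generate_dataset(pg.SyntheticConfig(seed=3))


def make_table(values, ids=None, names=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"C{i+1}" for i in range(values.shape[0])]
    names = names or [f"D{j+1}" for j in range(values.shape[1])]
    return pg.DescriptorTable(pd.DataFrame(values, index=ids, columns=names))


def make_dataset(values, labels_y, endpoint="inhibition", ids=None, names=None):
    """Build a one-endpoint LabeledDataset from a matrix and 0/1 labels."""
    table = make_table(values, ids=ids, names=names)
    lab = {cid: pg.ClassLabel("Y" if v else "N")
           for cid, v in zip(table.compound_ids, labels_y)}
    return pg.LabeledDataset(table, {endpoint: lab})
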