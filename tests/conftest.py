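import numpy as np
import pytest

from metaconn.atlas import load_atlas
from metaconn.suvr import SuvrDataset


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dataset(atlas, n_subjects, rng, label="G"):
    """An i.i.d. lognormal-ish positive SUVR dataset over the full atlas."""
    values = np.abs(rng.normal(1.0, 0.12, size=(n_subjects, len(atlas)))) + 0.05
    return SuvrDataset(
        group_label=label,
        subject_ids=[f"{label}_{i}" for i in range(n_subjects)],
        region_names=list(atlas.names),
        values=values,
    )
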