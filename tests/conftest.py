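import numpy as np
import pandas as pd
import pytest

from lesionet import RoiAtlas, Region, default_atlas, make_measurement_table


@pytest.fixture
def atlas():
    return default_atlas()


@pytest.fixture
def tiny_atlas():
    """Two bilateral pairs (4 regions) — small enough to reason by hand."""
    return RoiAtlas(
        regions=[
            Region("striatum_l", "left", "striatum"),
            Region("striatum_r", "right", "striatum"),
            Region("thalamus_l", "left", "thalamus"),
            Region("thalamus_r", "right", "thalamus"),
        ],
        lesion_side="right",
    )


def build_table(values, atlas, groups=None, whole_brain=None, modality="volume_mm3"):
    """Measurement table from a raw (n_subjects, n_regions) array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if groups is None:
        groups = ["ich"] * (n // 2) + ["sham"] * (n - n // 2)
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": groups,
            "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        }
    )
    if whole_brain is None:
        whole_brain = values.sum(axis=1) * 1.6 + 1.0
    vals = pd.DataFrame(values, columns=atlas.names)
    return make_measurement_table(modality, subjects, vals, whole_brain, atlas)


@pytest.fixture
def table_builder():
    return build_table
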