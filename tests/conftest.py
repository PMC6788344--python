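"""Shared fixtures: small seeded phantoms and networks."""

import numpy as np
import pytest

from longisym.nn import DeepSymNetConfig, InceptionSpec, build
from longisym.phantom import PhantomConfig, build_atlas, generate_cohort


@pytest.fixture(scope="session")
def clean_config() -> PhantomConfig:
    """Noiseless, perfectly aligned phantom conditions."""
    return PhantomConfig(noise_sd=0.0, misalign_max=(0.0, 0.0))


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    """Small noiseless cohort: 3 progressors, 3 non-progressors."""
    return generate_cohort(clean_config, {"progressor": 3, "non-progressor": 3})


@pytest.fixture(scope="session")
def atlas(clean_config):
    return build_atlas(clean_config)


@pytest.fixture()
def tiny_model():
    """A 4^3-input model small enough for brute-force checks."""
    cfg = DeepSymNetConfig(
        input_shape=(4, 4, 4),
        inception=InceptionSpec(filters_per_branch=2),
    )
    return build(cfg, seed=3)


@pytest.fixture()
def small_model():
    """A 16^3-input model at reduced width."""
    cfg = DeepSymNetConfig(
        input_shape=(16, 16, 16),
        inception=InceptionSpec(filters_per_branch=4),
    )
    return build(cfg, seed=1)


def records_to_dataset(records):
    """(session1, session2, label) triples with progressor = 1."""
    code = {"non-progressor": 0, "progressor": 1, "intermediate": 2}
    return [
        (
            np.asarray(r.session1.data, dtype=np.float32),
            np.asarray(r.session2.data, dtype=np.float32),
            code[r.class_label],
        )
        for r in records
    ]
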