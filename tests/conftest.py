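import numpy as np
import pytest

import gatedsurv as gs
from gatedsurv.fusion import ModelConfig, Params, init_params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-signal cohort small enough for fast training tests."""
    cohort, truth = gs.generate_cohort(
        gs.SimConfig(n_patients=200, cancer_types=("CA", "CB")), seed=11
    )
    return cohort, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One trained model shared across read-only tests."""
    cohort, _ = small_cohort
    model = gs.MultimodalSurvivalModel(cohort)
    return model.fit(
        train_config=gs.TrainConfig(epochs=15, patience=15, seed=11), seed=11
    )


@pytest.fixture
def tiny_config():
    return ModelConfig(C=3)


@pytest.fixture
def tiny_params(tiny_config):
    return Params(init_params(tiny_config, np.random.default_rng(5)))


def make_batch(rng, b=6, config=None, mask=None, with_labels=True):
    """Random well-formed batch for forward-pass tests."""
    config = config or ModelConfig(C=3)
    mask = (
        np.asarray(mask)
        if mask is not None
        else np.column_stack(
            [np.ones(b, int), rng.integers(0, 2, b), rng.integers(0, 2, b)]
        )
    )
    x_img = rng.standard_normal((b, config.d_img))
    x_rna = rng.standard_normal((b, config.d_rna)) * mask[:, 1:2]
    x_txt = rng.standard_normal((b, config.d_txt)) * mask[:, 2:3]
    return gs.Batch(
        patient_ids=[f"P{i}" for i in range(b)],
        x_img=x_img,
        x_rna=x_rna,
        x_txt=x_txt,
        mask=mask,
        cancer_index=rng.integers(0, config.C, b),
        tau=rng.integers(1, config.T + 1, b) if with_labels else np.ones(b, int),
        event=rng.integers(0, 2, b),
    )
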