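import numpy as np
import pytest

from rxnscheme import (
    ArrowTrainConfig,
    SchemaSpec,
    build_element_bank,
    build_patch_dataset,
    train_arrow_model,
)


@pytest.fixture(scope="session")
def bank():
    return build_element_bank(seed=42)


@pytest.fixture(scope="session")
def patch_split():
    """250 synthetic patches split 200 train / 50 held out."""
    data = build_patch_dataset(n_arrows=125, n_negatives=125, seed=2)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(data))
    train = [data[i] for i in idx[:200]]
    held = [data[i] for i in idx[200:]]
    return train, held


@pytest.fixture(scope="session")
def arrow_model(patch_split):
    """The two-branch arrow model trained once per session."""
    train, _ = patch_split
    return train_arrow_model(train, ArrowTrainConfig(seed=0))


@pytest.fixture(scope="session")
def linear_scheme(bank):
    """A minimal 1-step scheme: diagram -> arrow -> diagram."""
    from rxnscheme import compose_scheme

    schema = SchemaSpec(n_steps=1, diagrams_per_step=(1, 1), p_label=0.0,
                        p_conditions=0.0, n_negatives=(0, 0))
    return compose_scheme(schema, bank, seed=3)


def mask_to_image(mask: np.ndarray) -> np.ndarray:
    """Render a boolean ink mask as a white-background uint8 image."""
    return np.where(mask, 0, 255).astype(np.uint8)
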