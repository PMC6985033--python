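import numpy as np
import pytest

import movescreen as ms


@pytest.fixture(scope="session")
def body_model():
    return ms.build_default_segment_model()


@pytest.fixture(scope="session")
def templates():
    return ms.default_templates()


@pytest.fixture(scope="session")
def noise_free_trial(templates):
    """One noise-free step-down trial (no sway, no marker noise)."""
    return ms.synthesize_trial(templates[0], seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-athlete cohort over 4 templates for fast integration tests."""
    templates = ms.default_templates()[:4]
    return ms.assemble_cohort(6, templates=templates, seed=11)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
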