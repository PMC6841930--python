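import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from toothmark import LandmarkDataset, SimulationSpec, reference_fixture
from toothmark.io import dataset_from_arrays

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_rotation(d: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation with det +1."""
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_similarity(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    d = coords.shape[1]
    scale = rng.uniform(0.3, 4.0)
    return scale * coords @ random_rotation(d, rng) + rng.uniform(-10, 10, size=d)


@pytest.fixture(scope="session")
def fixture_datasets():
    """Default-condition reference sample (83 pits, 105 scores, 105x7 table)."""
    return reference_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_scores(rng) -> LandmarkDataset:
    """Small noisy 7x2 score dataset, two classes."""
    from toothmark import make_score_template

    spec = SimulationSpec(seed=5)
    configs, labels = [], []
    for cls in ("fox", "wolf"):
        template = make_score_template(cls, spec).coords
        for _ in range(6):
            configs.append(template + rng.normal(0, 0.02, size=template.shape))
            labels.append(cls)
    return dataset_from_arrays(np.stack(configs), labels, "score")
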