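import numpy as np
import pytest

from pestnet.labels import AnnotatedSample, StageTag
from pestnet.synthetic import DatasetSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_samples(spec: dict[int, dict[StageTag, int]],
                 prefix: str = "s") -> list[AnnotatedSample]:
    """Expand {species: {stage: count}} into a flat sample list."""
    out = []
    i = 0
    for species, stages in spec.items():
        for stage, count in stages.items():
            for _ in range(count):
                out.append(AnnotatedSample(f"{prefix}{i:05d}", species, stage))
                i += 1
    return out


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Tiny 3-species dataset shared by engine/synthetic tests."""
    root = tmp_path_factory.mktemp("smallds")
    spec = DatasetSpec(n_species=3, base_count=24, clutter_level=0.1,
                       occlusion_prob=0.05, min_count=5, image_size=64, seed=7)
    paths = generate_dataset(spec, root)
    return spec, paths
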