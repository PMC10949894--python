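import numpy as np
import pytest

from hemopipe.synthetic import CellImageSpec, PlantedFeatureSpec, make_cell_image, make_feature_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def cell_image():
    """Low-contrast 64x64 synthetic blood-smear RGB image."""
    return make_cell_image(CellImageSpec(size=(64, 64), contrast=0.2, seed=7))


@pytest.fixture(scope="session")
def planted():
    """Default planted feature fixture plus its informative truth indices."""
    return make_feature_dataset(PlantedFeatureSpec(seed=11))


@pytest.fixture(scope="session")
def small_planted():
    """Tiny, strongly separable 2-class fixture (40 rows, 20 columns)."""
    return make_feature_dataset(
        PlantedFeatureSpec(classes=2, per_class=20, dims=20, informative=5, effect=4.0, seed=5)
    )
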