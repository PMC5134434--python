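import numpy as np
import pytest

from mangograde.synthetic_scene import FruitSpec, Lobe, generate_fruit, render_scene


@pytest.fixture(scope="session")
def fruit_truth():
    """A default regular fruit with its exact ground truth."""
    return generate_fruit(FruitSpec())


@pytest.fixture(scope="session")
def misshapen_truth():
    spec = FruitSpec(
        lobes=(
            Lobe(position=0.3, amplitude_mm=7.0, width=0.12, side=1),
            Lobe(position=-0.4, amplitude_mm=-5.0, width=0.15, side=-1),
        )
    )
    return generate_fruit(spec)


@pytest.fixture(scope="session")
def clean_scene(fruit_truth):
    """Rendered frame with no artefacts."""
    return render_scene(fruit_truth)


@pytest.fixture(scope="session")
def noisy_scene(fruit_truth):
    """Rendered frame with stem, specks and shadow."""
    return render_scene(fruit_truth, noise={"stem": True, "specks": 10, "shadow": True}, seed=4)


@pytest.fixture()
def disc_mask():
    yy, xx = np.ogrid[:201, :201]
    return (yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
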