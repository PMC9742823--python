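import numpy as np
import pytest

from rosettearea.synthetic import default_scene, generate_plate

SMALL = (640, 480)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free axis-aligned six-shoot plate with marker (small image)."""
    spec = default_scene(seed=42, image_size=SMALL, noise_sd=0.0)
    img, truth = generate_plate(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def tilted_scene():
    """Same scene family at 8 degrees tilt with mild noise."""
    spec = default_scene(seed=42, image_size=SMALL, rotation_deg=8.0, noise_sd=3.0)
    img, truth = generate_plate(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def batch_dir(tmp_path_factory):
    """Ten-plate seeded synthetic batch with truth table."""
    from rosettearea.synthetic import generate_batch

    d = tmp_path_factory.mktemp("batch")
    truth = generate_batch(d, n_plates=10, seed=7, image_size=(800, 600))
    return d, truth
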