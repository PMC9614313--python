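import logging

import pytest

from pqctseg.phantom import PhantomSpec, generate_phantom

logging.getLogger("pqctseg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def phantom64():
    """Clean 66%-site phantom on a 64x64 grid (image, labels)."""
    return generate_phantom(PhantomSpec(site=66, seed=1, image_size=64))


@pytest.fixture(scope="session")
def phantom128():
    """Clean 66%-site phantom on a 128x128 grid (image, labels)."""
    return generate_phantom(PhantomSpec(site=66, seed=1, image_size=128))
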