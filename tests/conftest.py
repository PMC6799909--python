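import numpy as np
import pytest

from markermorph import render_cadaver_layout, render_phantom


@pytest.fixture(scope="session")
def cadaver_spec():
    """Noiseless cadaver-layout phantom spec (default geometry)."""
    return render_cadaver_layout()


@pytest.fixture(scope="session")
def cadaver_render(cadaver_spec):
    """Rendered noiseless cadaver phantom: (volume, ground truth)."""
    return render_phantom(cadaver_spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
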