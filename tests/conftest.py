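import numpy as np
import pytest

from ramanbayes.io import RamanSpectrum, SpectrumSet
from ramanbayes.synth import GeneratorConfig, generate_dataset


@pytest.fixture
def simple_spectrum() -> RamanSpectrum:
    w = np.arange(600.0, 700.0, 2.0)
    y = np.sin(w / 30.0) + 2.0
    return RamanSpectrum("s1", "p1", w, y)


@pytest.fixture(scope="session")
def small_dataset():
    """6 healthy + 6 tumor + 2 boundary synthetic targets with ground truth."""
    cfg = GeneratorConfig(seed=11)
    return generate_dataset(cfg, 6, 6, 2, seed=11)


@pytest.fixture(scope="session")
def separated_dataset():
    """20 healthy + 20 tumor end-member targets (no boundary)."""
    cfg = GeneratorConfig(seed=7)
    return generate_dataset(cfg, 20, 20, 0, seed=7)


def make_set(matrix: np.ndarray, axis: np.ndarray | None = None) -> SpectrumSet:
    """Wrap a 2-D intensity matrix into a SpectrumSet on a trivial axis."""
    matrix = np.atleast_2d(matrix)
    if axis is None:
        axis = 600.0 + 2.0 * np.arange(matrix.shape[1])
    return SpectrumSet(
        [
            RamanSpectrum(f"t{i}", "p0", axis, row)
            for i, row in enumerate(matrix)
        ]
    )
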