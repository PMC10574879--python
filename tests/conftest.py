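import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from tuberkit.datasets import load_species_summaries, load_tubercle_tables


@pytest.fixture(scope="session")
def tubercle_tables():
    return load_tubercle_tables()


@pytest.fixture(scope="session")
def species_summaries():
    return load_species_summaries()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230929)


def arc_points(radius: float, span_deg: float = 120.0, n: int = 60) -> np.ndarray:
    """Noise-free points on a circular arc centred on the y axis, apex up."""
    half = np.radians(span_deg) / 2.0
    theta = np.linspace(np.pi / 2 + half, np.pi / 2 - half, n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
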