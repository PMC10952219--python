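import numpy as np
import pytest

import swirlwell as sw


@pytest.fixture
def circular_series():
    """Uniform rotating locus, 1 Pa, 360 samples over one 0.4 s cycle."""
    return sw.make_locus(sw.circular(1.0), n_samples=360, period=0.4)


@pytest.fixture
def uniaxial_series():
    """Zero-mean tangential oscillation, amplitude 1 Pa."""
    return sw.make_locus(sw.uniaxial(1.0), n_samples=360, period=0.4)


@pytest.fixture
def steady_series():
    """Constant (0.3, 0.4, 0) Pa stress in the local frame (|τ| = 0.5)."""
    return sw.make_locus(sw.steady((0.3, 0.4, 0.0)), n_samples=360, period=0.4)


def random_locus_spec(rng: np.random.Generator) -> sw.LocusSpec:
    """A randomized non-degenerate locus drawn from the generator's regimes."""
    regime = rng.choice(["circular", "elliptic", "uniaxial_oscillatory", "steady"])
    if regime == "circular":
        amp = rng.uniform(0.05, 2.0)
        return sw.circular(amp, phase=rng.uniform(0, 2 * np.pi))
    if regime == "elliptic":
        return sw.elliptic(
            rng.uniform(0.05, 2.0),
            rng.uniform(0.05, 2.0),
            asymmetry=rng.uniform(0, 0.8),
            steady_offset=tuple(rng.normal(0, 0.2, 3) * [1, 1, 0]),
            phase=rng.uniform(0, 2 * np.pi),
        )
    if regime == "uniaxial_oscillatory":
        return sw.uniaxial(
            rng.uniform(0.05, 2.0),
            asymmetry=rng.uniform(0, 0.8),
            steady_offset=tuple(rng.normal(0, 0.2, 3) * [1, 1, 0]),
            phase=rng.uniform(0, 2 * np.pi),
        )
    return sw.steady(tuple(rng.normal(0, 1.0, 3) * [1, 1, 0]))


def random_series(seed: int, n_samples: int = 96) -> sw.WSSSeries:
    rng = np.random.default_rng(seed)
    return sw.make_locus(random_locus_spec(rng), n_samples=n_samples, period=0.4)
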