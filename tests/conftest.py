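import numpy as np
import pytest

from phasemc.core import RngStream
from phasemc.sources import AxiconSpec, BeamSpec, PlanoConvexLensSpec, SlitPairSpec


@pytest.fixture
def rng():
    return RngStream(12345)


@pytest.fixture
def beam_488():
    """488 nm plane-wave beam with 1 mW over a nominal 1 mm² area."""
    return BeamSpec(wavelength=0.488, power=1e-3, profile="plane", area=1e6)


@pytest.fixture
def slit_pair_488():
    """The double-slit geometry: width 10λ, separation 80λ, screen 10⁴λ away."""
    lam = 0.488
    return SlitPairSpec(slit_width=10 * lam, separation=80 * lam,
                        screen_distance=1e4 * lam, screen_extent=1000.0)


@pytest.fixture
def silica_lens():
    """Fused-silica plano-convex singlet: 5 mm semi-diameter, 2.2 mm thick,
    4.6 mm ROC."""
    return PlanoConvexLensSpec(radius=5000.0, thickness=2200.0, roc=4600.0,
                               n_lens=1.4631)


@pytest.fixture
def axicon_5deg():
    """5° axicon, 12.7 mm radius, fused silica."""
    return AxiconSpec(alpha=np.deg2rad(5.0), radius=12700.0, n_lens=1.4631,
                      thickness=2200.0)
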