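import numpy as np
import pytest

import axonquant as aq


@pytest.fixture
def default_model():
    return aq.PunctaModel()


@pytest.fixture
def resolvable_model():
    """Model with a wide, well-resolved punctum (sigma > 3 px) so bilinear
    image sampling stays within the round-trip tolerance."""
    return aq.PunctaModel(puncta_sigma=0.2)


@pytest.fixture
def straight_trace_50um():
    return aq.straight_trace((1.0, 2.0), (54.0, 2.0))


def normalize_self(profile):
    """Normalize a profile by its own mean (reference pool of one)."""
    return aq.normalize_profile(profile, aq.compute_reference_mean([profile]))


@pytest.fixture
def cosine_profile():
    """Pure 1.0 µm-period sinusoid over ~50 µm at 63 nm sampling."""
    x = np.arange(793) * 0.063
    prof = aq.LineProfile(0.063, x, np.cos(2 * np.pi * x / 1.0) + 1.0)
    return aq.normalize_profile(prof, 1.0)
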