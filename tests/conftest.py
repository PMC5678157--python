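from __future__ import annotations

import pytest

from pathtriad.profile_io import ProteinRatioProfile
from pathtriad.synthetic import SyntheticConfig, generate, small_config


def profile_from(name: str, **ratios: float) -> ProteinRatioProfile:
    """Shorthand: build a profile from symbol=log2_ratio keyword pairs."""
    return ProteinRatioProfile.from_pairs(name, ratios.items())


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic dataset (60-protein universe, exhaustive-friendly)."""
    return generate(small_config(seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale synthetic dataset shared across tests."""
    return generate(SyntheticConfig(rng_seed=1))
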