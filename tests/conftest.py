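import numpy as np
import pytest

from handnir import (
    FluorophoreSpec,
    OpticalProperties,
    build_hand_slab,
    embed_synovial_shell,
)
from handnir.io import build_from_config, load_config


@pytest.fixture(scope="session")
def props():
    """Default NIR soft-tissue optics."""
    return OpticalProperties(mu_a=0.01, mu_s_prime=1.0)


@pytest.fixture(scope="session")
def dye():
    return FluorophoreSpec(quantum_yield=0.12, molar_absorption_ex=5.5e-5)


@pytest.fixture(scope="session")
def small_domain():
    """Compact slab with the default synovial pocket, for mechanical tests."""
    dom = build_hand_slab(40, 30, 20, 1.0)
    return embed_synovial_shell(dom, center_depth=2.3)


@pytest.fixture(scope="session")
def default_domain_coarse():
    """The package's default hand-slab geometry on a 1 mm grid."""
    cfg = load_config(overrides={"geometry": {"spacing_mm": 1.0}})
    domain, *_ = build_from_config(cfg)
    return domain
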