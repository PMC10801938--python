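"""Shared fixtures: seeded generators and a reduced-width backbone config.

The reduced config keeps the full architecture (kernel 15, dilations 2^L,
strides 3/1/3/1/2, MDSC front end, CMFF fusion) but narrows the channel
widths so CPU training and probing stay fast; structural-contract tests use
the full default widths.
"""

import numpy as np
import pytest

from fhrfusion.backbone import BackboneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


SMALL_CHANNELS = (8, 8, 16, 16, 32)


@pytest.fixture
def small_backbone_cfg():
    return BackboneConfig(channels=SMALL_CHANNELS, mdsc_channels=2, seed=0)


@pytest.fixture(scope="session")
def default_latent():
    """One forward pass of the full default backbone on a 2-record batch."""
    from fhrfusion.backbone import SETCNBackbone

    cfg = BackboneConfig()
    bb = SETCNBackbone(cfg).eval()
    x = np.random.default_rng(0).normal(0, 1, size=(2, 7200, 1)).astype(np.float32)
    z, shapes = bb(x, return_intermediate=True)
    return cfg, bb, z, shapes
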