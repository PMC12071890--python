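"""Shared fixtures: desk-scale phantoms and registration fixtures.

Everything is generated programmatically and seeded; expensive fixtures are
session-scoped so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from sctselect import phantom
from sctselect.warping import invert_dvf, warp

# desk-scale grid used throughout the tests
GRID = (32, 32, 16)
SPACING = (8.0, 8.0, 10.0)


def desk_spec(**overrides) -> phantom.PhantomSpec:
    return phantom.PhantomSpec.scaled_to(GRID, SPACING, **overrides)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, couch-free phantom with ground-truth masks."""
    spec = desk_spec(noise_sigma=0.0, couch_kind="none", random_seed=0)
    vol, masks = phantom.make_thorax_phantom(spec)
    return vol, masks


@pytest.fixture(scope="session")
def noisy_couch_phantom():
    """Flat-couch phantom with noise, plus its ground-truth masks."""
    spec = desk_spec(noise_sigma=5.0, couch_kind="flat", random_seed=1)
    vol, masks = phantom.make_thorax_phantom(spec)
    return vol, masks


def registration_fixture(seed: int):
    """(dCT, pCT, true inverse DVF, body mask) with a known smooth field.

    The diagnostic image is the planning image backward-warped by a smooth
    random field of at most 5 mm; both get independent sigma=5 HU noise.
    """
    base = desk_spec(noise_sigma=0.0, couch_kind="none", random_seed=seed)
    clean, masks = phantom.make_thorax_phantom(base)
    g = phantom.make_smooth_dvf(
        phantom.DeformationSpec(
            n_blobs=4, amplitude_mm=(2.0, 5.0), width_mm=(30.0, 60.0),
            random_seed=seed + 100,
        ),
        clean,
    )
    dct = warp(clean, g)
    rng = np.random.default_rng(seed + 200)
    pct_n = clean.with_data(clean.data + rng.normal(0, 5, clean.shape))
    dct_n = dct.with_data(dct.data + rng.normal(0, 5, clean.shape))
    return dct_n, pct_n, invert_dvf(g), masks


@pytest.fixture(scope="session")
def registration_pair():
    return registration_fixture(0)
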