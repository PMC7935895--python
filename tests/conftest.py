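"""Shared fixtures: small synthetic catalogs and gameplay logs.

Everything is generated at test time from seeded generators; the catalog uses
scaled-down imagery (256x256 backgrounds, ~24 px crab radius) so the full
metric battery runs in seconds while preserving the metric structure.
"""

import numpy as np
import pytest

from camoseek.game import GameConfig
from camoseek.synth import (
    BackgroundGeneratorParams,
    make_background,
    make_catalog,
    make_gameplay_dataset,
)

SMALL_IMAGE = (256, 256)
SMALL_RADIUS = 24.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def uniform_background():
    """Featureless mid-grey-green background (no texture at all)."""
    return make_background(
        BackgroundGeneratorParams(lum_amplitude=0.0, colour_jitter_sd=0.0),
        size=(200, 200),
        rng=np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def textured_background():
    return make_background(
        BackgroundGeneratorParams(), size=SMALL_IMAGE, rng=np.random.default_rng(8)
    )


@pytest.fixture(scope="session")
def small_catalog():
    """30 crabs (5 per morph), 8 backgrounds, image-derived profiles."""
    mix = {m: 5 for m in ("Black", "Disruptive", "Green", "Mottled", "Pale", "Spotted")}
    return make_catalog(
        n_crabs=30,
        n_backgrounds=8,
        morph_mix=mix,
        rng=np.random.default_rng(99),
        image_size=SMALL_IMAGE,
        body_radius=SMALL_RADIUS,
    )


@pytest.fixture(scope="session")
def hazard_params():
    """Study-condition hazard parameterisation incl. switch mechanisms."""
    from camoseek.synth import default_hazard_params
    from dataclasses import replace

    return replace(
        default_hazard_params(),
        morph_switch_penalty=-0.3,
        novelty_coefs={"gabrat_a": -0.8},
    )


@pytest.fixture(scope="session")
def gameplay(small_catalog, hazard_params):
    """Simulated gameplay log + truth record (300 sessions of 24 slides)."""
    log, truth = make_gameplay_dataset(
        small_catalog,
        params=hazard_params,
        n_sessions=300,
        game_cfg=GameConfig(),
        rng=np.random.default_rng(321),
    )
    return log, truth
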