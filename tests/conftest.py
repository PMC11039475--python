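"""Shared fixtures: small seeded phantoms reused across test modules."""

import numpy as np
import pytest

from infarct3d.phantom import (generate_phantom, lobe_preset, submicron_preset)


@pytest.fixture(scope="session")
def lobe_day3():
    """Lobe-scale day-3 phantom (96³, seed 11): truth, zones, noisy render."""
    params = lobe_preset("3", grid=96, seed=11)
    truth, zones, volume = generate_phantom(params)
    return params, truth, zones, volume


@pytest.fixture(scope="session")
def lobe_day3_noiseless(lobe_day3):
    """Same phantom rendered without noise (piecewise-constant volume)."""
    from infarct3d.phantom import render_grayscale
    params, truth, zones, _ = lobe_day3
    clean = params.replace(noise_sd=0.0)
    return clean, truth, zones, render_grayscale(truth, clean)


@pytest.fixture(scope="session")
def submicron_small():
    """Submicron phantom (128³, 8 infarcts, seed 5) with microchannels."""
    params = submicron_preset("7", grid=128, seed=5, n_infarcts=8)
    truth, zones, volume = generate_phantom(params)
    return params, truth, zones, volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
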