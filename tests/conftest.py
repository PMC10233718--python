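"""Shared fixtures: small rendered sections and bead fields with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from nascentquant.detection import DetectionParams
from nascentquant.registration import ChannelTransform
from nascentquant.simulate import SimulationParams, render_bead_field, render_section


@pytest.fixture(scope="session")
def clean_section():
    """A small noiseless single-gene section: one cell, one allele, no clutter."""
    params = SimulationParams(
        genes=("geneA",), burst_probs=(1.0,), n_cells=1,
        image_shape=(20, 128, 128), autofluorescence_density=0.0,
        shot_noise=False, camera_noise_sd=0.0, background_level=0.0, seed=11,
    )
    stack, truth = render_section(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def noisy_section():
    """A realistic three-gene section with noise and clutter."""
    params = SimulationParams(
        burst_probs=(0.6, 0.6, 0.6), n_cells=8,
        image_shape=(20, 256, 256), seed=21,
    )
    stack, truth = render_section(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def bead_field_with_shift():
    """Bead field whose red channel carries a known similarity misalignment."""
    center = (127.5, 127.5)
    true = {
        "red": ChannelTransform(channel="red", dx=1.2, dy=-0.7,
                                rotation=np.deg2rad(0.5), scale=1.001, center=center),
    }
    stack, beads = render_bead_field(true, n_beads=40, channels=("farred", "red"),
                                     seed=5)
    return true, stack, beads


@pytest.fixture
def det_params():
    return DetectionParams(min_amplitude=200.0)
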