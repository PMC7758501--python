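"""Shared fixtures: small synthetic sections with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from striodens.synthetic import (
    default_effect_model,
    generate_section,
    render_section,
)


@pytest.fixture(scope="session")
def noise_free_effects():
    """Study-condition effect model with noise and shading switched off."""
    return default_effect_model(noise_sd=0.0, shading_amplitude=0.0)


@pytest.fixture(scope="session")
def noise_free_section(noise_free_effects):
    """One rostral WT section rendered without noise: (landmarks, truth, image)."""
    rng = np.random.default_rng(42)
    landmarks, truth = generate_section("rostral", noise_free_effects, rng)
    image = render_section(truth, noise_free_effects, rng)
    return landmarks, truth, image


@pytest.fixture(scope="session")
def noisy_effects():
    """Default study conditions: noise sd 5 on a 60-gray-level gap."""
    return default_effect_model()


@pytest.fixture(scope="session")
def noisy_section(noisy_effects):
    rng = np.random.default_rng(43)
    landmarks, truth = generate_section("rostral", noisy_effects, rng)
    image = render_section(truth, noisy_effects, rng)
    return landmarks, truth, image


def mirror_landmarks(lm):
    """Reflect a landmark set about the vertical image midline."""
    from striodens.geometry import LandmarkSet

    w = lm.image_shape[1]
    f = lambda p: (float((w - 1) - p[0]), float(p[1]))
    fo = lambda o: np.column_stack([(w - 1) - np.asarray(o)[:, 0], np.asarray(o)[:, 1]])
    return LandmarkSet(
        cp_outline_left=fo(lm.cp_outline_right),
        cp_outline_right=fo(lm.cp_outline_left),
        ac_lateral_tip_left=f(lm.ac_lateral_tip_right),
        ac_lateral_tip_right=f(lm.ac_lateral_tip_left),
        nacc_shell_upper_tip_left=f(lm.nacc_shell_upper_tip_right),
        nacc_shell_upper_tip_right=f(lm.nacc_shell_upper_tip_left),
        fiber_control_squares=list(lm.fiber_control_squares),
        pixel_size_um=lm.pixel_size_um,
        image_shape=lm.image_shape,
    )
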