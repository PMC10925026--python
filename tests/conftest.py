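"""Shared fixtures: synthetic renders and the control-derived dye threshold.

The expensive session fixtures render full-size (512 px, 800-fiber) control
sections once and reuse them across the image-pipeline and acceptance tests.
"""

import numpy as np
import pytest

from myodti.image_quantification import control_intensity_threshold, preprocess, tissue_mask
from myodti.synthetic_data import generate_control_sections

BACKGROUND_RADIUS = 25  # px, > 2x the ~8 px fiber radius of the default scenes


@pytest.fixture(scope="session")
def control_stack():
    """Six full-size negative-control sections (no planted dead fibers)."""
    return generate_control_sections(n_sections=6, seed=11)


@pytest.fixture(scope="session")
def control_preprocessed(control_stack):
    dye = [preprocess(c.dye_channel, BACKGROUND_RADIUS) for c in control_stack]
    auto = [preprocess(c.auto_channel, BACKGROUND_RADIUS) for c in control_stack]
    return auto, dye


@pytest.fixture(scope="session")
def dye_threshold(control_preprocessed):
    """Control-derived dye-positivity threshold for the default render model."""
    auto, dye = control_preprocessed
    return control_intensity_threshold(dye, [tissue_mask(a) for a in auto])
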