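import numpy as np
import pytest

from mupadflow import (
    ClassCoefficientModel,
    ClassCoefficients,
    ExperimentDesign,
    ExtractionConfig,
    RenderGeometry,
)


@pytest.fixture
def small_design() -> ExperimentDesign:
    """Scaled-down acquisition design: 2 sessions, 6 s at 10 fps, 50 retained frames."""
    return ExperimentDesign(
        n_sessions=2,
        classes=(0.1, 0.5, 1.0),
        replicates_per_class=3,
        fps=10.0,
        duration_s=6.0,
        reference_frames=10,
        frame_height_px=120,
        frame_width_px=60,
    )


@pytest.fixture
def small_model() -> ClassCoefficientModel:
    """Well-separated class coefficients sized for a 120-px-tall frame."""
    return ClassCoefficientModel(
        per_class={
            0.1: ClassCoefficients(mean_a=24.0, sd_a=1.0, mean_b=0.0, sd_b=0.5),
            0.5: ClassCoefficients(mean_a=18.0, sd_a=1.0, mean_b=0.0, sd_b=0.5),
            1.0: ClassCoefficients(mean_a=12.0, sd_a=1.0, mean_b=0.0, sd_b=0.5),
        },
        noise_sd_px=1.0,
    )


@pytest.fixture
def small_geometry() -> RenderGeometry:
    return RenderGeometry(
        frame_height_px=120,
        frame_width_px=60,
        strip_col_start=20,
        strip_col_end=40,
        baseline_row=100,
        pre_contact_padding=7,
    )


@pytest.fixture
def small_extraction() -> ExtractionConfig:
    return ExtractionConfig(
        roi=(20, 40),
        diff_threshold=30.0,
        min_wet_pixels_per_row=3,
        reference_frames=10,
    )
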