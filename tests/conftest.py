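import numpy as np
import pytest

from vesselperm import PhantomConfig, simulate_experiment


def small_config(**overrides) -> PhantomConfig:
    """Compact single-tube phantom used throughout the unit tests.

    A 600 µm field keeps each simulation around 20 ms while preserving
    the protocol's frame timing (61 frames at 10 s).
    """
    fields = dict(
        chamber_diameter_um=600.0,
        pixel_size_um=2.0,
        n_segments=1,
        radius_range_um=(20.0, 20.0),
        true_permeability_um_s=0.05,
        noise_sd=0.0,
        seed=3,
    )
    fields.update(overrides)
    return PhantomConfig(**fields)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free single-tube phantom (r = 20 µm, P = 0.05 µm/s)."""
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def noisy_phantom():
    return simulate_experiment(small_config(noise_sd=1.0, seed=11))


def truth_segment(truth, i=0):
    """Build a VesselSegment from phantom ground truth (bypassing
    segmentation) so estimator tests are independent of the mask step."""
    from vesselperm import VesselSegment

    tube = truth.tubes[i]
    centerline = np.stack([tube.p0, tube.p1]).round().astype(int)
    return VesselSegment(
        segment_id=f"truth{i}",
        centerline=centerline,
        radius_um=tube.radius_um,
        length_um=tube.length_px * truth.config.pixel_size_um,
        lumen_mask=truth.lumen_mask(i),
        window_mask=truth.window_mask(i),
    )
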