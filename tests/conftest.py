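import numpy as np
import pytest

from frapkit.synthetic_data import CentrosomeTruth, SceneSpec, generate_frap_series


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_frap_scene(
    seed: int,
    offset_um=(0.0, 0.0),
    microscope_shift_um=(0.0, 0.0),
    noise: bool = True,
    frame_times=(-30.0, 0.0, 30.0, 60.0),
    center_jitter_rng: np.random.Generator | None = None,
    **truth_overrides,
):
    """One synthetic centrosome FRAP scene with the calibrated defaults.

    Returns (series, spec, truth, center).  The centrosome centre gets a
    sub-pixel placement jitter when a generator is supplied.
    """
    center = np.array([4.8, 4.8])
    if center_jitter_rng is not None:
        center = center + center_jitter_rng.uniform(-0.3, 0.3, size=2)
    spec = SceneSpec(
        image_shape_px=(96, 96),
        frame_times_s=tuple(frame_times),
        bleach_frame_index=1,
        rng_seed=seed,
        shot_noise=noise,
        read_noise_sd=2.0 if noise else 0.0,
        background_level=10.0 if noise else 0.0,
    )
    truth_kwargs = dict(
        pcm_center_um=tuple(center),
        mother_pos_um=tuple(center + [0.05, 0.0]),
        daughter_pos_um=tuple(center + [0.25, 0.0]),
        pcm_sigma_um=0.35,
        channel_offset_um=tuple(offset_um),
        recovery_rate_per_s=(0.05, 0.05),
        recovered_fraction=(0.6, 0.5),
    )
    truth_kwargs.update(truth_overrides)
    truth = CentrosomeTruth(**truth_kwargs)
    series, truth = generate_frap_series(
        spec, truth, microscope_shift_um=microscope_shift_um
    )
    return series, spec, truth, center


@pytest.fixture
def frap_scene_factory():
    return make_frap_scene
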