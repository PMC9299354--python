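import pytest

from cervitrace import (
    CameraSpec,
    TrajectoryScript,
    build_zigzag_pattern,
    render_frames,
    simulate_trajectory,
)

# small camera keeps rendering fast; geometry checks are scale-free
SMALL_CAMERA = dict(width=640, height=360, fps=25.0)


@pytest.fixture(scope="session")
def pattern():
    """Default zigzag: 1000 mm path on A3 landscape."""
    return build_zigzag_pattern()


@pytest.fixture(scope="session")
def straight_pattern():
    """Degenerate straight-line target of the same 1000 mm length."""
    return build_zigzag_pattern(
        n_peaks=1, amplitude_mm=0.0, board_size_mm=(1100.0, 297.0)
    )


@pytest.fixture(scope="session")
def small_camera():
    return CameraSpec(**SMALL_CAMERA)


@pytest.fixture(scope="session")
def noiseless_render(pattern, small_camera):
    """Short noiseless trial (1 s dwell + 4 s traverse) rendered at 640x360."""
    script = TrajectoryScript(
        pattern=pattern, duration_s=4.0, dwell_s=1.0, fps=25.0,
        lateral_error_sd_mm=0.0, seed=7,
    )
    track, truth = simulate_trajectory(script)
    rendered = render_frames(pattern, track, small_camera)
    return dict(script=script, track=track, truth=truth, rendered=rendered)
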