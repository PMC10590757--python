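import numpy as np
import pytest

import vacuoscope as v


@pytest.fixture(scope="session")
def bcecf_cohort():
    """Default ratiometric-dye cohort (SDC regime), 15 cells, with truth."""
    cfg = v.cohort_config("SDC", n_cells=15, channels={"bcecf": v.BCECF, "ref": v.MCHERRY})
    return v.make_cohort(cfg)


@pytest.fixture(scope="session")
def bcecf_calibration_fit():
    series = v.make_calibration_series((v.BCECF, v.MCHERRY), seed=7)
    return v.fit_calibration(series, mode="sigmoid")


@pytest.fixture(scope="session")
def cohort_ph_and_peaks(bcecf_cohort, bcecf_calibration_fit):
    """Calibrated pH traces and detected peaks for the default cohort."""
    traces, truths = bcecf_cohort
    out = []
    for tr in traces:
        ph, _ = v.ratio_to_ph(bcecf_calibration_fit, tr.ratio("bcecf", "ref"))
        peaks = v.detect_peaks(ph, tr.times)
        out.append((tr, ph, peaks))
    return out, truths


@pytest.fixture(scope="session")
def rendered_scene():
    """Noise-free rendered stack of 10 moving vacuoles, 50 frames."""
    traces, _ = v.make_cohort(v.cohort_config("SDC", n_cells=10, duration=100.0, dt=2.0, seed=3))
    scene = v.ImageSceneConfig(
        frame_shape=(300, 300),
        poisson_noise=False,
        read_noise_sd=0.0,
        background_level=0.0,
        cell_motion_sd=0.4,
    )
    stacks, truth = v.render_image_stack(traces, scene, seed=4)
    return traces, stacks, truth


def disk_frame(shape, cx, cy, radius, value=1.0, background=0.0):
    """Antialiased disk test image (same edge model as the renderer)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    return background + value * np.clip(radius + 0.5 - dist, 0.0, 1.0)
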