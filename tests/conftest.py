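import numpy as np
import pytest

from fpmkit import (
    ComplexField,
    GSConfig,
    LEDGrid,
    OpticalConfig,
    make_ctf,
    run_gs,
    simulate_capture,
)
from fpmkit.dataset import build_truth_pairs, generate_synthetic_sources
from fpmkit.recon import bilinear_upsample


@pytest.fixture(scope="session")
def paper_optics():
    """The reference optical configuration: NA 0.13, λ 0.505 µm, 4× decimation."""
    return OpticalConfig(na=0.13, wavelength=0.505, upsample_factor=4, object_pixel_um=0.275)


@pytest.fixture(scope="session")
def paper_grid():
    return LEDGrid(rows=13, cols=13, pitch_mm=4.0, height_mm=90.0)


@pytest.fixture(scope="session")
def small_optics():
    """A 16→8 configuration whose pupil windows carry nonzero shifts."""
    return OpticalConfig(na=0.3, wavelength=0.505, upsample_factor=2, object_pixel_um=0.4)


@pytest.fixture(scope="session")
def small_grid():
    return LEDGrid(rows=2, cols=2, pitch_mm=40.0, height_mm=90.0)


@pytest.fixture(scope="session")
def small_sample(small_optics):
    rng = np.random.default_rng(7)
    amp = rng.uniform(0.2, 1.0, size=(16, 16))
    ph = rng.uniform(-1.0, 1.0, size=(16, 16))
    return ComplexField(amp * np.exp(1j * ph), pixel_um=small_optics.object_pixel_um)


@pytest.fixture(scope="session")
def scene_192(paper_optics):
    """A 192×192 textured complex scene built by the dataset generator."""
    src = generate_synthetic_sources(2, 192, seed=1)
    fields, _ = build_truth_pairs(src, 1, seed=1, pixel_um=paper_optics.object_pixel_um)
    return fields[0]


@pytest.fixture(scope="session")
def closed_loop(paper_optics, paper_grid, scene_192):
    """Shared simulate → reconstruct run at the reference scale (noise-free,
    50 rounds); reused by several tests to keep the suite fast."""
    stack = simulate_capture(scene_192, paper_optics, paper_grid)
    ctf = make_ctf(paper_optics, stack.side)
    recon, residuals = run_gs(stack, ctf, GSConfig(max_rounds=50))
    baseline = bilinear_upsample(
        stack.images[stack.central_index()], paper_optics.upsample_factor
    )
    return {
        "sample": scene_192,
        "stack": stack,
        "ctf": ctf,
        "recon": recon,
        "residuals": residuals,
        "baseline_intensity": baseline,
    }
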