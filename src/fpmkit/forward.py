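"""Forward imaging model: multi-angle acquisition of low-resolution intensities.

Each LED of the array illuminates the sample with a tilted plane wave
``exp(j k_n · r)``; tilting shifts the object spectrum so the objective's
pupil H(k) selects the region of O(k) centred at k_n.  The sensor records
the squared modulus of the pupil-filtered field on a grid decimated by
``upsample_factor``:

    I_n(r) = | F⁻¹{ O(k) · H(k + k_n) } |².
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import fourier
from .errors import InputError
from .optics import ComplexField, LEDGrid, OpticalConfig, PupilCTF, compute_wave_vectors, make_ctf

__all__ = ["LowResStack", "simulate_capture", "add_gaussian_noise"]


@dataclass
class LowResStack:
    """A stack of nonnegative low-resolution intensity images with their
    illumination wave vectors, in LED raster order."""

    images: np.ndarray  # (n_led, side, side) float
    wave_vectors: np.ndarray  # (n_led, 2) rad/um
    noise_sigma: float = 0.0
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.wave_vectors = np.asarray(self.wave_vectors, dtype=float)
        if self.images.ndim != 3:
            raise InputError(f"images must be a 3-D stack, got shape {self.images.shape}")
        if self.wave_vectors.shape != (self.images.shape[0], 2):
            raise InputError(
                f"wave_vectors shape {self.wave_vectors.shape} does not match "
                f"{self.images.shape[0]} images"
            )
        if self.noise_sigma == 0.0 and np.any(self.images < 0):
            raise InputError("clean intensity images must be nonnegative")

    @property
    def n_led(self) -> int:
        return self.images.shape[0]

    @property
    def side(self) -> int:
        return self.images.shape[1]

    def central_index(self) -> int:
        """Index of the normal-incidence (k_n = 0) image.

        Raises
        ------
        InputError
            If no LED is within numerical tolerance of normal incidence.
        """
        mags = np.hypot(self.wave_vectors[:, 0], self.wave_vectors[:, 1])
        idx = int(np.argmin(mags))
        if mags[idx] > 1e-9:
            raise InputError("stack has no normal-incidence (central LED) image")
        return idx


def simulate_capture(
    sample: ComplexField, optics: OpticalConfig, grid: LEDGrid, *, ctf: PupilCTF | None = None
) -> LowResStack:
    """Simulate the full multi-angle acquisition of ``sample``.

    The sample side must be ``upsample_factor`` × sensor side.  Returns one
    intensity image per LED in raster order, deterministic given inputs.
    """
    f = int(optics.upsample_factor)
    if sample.side % f != 0:
        raise InputError(
            f"sample side {sample.side} is not divisible by upsample_factor {f}"
        )
    sensor_side = sample.side // f
    if ctf is None:
        ctf = make_ctf(optics, sensor_side)
    kvecs = compute_wave_vectors(grid, optics.wavelength)
    O = fourier.spectrum(sample.values)
    images = np.empty((grid.n_led, sensor_side, sensor_side), dtype=float)
    for n, k_n in enumerate(kvecs):
        shift = fourier.integer_shift(k_n, ctf.dk)
        g = fourier.extract_lowres_field(O, ctf.mask, shift)
        images[n] = np.abs(g) ** 2
    return LowResStack(
        images=images,
        wave_vectors=kvecs,
        noise_sigma=0.0,
        meta={"optics": optics, "grid": grid},
    )


def add_gaussian_noise(stack: LowResStack, sigma: float, seed: int) -> LowResStack:
    """Additive zero-mean Gaussian noise on every intensity image.

    ``sigma`` is interpreted on intensities normalised to a stack peak of 1
    (the scale on which noise levels of 1e-4 to 3e-4 are quoted), so the
    noise actually added is ``sigma × max(stack)``.  Negative results are
    clipped to zero.  ``sigma = 0`` returns an identical copy.
    """
    if sigma < 0:
        raise InputError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return LowResStack(
            images=stack.images.copy(),
            wave_vectors=stack.wave_vectors.copy(),
            noise_sigma=0.0,
            meta=dict(stack.meta),
        )
    rng = np.random.default_rng(seed)
    peak = float(np.max(stack.images))
    scale = sigma * (peak if peak > 0 else 1.0)
    noisy = stack.images + rng.normal(0.0, scale, size=stack.images.shape)
    np.clip(noisy, 0.0, None, out=noisy)
    return LowResStack(
        images=noisy,
        wave_vectors=stack.wave_vectors.copy(),
        noise_sigma=sigma,
        meta=dict(stack.meta),
    )
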