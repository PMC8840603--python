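"""Optical system description: objective, LED illumination geometry, pupil.

Conventions used throughout the package
---------------------------------------
* All spatial frequencies are angular wavenumbers in rad/µm; the coherent
  cutoff of an objective with numerical aperture NA at wavelength λ is
  ``k_c = NA · 2π/λ``.
* Spectra are *centered*: the DC bin of an ``N``-pixel grid sits at index
  ``N // 2`` (``numpy.fft.fftshift`` convention), and the frequency step is
  ``Δk = 2π / (N · pixel_pitch)``.
* The object (high-resolution) grid has pixel pitch ``object_pixel_um``;
  the sensor grid is decimated by ``upsample_factor``, so its pitch is
  ``object_pixel_um · upsample_factor`` and both grids share one ``Δk``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, GeometryError, InputError

__all__ = [
    "OpticalConfig",
    "LEDGrid",
    "ComplexField",
    "PupilCTF",
    "compute_wave_vectors",
    "led_sweep_order",
    "make_ctf",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Objective and sampling parameters of the simulated microscope.

    Parameters
    ----------
    na : float
        Numerical aperture of the objective, 0 < na < 1.
    wavelength : float
        Illumination wavelength λ in µm.
    upsample_factor : int
        Ratio of object-grid side to sensor-grid side (≥ 1).
    object_pixel_um : float
        Object-plane pixel pitch in µm. The default keeps a 13×13 LED
        array within the 192-pixel spectrum extent at NA 0.13, λ 0.505 µm.
    """

    na: float = 0.13
    wavelength: float = 0.505
    upsample_factor: int = 4
    object_pixel_um: float = 0.275

    def __post_init__(self):
        problems = []
        if not (0 < self.na < 1):
            problems.append(f"na must be in (0, 1), got {self.na}")
        if not self.wavelength > 0:
            problems.append(f"wavelength must be > 0, got {self.wavelength}")
        if int(self.upsample_factor) != self.upsample_factor or self.upsample_factor < 1:
            problems.append(
                f"upsample_factor must be an integer >= 1, got {self.upsample_factor}"
            )
        if not self.object_pixel_um > 0:
            problems.append(f"object_pixel_um must be > 0, got {self.object_pixel_um}")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def cutoff(self) -> float:
        """Coherent cutoff NA·2π/λ in rad/µm."""
        return self.na * 2.0 * np.pi / self.wavelength

    @property
    def sensor_pixel_um(self) -> float:
        return self.object_pixel_um * self.upsample_factor


@dataclass(frozen=True)
class LEDGrid:
    """Planar LED array centred under the sample.

    The LED at grid position (row, col) sits at lateral offset
    ``((col - (cols-1)/2) · pitch, (row - (rows-1)/2) · pitch)`` from the
    optical axis, at distance ``height_mm`` below the sample.  LEDs are
    enumerated in raster order (row-major), which fixes the index ↔
    (row, col) bijection used by every stack.
    """

    rows: int = 13
    cols: int = 13
    pitch_mm: float = 4.0
    height_mm: float = 90.0

    def __post_init__(self):
        problems = []
        if self.rows < 1 or self.cols < 1:
            problems.append(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if self.pitch_mm < 0:
            problems.append(f"pitch_mm must be >= 0, got {self.pitch_mm}")
        if self.height_mm <= 0:
            problems.append(f"height_mm must be > 0, got {self.height_mm}")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def n_led(self) -> int:
        return self.rows * self.cols

    def index_to_rowcol(self, n: int) -> tuple[int, int]:
        return divmod(n, self.cols)

    def rowcol_to_index(self, row: int, col: int) -> int:
        return row * self.cols + col

    def offsets_mm(self) -> np.ndarray:
        """(n_led, 2) lateral offsets (dx, dy) in mm, raster order."""
        r0 = (self.rows - 1) / 2.0
        c0 = (self.cols - 1) / 2.0
        rows, cols = np.divmod(np.arange(self.n_led), self.cols)
        dx = (cols - c0) * self.pitch_mm
        dy = (rows - r0) * self.pitch_mm
        return np.stack([dx, dy], axis=1)


def compute_wave_vectors(grid: LEDGrid, wavelength: float) -> np.ndarray:
    """Illumination wave vectors k_n = 2π·(sin α_xn, sin α_yn)/λ, raster order.

    The direction sines follow from the LED geometry:
    ``sin α_x = -dx / sqrt(dx² + dy² + h²)`` (light travels from the LED
    towards the on-axis sample, so a LED at +x illuminates with a −x
    transverse component).  Units: rad/µm.

    Raises
    ------
    GeometryError
        If any LED would require |sin α| ≥ 1 (beyond grazing incidence).
    """
    if wavelength <= 0:
        raise InputError(f"wavelength must be > 0, got {wavelength}")
    offsets = grid.offsets_mm()
    h = grid.height_mm
    r = np.sqrt(offsets[:, 0] ** 2 + offsets[:, 1] ** 2 + h**2)
    sines = -offsets / r[:, None]
    mag = np.sqrt(np.sum(sines**2, axis=1))
    if np.any(mag >= 1.0):
        worst = int(np.argmax(mag))
        raise GeometryError(
            f"LED index {worst} is at or beyond grazing incidence (|sin α| = {mag[worst]:.3f})"
        )
    return 2.0 * np.pi * sines / wavelength


def led_sweep_order(wave_vectors: np.ndarray) -> np.ndarray:
    """Centre-outward sweep order: ascending |k_n|, ties broken by raster index.

    Low-frequency-first sweeps are the standard choice for the
    alternating-projection update, so the well-constrained centre of the
    spectrum is written before the outer sub-apertures.
    """
    k = np.asarray(wave_vectors, dtype=float)
    mags = np.hypot(k[:, 0], k[:, 1])
    return np.lexsort((np.arange(len(k)), mags))


@dataclass
class ComplexField:
    """A square 2-D complex amplitude o(x, y) with a physical pixel pitch."""

    values: np.ndarray
    pixel_um: float = 0.275

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InputError(f"field must be a square 2-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("field contains non-finite values")
        if not self.pixel_um > 0:
            raise InputError(f"pixel_um must be > 0, got {self.pixel_um}")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.values) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class PupilCTF:
    """Ideal coherent transfer function: a binary disk of radius ``cutoff``.

    ``mask`` lives on the centred frequency grid of the *sensor* plane;
    ``dk`` is the frequency step shared with the object grid.
    """

    mask: np.ndarray
    cutoff: float
    dk: float = field(default=0.0)

    @property
    def side(self) -> int:
        return self.mask.shape[0]


def frequency_grid(side: int, pixel_um: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Centred (kx, ky) coordinate arrays and the step Δk = 2π/(side·pixel)."""
    dk = 2.0 * np.pi / (side * pixel_um)
    coords = (np.arange(side) - side // 2) * dk
    kx, ky = np.meshgrid(coords, coords, indexing="xy")
    return kx, ky, dk


def make_ctf(optics: OpticalConfig, sensor_side: int, *, strict: bool = False) -> PupilCTF:
    """Binary pupil disk of radius NA·2π/λ on the sensor frequency grid.

    The mask is 1 inside (and on) the cutoff circle, 0 outside; the DC bin
    is always inside.  If the cutoff exceeds the Nyquist bound of the
    sensor frequency grid the pupil would wrap: ``strict=True`` raises,
    otherwise a warning is emitted.
    """
    if sensor_side < 2:
        raise InputError(f"sensor_side must be >= 2, got {sensor_side}")
    kx, ky, dk = frequency_grid(sensor_side, optics.sensor_pixel_um)
    k_c = optics.cutoff
    nyquist = np.pi / optics.sensor_pixel_um
    if k_c > nyquist:
        msg = (
            f"pupil cutoff {k_c:.3f} rad/um exceeds the sensor Nyquist bound "
            f"{nyquist:.3f} rad/um; the pupil disk is truncated by the grid"
        )
        if strict:
            raise ConfigError(msg)
        warnings.warn(msg, stacklevel=2)
    mask = (kx**2 + ky**2 <= k_c**2).astype(float)
    return PupilCTF(mask=mask, cutoff=k_c, dk=dk)
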