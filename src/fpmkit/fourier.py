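"""Centred-FFT helpers shared by the forward model and the reconstruction.

Scaling convention
------------------
Spectra are computed with the unnormalised FFT and kept centred
(``fftshift``).  When a sensor-sized window of side ``n`` is cut from a
high-resolution spectrum of side ``N`` and inverse-transformed, the field is
multiplied by ``(n/N)²`` so that *spatial amplitudes* are preserved: a unit
transmission object yields a unit-amplitude low-resolution field under
on-axis illumination.  The inverse operation (embedding a sensor-grid
spectrum back into the window) multiplies by ``(N/n)²``, making the pair an
exact projector.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

__all__ = [
    "spectrum",
    "field",
    "integer_shift",
    "window_slices",
    "extract_lowres_field",
    "embed_sensor_spectrum",
]


def spectrum(values: np.ndarray) -> np.ndarray:
    """Centred spectrum of a spatial field (unnormalised FFT)."""
    return np.fft.fftshift(np.fft.fft2(values))


def field(spec: np.ndarray) -> np.ndarray:
    """Spatial field of a centred spectrum (unnormalised inverse FFT)."""
    return np.fft.ifft2(np.fft.ifftshift(spec))


def integer_shift(k_n: np.ndarray, dk: float) -> tuple[int, int]:
    """Nearest-pixel frequency-plane shift (sx, sy) for a wave vector.

    Sub-pixel residuals are discarded: the standard discretisation of the
    sub-aperture position on a shared frequency grid.
    """
    sx = int(np.rint(k_n[0] / dk))
    sy = int(np.rint(k_n[1] / dk))
    return sx, sy


def window_slices(hires_side: int, sensor_side: int, shift: tuple[int, int]) -> tuple[slice, slice]:
    """(row, col) slices of the sensor-sized sub-aperture window centred at
    the shifted pupil position inside the high-resolution centred spectrum.

    Raises
    ------
    GeometryError
        If the window would extend past the high-resolution spectrum.
    """
    sx, sy = shift
    c = hires_side // 2
    half = sensor_side // 2
    r0 = c + sy - half
    c0 = c + sx - half
    if r0 < 0 or c0 < 0 or r0 + sensor_side > hires_side or c0 + sensor_side > hires_side:
        raise GeometryError(
            f"pupil window shifted by {shift} pixels exceeds the {hires_side}-pixel "
            "spectrum extent; reduce the LED angles or enlarge the object grid"
        )
    return slice(r0, r0 + sensor_side), slice(c0, c0 + sensor_side)


def extract_lowres_field(
    hires_spectrum: np.ndarray, ctf_mask: np.ndarray, shift: tuple[int, int]
) -> np.ndarray:
    """Sensor-plane complex field F⁻¹{O(k)·H(k + k_n)} for one illumination.

    Cuts the sensor-sized window at the shifted pupil position, applies the
    binary pupil, and inverse-transforms with the amplitude-preserving
    ``(n/N)²`` factor.
    """
    big = hires_spectrum.shape[0]
    small = ctf_mask.shape[0]
    rs, cs = window_slices(big, small, shift)
    sub = hires_spectrum[rs, cs] * ctf_mask
    return field(sub) * (small / big) ** 2


def embed_sensor_spectrum(
    hires_spectrum: np.ndarray,
    sensor_field: np.ndarray,
    ctf_mask: np.ndarray,
    shift: tuple[int, int],
) -> None:
    """Write F{sensor_field} into the shifted pupil window, in place.

    Only pixels where the pupil mask is nonzero are touched; everything
    outside H(k + k_n) is left bit-identical.
    """
    big = hires_spectrum.shape[0]
    small = ctf_mask.shape[0]
    rs, cs = window_slices(big, small, shift)
    sub_spec = spectrum(sensor_field) * (big / small) ** 2
    inside = ctf_mask > 0
    window = hires_spectrum[rs, cs]
    window[inside] = sub_spec[inside]
    hires_spectrum[rs, cs] = window
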