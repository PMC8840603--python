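"""Alternating-projection (Gerchberg–Saxton) phase retrieval.

The reconstruction alternates between the spatial domain, where the
measured low-resolution amplitudes replace the estimated ones, and the
frequency domain, where each measurement updates only the sub-aperture of
the object spectrum selected by the shifted pupil H(k + k_n):

    g_n  = F⁻¹{ O(k) · H(k + k_n) }            (forward low-res estimate)
    ḡ_n  = √I_n · g_n / |g_n|                   (amplitude replacement)
    O(k) ← O(k)·[1 − H(k+k_n)] + F{ḡ_n}·H(k+k_n)   (sub-spectrum update)

One sweep visits every LED once; sweeps repeat until ``max_rounds`` or
until the relative spectrum change drops below ``convergence_tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage.transform import resize

from . import fourier
from .errors import InputError
from .forward import LowResStack
from .optics import ComplexField, PupilCTF, led_sweep_order

__all__ = [
    "GSConfig",
    "SpectrumEstimate",
    "initialize_spectrum",
    "forward_lowres_estimate",
    "replace_amplitude",
    "update_subspectrum",
    "run_gs",
]

#: |g| below this is treated as a zero-amplitude pixel; its phasor is taken
#: as 1 (any unit phasor is admissible on a measure-zero set).
ZERO_AMP = 1e-12


@dataclass(frozen=True)
class GSConfig:
    """Iteration parameters for the alternating-projection reconstruction.

    ``max_rounds`` full sweeps (50 by default, the customary budget for this
    class of reconstructions); ``convergence_tol`` is a relative Frobenius
    change between consecutive rounds (0 disables early stopping, and the
    residual history is then purely diagnostic); ``init_phase`` is the flat
    initial phase guess φ0; ``led_order`` is ``"center_out"`` (ascending
    |k_n|) or ``"raster"``.
    """

    max_rounds: int = 50
    init_phase: float = 0.0
    convergence_tol: float = 0.0
    led_order: str = "center_out"

    def __post_init__(self):
        if self.max_rounds < 1:
            raise InputError(f"max_rounds must be >= 1, got {self.max_rounds}")
        if self.convergence_tol < 0:
            raise InputError(f"convergence_tol must be >= 0, got {self.convergence_tol}")
        if self.led_order not in ("center_out", "raster"):
            raise InputError(f"unknown led_order {self.led_order!r}")


@dataclass
class SpectrumEstimate:
    """The evolving high-resolution object spectrum with bookkeeping."""

    spectrum: np.ndarray  # centred, high-res grid
    round: int = 0
    last_led: int = -1
    residual_history: list = dc_field(default_factory=list)

    @property
    def side(self) -> int:
        return self.spectrum.shape[0]


def bilinear_upsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Order-1 (bilinear) enlargement by an integer factor; identity at 1."""
    if factor == 1:
        return np.asarray(image, dtype=float).copy()
    out_side = image.shape[0] * factor
    return resize(
        np.asarray(image, dtype=float),
        (out_side, out_side),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def initialize_spectrum(
    stack: LowResStack,
    ctf: PupilCTF,
    cfg: GSConfig,
    *,
    upsample_factor: int | None = None,
) -> SpectrumEstimate:
    """Initial spectrum guess from the normal-incidence image.

    The central image's amplitude is bilinearly enlarged to the
    high-resolution grid, given the flat phase φ0, and transformed:
    ``O⁰ = F{ B(√I_central) · exp(jφ0) }``.  Under the package's
    amplitude-preserving scaling no further factor is needed.

    ``upsample_factor`` defaults to the value recorded in the stack's
    metadata (1 if absent).
    """
    if stack.n_led == 0:
        raise InputError("stack is empty")
    idx = stack.central_index()
    factor = upsample_factor if upsample_factor is not None else _upsample_factor(stack)
    amp = np.sqrt(stack.images[idx])
    up = bilinear_upsample(amp, factor)
    field0 = up * np.exp(1j * cfg.init_phase)
    return SpectrumEstimate(spectrum=fourier.spectrum(field0), round=0, last_led=idx)


def _upsample_factor(stack: LowResStack) -> int:
    optics = stack.meta.get("optics")
    if optics is not None:
        return int(optics.upsample_factor)
    return 1


def forward_lowres_estimate(
    est: SpectrumEstimate, ctf: PupilCTF, k_n: np.ndarray
) -> np.ndarray:
    """Low-resolution complex field g = F⁻¹{O(k)·H(k+k_n)} on the sensor grid."""
    if ctf.side > est.side:
        raise InputError(
            f"ctf side {ctf.side} exceeds spectrum side {est.side}"
        )
    shift = fourier.integer_shift(np.asarray(k_n, dtype=float), ctf.dk)
    return fourier.extract_lowres_field(est.spectrum, ctf.mask, shift)


def replace_amplitude(g: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """Spatial-domain projection: keep the phase of g, impose √I as amplitude."""
    if g.shape != measured.shape:
        raise InputError(f"shape mismatch: {g.shape} vs {measured.shape}")
    if np.any(measured < 0):
        raise InputError("measured intensities must be nonnegative")
    mag = np.abs(g)
    phasor = np.where(mag > ZERO_AMP, g / np.where(mag > ZERO_AMP, mag, 1.0), 1.0)
    return np.sqrt(measured) * phasor


def update_subspectrum(
    est: SpectrumEstimate, g_bar: np.ndarray, ctf: PupilCTF, k_n: np.ndarray
) -> SpectrumEstimate:
    """Frequency-domain projection: write F{ḡ} into the shifted pupil support.

    Pixels outside H(k + k_n) are left bit-identical (the update is local to
    the sub-aperture).  Mutates and returns ``est``.
    """
    shift = fourier.integer_shift(np.asarray(k_n, dtype=float), ctf.dk)
    fourier.embed_sensor_spectrum(est.spectrum, g_bar, ctf.mask, shift)
    return est


def sweep(
    est: SpectrumEstimate,
    stack: LowResStack,
    ctf: PupilCTF,
    order: np.ndarray,
    *,
    use_estimate_phase: bool = True,
    amplitude_mode: str = "sqrt",
) -> float:
    """One pass over all LEDs; returns the mean relative amplitude mismatch.

    With ``use_estimate_phase=True`` this is one full alternating-projection
    round.  With ``False`` the measured amplitude replaces the sub-spectrum
    directly (zero phase), the single-pass synthesis used to build the
    network input; ``amplitude_mode`` then selects √I (``"sqrt"``) or the
    raw intensity (``"literal"``) as that amplitude.
    """
    if amplitude_mode not in ("sqrt", "literal"):
        raise InputError(f"unknown amplitude_mode {amplitude_mode!r}")
    residuals = []
    for n in order:
        k_n = stack.wave_vectors[n]
        measured = stack.images[n]
        target = np.sqrt(measured) if amplitude_mode == "sqrt" else measured
        if use_estimate_phase:
            g = forward_lowres_estimate(est, ctf, k_n)
            norm = np.linalg.norm(target)
            mismatch = np.linalg.norm(np.abs(g) - target) ** 2
            residuals.append(mismatch / norm**2 if norm > 0 else 0.0)
            g_bar = replace_amplitude(g, measured)
        else:
            g_bar = target.astype(complex)
        update_subspectrum(est, g_bar, ctf, k_n)
        est.last_led = int(n)
    return float(np.mean(residuals)) if residuals else 0.0


def run_gs(
    stack: LowResStack, ctf: PupilCTF, cfg: GSConfig = GSConfig()
) -> tuple[ComplexField, list]:
    """Full reconstruction: returns the recovered complex field and the
    per-round residual history (mean relative amplitude mismatch).

    Stops after ``max_rounds`` sweeps, or earlier when the relative
    Frobenius change of the spectrum between rounds falls below
    ``convergence_tol`` (if positive).
    """
    if stack.n_led == 0:
        raise InputError("stack is empty")
    est = initialize_spectrum(stack, ctf, cfg)
    if cfg.led_order == "center_out":
        order = led_sweep_order(stack.wave_vectors)
    else:
        order = np.arange(stack.n_led)
    for i in range(cfg.max_rounds):
        prev = est.spectrum.copy() if cfg.convergence_tol > 0 else None
        res = sweep(est, stack, ctf, order, use_estimate_phase=True)
        est.round = i + 1
        est.residual_history.append(res)
        if prev is not None:
            denom = np.linalg.norm(prev)
            change = np.linalg.norm(est.spectrum - prev) / denom if denom > 0 else 0.0
            if change < cfg.convergence_tol:
                break
    optics = stack.meta.get("optics")
    pixel = optics.object_pixel_um if optics is not None else 1.0
    values = fourier.field(est.spectrum)
    return ComplexField(values=values, pixel_um=pixel), list(est.residual_history)
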