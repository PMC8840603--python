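"""Single-pass Fourier-domain fusion of a low-resolution stack.

Instead of feeding the network all N_LED raw images, the whole stack is
collapsed into one complex amplitude by a single, non-iterative pass over
the sub-apertures: starting from the normal-incidence initialisation, each
measured image's spectrum overwrites the region of the object spectrum
selected by its shifted pupil,

    O_n(k) = F{a_n(r)} · H(k + k_n) + O_{n−1}(k) · [1 − H(k + k_n)],

and the result is inverse-transformed, o(r) = F⁻¹{O_LED(k)}.  Its intensity
and phase become the two input channels of the reconstruction network — a
representation whose channel count is independent of the number of LEDs.

The measured amplitude a_n is √I_n by default (consistent with the
amplitude-replacement projection of the iterative reconstruction); the raw
intensity can be substituted with ``amplitude_mode="literal"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fourier
from .errors import InputError
from .forward import LowResStack
from .optics import OpticalConfig, PupilCTF, led_sweep_order
from .recon import GSConfig, initialize_spectrum, sweep

__all__ = ["DualChannelInput", "synthesize_input"]


@dataclass
class DualChannelInput:
    """The network input/output representation: an intensity channel
    |o(r)|² and a phase channel angle(o(r)) wrapped to (−π, π]."""

    intensity: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.intensity.shape != self.phase.shape:
            raise InputError(
                f"channel shapes differ: {self.intensity.shape} vs {self.phase.shape}"
            )

    @property
    def side(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return 2

    def stacked(self) -> np.ndarray:
        """(2, side, side) array: channel 0 intensity, channel 1 phase."""
        return np.stack([self.intensity, self.phase], axis=0)

    @classmethod
    def from_stacked(cls, arr: np.ndarray) -> "DualChannelInput":
        if arr.shape[0] != 2:
            raise InputError(f"expected 2 channels, got {arr.shape[0]}")
        return cls(intensity=arr[0], phase=arr[1])

    @classmethod
    def from_complex(cls, values: np.ndarray) -> "DualChannelInput":
        return cls(intensity=np.abs(values) ** 2, phase=np.angle(values))


def synthesize_input(
    stack: LowResStack,
    ctf: PupilCTF,
    optics: OpticalConfig,
    *,
    amplitude_mode: str = "sqrt",
    led_order: str = "center_out",
) -> DualChannelInput:
    """Fuse a whole stack into a dual-channel image in one pass.

    Exactly one sub-spectrum update is applied per LED (the pass shares the
    sweep kernel of the iterative reconstruction, with the phase-projection
    step disabled).  Output side = ``upsample_factor`` × sensor side.
    """
    if stack.n_led == 0:
        raise InputError("stack is empty")
    cfg = GSConfig(max_rounds=1, led_order=led_order)
    est = initialize_spectrum(stack, ctf, cfg, upsample_factor=int(optics.upsample_factor))
    if led_order == "center_out":
        order = led_sweep_order(stack.wave_vectors)
    else:
        order = np.arange(stack.n_led)
    sweep(est, stack, ctf, order, use_estimate_phase=False, amplitude_mode=amplitude_mode)
    o = fourier.field(est.spectrum)
    return DualChannelInput.from_complex(o)
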