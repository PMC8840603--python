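"""Independent brute-force oracles used by the test suite.

Everything here is written as explicit sums/loops, deliberately avoiding
the library's FFT-based code paths, so agreement is a genuine
cross-check rather than a tautology.
"""

import numpy as np

from fpmkit import compute_wave_vectors, make_ctf
from fpmkit.fourier import integer_shift


def dft_centered(values: np.ndarray) -> np.ndarray:
    """Centred spectrum by explicit double-loop discrete Fourier sums."""
    n = values.shape[0]
    out = np.zeros((n, n), dtype=complex)
    xs = np.arange(n)
    for pi in range(n):
        for qi in range(n):
            p, q = pi - n // 2, qi - n // 2
            phase = np.exp(-2j * np.pi * (p * xs[:, None] + q * xs[None, :]) / n)
            out[pi, qi] = np.sum(values * phase)
    return out


def idft_centered(spec: np.ndarray) -> np.ndarray:
    """Spatial field of a centred spectrum by explicit sums."""
    n = spec.shape[0]
    out = np.zeros((n, n), dtype=complex)
    ps = np.arange(n) - n // 2
    for x in range(n):
        for y in range(n):
            phase = np.exp(2j * np.pi * (ps[:, None] * x + ps[None, :] * y) / n)
            out[x, y] = np.sum(spec * phase) / n**2
    return out


def lowres_field_oracle(sample_values, optics, k_n):
    """One illumination's sensor field by brute force: explicit DFT of the
    object, sensor-window crop at the integer pupil shift, pupil mask,
    explicit inverse DFT, amplitude-preserving (n/N)² scale."""
    N = sample_values.shape[0]
    n = N // int(optics.upsample_factor)
    ctf = make_ctf(optics, n)
    O = dft_centered(sample_values)
    sx, sy = integer_shift(np.asarray(k_n, dtype=float), ctf.dk)
    c, half = N // 2, n // 2
    win = O[c + sy - half : c + sy - half + n, c + sx - half : c + sx - half + n] * ctf.mask
    return idft_centered(win) * (n / N) ** 2


def capture_oracle(sample, optics, grid):
    """Full brute-force acquisition: one intensity image per LED."""
    kvecs = compute_wave_vectors(grid, optics.wavelength)
    return np.array(
        [np.abs(lowres_field_oracle(sample.values, optics, k)) ** 2 for k in kvecs]
    )


def mse_oracle(a, b):
    """Per-pixel double-loop mean squared error."""
    m, n = a.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += abs(a[i, j] - b[i, j]) ** 2
    return total / (m * n)


def psnr_oracle(a, b, max_i):
    return 20.0 * np.log10(max_i / np.sqrt(mse_oracle(a, b)))


def ssim_oracle(a, b, l):
    """Component-wise recomputation: luminance × contrast × structure with
    C3 = C2/2, whole-image population statistics."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    npix = a.size
    mu_x = a.sum() / npix
    mu_y = b.sum() / npix
    var_x = ((a - mu_x) ** 2).sum() / npix
    var_y = ((b - mu_y) ** 2).sum() / npix
    cov = ((a - mu_x) * (b - mu_y)).sum() / npix
    c1 = (0.01 * l) ** 2
    c2 = (0.03 * l) ** 2
    c3 = c2 / 2.0
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    struc = (cov + c3) / (sd_x * sd_y + c3)
    return lum * con * struc
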