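# fpmkit

A toolkit for **Fourier ptychographic microscopy (FPM)**: simulation of
multi-angle LED-illuminated acquisition, high-resolution complex-amplitude
recovery by alternating-projection phase retrieval, synthetic training-set
construction, whole-image quality metrics, and a toy-scale multi-feature
fusion reconstruction network.

FPM trades acquisition time for resolution: a programmable LED array
illuminates the sample from many angles, each tilted plane wave shifting a
different region of the object spectrum O(k) into the objective's pupil
H(k) — an ideal binary disk of radius NA·2π/λ.  The sensor records only
intensities,

&nbsp;&nbsp;&nbsp;&nbsp;I_n(r) = | F⁻¹{ O(k) · H(k + k_n) } |²,&nbsp;&nbsp;&nbsp;&nbsp;k_n = 2π (sin α_xn, sin α_yn)/λ,

and the reconstruction stitches the sub-apertures back together by
alternating projections (Gerchberg–Saxton): keep the estimated phase,
impose the measured amplitude √I_n in the spatial domain, and write the
result back into the pupil-selected sub-spectrum,

&nbsp;&nbsp;&nbsp;&nbsp;O(k) ← O(k)·[1 − H(k+k_n)] + F{ √I_n · g_n/|g_n| }·H(k+k_n).

For learned reconstruction, the whole stack is also collapsed by a single
non-iterative pass of the same sub-spectrum update into one complex image
o(r), whose intensity and phase form a **dual-channel input** whose size is
independent of the LED count.  A small network (three parallel extractors
carrying residual skips, channel attention and dense connectivity; cascade
feature fusion by channel concatenation; a convolution + pixel-shuffle
upsampling head) maps that input to the high-resolution intensity and
phase.  Quality is scored with MSE, PSNR = 20 log₁₀(MAX_I/√MSE) and a
whole-image SSIM with C1 = (0.01 L)², C2 = (0.03 L)², C3 = C2/2.

The package is aimed at computational-imaging researchers who want a
self-contained, deterministic sandbox for FPM reconstruction experiments —
no microscope, GPU, or external data required.

## Worked example

```python
import numpy as np
from fpmkit import (OpticalConfig, LEDGrid, simulate_capture, make_ctf,
                    run_gs, GSConfig, synthesize_input)
from fpmkit.dataset import generate_synthetic_sources, build_truth_pairs
from fpmkit.metrics import evaluate_pair
from fpmkit.recon import bilinear_upsample

optics = OpticalConfig()              # NA 0.13, wavelength 0.505 um, 4x decimation
grid = LEDGrid()                      # 13x13 LEDs, 4 mm pitch, 90 mm below sample
src = generate_synthetic_sources(2, 192, seed=1)
sample, _ = build_truth_pairs(src, 1, seed=1, pixel_um=optics.object_pixel_um)
sample = sample[0]                    # a 192x192 complex amplitude

stack = simulate_capture(sample, optics, grid)
print(f"{stack.n_led} captures of {stack.side}x{stack.side} px")

ctf = make_ctf(optics, stack.side)
recon, residuals = run_gs(stack, ctf, GSConfig(max_rounds=50))
report = evaluate_pair(recon.intensity, sample.intensity, max_i=1.0)
base = bilinear_upsample(stack.images[stack.central_index()], 4)
base_psnr = evaluate_pair(base, sample.intensity, max_i=1.0).psnr
print(f"intensity PSNR {report.psnr:.2f} dB (bilinear baseline {base_psnr:.2f} dB)")
print(f"intensity SSIM {report.ssim:.4f}; final residual {residuals[-1]:.2e}")

dual = synthesize_input(stack, ctf, optics)
print(f"network input: {dual.n_channels} channels of {dual.side}x{dual.side} px")
```

Output:

```
169 captures of 48x48 px
intensity PSNR 34.46 dB (bilinear baseline 21.30 dB)
intensity SSIM 0.9880; final residual 2.11e-29
network input: 2 channels of 192x192 px
```

The 13×13 array produces 169 low-resolution images; fifty reconstruction
rounds raise the intensity PSNR about 13 dB above the bilinear upsample of
the on-axis capture, with the data-mismatch residual driven to numerical
zero on noise-free data.

## Command line

```bash
fpmkit simulate --amplitude a.png --phase p.png --out stack.h5
fpmkit reconstruct gs --stack stack.h5 --rounds 50 --out recon.h5
fpmkit synthesize-input --stack stack.h5 --out input.h5
fpmkit build-dataset --config cfg.yaml --out dataset/
fpmkit evaluate --pred recon.h5 --truth truth.h5 --out report.json
fpmkit demo --seed 1         # closed-loop simulate -> reconstruct -> score
```

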