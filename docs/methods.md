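# Methods

## Imaging model

The sample is a complex transmission function o(x, y) on a square grid of
pitch `object_pixel_um` (default 0.275 µm).  Illumination by the LED at
lateral offset (dx, dy) and height h is a tilted plane wave with
transverse wave vector k_n = 2π·(sin α_x, sin α_y)/λ, with direction
sines −(dx, dy)/√(dx² + dy² + h²) — the angular-wavenumber convention is
used throughout, so the pupil cutoff NA·2π/λ and the illumination shifts
live in one unit system (rad/µm).  The objective is an ideal coherent
low-pass: a binary disk H(k) of radius NA·2π/λ, no aberrations.  The
sensor grid is decimated by the integer `upsample_factor` (default 4), so
object and sensor grids share one frequency step Δk = 2π/(N·pitch); each
acquisition crops the sensor-sized window of the centred object spectrum
at the integer-pixel offset round(k_n/Δk), masks it with the pupil, and
records the squared modulus of the inverse transform.  Sub-pixel shift
residuals are discarded — the standard discretisation when all
sub-apertures live on a shared frequency grid.

**Spectral scaling.**  Spectra use the unnormalised FFT; the window-crop
inverse transform carries an explicit (n/N)² factor, and the reverse
embedding (N/n)².  This makes the pair amplitude-preserving — a unit
transmission object yields a unit-amplitude on-axis capture — and an exact
projector (embed ∘ extract = identity on the pupil support).  Under this
convention the initialisation needs no extra energy factor, and all
Parseval checks in the test suite carry the normalisation explicitly.

**Default geometry.**  LED pitch 4 mm and height 90 mm are plumbing
defaults chosen so a 13×13 array stays far below grazing incidence and
its outermost pupil window (≈ 37 px offset + 24 px half-window at the
192-pixel scale) stays inside the high-resolution spectrum.  The default
object pixel of 0.275 µm keeps the pupil cutoff below the sensor Nyquist
bound with ≈ 80 % overlap between adjacent sub-apertures.  Neither pitch
nor height is claimed to match any particular instrument; both are config
fields.

**Noise.**  Sensor noise is additive i.i.d. zero-mean Gaussian on
intensities, with σ quoted on a peak-normalised scale (the stack maximum
maps to 1), so the conventional levels 1e-4–3e-4 are meaningful whatever
the simulation's raw intensity scale; negative results are clipped to
zero.  σ = 0 is an exact no-op.  Shot noise and quantisation are out of
scope.

## Alternating-projection reconstruction

Initial guess: the on-axis image's amplitude √I, bilinearly enlarged to
the high-resolution grid with flat phase φ0 = 0, transformed.  Each sweep
visits every LED once, centre-outward by |k_n| (ties broken by raster
index) — low-frequency-first is the standard choice, writing the
well-constrained spectrum centre before the outer sub-apertures; a raster
order is available.  Per LED: forward-project to the sensor plane, replace
the amplitude with √I keeping the phase (pixels with |g| < 1e-12 get a
unit phasor — any phasor is admissible on a measure-zero set), transform
back, and overwrite only the pupil-selected sub-spectrum.  The default
budget is 50 sweeps; an optional early stop triggers when the relative
Frobenius change of the spectrum between sweeps falls below
`convergence_tol` (0 = disabled, since the fixed-round budget is the
customary protocol).  The logged residual is the mean over LEDs of
‖|g_n| − √I_n‖²/‖√I_n‖², recorded per sweep before the update; it is
diagnostic, not an objective being minimised, but is non-increasing on
noise-free data in practice and the closed-loop tests assert that.

Phase retrieval recovers the field up to a global phase factor; tests that
compare reconstructed and true spectra first align this factor.

## Dual-channel input synthesis

One non-iterative pass over the stack: starting from the same
initialisation, the measured amplitude (√I_n by default) directly
replaces each pupil-selected sub-spectrum — exactly one update per LED —
and the result is inverse-transformed into a complex image whose
intensity and phase become the two network channels.  The synthesis and
the iterative reconstruction share one sweep kernel; the only difference
is that the synthesis skips the phase-keeping projection.  An
`amplitude_mode="literal"` switch substitutes the raw intensity I_n for
√I_n, for comparison with the formulation that transforms intensities
directly; the square-root mode is the default because it is the one
consistent with the amplitude-replacement projection and with the
measured image being an intensity.

## Dataset construction

Ground truths pair source images randomly: each of the `n_sources`
grayscale images (default 400) serves as an amplitude map and is paired
with `pairing_multiplicity` (default 4) distinct phase sources, drawn
without replacement per amplitude so no (amplitude, phase) tuple repeats;
phase maps are scaled into [−π/2, π/2] by default.  Each truth field is
simulated, noise is added to the low-resolution intensities *before*
synthesis (matching where noise arises physically), and
`crops_per_pair` (default 16) aligned random crops of input and truth
(default 192 px from 256-px fields) become examples.  A seeded shuffle
then a contiguous cut yields round(0.9·N) training examples —
at the reference scale 400 → 1,600 → 25,600 → 23,040/2,560.

The builder separates the *manifest* — pairing, crop offsets, per-pair
noise seeds, split labels, all counts, byte-reproducible from the seed —
from *materialisation* of pixel data, so full-scale count algebra is
verifiable in seconds while rendering is done only for the pairs
requested.

**Synthetic sources.**  The procedural generator emulates the multi-scale
statistics of stained-tissue micrographs: three scales of low-pass
Gaussian noise plus soft-thresholded blob boundaries, stretched to [0, 1].
It does **not** emulate real tissue morphology, staining variability,
illumination falloff, or camera artefacts — passing tests therefore
demonstrate correctness of the pipeline and recoverability under the
stated model, not performance on real micrographs.  The fine-tune loader
ingests externally acquired pairs in the same HDF5 layout without any
generation, and a seeded interleaver mixes them into the simulated set.

## Quality metrics

MSE, PSNR = 20·log₁₀(MAX_I/√MSE) (identical images report an `inf`
sentinel), and SSIM from whole-image statistics with C1 = (0.01 L)²,
C2 = (0.03 L)², C3 = C2/2; variances and covariance are population
statistics (divide by pixel count), consistent with the plain-mean μ.
Dynamic range is inferred from dtype (255 for 8-bit, 1.0 for floats) and
overridable.  The three-factor luminance·contrast·structure product with
C3 = C2/2 is algebraically identical to the simplified two-factor form;
the suite asserts this to 1e-12.  A Gaussian-windowed local-SSIM variant
is available behind a flag for comparison with common practice; the
global form is the default.  Phase channels are scored as plain images on
their wrapped values — no unwrapping, so a reconstruction that differs by
a phase wrap scores poorly by design.

## Reconstruction network

The toy-scale model maps a 2-channel S×S input to a 2-channel S×S output
for any even S.  Three parallel stride-2 extractors each embody one
signature mechanism — residual skip, channel-attention gating
(global average pool → 1×1 convolution → sigmoid), and dense
connectivity — standing in for truncated pretrained backbones, which
would require an optional deep-learning framework (requesting them raises
a capability error rather than silently substituting).  Cascade feature
fusion is plain channel concatenation in branch order, so the fused
channel count is the sum of the branch counts and every value is
conserved; the printed index-interleaving of the fusion formula assigns
conflicting destinations across consecutive channels, so the
channel-sum statement is taken as authoritative.  The head is one
convolution + pixel-recombination stage per factor of 2 of extractor
downsampling (here one stage), each rearranging 4-channel groups into
2×2 spatial blocks, followed by a final convolution and a global residual
skip from the input — the standard arrangement in super-resolution heads,
which also makes tiny-data optimisation well-conditioned.

Training minimises MSE with an adaptive-moment (Adam) optimiser; the
default configuration is learning rate 4e-5, batch 4.  The whole stack
(convolutions, activations, attention, shuffle, loss) is NumPy with
hand-written reverse-mode gradients, verified against central finite
differences; everything is deterministic under a fixed seed.  Paper-scale
training (tens of thousands of examples, hundreds of epochs) is a
non-goal: the trainer targets smoke tests (32 examples × 20 epochs at
learning rate 1e-3) and a single-example overfit oracle (200 steps at
1e-2–5e-3, reaching ~1e-4 per-pixel MSE), with divergence reported via an
exception carrying the last finite-loss parameters.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full reference-scale
closed loop (192×192 scene, 169 LEDs, 50 sweeps — a few seconds) but keep
brute-force DFT oracles at 16×16/8×8 grids, dataset materialisation at a
handful of pairs (the full-scale build is exercised at the manifest
level, where every count is exact), and network training at 16×16
examples; these sizes were chosen as the smallest that exercise every
code path with non-trivial pupil shifts.  Key tolerances: DFT-oracle
agreement 1e-8 relative; projector idempotence 1e-10; metric oracles
1e-10 absolute; factor-form equivalence 1e-12; reconstruction support
error 1e-3 after 50 sweeps.  Degenerate inputs are defined rather than
left to chance: empty pupil masks update nothing, zero-amplitude pixels
take a unit phasor, σ = 0 noise is a bit-exact copy, and an empty stack
is an input error.

## Known limitations

Ideal binary pupil only — no aberration estimation, LED miscalibration,
or multiplexed illumination; integer-pixel sub-aperture placement; no
phase unwrapping in scoring; the network is deliberately tiny and CPU
bound, and no claim is made that its toy-scale results transfer to
pretrained-backbone performance on real acquisitions.
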