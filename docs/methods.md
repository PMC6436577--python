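# Methods

`nsctfuse` fuses a pseudo-colored functional brain image (SPECT-like) with
a grayscale anatomical image (CT-like).  The design goal is to keep the
functional image's color (where physiology is encoded) while importing the
anatomical image's spatial detail.  This note records the model, every
tunable that matters, the numerical conventions, and what the synthetic
phantoms do and do not establish.

## Pipeline

1. **IHS decomposition.** The RGB functional image is mapped to intensity,
   hue and saturation with the *linear triangular* model

       I  = (R + G + B) / 3
       v1 = (2B − R − G) / √18,   v2 = (R − G) / √2
       H  = atan2(v2, v1),        S = √(v1² + v2²)

   chosen because it has an exact linear inverse, so fusing only `I` and
   inverting provably leaves H and S untouched.  H is fixed at 0 on the
   gray axis (S = 0), and the forward transform is evaluated elementwise
   rather than as a matrix product so that R = G = B cancels exactly in
   floating point.  After intensity substitution the inverse can leave the
   RGB gamut; overflowing samples are clipped to [0, 1] and counted
   (rescaling instead would shift hue balance globally).

2. **NSCT.** Both `I` and the (unit-rescaled) anatomical image are
   decomposed by a non-subsampled contourlet transform: an à-trous pyramid
   (kernels dilated by `2^(j−1)` at level `j`, no decimation) followed by a
   binary tree of fan/wedge filters splitting each level's highpass into
   `2^n_j` orientation bands.  Every band keeps full image size, which makes
   the transform shift-invariant in the interior and lets sub-band fusion
   operate pixel-for-pixel.

   *Filters.* The built-in family uses the separable cubic-B-spline 5×5
   lowpass (maximally flat, DC gain 1) with the complementary highpass
   `H2 = δ − H1`, identity synthesis kernels, and frequency-sampled,
   Hann-windowed 21×21 wedge filters (fan pair at stage 1) with
   complementary siblings at every tree node.  Because convolution is
   linear in the kernel, `x = (x∗H1) + (x∗(δ−H1))` holds for any boundary
   handling, so perfect reconstruction is exact to rounding *including
   borders* — round-trip error is ~1e−15, far inside the 1e−6 contract —
   and both filter-bank identities hold to machine precision.  Wedge
   filters are approximate in frequency (energy of an axis-aligned
   sinusoid concentrates >80 %, not 100 %, in the matching bands); that
   affects only how cleanly orientations separate, never invertibility.
   Boundary handling is symmetric (mirror) extension everywhere.

   *Defaults.* 3 pyramid levels with direction exponents (2, 3, 3), i.e.
   4/8/8 bands — deep enough to separate coarse anatomy from fine edges at
   128×128 while keeping 2^J well below the image size.

3. **PCNN sub-band selection.** Each sub-band pair is fused by comparing
   per-pixel firing counts of a simplified pulse-coupled neural network run
   on each band's normalized magnitude (|coefficient|, min-max mapped to
   [0, 1]; magnitude because high-frequency coefficients are signed):

       L[n] = W ⊛ Y[n−1]
       U[n] = S · (1 + β·L[n])
       Y[n] = 1  iff  U[n] > e^(−αθ)·θ[n−1]      (strict)
       θ[n] = e^(−αθ)·θ[n−1] + Vθ·Y[n]

   with `Y[0] = θ[0] = 0`, so every stimulated neuron fires at n = 1.  The
   threshold decays *before* the comparison at step n; ties do not fire.
   The simplified model (no feeding leak, unit feeding gain, one linking
   compartment) exposes exactly the three optimized scalars — threshold
   decay `αθ`, linking strength `β`, threshold amplification `Vθ` — plus
   two structural choices: the linking kernel `W` (3×3 inverse Euclidean
   distances, zero center) and the iteration count `T` (library default
   100; the worked examples use 20–30, which is enough to separate firing
   counts at 8-bit contrast).  The per-pixel cumulative count over `T`
   iterations is the activity measure; the fused coefficient is taken from
   the band with the strictly larger count, ties averaging the two
   coefficients (symmetric, and it makes self-fusion an exact identity).

4. **Parameter search.** The three PCNN scalars are tuned per band by the
   shuffled frog-leaping algorithm: uniform population in the box
   `αθ ∈ [0.01, 1]`, `β ∈ [0, 1]`, `Vθ ∈ [1, 50]` (typical operating
   ranges for the simplified model), sorted, dealt round-robin into
   memeplexes; each memeplex repeatedly leaps its worst frog toward the
   memeplex best by `S = rand·(P_b − P_w)` clamped per coordinate to
   ±S_max (default: half the box width), retrying toward the global best
   and finally replacing the worst frog with a fresh random one; after N
   steps per memeplex the population is shuffled.  Out-of-bounds
   candidates are rejected (triggering the cascade), not clipped.  The
   random leap factor is drawn **per coordinate** by default: with one
   scalar factor every leap is collinear with `P_b − P_w`, and on the
   sphere benchmark that measurably causes premature convergence (23/30
   seeds reach 1e−2 of the optimum versus 29/30 per-coordinate at the same
   budget).  The scalar reading, which matches the update rule's scalar
   notation, remains available via `per_coordinate_rand=False`.

   *Fitness.* The optimized objective is the information entropy of the
   fused band linearly remapped to 8 bits.  Entropy is the most defensible
   reading of an otherwise open choice — it is the headline metric the
   method is expected to improve — and it is what the shipped comparison
   actually shows the tuned method winning.  `mean_gradient` and an
   equal-weight normalized blend (`0.5·E/8 + 0.5·Ḡ/255`) are selectable.
   Optimization runs per band by default (seeds per band derived from one
   `SeedSequence`, so runs are reproducible); a single shared optimization
   over the mean band fitness is available by config.

   *Budgets.* Library default F=10 frogs, m=2 memeplexes, N=5 local steps,
   5 shuffles — a desk-scale budget (≈160 fitness evaluations per band)
   that reliably dominates fixed parameters; population sizes used in the
   original experiments were never reported, so this is a deliberate
   small-but-sufficient choice, fully exposed in config.

5. **Baselines.** `ihs` (replace I by the anatomical image outright),
   `nsct_fl` (max-|coefficient| high bands, averaged low band), `dwt`
   (2-level orthonormal Haar with the same max/average rule; Haar is
   hand-rolled because no wavelet library is available in the target
   environment, and its reconstruction is exact), and `nsct_pcnn` (the
   same selection rule with fixed parameters αθ=0.3, β=0.2, Vθ=20 —
   mid-box values).  With `inject_fixed_params=True` the fixed triple is
   seeded into every band's initial population, which guarantees the tuned
   method's band fitness is ≥ the fixed baseline's (optimizer dominance).

   A conclusion-style variant that fuses the low band by 3×3 regional
   average energy instead of the tuned PCNN ships behind
   `low_rule="regional_energy"`, since the source description of the
   low-band rule is self-contradictory; the default follows the stepwise
   algorithm (tuned PCNN for all bands).

## Quality metrics

All four are no-reference statistics on the 8-bit gray scale; color
images are scored on the IHS intensity plane (the plane fusion actually
modifies).  SD is the population standard deviation; the mean gradient
averages `√((Δx²+Δy²)/2)` of forward differences on the (M−1)×(N−1)
interior grid; spatial frequency is `√(RF²+CF²)` with RF/CF the RMS row
and column first differences normalized by M·N; entropy is Shannon
entropy (base 2, L=256 bins), with 8-bit images binned on their own scale
and raw float bands min-max remapped.  Note the mean gradient as defined
is *not* invariant under 180° flips (the forward-difference grid is
cropped asymmetrically); it is invariant under transposition.

## Synthetic phantoms

The generator emulates just the features the pipeline exercises: the
CT-like phantom has a bright skull annulus (≈230), a weakly textured
mid-gray interior (Gaussian-smoothed noise, σ_texture = 8 gray levels) and
a dark background — sharp bone edges, high mean gradient; the SPECT-like
phantom has 1–n smooth Gaussian activity blobs inside the same head mask,
rendered through a fixed hot-iron colormap (black→red→yellow→white), black
outside the mask.  Default: 128×128, 3 blobs, blob σ = 0.08·size, additive
noise SD 2 gray levels (mild detector noise); all randomness flows from
one `SeedSequence`, with separate streams for the two modalities.

What the phantoms do **not** emulate: anatomically realistic cortex,
partial-volume effects, attenuation artifacts, registration error, or the
Harvard atlas images the original experiments used.  A green phantom test
therefore establishes algorithmic correctness (invertibility, selection
logic, optimizer dominance, determinism) — not clinical image quality, and
not the published per-image metric tables, which additionally depend on
filter/level/parameter choices that were never published.

## Numerical conventions and degenerate inputs

- Constant images: `normalize_intensity` maps them to all zeros; their
  entropy/SD/gradients are 0; a constant stimulus fires periodically and
  uniformly.
- Strict inequalities everywhere a tie is possible (PCNN firing, firing
  count comparison, fitness improvement), with explicit tie policies.
- 16-bit inputs are linearly rescaled to 8 bits on load; registration is
  validated (exact shape match) but never performed.
- All tolerances asserted in tests: NSCT round trip < 1e−6 (measured
  ~1e−15), filter identities < 1e−8 (measured ~4e−16), IHS round trip
  < 1e−9, self-fusion end-to-end < 1e−5.

## Known limitations

- Wedge filters trade frequency sharpness for a 21×21 support; very small
  images (< 32 px) get weak directional separation.
- Per-band SFLA at the default budget costs ~160 PCNN-pair evaluations per
  band; at 128×128 with the (2,3,3) spec a full run takes tens of seconds
  on one CPU.  Use `granularity="shared"`, a smaller NSCT spec, or lower
  `T` for interactive work.
- Only PNG/TIFF I/O; DICOM and clinical workflow handling are out of scope.
- Two-image fusion only; the method is modality-agnostic but is only
  validated here on SPECT/CT-like phantoms.
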