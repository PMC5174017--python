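# Methods

## Pipeline and assumptions

The codec assumes a volumetric grayscale image: S same-sized slices of
R×C integer voxels, 8–16 bits deep, with substantial inter-slice
correlation and smooth spatial structure. Codec geometry is restricted to
square power-of-two slices (R = C) and a power-of-two slice count; the
default study geometry is S = 8 slices of 128×128 at 8 bits.

Stages, in encoding order:

1. **Spectral KLT.** Per-slice means are removed; the S×S inter-slice
   sample covariance is eigendecomposed and the volume is projected onto
   the eigenbasis, ordered by descending eigenvalue. The transform order —
   KLT across slices first, then a 2D wavelet per decorrelated component —
   makes each component an ordinary 2D pyramid, which is what the 1D
   arrangement expects. Eigenvector sign is pinned (largest-magnitude entry
   nonnegative) so coefficient arrays, and therefore bitstreams, are
   reproducible across runs and LAPACK builds. For S = 1 the stage is the
   identity with zero mean. A rank-deficient covariance (e.g. identical
   slices) is not an error: `eigh` completes the basis deterministically
   and trailing eigenvalues clamp to 0.

2. **Spatial DWT.** Separable lifting with whole-sample symmetric
   boundary extension, L levels (default 5 at 128×128). Two filters:
   - `cdf97`: the 9/7 four-step lifting factorization with scaling
     ζ = 1.1496044, giving the lowpass branch a DC gain of ~√2 per level
     (near-orthonormal, so bit-plane significance order tracks MSE
     relevance). Round-trip error is float-level (< 1e-6 observed bound,
     asserted in tests).
   - `cdf53`: the reversible integer 5/3 lifting (floor-rounded steps);
     exact on integer input. Both kernels are implemented here because no
     installed wavelet library exposes a reversible integer path or a
     lifting API with this boundary handling; the cdf97 kernel is
     cross-checked in the tests against PyWavelets' bior4.4 analysis on
     smooth input.

3. **Quantization.** Coefficients are scaled by 2^qscale and rounded half
   away from zero. Defaults: qscale 4 for cdf97 (transform-domain
   quantization error ≤ 2⁻⁵, far below the 8-bit voxel rounding threshold;
   > 55 dB reconstruction PSNR asserted on fixtures), qscale 0 for cdf53.
   "Lossless" therefore means lossless with respect to the integer
   coefficient array; true voxel-lossless holds on the cdf53 path when the
   KLT stage is the identity (S = 1). This is a documented limitation: the
   float KLT is inherently lossy at finite precision for S > 1.

4. **1D arrangement.** Combined coarsest block (all LL_L squares, slice
   order), then combined detail levels coarsest→finest; inside a combined
   level, slice 1..S each contribute HL, LH, HH in that order; inside a
   subband, Morton order with column bits in the even positions of the
   rank (quadrant order TL, TR, BL, BR). Morton order is what makes every
   aligned 4^v block contiguous, which the quad split requires. The
   interleaving (slices contiguous within a level, subbands inside) is the
   one consistent with the arithmetic of the reference leading-index
   tables; tests pin all 48 per-slice leaders at (8, 128, 128, 5).

5. **Listless coder.** Static marker m of the combined coarsest block is
   log2(C) − L + 1; detail level ℓ carries m = log2(C) − ℓ + 2 (range
   3..8 at the reference geometry). Non-leader positions hold the sentinel
   log2(C) + 2, which both satisfies the "initialize Dm above the largest
   marker" rule and fits 4 bits for any C ≤ 8192. Coefficient statuses
   INC/NSC/SCR live in a parallel 2-bit field rather than overloaded Dm
   values, keeping every transition separately testable. The static table
   stores one marker per per-slice leading index — 8(L+1) = 48 entries at
   the reference geometry. (Different counts circulate for this table:
   the 8L+1 = 41 of the analytic memory formula and a 15·3 = 45 figure;
   the package implements the 48-entry table its index lists imply and
   reports the analytic formula unchanged.)

## Coding passes and numerical choices

Per plane n = n_max .. 0 (n_max = ⌊log2 max|ξ|⌋; an all-zero array sets a
header flag and emits nothing):

- **Pass 1** tests previously exposed, still-insignificant singletons in
  index order: bit 1 + sign (0 = nonnegative) for a newly significant
  coefficient (status → NSC), else bit 0.
- **Pass 2** tests every surviving block. The significance window
  2^n ≤ |c| < 2^(n+1) is implemented with a *strict* upper bound so each
  magnitude is significant in exactly one plane; because a tested block was
  insignificant at every higher plane, the windowed test coincides with the
  usual |c| ≥ 2^n test, and the coder exploits that equivalence for speed
  (a max over the block extent). A significant block splits — octal to
  per-slice children, tri to subbands (detail levels only; coarsest
  children are already squares, so the ladder there skips the tri step),
  quad to Morton quadrants — and children are tested depth-first in index
  order within the same pass, singletons coded as in Pass 1.
- **Pass 3** emits bit n of each SCR coefficient's magnitude; NSC → SCR
  promotion happens after the pass, so a coefficient is never refined in
  its discovery plane.

The quad-split index arithmetic places children at offsets j·4^(v−1)
*after* the marker decrement; this is the only reading that reproduces the
reference leading-index tables, and it is the one implemented.

**Decoder.** One pass engine drives both directions through a
read/write adapter, so the decoder's marker trajectory is identical to the
encoder's by construction (also asserted by a twin-run test). A
coefficient discovered at plane n reconstructs at the uncertainty-interval
midpoint 1.5·2^n; each refinement bit b at plane n sets magnitude to
known + b·2^n + 2^(n−1); after plane 0 no offset remains, making the
full-budget decode exactly lossless. A sign bit cut off by the budget
leaves its coefficient uncommitted, which keeps budget-decode and
truncation-decode bit-identical.

**Rate control.** budget = round(rate_bpp · S·R·C) payload bits; the
encoder stops mid-symbol the moment the budget is hit and the stream is cut
exactly there. The header (magic, geometry, filter, qscale, n_max, the
S² + S float64 KLT sidecar, and a payload-bit count) is excluded from the
bpp accounting by default — at the default geometry it is 601 bytes, and
including it would make small-volume bpp figures uninterpretable — with a
`--count-header` flag to charge it. The explicit payload-bit count in the
header exists because byte padding would otherwise be indistinguishable
from payload and exact prefix equality would fail.

## Synthetic fixtures

Clinical test volumes are not redistributable, so fixtures are generated:

- `blobs` — randomly placed 2D Gaussian bumps whose amplitudes drift
  across slices as AR(1) with coefficient ρ (default 0.95): smooth,
  phantom-like, highly compressible.
- `correlated-noise` — spatially smoothed white noise propagated as
  slice_s = ρ·slice_{s−1} + √(1−ρ²)·innovation, giving lag-1 inter-slice
  correlation ≈ ρ (asserted within 0.05).
- `constant`, `impulse` — degenerate edge cases.

Fixtures are integer-deterministic from (model, shape, seed). They emulate
the two statistics the codec exploits — spectral correlation and spatial
smoothness — but none of the structure of real scans (anatomy, bias
fields, Rician noise, windowing). Passing tests therefore demonstrate
correctness of the coder and its scalability properties, not clinical-image
rate-distortion performance; published per-slice PSNR tables for real MRI,
knee and angiogram volumes are not reproducible without those volumes and
are not targeted.

## Evaluation

PSNR is per-slice, 10·log10(peak²/MSE) with peak = 2^bit_depth − 1,
+∞ for an identical slice; volumes are compared on stored integer pixels
as read (no DICOM windowing/rescale is applied). `rd_sweep` encodes once
at the top rate and decodes truncations, which is exact by the embedded
property. Memory models are closed-form: state table R·C/2 + (8L+1)/2
bytes; SPIHT worst-case lists [Y·(N_LIP+N_LIS+N_LSP) + N_LIS]/8 bytes with
N_LIP+N_LSP = 3RC, N_LIS = 3RC/4 — Y in *bits* of addressing there, in
*bytes* per coefficient in the total-memory formula; both parameters carry
explicit unit names in the API.

## Problem sizes and defaults

Defaults throughout: L = 5, cdf97/qscale 4, rate sweep 0.25–2.0 bpp,
8×128×128 8-bit fixtures (the study geometry). The property suites run the
coder losslessly on random arrays at (1,8,8,1), (2,16,16,2) and
(8,32,32,3) — sizes chosen so exhaustive and repeated randomized checks
stay cheap while covering every split type (S = 1 degenerate octal, multi-
slice, multi-level).

## Known limitations

- No entropy back-end: significance/sign/refinement bits are emitted raw,
  so rates are ~10–20% above what a context-coded variant would reach.
- No color/multichannel volumes, compressed DICOM transfer syntaxes,
  anisotropic resampling, ROI weighting, or random access.
- No reversible integer KLT; voxel-lossless coding of multi-slice volumes
  is out of reach of the float KLT path (see above).
- The pass engine is pure Python over numpy state; an 8×128×128 encode at
  2 bpp runs in well under a second, but throughput is far from a
  production C implementation.
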