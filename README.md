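# hlck — 3D hierarchical listless block codec for volumetric images

`hlck` compresses volumetric grayscale medical images (MRI/CT slice stacks,
DICOM series, angiogram sequences) into a single **embedded** bitstream: any
prefix of the stream decodes to a valid lower-rate reconstruction, so one
encoded file serves every target bit rate from heavy lossy preview up to the
coefficient-lossless point. That property is what progressive transmission
in telemedicine and teleradiology needs — send bits until the link or the
diagnostic-quality requirement says stop.

It is aimed at people building or studying scalable medical-image codecs:
the full coder, decoder, rate-distortion harness and deterministic synthetic
test volumes are importable as a library and drivable from a CLI.

## The method

**1. Hybrid 3D transform.** Adjacent slices of a volume are highly
correlated. A Karhunen–Loève transform along the slice (spectral) axis —
the eigenbasis of the S×S inter-slice sample covariance — decorrelates them
optimally in the MSE sense; each decorrelated component image is then
decomposed with an L-level 2D lifting wavelet (CDF 9/7 for lossy work,
integer CDF 5/3 for a reversible spatial path). Real-valued coefficients are
made bit-plane-codable by uniform scalar quantization: `round(2^q · c)`.

**2. Hierarchical 1D arrangement.** The S wavelet pyramids are mapped to
one 1D array ξ of length S·R·C: the combined coarsest block (all slices'
LL_L squares) first, then one *combined level* per decomposition level,
coarsest to finest, each holding every slice's HL/LH/HH subbands. Within a
subband, coefficients follow the Morton (Z) order, so every aligned
power-of-four block is a contiguous run of indices. For 8 slices of 128×128
with L = 5 the combined blocks start at indices 1, 129, 513, 2049, 8193,
32769 (1-based).

**3. Listless set-partitioning coder.** Instead of SPIHT/SPECK's linked
lists, the coder keeps two marker tables: a static table `Sm` at block
leading indices and one 4-bit dynamic marker `Dm[k]` per coefficient. For a
block leader with static marker m, `Dm = m` means "whole combined level —
skippable with one bit", `Dm = m−1` one slice's level, `Dm = m−2` one
subband, smaller values Morton squares of 4^v coefficients. Significance of
a block against the plane-n threshold 2^n,

    ζ_n(γ) = Σ_k [ 2^n ≤ |γ(k)| < 2^(n+1) ],   significant ⇔ ζ_n > 0,

drives octal (combined → per-slice), tri (level → 3 subbands) and quad
(square → 4 quadrants) splits. Each bit plane, from
`n_max = ⌊log2 max|ξ|⌋` down to 0, runs an insignificant-coefficient pass,
an insignificant-set pass and a refinement pass; the decoder mirrors the
encoder bit for bit, reconstructing a coefficient discovered at plane n at
the interval midpoint ±1.5·2^n.

The whole coder state is `R·C/2 + (8L+1)/2` bytes — 8 kB for a 128×128
slice at L = 5, versus ~181 kB of worst-case auxiliary lists for a
SPIHT-style coder with 24-bit addressing.

## Worked example

```sh
# a deterministic 8×128×128 8-bit synthetic volume with inter-slice
# correlation 0.95 (real scan series are not redistributable)
hlck synth --shape 8x128x128 --model correlated-noise --seed 7 --output mri_like.raw

# one encode at 1.0 bpp; decode a 0.5 bpp prefix of the same stream
hlck encode --input mri_like.raw --output m.hlck --rate 1.0
hlck decode --input m.hlck --output recon.raw --rate 0.5

# rate-distortion sweep (single encode, truncation decodes)
hlck eval --input mri_like.raw --rates 0.5,1.0,2.0 --report rd.csv
```

The sweep prints the analytic memory comparison and writes per-slice PSNR:

```
memory report (worst case):
  3D-HLCK state table :     8212.5 bytes (8.0 kB)
  3D-SPIHT lists      :   185856.0 bytes (181.5 kB)

rate_bpp,slice_1,...,slice_8,mean
0.5,55.3656,...,55.5052,55.4416
1.0,60.0138,...,60.2968,60.0639
2.0,68.8762,...,68.9078,69.0042
```

Reading the numbers: mean PSNR rises monotonically with rate (the embedded
property guarantees each row is a prefix of the next), the 0.5 bpp decode of
the 1.0 bpp stream reproduces exactly what a direct 0.5 bpp encode would
(55.44 dB here), and the state-table figure is the closed-form
`R·C/2 + (8L+1)/2` evaluated at this geometry.

The same pipeline is available as a library:

```python
import hlck
from hlck.synthetic_fixtures import FixtureSpec, generate

vol = generate(FixtureSpec(shape=(8, 128, 128), model="blobs", seed=7))
stream = hlck.encode_volume(vol, L=5, filter_id="cdf97", rate_bpp=2.0)
half_rate = hlck.truncate_bitstream(stream, vol.data.size // 2)  # 0.5 bpp
print(hlck.psnr(vol, hlck.decode_volume(half_rate)).psnr_mean)
```

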