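# Methods

## Problem setting

Clinical archives face two coupled requirements: patient metadata must stay
attached to the image it describes without being readable at a glance, and
the image must be stored compactly without any loss, because a recompressed
diagnostic image is a changed diagnostic image. `stegowave` addresses both
with a steganographic embedding stage followed by a lossless transform-coding
stage, each exactly invertible, so the composition is exactly invertible.

## Knight-tour embedding

The embedding substitutes payload bits into least-significant bits (LSBs),
the classical minimal-distortion scheme: a written pixel changes by 0 or 1
intensity level, which bounds the per-pixel error at 1 and the MSE at 1
regardless of payload size. What distinguishes the scheme is the *order* in
which pixels are written. The cover plane is padded to a rows-multiple-of-3,
columns-multiple-of-2 grid and traversed with the L-move (+3 rows, +1 column),
both coordinates wrapping. Because 3 divides the padded height, the orbit of
this move closes after lcm(rows/3, cols) steps — long before covering the
grid — so the tour chains orbits: each time the step would revisit a cell,
the walk restarts at the first unvisited cell in raster order. This rule was
a genuinely open choice; we picked raster restart because it is
deterministic, covers every cell (proved by the exhaustive permutation
tests), and is reproducible by hand for small grids.

Padded cells hold the sentinel value 256, one above the 8-bit range, in a
16-bit working matrix; they are *skipped* during both embedding and
extraction and stripped before the stego image is returned. Writing payload
into cells that are subsequently deleted would destroy bits, so skipping is
the only deletion-safe reading of "pad, embed, delete".

Framing: the payload is 7-bit ASCII; each character is stored as 8 bits
MSB-first, preceded by a 32-bit big-endian header carrying the body length
in bits. Without a header the extractor cannot know where the payload ends.
A stream shorter than 32 bits is treated as zero-extended — an image that
never went through `embed` and happens to have all-zero LSBs therefore
decodes to the empty string rather than raising — while a header that claims
more bits than the image holds raises a truncation error. Capacity is
checked up front (header + body vs. non-sentinel cell count; channels count
three-fold for RGB, filled in R, G, B order); an oversized payload is a hard
error, never a silent truncation.

## Wavelet transforms

Two arithmetics realize the same Haar filter bank, h = (1/√2, 1/√2),
g = (1/√2, −1/√2):

* **Orthonormal float** — the separable 2-D transform (filter and
  downsample along columns, then rows). It conserves energy (Parseval), so
  the distortion of any coefficient manipulation can be read off in the
  coefficient domain: SSE in coefficients = SSE in pixels. This is the
  analysis arithmetic for lossy thresholding.
* **Integer lifting (S-transform)** — s = ⌊(x₀+x₁)/2⌋, d = x₀−x₁ with the
  exact inverse x₀ = s + ⌊(d+1)/2⌋, x₁ = x₀−d. All-integer, bit-exact
  (verified exhaustively over all 65 536 8-bit pairs), and the basis of the
  lossless compression path. A float transform with rounding could not
  honour a "lossless" contract; the lifting form makes it literally true.

Subband naming follows the common convention (LL approximation, LH
horizontal detail, HL vertical detail, HH diagonal), verified band-by-band
against PyWavelets' `haar`/periodization as an independent reference.

Odd-sized inputs are extended by replicating the last row/column before
each level (symmetric half-sample extension); the pre-extension shape is
recorded and restored on inversion. Replication is exactly invertible under
both arithmetics and keeps padded-region detail coefficients at zero.

Two decompositions are offered: the pyramid (`multilevel_dwt2`, recursing
only on LL, default 2 levels — the depth used throughout the pipeline) and
the full wavelet packet (`packet_decompose`, recursing on *all* four
subbands, giving 4^L leaves). The compressor uses packets: detail subbands
of medical images still carry structure worth decorrelating, and a full
quad-tree makes the container geometry derivable from the image dimensions
alone (every node of a level shares one shape). Packet depth accepts any
value in [1, 12] for any image size — edge extension makes deeper levels
well defined even on 1×1 inputs — whereas the pyramid raises once
2^levels exceeds the largest dimension, since a pyramid below one pixel of
approximation has no meaning.

## Compression path

Per plane (RGB images first pass through the reversible color transform,
below): packet-decompose to depth L (default 2) → optional thresholding →
symbolization → canonical Huffman coding.

* **Thresholding** (lossy only): hard keeps x where |x| > T and zeroes the
  rest; soft additionally shrinks survivors by T toward zero,
  sign-preservingly (the naïve x − T is correct only for positive x and
  would grow the magnitude of negative coefficients). The all-lowpass leaf
  is never thresholded — shrinking the global brightness is never the
  intent. T has intensity units and no default heuristic: T = 0/`none` (the
  lossless mode) unless the caller chooses otherwise.
* **Symbolization**: lifting coefficients are integers and are coded
  directly. Float coefficients are uniformly quantized with step 1.0 by
  default (one intensity level — below the visibility threshold for 8-bit
  data, and the natural unit once T ≫ 1 dominates the distortion).
* **Entropy coding**: canonical Huffman with one code per plane. The
  container stores only (symbol, code length) pairs; both ends assign
  codes by sorting on (length, symbol). A prefix code satisfies
  h(s) ≤ L̄ < h(s)+1 bits/symbol, which the tests assert on every plane;
  a single-symbol alphabet gets a 1-bit code. Huffman was chosen over
  arithmetic/range coding for transparency and because the within-one-bit
  bound is all the design claims.

The container (`.msc`) is big-endian throughout: magic `MSC1`, version,
dimensions, channel count, arithmetic, depth, threshold rule, quantization
step, per-plane code table and bit-packed body, CRC-32 trailer. Bad magic
is a format error; a failed checksum or short read is a corruption error.

### Color handling

The lossless path uses the reversible integer transform
Yr = ⌊(2G+R+B)/4⌋, Vr = R−G, Ur = B−G, inverted exactly by
G = Yr − ⌊(Vr+Ur)/4⌋, R = G+Vr, B = G+Ur (floor division throughout; the
floor is what makes the inverse exact, verified on a 32-step RGB lattice
plus 10 000 random triples). A real-valued YCbCr pair with the weights
(0.3, 0.6, 0.1 / −0.2, −0.3, 0.5 / 0.5, −0.4, −0.1) is provided for
analysis; its decoder inverts the forward matrix *numerically*, because the
traditional rounded inverse (1, 0.1, 1.3 / 1, 0.3, −0.5 / 1, 1.8, −0.1) is
only approximate and fails the round trip by several intensity levels. The
rounded matrix remains available behind `approximate=True` for comparison.

## Metrics

MSE, SNR = 10·log₁₀(Σa²/Σ(a−b)²) (referenced to the first image — one of
several circulating conventions, stated explicitly for that reason), PSNR
with peak fixed at 255, and SSIM in its standard published form: 11×11
Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03, dynamic range 255,
population local moments, border pixels within half a window excluded.
Identical images give SSIM exactly 1 and an explicit +∞ PSNR/SNR sentinel
(never an exception — identical pairs are the *expected* case in lossless
testing). BER reports both the count and percentage of flipped payload
bits. Compression ratio is 100·compressed/original and compression
percentage its complement; the two terms are used loosely in the
literature, so both definitions are pinned down here and always sum to 100.

## Synthetic phantoms

The generator emulates the statistical regimes that matter to the coder,
not radiographic physics: `constant` (degenerate statistics, near-zero
entropy), `gradient` (smooth, small detail coefficients), `ellipse`
(nested elliptical "tissues" of distinct intensity on a dark background
plus Gaussian noise — the closest stand-in for a tomographic slice), and
`speckle` (i.i.d. uniform noise, the entropy-coder worst case). Default
test scenes are 128×128 with noise σ = 5 intensity levels, a realistic
acquisition-noise scale for 8-bit data; acceptance sweeps use sizes from
1×1 to 512×512 to keep full-suite runtime in seconds-to-minutes. All
randomness flows from explicit integer seeds; equal spec + seed gives
bit-identical images. Payloads are `ID:…;Name:…;Dx:…;Date:…`-shaped ASCII
of exact requested length.

What passing tests on phantoms shows: exactness properties (lossless round
trips, tour coverage, transform inversion, RCT identity) hold for *all*
8-bit inputs, since they are data-independent or tested exhaustively.
What they do not show: compression *ratios* on real radiographs — those
depend on real-image statistics that phantoms only sketch, so the reported
ratios characterize the phantoms, not clinical corpora.

## Numerical choices and degenerate inputs

Float round trips are asserted at 1e−9 absolute (double precision leaves
~1e−13 for these sizes); Parseval at 1e−9 relative; the lossy
MSE-equals-removed-energy identity at 1e−6 relative (it accumulates over
~16k coefficients). Lifting paths are asserted bit-exact, never within a
tolerance. 1×1 images are legal everywhere: padding makes the tour 3×2 (so
a 1×1 cover has capacity 1 bit — any framed payload overflows it, by
design), and edge extension makes depth-2 packets well defined. Huffman
ties are broken deterministically by insertion order on a sorted alphabet,
so containers are byte-reproducible across runs and platforms.

## Known limitations

* LSB substitution is fragile by construction: any re-quantization (JPEG
  write, tone mapping) destroys the payload. The I/O layer therefore
  refuses lossy writes; this is a feature, not a gap.
* The tour is fixed and public; it scatters the payload but is not a
  cryptographic protection. Encrypting the payload before embedding is out
  of scope and composes trivially.
* Huffman coding costs up to 1 bit/symbol over the entropy; range coding
  would shave a few percent at the price of opacity.
* Compression ratios on synthetic phantoms do not transfer to clinical
  images (see above); the lossless guarantee does.
* DICOM, 16-bit depths and color profiles are out of scope; inputs are
  8-bit PNG/PGM (and JPEG read-only).
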