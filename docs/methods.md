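# Methods

`holoquant` reads a colour-responsive holographic sensor out of a smartphone
photograph and converts its colour to analyte concentration (pH).  This note
records the models each stage implements, the parameters that matter, the
design choices that were genuinely open, and what the synthetic test bench
does and does not demonstrate.

## The synthetic acquisition campaign

The sensing physics — a hydrogel diffraction grating whose replay wavelength
red-shifts as the gel swells with rising pH — enters the package only through
its observable: a circular coloured region whose hue falls monotonically from
blue (~240°) at pH 3.00 toward red as pH rises.  The simulator implements
that observable directly with a linear hue↔pH map over pH 3.00–6.50; the red
end is parked at 5° rather than 0° so hue never wraps through the 0°/360°
discontinuity inside the operating range (a wrap would put a spurious jump in
one coordinate of the colour descriptor).  A sigmoidal swelling profile around
the gel's effective pKa could be substituted without touching any other
stage; linearity was chosen because the calibration network is agnostic to
the exact monotone shape.

A campaign consists of 6 sensors × 11 buffer levels
{3.00, 4.00, 4.50, 4.75, 5.00, 5.25, 5.50, 5.75, 6.00, 6.25, 6.50} = 66
scenes, one chart, one grey card.  Sensor-to-sensor variation is a small
deterministic hue offset (±2° across the six sensors), emulating
batch-to-batch grating differences.

Every render passes through the forward camera

    image = clip( V · (M · S)^(1/γ) + ε ,  0, 1 )

with `S` the linear-light scene, `M` a 3×3 channel-mixing matrix (defaults
have ~5–8 % cross-talk), per-channel exponents `γ` (defaults 2.1/2.0/1.9,
typical of consumer sensors), radial vignetting `V = 1 − s·(r/r_corner)²`
(default strength 0.25) and i.i.d. additive Gaussian noise (default sd 0.003
channel units, i.e. ≈0.8 of an 8-bit step).  Scenes are 512×512 by default —
large enough for stable keypoint matching, small enough that the full
66-scene campaign runs in a few minutes on one core.

Scenes contain a deterministic QR-style fiducial (three finder squares, a
pseudo-random module field, a reserved black centre holding the sensor disc)
pasted under a random similarity transform (rotation ±30°, scale 0.75–0.95 of
roughly half the frame, small translation), over a gradient background with
`clutter`-scaled coloured distractors, a shadow ramp and specular highlight
blobs.  At clutter ≥ 0.6 one distractor is deliberately given a hue within
~12° of the sensor's and drawn in a corner — a hard negative the recogniser
must reject by context rather than hue alone.  Every render returns full
ground truth (sensor mask, fiducial corners, true hue and pH, chart
reference XYZ), so each downstream stage is scored without re-derivation.

What the simulator does **not** emulate: spectral rendering (patch colours
are linear-RGB reflectances, reference XYZ comes from a fixed primaries
matrix rather than integration over reflectance spectra), lens distortion,
out-of-plane pose, demosaicing artefacts, JPEG blocking, and angle-dependent
replay of a real grating.  Passing tests therefore demonstrate that the
*algorithmic chain* is correct and self-consistent under a realistic camera
model — not that a specific handset will reach the same accuracy on real
scenes.

## Secure transfer

A passcode over the 36-symbol alphanumeric alphabet is encoded to its
base-36 value (mod 2³²), which seeds a deterministic PRNG (PCG64).
Encryption is the classical confusion/diffusion pair: a Fisher–Yates
permutation of pixel positions, then XOR with a key-derived byte stream.
Both steps are bijections on 8-bit data, so decryption is exact; the scheme
is an obfuscation layer for transfer, not audited cryptography.

Compression is a single-level 2-D DWT per channel (Haar or 4-tap Daubechies,
periodised boundaries).  The approximation subband is kept in full; detail
coefficients are hard-thresholded to the top `keep_fraction` by magnitude
globally across channels.  Coefficients are quantised to 8 bits per subband
with a per-subband scale, wraparound delta-coded (smooth subbands become
near-zero byte streams) and deflate-coded.  At `keep_fraction = 0.05` a
simulated scene compresses ~7–8× at ≈50 dB PSNR; `quantise=False` stores
float64 coefficients and is exact at `keep_fraction = 1`.  Payloads are
compressed first and the coefficient byte stream encrypted second — permuted
pixels have no spatial smoothness left for a wavelet to exploit.

## Localisation

Template and scene are converted to greyscale (ITU-R 601 luma) and ORB
keypoints/descriptors extracted (default 800, one retry at 1600).  Putative
matches are mutual-nearest-neighbour under Hamming distance.  A Lowe ratio
test is available but **off** by default: on a self-similar binary target the
first and second nearest binary descriptors are near-equidistant and a 0.75
ratio starves the estimator of correct matches (measured: 0–1 survivors vs
60–80 cross-checked matches).  RANSAC (reprojection threshold 3 px, 2000
trials, seeded) fits a homography, which is refit on its inliers; a
detection needs ≥ 12 inliers and a convex projected quad, otherwise a
no-detection error tells the caller to re-capture.  The sensor window is the
central 30 % of the rectified fiducial — comfortably inside the reserved
black centre (9 of 29 modules) while covering the sensor disc.

## Camera characterisation

Order of operations: **flat-field → gamma → polynomial**.  The gain map is
estimated on the *encoded* grey card as `gain = channel_mean / surface`,
where `surface` is a degree-4 least-squares polynomial surface per channel —
a global fit has no boundary bias on a curved falloff field, unlike
convolution smoothing, and is exact for the simulator's quadratic vignette.
Because vignetting multiplies the encoded signal, dividing it out *before*
linearisation removes it exactly; the per-channel exponents are then fitted
on the flat-fielded neutral-ramp patches in the log–log domain with a free
intercept, `value = A·luminance^(1/γ)` (the intercept absorbs exposure and
channel mixing of the neutral axis; without it, any overall scale biases the
exponent).  Patch means use the central 50 % of each patch cell to avoid
edge bleed.

The RGB→XYZ regression is linear least squares on augmented monomial terms
`R^p G^q B^r`.  Term sets are data; shipped presets have 3, 5, 8, 11 and 20
terms (the full degree ≤ 3 monomial basis).  Larger published sets can be
passed as explicit exponent lists.  Model selection minimises the median
CIE76 ΔE*ab between predicted and reference patch colours in L\*a\*b\*
(D65/2° white, Y = 100 scale); ties go to the smaller model.  On simulated
cameras (γ ∈ [1.5, 2.5], vignette ≤ 0.4, noise ≤ 0.005) the exponents are
recovered well within 3 % and held-out patch median ΔE stays below 1.

## Segmentation and cluster-count selection

Images are Gaussian-smoothed (σ = 1 px, reflect boundaries) and clustered in
the chosen space: RGB as-is; CIELAB scaled by 1/100; HSI embedded as
(0.5·S·cos H, 0.5·S·sin H, I) so that distances respect hue circularity (the
chord length is monotone in the shortest angular difference, and saturation
weighting makes near-achromatic pixels hue-indifferent).  k-means is Lloyd's
algorithm with k-means++ initialisation (tol 1e-6, ≤300 iterations, seeded);
fuzzy c-means uses fuzzifier q = 2, membership tolerance 1e-5.  Clustering
runs on ≤ 50 000 subsampled pixels, and the winning centres label the full
image by nearest centre.

The validity measure is `VM(k) = y(k) · intra / inter` with
`intra = (1/M)ΣΣ‖x−c_i‖²`, `inter = min‖c_i−c_j‖²`, and
`y(k) = m·N(μ,σ)(k) + 1` (m = 20, μ = 2, σ = 1, k searched over 2…10); the
minimum VM picks k.  The Gaussian multiplier as printed in the source
criterion carries a minus sign, which makes y negative near k = μ and turns
the intended small-k penalty into a reward; the package defaults to the
positive Gaussian (`sign_variant="positive_gaussian"`), with `"as_printed"`
available for comparison.  With μ+3σ = 5, essentially all selected counts
fall in 2–5, and planted 3- and 5-cluster fixtures are recovered exactly.

## Recognition

Each segment is summarised by the 9-vector of means (R, G, B, H, S, I, L\*,
a\*, b\*); hue is averaged circularly with saturation weights.  Colour-space
quality is ranked by Fisher separability.  The printed form of the criterion
is a plain product `trace(Sb·Sw)`, which is not scale-invariant and *falls*
as classes tighten, contradicting its use as a higher-is-better score; the
package therefore defaults to the ratio form `J = trace(Sw⁻¹Sb)` and keeps
the literal product behind a switch.  On fixtures with multiplicative
lighting clutter (shadows/highlights), J ranks LAB > HSI > RGB, the ordering
expected when lightness is decoupled from chromaticity.

The recogniser is a 10×10 self-organising map trained unsupervised on
z-scored descriptors (learning rate 0.5 → 0.01 linear, Gaussian
neighbourhood radius 5 → 1; epochs configurable, 60 in the pipeline, where
the descriptor clouds are well separated and more epochs only add runtime).
After training, each node takes the majority label of the samples it wins;
empty nodes inherit the nearest labelled node's class.  The sensor region is
the segment classified "hologram" (largest pixel count on ties); none found
raises a re-capture error.

## Agreement statistics

The one-way random-effects ICC is computed exactly from the between- and
within-target mean squares of an n-targets × k-methods table; for two
segmentation methods quantifying the three colour coordinates of the sensor
region, n = 3 and k = 2 per scene, and per-scene ICCs are averaged across
the campaign (both per-scene and pooled forms are exposed).  Bland–Altman
limits use the sample (n−1) standard deviation and the 1.96 multiplier.

## Calibration

The MLP has 9 inputs, hidden layers of 10 and 5 log-sigmoid units and a
linear output; training is full-batch backpropagation on the MSE with
classical momentum (lr 0.01, momentum 0.9; momentum = 0 recovers plain
descent, under which the loss is provably non-increasing for small steps).
It stops at 10 000 iterations or training MSE < 1e-6.  Inputs are z-scored
with training statistics stored in the model; the output layer starts at the
training-target mean so early iterations shape the hidden layers rather than
chase the offset.  The network is written out in NumPy because the stopping
rule (an absolute training-error threshold) and bit-level seeding are part
of its contract.  Hidden sizes (10, 5) suit the 44-sample training regime;
the split holds out whole sensors (2 of 6), so evaluation simulates unseen
devices.  Predictions outside pH 2.5–7.0 are flagged but returned.

## Numerical and degenerate-input choices

* Colour: D65/2° white fixed at (95.047, 100, 108.883); Lab uses the
  two-piece function with the (6/29)³ threshold; achromatic HSI reports
  H = 0; ΔE is CIE76 (plain Euclidean), not CIEDE2000.
* Validity: coincident centres raise a degenerate-clustering error and that
  k is skipped; an all-equal agreement table raises rather than returning
  0/0.
* FCM: a pixel exactly on a centre receives full membership there (the
  analytic limit of the update rule).
* Rank-deficient polynomial designs raise with advice instead of silently
  regularising.
* All randomness flows from explicit integer seeds (PCG64); identical
  (config, arguments) pairs render bit-identical images.

## Problem sizes

The test suite and the reproduction script use: the full 66-scene campaign
at 512×512 and clutter 0.3 for the end-to-end metrics; 20 random cameras at
256×256 for parameter recovery; 100 random instances per statistic for the
brute-force oracle comparisons; and 100 random image/passcode pairs for the
cipher bijection check.

## Known limitations

* The secure layer is reversible obfuscation, not cryptography; no
  cryptanalysis is claimed.
* Localisation assumes the fiducial is approximately planar and mostly
  unoccluded; out-of-plane pose beyond what a homography absorbs is not
  modelled.
* A real camera's gamut limit can compress distinct sensor colours into the
  same recorded colour at one end of the operating range, putting a floor on
  resolvable concentration differences there; the simulator's camera is
  gamut-unrestricted, so this failure mode is documented rather than
  reproduced.
* Separability is computed on segment pixels in each space; other choices
  (e.g. per-segment descriptors) would change J's scale, though not the
  lightness-decoupling argument behind the ordering.
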