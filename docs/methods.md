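# Methods

## Model and assumptions

`cbctfuse` enhances single-channel low-dose CBCT slices with a fixed,
deterministic chain of pointwise and global transforms; nothing is learned
or fitted. The design assumption is that low-dose degradation is a
combination of (a) detail loss in badly exposed regions, (b) globally
depressed visibility, and (c) compressed contrast — and that each defect
is best addressed by a dedicated transform whose outputs are then fused.
All math is done in float64 on intensities in [0, 1]; files are quantized
only on write.

**Sharpening.** `Z = (I + N{I - G*I})/2`, with `G` a Gaussian kernel and
`N` a *global* min-max stretch of the detail layer (a single scalar min and
max over the slice, not per tile). A flat detail layer is mapped to zeros:
it carries no edges, so the sharpening term should vanish rather than be
amplified — the same degenerate rule is used by every min-max stretch in
the package. Consequences worth knowing: a constant slice of level c maps
to c/2, and on noisy slices the detail layer is noise-dominated, so the
normalization stretches that noise to full range before averaging. That is
the transform's definition, not an implementation artifact.

**Visibility restoration.** The sharpened slice is read as a type-II fuzzy
set: upper bound `u = Z^a + (1 - Z^a) (s^2)^a`, lower bound
`w = (k*mu/(sigma+b))(Z - c*mu) + mu^d`, where `mu`, `sigma` are the slice
mean and sample (n−1) standard deviation and `s^2 = sigma^2`. For
intensities in [0, 1] the sample variance never exceeds 1, so `u` stays in
[0, 1] and the Hamacher t-conorm
`t = (u + w + (s^2-2)uw) / (1 - (1-s^2)uw)` is well defined; memberships
are clipped to [0, 1] first (the t-conorm's domain), and a vanishing
denominator (|den| < epsilon) returns the saturation limit 1. The gamma
restoration `L1 = max(t) * (t/max(t))^(1.5a)` uses the *global* maximum —
the formula reads as a scalar max — and therefore preserves it exactly.

**Contrast enhancement.** `l = sqrt(g + s + g*s)` with `g` the standard
normal density of the pixel and `s` its softplus, both with natural
logarithm/exponential (the conventional base for softplus). `l(Z)` is
strictly increasing on [0, 1] — verified numerically on a dense grid —
so the branch preserves pixel ordering. The final stretch
`L2 = ((l - min l)/(max l - min l))^eta` lands exactly on [0, 1].

**Perceptual fusion.** Weights per input image n: well-exposedness
`w1_n = exp(-(L_n - (1-m_n))^2 / (2 sigma_n^2))`, and inverse
CDF-slope `w2_n ∝ 1/Grad_n(L_n)` where `Grad_n` at level v is
`(bin count)/(pixel count * bin width)` of a 256-bin histogram on [0, 1] —
the slope of the empirical cumulative histogram, so rare intensity levels
(flat CDF regions, i.e. high global contrast there) receive more weight.
The width rule sorts images by ascending mean first, making the
neighbouring-mean differences non-negative: `sigma_n` is 1.5x the gap to
the single neighbour for the extreme images and 0.75x the straddling gap
for interior ones; with two images both reduce to `1.5 (m_2 - m_1)`.
`sigma_n` is floored at epsilon so equal means do not divide by zero.
Final weights `W_n = w1_n w2_n / (sum_n w1_n w2_n + epsilon)`; the fused
slice is `F = sum_n W_n L_n`, clipped to [0, 1] only when written to file.

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.95 | fuzzification exponent; also sets the restoration gamma 1.5·alpha = 1.425 |
| `eta` | 0.8 | contrast-branch normalization gamma (< 1 brightens midtones) |
| `blur_sigma` | 2.0 px | detail-layer Gaussian scale; kernel truncated at 4 sigma, edge-replicated boundaries (zero padding would create dark rim halos) |
| `k, b, c, d` | 1, 1e-6, 1, 1 | lower-membership coefficients; these have no canonical published values, and the defaults reduce the bound to a mean-centred stretch with gain ~mu/sigma — a known gap, all exposed in config |
| `epsilon` | 1e-6 | guard in weight normalization, histogram-slope floor, Hamacher denominator |
| `hist_bins` | 256 | cumulative-histogram resolution for the gradient weights |
| `clip_memberships` | true | clip u, w to [0, 1] before the t-conorm |

## Numerical choices

- Degenerate min-max (constant field → zeros) is shared by the sharpening
  normalizer and the contrast stretch.
- At pixels where the fusion weight products sum to ≤ epsilon (both weight
  families vanished — e.g. fusing two images of identical mean, where the
  width rule collapses to the epsilon floor), the combined weights fall
  back to the uniform 1/N. Without this guard the +epsilon denominator
  would send all weights to zero and the fused value with them; uniform
  weights are the natural indifference limit and keep `F = L` exact when
  both inputs are the same image.
- The `+epsilon` denominator means the weight sum is `P/(P+eps)` — always
  slightly below 1 and materially below it wherever the products `P` are
  small (pixels far from both well-exposedness peaks). The fused output is
  therefore a *sub*-convex combination at such pixels; the convex-envelope
  guarantee holds exactly where |sum W − 1| ≤ 1e-6.
- Ablations (`no_vrm`, `no_cem`) bypass fusion entirely and return the
  surviving branch; a `self_fusion` flag instead fuses the branch with
  itself (numerically the same up to weight normalization).
- 8-bit files quantize with round-half-even at 255 steps, 16-bit at 65535;
  round trips are exact to half a step.

## Synthetic phantom

The generator emulates the *geometry and degradations* of a low-dose oral
CBCT axial slice: dark air background (0.05), an elliptical jaw arch band
(0.45), tooth discs along the arch (0.7), miniscrew foci (0.95), all
edge-smoothed; degradation = affine contrast compression toward mid-grey,
gamma underexposure, optional saturated patch, seeded Gaussian noise. The
default degradation (compression 0.5, gamma 1.8, noise 0.01) represents a
markedly degraded acquisition. One `numpy.random.default_rng(seed)` stream
drives everything, so a spec+seed pair is bit-reproducible across
platforms.

It deliberately does **not** model projection/reconstruction physics, beam
hardening, metal streaks, or soft-tissue texture. Tests passing on
phantoms therefore demonstrate the pipeline's mathematical contracts and
directional behaviour, not clinical image quality; in particular the
phantom's intensity variance is much lower than a real slice's, which
makes the visibility branch's mu/sigma gain (~5 with the default
coefficients) far stronger than it would be on real data, and lets it
amplify phantom noise. Average gradient counts that amplified noise as
"detail", which is why the visibility-only ablation can out-score the
fused output on phantoms — an artifact of the coefficient gap and the AG
metric, not a property to expect on real CBCT.

Problem sizes used by the test suite and the acceptance script — 20
phantom seeds at 128–256 px, 100 random 32-px images, one 512-px timing
image — were chosen as the smallest sizes at which every global statistic
(histograms, means, variances) is stable.

## Known limitations

- The learned no-reference scores (BRISQUE, NIQE, FADE) are not
  implemented; `third_party_scores` forwards to an installed external
  implementation if present and is non-authoritative. Only AG is
  first-party, and AG magnitudes are intensity-scale-dependent: compare
  orderings, never absolute values, across sources.
- DICOM support is read-only, single-frame grayscale; colour inputs are
  collapsed by luminance with a warning.
- The lower-membership coefficients `k, b, c, d` have no published values;
  results are sensitive to them (see the phantom discussion above).
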