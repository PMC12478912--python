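# Methods

## Decomposition model

The pipeline's default backend is a Gaussian residual pyramid. With
`L_0` the input image, each level computes

    H_i = L_{i-1} - G_sigma(L_{i-1})        (signed detail subband)
    L_i = down2(G_sigma(L_{i-1}))           (next approximation)

for i = 1..L, keeping `H_1..H_L` and the terminal `L_L`. `G_sigma` is a
normalized Gaussian, truncated at radius `ceil(3*sigma)` with reflective
boundaries. The default `sigma = 20` is deliberately large: the residual
then carries nearly all structure and the decimated approximation only
the coarse intensity layout. `down2` keeps every second pixel starting
at index 0 (the heavy smoothing is the anti-alias filter); odd
dimensions follow the ceiling convention, and the per-level shapes are
recorded so that synthesis is shape-exact.

Synthesis is the coarse-to-fine recursion `R_{i-1} = up2(R_i) + H_i`
with `R_L = L_L`, where `up2` is bilinear interpolation to the exact
recorded shape. A single-expansion synthesis formula cannot be
shape-consistent for more than one level; the recursion is its unique
consistent reading and reduces to the single-expansion form at each
step. The scheme is *not* perfect-reconstruction — `up2(down2(.))` is
not the identity — but the resampling error acts only on the
sigma-smoothed field, so the self-round-trip error stays below 2%
relative RMSE on 256x256 phantoms (the acceptance run reports the
achieved value, about 1.8%).

A classical Burt–Adelson Laplacian pyramid (5-tap binomial kernel
[1,4,6,4,1]/16, residuals stored against the expanded next level) is
provided as a second backend; it is exactly invertible to below 1e-9
and serves as the reference multiscale transform. Its expansion step
zero-stuffs and convolves with `2h` per axis; the expansion uses a
mirror boundary (no edge duplication) because edge-duplicating
reflection breaks the even/odd parity of the zero-stuffed lattice and
constants would no longer expand to constants. A directional filter
stage is deliberately out of scope: the fusion recursion above neither
produces nor consumes directional subbands.

## Curvature filtering

Detail subbands are sharpened/denoised with mean-curvature flow

    du/dt = kappa(u),   kappa = div( grad u / ||grad u||_eps ),
    ||grad u||_eps = sqrt(u_x^2 + u_y^2 + eps)

discretized with central differences in the interior, one-sided at the
borders, and advanced by explicit Euler. Defaults: `dt = 0.0005`, 15
iterations, `eps = 1e-4`. The stabilizer sits under the square root, so
flat regions (gradient ~ 0) evolve negligibly instead of dividing by
zero. Constants and linear ramps are interior fixed points; circular
level sets contract at rate 1/r (verified against the analytic cone to
< 5% relative error on an interior annulus).

Note the total evolution time `15 * 0.0005 = 0.0075` is small relative
to typical curvature magnitudes of subbands, so the default filter is a
gentle regularization, not an aggressive smoother; the strength is fully
exposed through `FlowParams`. By default only the terminal-level
subbands are filtered (`filter_scope="level_L_only"`), of *both*
sources, before fusion — filter-then-fuse keeps the rule symmetric in
the sources. `all_levels` and `none` are selectable.

Variants: TV flow shares the identical stabilized right-hand side (one
entry point per name); Gaussian curvature
`K = (u_xx u_yy - u_xy^2)/(1 + u_x^2 + u_y^2)^2` is a pointwise
diagnostic, not a flow; weighted mean-curvature flow updates
`u <- u - dt * w * H(u)` with a caller-supplied weight map `w` and
`H = kappa`, so `w = -1` reproduces the plain flow exactly and `w = 0`
is the identity. The weight function is intentionally left to the
caller — no canonical choice exists.

## Fusion rules

Low-frequency images combine by weighted averaging
`F_L = alpha*L_A + (1-alpha)*L_B`, `alpha = 0.5` by default (equal
trust in both modalities' brightness). Detail subbands combine by the
max-absolute rule: keep the coefficient of larger magnitude. The
inequality is strict, so exact-magnitude ties (including zero-zero)
resolve to the second input — an arbitrary but fixed convention,
logged at INFO level for auditability. Ablation variants: weighted
averaging for details (`high_rule="weighted"`) and single-source low
frequency (`low_mode="a_only"/"b_only"`); `ablation_suite` tabulates
all four. Subbands stay signed and unclamped throughout; only the final
image is clamped to [0, 255].

## Metric conventions

* Histogram scores (Entropy, MI/MIF/FS1) quantize to uint8 first
  (round-half-even, clamp), so the 256-level histograms are well
  defined; gradient scores (AG, SF, QAB/F) use the floating image.
* AG and SF sum squared first differences over valid index pairs only
  but keep the 1/(M*N) divisor by default (a `divisor="valid"` switch
  normalizes by the pair count instead). With the M*N divisor the 2x2
  checkerboard gives SF = 255 exactly.
* FS1 defaults to the fusion-symmetry scale
  `2 - |MI(F,A)/(MI(F,A)+MI(F,B)) - 0.5|`, which lives in [1.5, 2]
  (2 = perfectly balanced information split) and matches the scale on
  which fusion-symmetry values are conventionally reported; the
  normalized-difference form `(MI_A - MI_B)/(MI_A + MI_B)` in [-1, 1]
  is available as `variant="printed"`.
* Corr reports the mean of Corr(F,A) and Corr(F,B) by default (single
  pairings selectable); a constant argument raises, as correlation is
  undefined at zero variance.
* QAB/F uses Sobel gradient strength and orientation, sigmoidal
  strength/orientation preservation models with the standard constants
  (0.9994, -15, 0.5) and (0.9879, -22, 0.8), and edge-strength-weighted
  averaging over both sources. Each sigmoid is normalized by its value
  at perfect preservation, so an exact copy of the sources scores 1.0
  exactly; without that normalization a perfect copy scores ~0.975,
  which makes scores across images harder to interpret.
* The plug-in MI estimator is biased upward by roughly
  `(K-1)(L-1)/(2N ln 2)` bits for K x L bins and N pixels (~0.72 bits
  at 256x256 pixels); MI-based scores on small images should be read
  with that floor in mind.

## Synthetic phantoms

`make_phantom_pair` emulates a co-registered anatomical pair of a head
section: the MRI-like image has smooth Gaussian tissue blobs on a
mid-gray base, a bright fluid ellipse and a dark bone ring; the CT-like
image has a bright ring at the same coordinates and a flat interior.
Shared geometry guarantees pixelwise co-registration; independent
additive Gaussian noise (sd 2.0 intensity units by default) models
acquisition noise. One seeded generator per call, no global state:
identical specs are bitwise-identical. Default size 256x256 — large
enough for sigma = 20 smoothing to be meaningful, small enough for
sub-second tests.

What the phantoms do *not* model: anatomical realism, modality-specific
noise physics (Rician MRI noise, CT streaking), partial-volume effects,
registration error, or 3-D structure. Passing the synthetic suite
demonstrates the pipeline's mathematical properties (round-trip
fidelity, edge retention of max-abs over averaging, metric
correctness), not clinical image quality.

## Numerical choices and degenerate inputs

* All images are float64 on the 0-255 scale internally; 16-bit files
  are rescaled by 255/65535 at load; RGB collapses to BT.601 luminance
  with a warning.
* Images must be finite; NaN/Inf raise. Decomposition requires the
  terminal level to be at least 2x2; smaller inputs raise rather than
  silently truncating the pyramid.
* Exact floating-point lossless-ness of constant self-fusion holds at
  export (uint8) precision; in float arithmetic the normalized Gaussian
  reproduces constants to ~1e-14 relative.
* Problem sizes in the test and acceptance runs (256x256 phantoms, 50
  32x32 round-trip images, 20 ablation pairs) were chosen as the
  smallest sizes at which the asserted properties are stable.

## Limitations

* Registration is out of scope; inputs must already be co-registered
  (shape equality is enforced, alignment is trusted).
* Two sources only, 2-D grayscale only; PET/SPECT color maps must be
  collapsed to grayscale first.
* The Gaussian residual backend is not perfect-reconstruction (by
  design, following the decomposition equations); use the
  Laplacian-pyramid backend where exact invertibility matters.
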