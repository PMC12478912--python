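# curvefuse

Multiscale multimodal medical image fusion with mean-curvature
enhancement of detail subbands, plus the objective quality-metric suite
used to evaluate fusion results.

## The problem

Anatomical modalities are complementary: CT renders bone brightly but
has poor soft-tissue contrast, while MRI separates soft tissue well but
leaves bone dark. Clinicians reading both side by side must mentally
co-register them. Image fusion combines a co-registered pair into a
single image that keeps the bright skull of the CT *and* the
tissue/fluid contrast of the MRI. The hard part is preserving edges and
texture from both sources without halos, blur or contrast loss.

`curvefuse` is for researchers evaluating fusion pipelines: it provides
the fusion method, a nine-score evaluation suite, a seeded synthetic
phantom generator (so everything is testable without clinical data),
and a CLI.

## The method

Both sources A and B (2-D grayscale, 0–255 scale, identical shapes) are
decomposed into a Gaussian residual pyramid with L = 3 levels and a
heavy smoothing width σ = 20:

    H_i = L_{i-1} − G_σ(L_{i-1}),     L_i = ↓2(G_σ(L_{i-1})),  L_0 = image

so each level yields a signed detail subband H_i and the recursion ends
in a small low-frequency image L_3. The components are fused by:

* **low frequency** — weighted averaging, F_L = α·L_A + (1−α)·L_B with
  α = 0.5 (brightness consistency);
* **detail subbands** — the terminal-level subbands of both sources are
  first sharpened by mean-curvature flow, ∂u/∂t = κ(u) with
  κ = ∇·(∇u/‖∇u‖_ε), explicit Euler at Δt = 0.0005 for 15 iterations;
  then every level is fused pixelwise by the max-absolute rule
  (keep the coefficient of larger magnitude — edge retention).

The fused pyramid is reconstructed coarse-to-fine,
R_{i−1} = ↑2(R_i) + F_{H_i}, and clamped to [0, 255] at export. A
classical (exactly invertible) Laplacian-pyramid backend, TV /
Gaussian-curvature / weighted-MC filter variants, and the ablation
variants (weighted detail averaging, single-source low frequency) are
included.

The metric suite scores a (fused, A, B) triplet: API (mean intensity),
SD (contrast), AG (mean gradient), Entropy, MIF = MI(F,A)+MI(F,B), FS1
(information symmetry), Corr, SF (spatial frequency), and QAB/F
(Sobel-based edge preservation, in [0, 1]).

## Worked example

Generate a seeded 256×256 phantom pair (MRI-like: smooth tissue blobs,
bright fluid ellipse, dark bone ring; CT-like: bright ring, flat
interior), fuse it and score the result:

```sh
curvefuse demo --seed 0 --outdir demo_out
```

writes `a.png`, `b.png`, `fused.png`, `report.json` and prints

```json
{
  "API": 73.48921922584711,
  "SD": 72.36287567417895,
  "AG": 7.414472561416746,
  "Entropy": 4.893229159049508,
  "MIF": 3.8503610679198648,
  "FS1": 1.8659617051675697,
  "Corr": 0.7659118574539105,
  "SF": 27.151012683040992,
  "QABF": 0.6600818403691434
}
```

Read: the fused phantom keeps a wide intensity spread (SD ≈ 72) and
strong detail (SF ≈ 27, AG ≈ 7.4); it shares ≈ 3.85 bits of information
with the two sources combined, split almost symmetrically (FS1 ≈ 1.87
on the [1.5, 2] scale, 2 = perfectly balanced); two thirds of the
source edge information survives with strength and orientation intact
(QAB/F ≈ 0.66 against noisy sources). Equivalent library calls:

```python
from curvefuse import PhantomSpec, make_phantom_pair, fuse_images, report

a, b = make_phantom_pair(PhantomSpec(seed=0))
fused = fuse_images(a, b)          # defaults: L=3, sigma=20, alpha=0.5
print(report(fused, a, b).as_row())
```

`curvefuse fuse --a mri.png --b ct.png --out fused.png` runs on real
image files; `curvefuse ablate` emits the four-variant ablation table
as CSV; `curvefuse metrics` scores an existing fused image.

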