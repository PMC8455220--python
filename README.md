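# fuzzyseg

Noise-robust fuzzy c-means segmentation of grayscale images.

Pixel-intensity clustering with fuzzy c-means (FCM) falls apart on noisy
images because each pixel is classified in isolation. `fuzzyseg`
implements a family of FCM variants that stay accurate under heavy
Gaussian, salt & pepper, or Rician corruption by injecting spatial
structure in two complementary ways, together with the synthetic
phantoms, noise models, and accuracy harness needed to evaluate them.
It is aimed at image-analysis work where tissue-like regions must be
recovered from noisy intensity data — e.g. brain-MRI tissue maps —
and at anyone benchmarking noise-robust clustering.

## The methods

Fuzzy c-means partitions pixels `x_n` into `C` clusters by minimizing

    J(U, V) = Σ_c Σ_n u_cn^m ‖x_n − v_c‖²,   Σ_c u_cn = 1,

alternating the closed-form membership and prototype updates (Picard
iteration) until `|ΔJ| < ξ`. On top of this engine:

* **FCM_S1 / FCM_S2** add a spatial penalty `α‖x̄_n − v_c‖²`, where `x̄`
  is the 3×3 box-mean (S1) or median (S2) image.
* **FCM+GF** smooths each cluster's membership map every iteration with
  a *guided filter* — a local linear model `q_i = ā_i I_i + b̄_i` whose
  coefficients solve a ridge regression (regularizer `ε`) of the
  membership map on the noisy image `I` — so memberships are smoothed
  on flat regions but preserved across image edges.
* **IFCM_GF** multiplies the guidance image by an *influence factor*
  `ρ`, which is provably identical to running the guided filter with
  regularizer `ε/ρ²`: a single scalar adapts the smoothing strength to
  the noise level.
* **MRIFCM_GF** first computes the morphological closing reconstruction
  `β` of the noisy image (geodesic reconstruction with a 3×3
  structuring element, which removes noise grains of either polarity
  while preserving contours) and clusters `β` while keeping the raw
  image as guidance. Reconstruction makes one small `ρ` work across
  noise types and rates.

Accuracy is scored as SA = D/N, the fraction of correctly labeled
pixels under the optimal cluster-to-class assignment, averaged over
repeated seeded runs (ASA) that redraw both the noise and the random
prototype initialization.

## Worked example

```python
import numpy as np
import fuzzyseg as fs

img, truth = fs.make_phantom("ST")                     # 256x256, 3 classes
noisy = fs.add_noise(img, fs.NoiseSpec("salt_pepper", 0.10, seed=42))

cfg = fs.ClusteringConfig(n_clusters=3, seed=0,
                          gf=fs.GuidedFilterParams(radius=1, epsilon=1e-4, rho=0.008))
result = fs.ifcm_gf(noisy, cfg)
sa = fs.segmentation_accuracy(result.labels, truth)

print(f"iterations: {result.n_iter} (converged={result.converged})")
print(f"centers:    {np.round(result.centers * 255, 2)}")
print(f"SA:         {sa.sa:.4f}  ({sa.n_correct} of {sa.n_total} pixels)")

asa = fs.run_asa("ifcm_gf", "ST", fs.NoiseSpec("salt_pepper", 0.10), cfg,
                 reps=20, base_seed=0)
print(f"ASA over 20 runs: {asa.asa:.4f} +/- {asa.se:.4f}")
```

prints

```
iterations: 7 (converged=True)
centers:    [ 10.43  88.26 167.29]
SA:         0.9996  (65509 of 65536 pixels)
ASA over 20 runs: 0.9996 +/- 0.0000
```

With 10% of pixels destroyed, the influence-factor-tuned filter still
recovers 99.96% of the label map; the prototypes land near the true
class intensities 0/85/170 (shifted slightly by the corruption). Plain
FCM on the same image scores about 0.94.

The same operations are available from the shell:

```sh
fuzzyseg generate --phantom ST --noise gaussian --level 0.05 --seed 42 --out data/
fuzzyseg reconstruct --in data/ST_gaussian_0.05.png --se 3 --out beta.png
fuzzyseg segment --method mrifcm_gf --in data/ST_gaussian_0.05.png \
    --clusters 3 --rho 0.009 --seed 1 --out labels.png --truth data/ST_truth.png
fuzzyseg reproduce --table T1 --reps 20 --out results/
fuzzyseg sweep --method mrifcm_gf --phantom ST --noise gaussian --level 0.15 \
    --rho-grid 0.001:0.1:log20 --reps 5
```

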