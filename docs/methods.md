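# Methods

## Model and procedure

All algorithms cluster scalar pixel intensities on the normalized
[0, 1] scale. The shared engine minimizes the fuzzy c-means objective

    J(U, V) = Σ_c Σ_n u_cn^m ‖x_n − v_c‖²,  Σ_c u_cn = 1,  0 ≤ u_cn ≤ 1,

by Picard iteration: with prototypes fixed, the memberships have the
closed form `u_cn = 1 / Σ_j (d_cn / d_jn)^(2/(m−1))`; with memberships
fixed, each prototype is the `u^m`-weighted mean of the data. For pure
FCM this alternation never increases J (asserted in tests). Iteration
stops when `|J_t − J_{t−1}| < ξ` or at `max_iter`; hitting the cap
flags the result `converged=False` rather than raising, since the label
map is still usable.

The guided-filter variants insert one step between the two updates: each
cluster's membership row, reshaped to the image grid, is passed through
the guided filter with the raw noisy image as guidance, then clipped at
zero and renormalized per pixel so columns stay stochastic (a pixel
whose filtered column sums to zero falls back to its pre-filter
memberships; in practice this never fires on real inputs). Filtering
sits after the membership update and before the prototype update, so
prototypes are always estimated from spatially regularized memberships.

MRIFCM_GF computes the closing reconstruction β of the input once,
before iterating, and substitutes β for the raw image in the membership
and prototype updates only — the guidance image stays the raw input, so
edge evidence is never taken from the already-smoothed reconstruction.

### The influence factor

For a window ω_k the guided-filter coefficients are

    a_k = (mean(I·p) − μ_k·p̄_k) / (σ_k² + ε),   b_k = p̄_k − a_k μ_k,

and q_i = ā_i I_i + b̄_i. Substituting ρ·I for I multiplies σ_k² by ρ²,
which is algebraically identical to leaving I alone and replacing ε by
ε/ρ². The implementation literally scales the guidance image, and the
identity is verified to relative tolerance 1e-8 over random inputs,
factors, and window radii — it is the package's central invariant, and
it means a user can tune a single well-scaled scalar ρ instead of the
raw regularizer.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `m` | 2.0 | fuzzifier; 2 is the conventional choice for intensity clustering |
| `xi` | 1e-8 | absolute ΔJ convergence threshold (intensities on [0, 1]) |
| `max_iter` | 200 | iteration cap; ξ-convergence typically needs 5–60 iterations |
| `alpha` | 3.8 | spatial-penalty weight for FCM_S1/S2 |
| `epsilon` | 1e-4 | guided-filter ridge regularizer |
| `radius` | 1 | filter window half-width (3×3 windows throughout) |
| `rho` | 1.0 | influence factor on the guidance image; useful values for the benchmarks lie in ~[0.001, 0.05] |
| `se_size` | 3 | structuring-element side for the reconstruction |

Prototype initialization draws C distinct pixel intensities uniformly
from the image with the seeded generator; supplying `init_centers`
overrides this (used by the permutation-invariance tests).

## Numerical choices

* **Borders.** Every window statistic (box mean, median, filter
  coefficients, coefficient averaging) uses the window truncated to the
  image with the actual pixel count as divisor; dilation/erosion take
  max/min over in-image neighbors only. No padding values ever enter a
  computation.
* **Degenerate windows.** With ε = 0 a constant guidance window makes
  the slope 0/0; the minimal-norm solution a_k = 0, b_k = p̄_k is used.
* **Zero distances.** A pixel coinciding with one or more prototypes
  gets membership split equally among the coinciding clusters.
* **Empty clusters.** A cluster with zero total membership mass is
  re-seeded from a random pixel and the event logged.
* **Reconstruction.** Grayscale geodesic reconstruction runs to its
  exact fixed point (the production path is scikit-image's propagation
  algorithm; tests assert exact agreement with the literal
  iterate-until-stable definition, plus the sandwich bounds,
  erosion/dilation complement duality, and idempotence). The composite
  operator used before clustering is closing-by-reconstruction followed
  by opening-by-reconstruction of its result; the composition order of
  the two composite operators is ambiguous in common notation, and this
  reading was chosen because the alternating filter removes bright and
  dark grains symmetrically, which is what the reconstruction is for
  here.

## Synthetic benchmark

Two phantoms drive the quantitative evaluation, both 256×256 with
pixel-aligned ground truth:

* **ST** (3 classes, 8-bit levels 0/85/170): equal vertical thirds plus
  a class-2 disk crossing the first band boundary and a class-0 square
  crossing the second.
* **SF** (4 classes, levels 0/85/170/255): 2×2 quadrants plus a
  centered class-3 disk crossing all four.

Only the class counts, intensities, and image size of these benchmark
images are externally fixed; the geometric layout is this package's own
(versioned) choice, made to include large flat regions plus straight
and curved boundaries, and defined in relative coordinates so phantoms
render at any size (the test suite uses 48–128 px). Consequences:
ASA cells dominated by intensity overlap (plain FCM or weakly smoothed
variants under strong Gaussian noise) depend on the class-area
proportions and reproduce external reference values only to within a
few percent (observed: up to ~0.08 on the worst cell), while
high-accuracy cells (≥ 0.95) and the ordering of the methods are
insensitive to the layout. Passing benchmarks therefore demonstrate
noise robustness on piecewise-constant imagery with known class count —
not performance on textured or intensity-inhomogeneous real images.

Noise conventions: "x% Gaussian" adds zero-mean noise of *variance*
x/100 on [0, 1]; "x% salt & pepper" replaces exactly round(x/100·N)
uniformly chosen pixels, half by 1 and half by 0 (odd counts favor
salt); Rician noise forms √((v+n₁)² + n₂²) with σ = level × brightest
intensity. Outputs are clipped to [0, 1], matching 8-bit camera/scanner
behavior and keeping all downstream operators on a closed range. The
clipping slightly deflates the *realized* noise variance at the extreme
classes; moment tests therefore use a mid-gray image.

## Evaluation protocol

ASA averages SA over seeded repetitions; repetition `rep` derives two
independent child seeds from `base_seed + rep` (one for the noise
realization, one for the initialization), so both randomness sources
are refreshed per repetition and every number in the package is exactly
reproducible from a single integer. The default for table reproduction
and the acceptance script is 20 repetitions — the per-cell standard
errors (reported alongside every mean) are already ≤ 0.02 there — with
the 100-repetition protocol one flag away.

## Known limitations

* Scalar (single-channel) intensities only; no color or multichannel
  guidance.
* 2-D images only; volumetric data must be passed slice-wise.
* The cluster count is an input, not estimated.
* Membership smoothing can flip a handful of isolated pixels at the
  highest-curvature boundaries even on noise-free input (SA 0.9999
  rather than 1.0 on clean phantoms for the GF variants).
* Convergence is monitored on the objective; for the GF variants the
  filtered objective is not guaranteed monotone (not observed to
  diverge, but oscillation near the fixed point can leave a run at the
  iteration cap, which is reported rather than raised).
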