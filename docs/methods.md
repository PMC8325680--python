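# Methods

## Problem and model

`leaftopo` identifies plant cultivars from single-leaf transmitted-light
images. Cultivars of the same species differ only subtly, so the
classifier combines three topological descriptor families with a
conventional image feature vector:

1. **Shape.** The binary leaf mask is swept by height functions
   h_θ(p) = ⟨p − c, (cos θ, sin θ)⟩ from 30 equally spaced directions
   (c = mask centroid; values normalised by the maximal radius so they
   lie in [−1, 1]). The degree-0 persistence diagram of each sweep
   records how marginal teeth and lobes merge, which encodes contour
   geometry direction by direction. Diagrams of three consecutive
   directions are stacked as the three channels of one input stream,
   keeping local directional context together; 30 streams in all.
2. **Texture.** The contrast-enhanced grayscale lamina, restricted to
   the leaf mask, is filtered by sublevel sets. Degree-0 classes are
   dark blotches, degree-1 classes bright rings; together they summarise
   the transmittance texture at all intensity scales.
3. **Venation.** The Euclidean distance transform of the binary vein
   network is filtered by sublevel sets. Degree-1 classes are areoles —
   closed vein loops — born at distance 0 and dying at the loop
   inradius, so the diagram encodes the loop-size distribution; degree-0
   tracks vein-network fragmentation across scales.

Each of the 34 streams (30 shape + texture PD0/PD1 + venation PD0/PD1)
passes through a ten-layer branch: a trainable vectorization input
layer, a 16-filter 1-D convolution, max-pooling **along the filter
dimension**, dropout, batch normalisation, ReLU, a second
convolution/pool/dropout block, and a dense layer to 256 units. The
34 × 256 = 8704-dimensional topological feature is concatenated with a
2048-dimensional image-branch vector (early fusion; 10 752 total) and
classified by dropout (0.5) → dense 2048 → batch norm → softmax.

Diagrams enter the network as fixed-capacity point lists: points are
mapped to (birth, lifetime), sorted by lifetime descending (longer-lived
classes carry more signal; near-diagonal points are mostly noise), cut
at 700 points per shape diagram and 1000 per texture/venation diagram,
and padded with (0, 0). The vectorization layer evaluates anisotropic
exponential structure elements

    out[j] = Σ_p exp(−(s_j0² (b_p − μ_j0)² + s_j1² (l_p − μ_j1)²))

with trainable centers μ and sharpness s (64 elements per channel,
initialised on an 8 × 8 grid over the expected (birth, lifetime) window,
sharpness = one inverse cell width). Padding points are masked out of
the sum, so capacity never leaks into the feature. This is the
exponential-structure-element core of trainable PD vectorization; the
logarithmic far-tail variant is deliberately omitted for simplicity.

When several growth periods of the same cultivar are available, one
model is trained per period and predictions are combined by score-level
fusion: G(X) = argmax (1/T) Σ_t g_t(x_t), the equal-weight average of
the per-period class-probability vectors. Argmax ties are broken toward
the lowest class index for determinism.

## Persistence computation

Persistence is computed on the V-construction cubical complex: pixels
are vertices, edges join 4-neighbours, squares fill 2 × 2 blocks, and
every cell carries the maximum of its vertices. Degree 0 is union-find
over pixels in increasing value order with the elder rule (ties broken
by processing order; the resulting diagram multiset is
order-independent). Degree 1 uses planar duality: holes of the sublevel
set correspond to 8-connected superlevel components of the complement,
including a virtual outside node, processed in decreasing order; a merge
at value v that kills a component born at value b emits the hole
(v, b). Both kernels are numba-compiled.

Conventions, chosen once and asserted by tests:

* **Zero-persistence pairs are dropped**; they are invisible to any
  downstream consumer and keeping multisets canonical makes the
  oracle comparison exact.
* **Essential classes are clamped** to the maximum finite filtration
  value and flagged, rather than dropped: top-k selection needs finite
  lifetimes and the global component's birth (the global minimum) is
  informative.
* Background pixels carry +inf and never enter the filtration; each
  4-connected finite component contributes exactly one essential
  degree-0 class.
* The filled mask (not the boundary curve) is filtered for shape;
  degree 0 only, since a filled mask has trivial degree-1 homology
  except for raster artifacts.

An independent oracle (`leaftopo.oracle.persistence_oracle`) computes
the same diagrams by explicit Z/2 boundary-matrix reduction over the
full complex, capped at 12 × 12 grids (it is cubic in the cell count).
The test suite asserts exact multiset equality with the union-find path
on hundreds of random quantized grids, plus closed-form cases (a 1 × 5
strip, a 3 × 3 ring, a rasterized square areole) and an
ε-perturbation stability bound checked with an exact bottleneck-distance
implementation (binary search + Hopcroft–Karp matching).

## Preprocessing

Segmentation is Otsu's global threshold (the leaf is dark on a bright
background under transmitted light; polarity is configurable), keeping
the largest 4-connected component and filling interior holes. Contrast
enhancement linearly stretches the within-mask 1st–99th percentile
range to [0, 1]; the background is set to 1.0. Venation is extracted
with a multiscale Sato (Hessian tubeness) ridge filter at scales
{1, 2, 4} px for bright ridges, hysteresis thresholding at the 0.85/0.97
within-leaf response quantiles, and removal of components under 20 px.
All of these are configuration knobs; the quantile pair was chosen so
that recovered veins overlap the generator's ground-truth skeleton with
recall well above 0.7 at 2 px tolerance across cultivars.

## Training recipe

RMSProp (ρ = 0.9) with initial learning rate 10⁻³; the rate halves
whenever validation loss fails to improve for five consecutive epochs;
the parameter snapshot with the smallest validation loss is returned.
Splits are stratified with test fraction 0.3 and validation fraction
0.1. Default batch size 32 and branch dropout 0.25 (both unconstrained
by the published recipe; the head dropout 0.5 and dense width 2048 are
fixed). The default epoch budget is 200; the synthetic experiments in
the tests and the acceptance script use 18–40 epochs, which is where
their validation loss plateaus at these problem sizes. All randomness
(initialisation, shuffling, dropout) derives from the run seed; repeated
runs with the same seed are bit-identical.

The image branch is pluggable. `stub` — the default and the only
backbone exercised by the tests — is a frozen, seeded random-projection
convnet ending in global average pooling to 2048 dimensions; it
satisfies the fusion interface deterministically and offline.
`xception_imagenet` / `xception_random` name pretrained-CNN transfer
learning and require an optional deep-learning framework; requesting
them without one installed raises a configuration error. The fusion
model also trains with the image branch ablated to a zero vector
(`use_image_branch=False`), which is the configuration used for all
PD-only experiments.

## Synthetic data

The generator replaces field-collected leaf scans for testing. A
cultivar is: a Fourier contour r(θ) = r₀(1 + Σ_{k≤6} a_k cos kθ +
b_k sin kθ); sawtooth margin serration (amplitude ≤ 0.055, 8–28 teeth);
a venation plan (midrib, 4–9 secondary veins per side at a 30–70°
branch angle, areole-bridging probability up to 0.6); and texture
statistics (lamina transmittance 0.28–0.44, vein contrast 0.16–0.34,
correlated noise of amplitude 0.02–0.10 and correlation length
1.5–4 px). Cultivar specs are rejection-sampled to a minimum pairwise
normalized distance (default 0.15, L∞ over range-normalised
parameters) so classes are learnable by construction. Growth periods
R1–R6 change only scale (0.60 → 1.00), elongation (1.00 → 1.22) and
degradation (disease spots and bright wormholes, probability rising to
R6), leaving cultivar identity in the contour/venation/texture — the
periods supply different but complementary views of the same class.

What the generator does **not** emulate: petiole and leaf-base
asymmetry, tertiary venation hierarchies, specular or vignetting
artifacts of real scanners, intra-cultivar biological variance beyond
i.i.d. noise and small rotations, and occlusions. Passing tests
therefore demonstrate that the pipeline recovers class structure that
is expressed through contour, serration, vein density/loops, and
texture statistics — not field-readiness on real scans.

Default experiment sizes — 5 cultivars × 40 images at one period for
recovery, 4 cultivars × 14 images × 3 periods for fusion, 128 px
canvas — keep a full from-scratch run of the suite and the acceptance
script to a few minutes each while leaving all accuracy bars far above
their chance levels (0.20 and 0.25).

## Numerical choices and degenerate inputs

* Lifetime-sort ties in point selection break by ascending birth, then
  death, so feature records are reproducible across platforms.
* An empty diagram yields an all-padding point set (n_real = 0) and a
  zero vectorization output, not an error.
* A uniform image raises a segmentation error; a constant-intensity
  lamina passes contrast enhancement unchanged with a warning; an empty
  vein mask after thresholding raises with advice to relax parameters.
* Sharpness parameters are projected to ≥ 10⁻³ after every optimizer
  step, keeping structure elements well-defined.
* Batch normalisation uses momentum 0.9 running statistics in
  evaluation mode; evaluation is therefore deterministic.

## Known limitations

* Degree-2 homology, 3-D stacks, and time-varying (vineyard)
  persistence are out of scope.
* The oracle is exponential-free but cubic; it exists for testing, not
  production use.
* The numpy layer stack is single-threaded and CPU-bound; it trains the
  34-branch model on hundreds of images in minutes but is not meant for
  datasets of thousands of high-resolution scans.
* Accuracy figures on synthetic data say nothing quantitative about
  accuracy on real cherry or soybean scans.
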