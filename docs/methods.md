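# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind the `ugfc` package. Notation: gray levels `z, y` on
`[0, L-1]` (default `L = 256`), memberships `mu`, centroids `v`, level-set
function `phi` (negative inside the contour).

## 1. Fuzzy contrast enhancement

Pointwise Mamdani inference with three rules (dark→darker, gray→gray,
bright→brighter), min-implication, max-aggregation and centroid
defuzzification over `p = min(L, 4096)` output grid points. Because the
map depends only on `z`, it is materialized once as an `L`-entry lookup
table; outputs are rounded half-up for image output and kept as floats
when feeding the clustering stage.

**Membership geometry.** The input sets are piecewise linear: *dark* is 1
on `[0, 64]` falling to 0 at 128; *gray* is a triangle on `[64, 191]`
peaking at 127.5; *bright* mirrors *dark*. The output sets are unit
triangles peaking at 0, 127.5 and 255 with half-width 64. Two properties
drove this geometry and are asserted by tests: the induced lookup table is
monotone non-decreasing, and an image occupying an interior intensity band
is expanded outward (`min` maps lower, `max` maps higher). Wider input
sets — e.g. a gray triangle spanning the whole range — make the mid-gray
output set dominate the centroid for almost every input and produce a
contrast-*reducing* map, which contradicts the stated intent of the rules;
the narrower overlap above is the simplest geometry that darkens
below-mid-range pixels and brightens above-mid-range ones. All knots are
configurable (`sets:` in the YAML config, `--sets` on the CLI).

A vanishing aggregated response cannot occur with covering sets; if custom
sets leave a level uncovered, that level maps to itself and a warning is
logged.

## 2. Unified gravitational fuzzy clustering

**Initialization.** Centroids are seeded at the modes of a Gaussian KDE of
the gray-level histogram, `p(x) = (1/Nh) sum_j psi((x - x_j)/h)`, computed
from the `L`-bin histogram (identical by linearity, O(L²) instead of
O(NL)). The bandwidth is scanned over 50, 49.5, …, 0.5 and the critical
bandwidth is the smallest value with exactly `c` strict local maxima; if no
scanned `h` gives exactly `c` modes, the `c` most prominent modes at the
smallest bandwidth are used (logged).

**Iteration.** With intensity distances `d_ij = |x_j - v_i|`:

1. fuzzy-c-means memberships, fuzzifier `w` (default 1.7, valid range
   (1.4, 2.6); ties at zero distance split equally);
2. hard core: pixels with `max_i mu_ij >= theta` (default 0.85) are
   hard-assigned to their best cluster. Hard status *accretes*: once a
   pixel has flowed into an object it stays hard — membership-qualified
   pixels keep tracking their best cluster, gravity-captured pixels keep
   the label their capture gave them. Without accretion, single borderline
   pixels oscillating between hard and fuzzy perturb the tiny fuzzy
   objective and make the product objective non-monotone between its first
   and final iterate;
3. gravity capture: a remaining fuzzy pixel is hard-assigned to cluster
   `i` when the Newtonian attraction `F_i = 2 m_i / d_i²` exceeds every
   competitor by the dominance factor `gamma` (default 2). `m_i` counts the
   cluster's hard pixels ("the quality of each pixel is 1"); `d_i` is the
   planar distance to the cluster's **nearest core pixel**, floored at one
   pixel spacing. Distance-to-nearest-core rather than
   distance-to-spatial-centroid matters for annular clusters: the
   background surrounding the head has its centroid *inside* the brain,
   and a point-mass model would capture interior pixels. A cluster is only
   eligible to capture a pixel it could plausibly own
   (`mu_ij >= 1/c`): gravity arbitrates genuinely controversial pixels
   (partial-volume interfaces), it does not override categorical
   non-membership;
4. centroid update `v_i = (sum_hard x + sum_fuzzy mu^w x) /
   (n_hard + sum_fuzzy mu^w)` — the stationary point of `J_GC + J_CM` for
   fixed assignments. The product objective `J_GFC = J_GC · J_CM` is
   monitored per iteration (each trace entry pairs an iteration's
   assignments with the centroids that generated them); when no pixel is
   hard, `J_GC := 1` so the product reduces to `J_CM`.

Convergence: `max_i |v_i(t+1) - v_i(t)| < rho` with `rho = 0.01` gray
levels, or `max_iter = 100` (flagged, not raised). The product objective
is monitored, not optimized jointly: the centroid update is stationary for
the *sum* `J_GC + J_CM` (stable, and exact in the k-means and FCM limits),
so on a few percent of phantom seeds the trade of a tiny absolute increase
in the minuscule fuzzy term against a large decrease in the hard term can
leave the final product ~1 % above its initial value. With `theta > 1` and
`gamma = inf` the loop reduces exactly to textbook fuzzy c-means, which an
independent implementation verifies to 1e-6.

**ROI extraction.** The lesion is taken as the cluster with the highest
centroid (hyperintense-lesion convention; `index:K` selects any other),
each pixel voting by hard label or argmax membership. An optional border
filter removes connected components touching the image edge (skull/scalp
suppression on real images). An empty ROI sets a flag and short-circuits
refinement rather than raising.

## 3. Level-set refinement

Gradient flow
`phi_t = beta (lap phi - div(grad phi/|grad phi|)) + lambda delta(phi)
div(g grad phi/|grad phi|) + nu g delta(phi)`
with edge indicator `g = 1/(1 + |grad(G_sigma * I)|²)` computed on the
*enhanced* image (the data the contour must lock to, rather than a
piecewise-constant cluster map). Discretization: central differences,
5-point Laplacian, replicate boundaries, `|grad phi|` floored at 1e-10;
explicit Euler with `beta · dt < 0.25` enforced. Dirac/Heaviside are the
cosine-regularized pair with half-width `eps = 1.5` grid units.

Defaults and why:

- `beta = 0.04`, `dt = 5` (stability product 0.2), `lambda = 5`,
  `sigma = 1.5`.
- `nu = 1.0`, the minimum of the admissible magnitude range [1, 3.5]. At
  an edge-locked front the shrink pressure `nu·g` balances the attraction
  `lambda · dg/dn` slightly *inside* the gradient valley; the weakest
  admissible pressure minimizes this systematic inward offset (measured
  ~1 px at `nu = 1.5` on phantom lesions of radius 9, costing ~0.02 Dice).
- `c0 = 8` for the binary-step initialization `phi = ±c0`. The far field
  plateaus at `|phi| = c0`, so `c0` must exceed the band (here `|phi| < 6`)
  in which the internal energy is expected to restore unit slope; small
  steps (e.g. `c0 = 2`) leave the whole plateau inside the band and the
  Eikonal property can never be met there.
- `max_iter = 400`, `min_iter = 300`, stop when the inside mask changes by
  fewer than 2 pixels over a 10-iteration window. The binary step needs a
  relaxation phase: the Dirac band is empty until the step diffuses, the
  front then overshoots inward and recovers to the edge equilibrium over
  roughly 250 iterations, so the stopping window is only consulted after
  the transient.
- `dirac="gradient"` replaces `delta_eps(phi)` by `|grad phi|` — the
  standard whole-domain extension. It is used for analytic benchmarks
  (pure curvature flow obeys `r(t) = sqrt(r0² − 2λt)` exactly for the zero
  set, whereas the regularized delta rescales the front speed by
  `delta_eps(0) ≠ 1`); segmentation always uses the cosine delta.

Contour splitting and merging are ordinary events; a single contour
enclosing two lesions splits into two components.

## 4. Evaluation

Dice, Jaccard, sensitivity, specificity from the pixelwise 2×2 table over
the full image grid (specificity's true negatives need a bounded
complement; the full grid matches the near-1 specificities typical when
background dominates). Zero-denominator metrics are reported as
null/None, never silently as 0. The identity `D = 2R/(1+R)` and exact
agreement with set-cardinality counting are tested on random mask pairs.

## 5. Synthetic phantoms — what they do and do not show

`make_phantom` renders flat-intensity tissue ellipses (background 10,
"gray matter" 90, "white matter" 140, a dark ventricle 40), lesion blobs
at 210 (radius 9 by default, placed randomly inside the white matter,
ventricle avoided), a 2nd-order polynomial multiplicative bias field of
±15 % peak amplitude, and additive Gaussian (or magnitude/Rician) noise
with σ = 8 — emulating a contrast-enhanced T1/FLAIR slice with coil
inhomogeneity. Identical spec + seed is bit-reproducible.

The phantom family exercises every failure mode the cascade addresses —
low contrast, smooth intensity non-uniformity, noise, multiple lesions —
but not anatomy: no cortical folding, no partial-volume texture, no
pathology-dependent intensity heterogeneity. Passing the phantom suite
demonstrates the algorithmic contract (parameter recovery, objective
behavior, edge locking, topology handling), not clinical accuracy.

Noise sensitivity is asserted as a monotone trend on the
*clustering-stage* overlap (σ ∈ {8, 24, 40}): the refinement stage
deliberately collapses noise-induced speckle, which keeps the end-to-end
Dice nearly flat over this noise range and would hide the trend.

## 6. Problem sizes

Defaults used throughout the tests and the acceptance script: 128×128
phantoms, 20 seeds for family statistics, 10 small 1-D datasets
(n ≤ 200) for the fuzzy-c-means limit, 800 explicit steps for the
curvature-flow benchmark. The full test suite runs in ~20 s and the
acceptance script in ~10 s on one CPU.

## 7. Known limitations

- Single 2-D slices only; no volumetric clustering or 3-D level sets.
- The lesion is identified as the brightest cluster — a convention for
  hyperintense lesions, not a learned rule; hypointense lesions need
  `index:K`.
- Cluster count `c` is user-set (default 4); the critical-bandwidth scan
  seeds centroids but does not select `c`.
- Bias fields are handled only implicitly (enhancement + fuzzy
  memberships absorb moderate inhomogeneity); there is no explicit
  bias-field correction.
- The edge-locked contour equilibrium sits a fraction of a pixel inside
  the gradient valley, a small systematic erosion visible on noiseless
  phantoms.
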