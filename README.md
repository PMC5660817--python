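# ugfc — brain-lesion detection by unified gravitational fuzzy clustering

`ugfc` segments hyperintense brain lesions on single 2-D MR-like gray
images (T1/FLAIR-style contrast) with minimal user input. It is aimed at
researchers prototyping lesion-detection pipelines and at anyone who needs
a fast, fully automatic, deterministic baseline segmenter with a built-in
synthetic ground truth — no patient data or downloads are required to run,
test or validate it.

The method is a three-stage cascade:

1. **Fuzzy rule-based contrast enhancement.** Three Mamdani rules — *IF a
   pixel is dark THEN make it darker; IF gray THEN keep it gray; IF bright
   THEN make it brighter* — fire with strength `min(mu_s(z), mu_out(y))`,
   are aggregated by `max`, and the crisp output is the center of gravity
   `y0 = sum(y Q(y)) / sum(Q(y))` on a discrete output grid. The transform
   depends only on the gray level, so it is applied as a lookup table.

2. **Unified gravitational fuzzy clustering (UGFC).** Gray levels are
   clustered with `c` centroids seeded at the modes of a Gaussian kernel
   density estimate of the histogram at the critical bandwidth (the
   smallest `h` with exactly `c` modes). Unambiguous pixels
   (`max_i mu_ij >= theta`) are hard-assigned; ambiguous pixels keep
   fuzzy-c-means memberships `mu_ij = [sum_k (d_ij/d_kj)^(2/(w-1))]^-1`;
   and a Newtonian gravity rule `F = 2 m_i / d^2` lets a massive, spatially
   adjacent cluster capture controversial pixels. The monitored objective
   is the product `J_GFC = J_GC * J_CM` of the hard (k-means-style) and
   fuzzy objectives. The brightest cluster is extracted as the lesion
   region of interest.

3. **Reinitialization-free level-set refinement.** The ROI boundary
   evolves under
   `phi_t = beta (lap phi - div(grad phi/|grad phi|)) + lambda delta(phi)
   div(g grad phi/|grad phi|) + nu g delta(phi)`,
   with edge indicator `g = 1/(1 + |grad(G_sigma * I)|^2)`. The first term
   keeps `phi` an approximate signed distance function (`|grad phi| = 1`),
   so the cheap binary-step initialization needs no reinitialization; the
   contour locks onto the lesion edge, and splits or merges freely.

Predicted masks are scored against ground truth with Jaccard
`R = TP/(TP+FP+FN)`, Dice `D = 2TP/(2TP+FP+FN)`, sensitivity and
specificity.

## Worked example

```bash
python examples/full_detection.py
```

builds a 128×128 head phantom (tissue ellipses at gray levels 10/90/140/40,
one 9-px-radius lesion blob at 210, ±15 % polynomial bias field, Gaussian
noise σ = 8) and runs the cascade:

```
stages: enhance -> cluster -> refine
clustering: 3 iterations, centroids [21.2, 84.2, 141.7, 233.9]
level set:  300 iterations
overlap: Dice 0.926  Jaccard 0.863  Se 0.863  Sp 1.0000
```

The four centroids recover background, gray matter, white matter and the
lesion; the lesion is the brightest cluster, and the refined contour
overlaps the generated truth at Dice 0.93. `examples/` holds one script
per stage (`enhance_phantom.py`, `segment_phantom.py`,
`refine_contour.py`) printing the intermediate quantities.

The same cascade is scriptable from a shell:

```bash
ugfc phantom -o img.png --truth truth.png --seed 4
ugfc detect img.png -o mask.png --truth truth.png --metrics scores.json
ugfc eval truth.png mask.png -o scores.json
```

with `enhance`, `segment` (writes the `t, J_GC, J_CM, J_GFC, v_i,
hard_count` trace as CSV) and `refine` exposing the individual stages.
Exit codes: 0 success, 2 validation error, 3 numerical failure, 4 empty
region of interest.

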