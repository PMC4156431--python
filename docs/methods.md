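# Methods

This note documents the models, conventions and numerical choices behind
`ftlquant`, and what the synthetic tests do and do not demonstrate about
real tissue data.

## Thresholding model

A label pixel is "positive" when its intensity strictly exceeds
`mean + k·SD` of a reference pixel sample, with `k = 2` by default and the
SD using the n−1 (sample) denominator. Ties at the cutoff are negative.
Two provenances for the reference sample are implemented:

* **`global_aggregate`** (default): the pooled multiset of every pixel
  inside every section's traced ROI, across all groups and levels. This is
  the deliberately non-local step of the pipeline: it normalizes staining
  and preparation variability between animals, at the documented cost that
  adding or removing a section changes every mask in the run. Because the
  pool is a mixture of background and label, the cutoff rises with label
  abundance; at the default scene parameters it lands far above background
  and well below cell intensity, so masks equal the planted label almost
  exactly.
* **`per_image_background`**: per-section cutoff from that section's
  non-label ROI pixels (synthetic mode only, where the truth defines
  "non-label"). This cutoff sits at background mean + 2 SD, so ~2.3 % of
  background pixels cross it. Isolated false positives fall below the
  detector's area band, but they can bridge the small gaps between dense
  β-gal somata and their processes and merge components — an inherent
  property of low thresholds on dense cytoplasmic label, visible in the
  pipeline as β-gal undercounting. The pixel metrics are unaffected in any
  meaningful way; c-Fos counting, whose nuclei are widely spaced, is
  robust.

## ROI rasterization

Polygons are ordered `(x, y)` vertex lists, 0-based, `x = column`,
implicitly closed. A pixel `(i, j)` (center `(j + 0.5, i + 0.5)`) belongs
to the ROI iff its center is inside the polygon under the even-odd rule;
boundary ties resolve half-open (centers on a left/top edge are inside, on
a right/bottom edge outside). Consequences that the tests rely on:

* an axis-aligned square with corners (0,0)–(10,10) covers exactly 100
  pixels;
* polygons sharing an edge tile the plane — masks are exactly additive;
* vertex-order reversal changes nothing.

Self-intersection is rejected (checked with shapely); rasterization itself
is a short scanline fill whose semantics are pinned by an independent
per-pixel crossing-number oracle in the test suite. ROI transfer between
channels copies vertex coordinates verbatim (channels are co-registered by
acquisition) after validating that the channel rasters share dimensions.

## Cell detection and double labels

Detection is connected-component labeling (8-connectivity by default) of
the thresholded mask restricted to the ROI, keeping components whose
in-ROI area lies in `[min_area, max_area]`. Defaults are derived from the
scene geometry as [0.5×, 2×] the nominal rendered body area — the nucleus
disk for c-Fos (37 px at radius 3), the soma disk for β-gal (97 px at
radius 5, the 2× bound absorbing the radiating processes). The lower bound
is what excludes sub-nuclear punctate label (9 px at radius 1), replacing a
human judgement of "too small to be a nucleus" with a reproducible rule.
Components clipped by the ROI boundary are kept if their in-ROI area fits
the band.

A cell is double-labeled when at least `overlap_fraction_for_double` of
its pixels are also positive in the other channel's mask. The criterion is
asymmetric by geometry: a nuclear c-Fos disk inside a β-gal soma is fully
covered (fraction ≈ 1), while the soma is only fractionally covered by the
nucleus (≈ the nucleus/soma area ratio, 37/97 ≈ 0.38 at the defaults). The
c-Fos detector therefore uses 0.5 and the β-gal detector half the area
ratio (≈ 0.19), so both one-sided populations — c-Fos cells without β-gal
and β-gal cells without c-Fos — are counted correctly.

No watershed splitting is attempted: touching cells merge and fall out of
the area band. The generator is built so planted cells never touch (see
below); on real tissue this is a genuine limitation.

## Statistics

The analysis unit is one response per animal per level. Only balanced
designs are accepted (equal replicates per group × level cell) — this
removes the Type-I/II/III sums-of-squares ambiguity entirely; unbalanced
input raises an error rather than silently choosing a decomposition.
The classical fixed-effects decomposition is used with df
`(a−1), (b−1), (a−1)(b−1), ab(n−1)`; for the default 4 × 3 design with
n = 3 animals this gives F(3, 24), F(2, 24) and F(6, 24). p values come
from the F distribution's upper tail. A zero residual mean square flags
the fit degenerate (infinite F for effects with positive mean square)
rather than erroring; Tukey comparisons on a degenerate fit do error.

Tukey HSD uses `q = |ȳᵢ − ȳⱼ| / √(MS_residual/m)` with `m` responses per
marginal mean and adjusted p from the studentized range distribution at
the residual df (`scipy.stats.studentized_range`, numerical tail
integration; verified in the tests against a direct double-quadrature of
the studentized-range integral to 1e−6). α = 0.05 by default, configurable
in the run config. Level is treated as a plain crossed factor, not as a
repeated measure within animal; no nonparametric alternatives are offered.

## Synthetic scenes

The generator emulates the staining structure the analysis assumes, not
optics: no point-spread function, bleed-through, illumination gradients,
stitching seams or 3-D structure. Per channel:

* **c-Fos** — disk nuclei (radius 3 px) plus smaller non-specific puncta
  (radius 1 px), both at the cell intensity;
* **β-gal** — filled cytoplasmic somata (radius 5 px) with two 1-px-wide
  radiating processes 2–4 soma radii long, emulating dense tau-shuttled
  label;
* **Nissl** — the region of interest at +8 background-SD intensity so the
  boundary is traceable without consulting the label channels.

The ROI is an irregular star-shaped polygon (24 vertices, smooth harmonic
radius perturbation), inset `roi_margin` px from the border. Noise is
independent per-pixel Gaussian (default mean 100, SD 10 in 16-bit camera
counts) truncated at zero; label pixels carry the cell intensity (default
600 = 50 background SDs) plus the same noise. Images default to
320 × 320 px, sized so the densest scenario rows (~85 bodies) stay near a
quarter of the rejection-sampling jamming density.

Placement is rejection sampling inside the ROI eroded by one soma radius
(+2 px guard), with minimum centroid separation of one soma diameter plus
a 3 px guard — at exactly one diameter, integer-rasterized disks can touch
and become 8-connected, which would corrupt the planted truth. Processes
are drawn after all somata and stop before leaving the ROI or becoming
8-adjacent to another cell's pixels, so planted components never merge and
the truth sidecar (rendered-pixel centroids and areas per cell, exact
label-area fractions) describes the image bit-for-bit. Double-labeled
cells share their planting site across channels; their count is
`round(f · min(n_cfos, n_bgal))` for fraction `f`.

Study generation derives per-row seeds from `SeedSequence([base_seed,
row_index])`, making studies reproducible bit-for-bit. With
`poisson_counts` (the pipeline default) the configured per-row counts are
Poisson means, supplying the between-animal variability the ANOVA residual
needs — without it every between-group test would be degenerate.

### Scenarios

* **`paper-pattern`** — β-gal means graded by level (Rostral 55,
  Intermediate 40, Caudal 25), identical across groups; c-Fos mean 10
  everywhere except ×3 (30) in the MSG group. The gradient steps are
  deliberately well separated: at n = 3 animals per group a ~7-cell step
  sits on the Tukey significance boundary and the planted ordering would
  be unrecoverable by design, which would test luck rather than the
  pipeline.
* **`null`** — flat means everywhere (c-Fos 10, β-gal 40): no planted
  effect.
* **`custom`** — every row uses the base scene parameters unchanged.

### What passing tests show — and don't

Perfect recovery (counts exact, centroids to machine precision, percent
labeled to within rounding) holds at the default high signal-to-noise
settings where planted bodies are bright, compact and non-touching. Real
tissue has touching cells, intensity gradients within and between somata,
section-to-section staining differences and genuinely ambiguous small
bodies; the synthetic results bound what the *algorithmic* chain does with
unambiguous input, not what an antibody does in tissue. The scenario
detection rates are statements about the planted effect sizes at n = 3,
not about biological effect sizes.

## Numerical conventions

* Intensities stored as uint16, clipped to [0, 65535] after rounding.
* Threshold cutoff preserved as the exact identity
  `cutoff = mean + k·sd` of the stored sample moments.
* Binarization is strict (`>`); percent labeled is `100·above/roi` in
  float64.
* Centroids are unweighted pixel centroids in (x, y) index coordinates.
* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  identical configs reproduce identical CSV bytes.
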