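# Methods

This note documents the models, parameter choices and known limitations of
`slidequant`. Everything quantitative stated here is computed by the test
suite or the scripts in `examples/` and `scripts/`.

## Slide model and coordinates

A whole-slide image is a pyramid: the same scene at strictly decreasing
magnifications, stored as a multi-page TIFF. Layers are matched to a request
by minimizing |log(m/target)| — magnification is a multiplicative scale, so
closeness is measured in log-ratio, with ties broken toward the higher
magnification. Pages without magnification tags get magnifications from their
width ratio to the largest page, whose nominal magnification is configurable
(default 40, a common scanner setting). All rasters are row-major, 0-based,
origin top-left, half-open pixel intervals. Package outputs (tiles, masks,
thumbnails, pyramids) are always lossless, even when the source used
JPEG-in-TIFF pages.

## Masking

The mask marks what is analyzed (white/keep) versus hidden (black/hide). It
is generated from a miniature layer (default target 1.25x): Gaussian blur
(sigma 2 px at mask scale) suppresses dust, then every pixel whose blurred
color lies within Euclidean RGB distance `fuzz * sqrt(3)*255` of reference
white (default fuzz 0.10, reference (255,255,255) or the modal border color
on request) is hidden. Keep-speckles under 50 px are dropped. The rule is a
global color-distance selection, not a flood fill, so enclosed white holes
(lumen, tears) are hidden too. Blur and fuzz are deliberately non-stringent:
the keep region dilates about one mask-pixel past the true tissue boundary,
which errs on the side of keeping tissue.

Masks round-trip through ordinary image editors (8-bit PNG, binarized at 50%
luminance on load); a shape check on load guards against mask/slide mix-ups.
One deliberate deviation from a literal "background replaced with black":
when hidden pixels are composited into tiles they are filled with reference
*white*, because black pixels carry maximal optical density and would be
detected as tissue by the inversion step downstream.

## Tiling

The analysis layer (default target 20x) is partitioned into a
ceil(W/T) x ceil(H/T) grid of square tiles (default T = 2048; edge tiles are
smaller). The mask is laid over the layer by nearest-neighbor pixel-center
sampling — equivalent to upscaling the whole mask, but touching only
O(tile area) memory per tile. Tiles with keep fraction below `min_keep`
(default 0.01) are excluded entirely. Tiles do not overlap and are analyzed
independently; objects touching tile borders are *kept* (discarding them
would systematically undercount at seams), at the cost of occasionally
counting a seam-straddling nucleus in both tiles or dropping one whose halves
each fail the size gate. On synthetic slides this seam effect is within a few
objects per hundred and is identical across replicate scans, so it cancels in
agreement statistics.

## Detection

Optical density uses OD_c = -log10((v_c+1)/(I0_c+1)), clipped at 0; the +1
regularization keeps zero pixels finite. Unmixing solves the per-pixel least
squares problem onto the stain basis (default: published Ruifrok–Johnston
DAB and hematoxylin OD vectors, unit-normalized, config-overridable),
clips negative amounts, and rescales by c_max = 1.5 OD so that the absolute
threshold bounds 0.5/1.0 are meaningful on a [0,1] concentration scale.

The DAB channel is thresholded by exhaustive three-class Otsu over all
ordered histogram-boundary pairs (256 bins over [0,1]). The default
criterion minimizes the weighted sum of within-class entropies,
`sum_k w_k * H_k` with H_k the entropy of the class-normalized histogram;
algebraically this reduces to minimizing `sum_k w_k log w_k`, which the
implementation exploits (the brute-force oracle in the tests uses the
unreduced definition). A weighted intra-class variance criterion is also
provided. One consequence of the entropy criterion worth knowing: across
empty histogram gaps the criterion is flat, and the lowest tied boundary
pair wins. With the middle class assigned to the foreground the operative
raw threshold is t_low; the final threshold is
clamp(1.3 * t_low, 0.5, 1.0). On near-constant channels (blank tiles),
where three-class search is undefined, the lower clamp bound is used
directly — it yields zero foreground on blanks.

Declumping seeds are local maxima of the Gaussian-smoothed channel
(sigma = suppression_radius/2, suppression_radius defaulting to half the
minimum diameter, 4 px), taken as maximum-filter equality over the
suppression window. Connected plateaus of maxima count as *one* seed —
otherwise any large uniform blob would shatter into nucleus-sized watershed
fragments. Components without a seed are seeded at their maximum, then a
watershed on the negated intensity, constrained to the foreground, assigns
every foreground pixel to exactly one object. Objects with equivalent
diameter outside [8, 26] px are removed entirely.

Tissue is segmented from grayscale luminance smoothed with a Gaussian of
20 px "diameter"; the diameter-to-sigma mapping is not standardized, so it is
explicit config with default sigma = diameter/4 = 5. The inverted image is
thresholded at an absolute 0.03 and components under the 40 px gate removed.
The 40 px gate is read as minimum *equivalent diameter*, consistent with the
nucleus gate's convention; an area reading would be far weaker (40 px^2
roughly equals a 7 px diameter). DAB objects that do not touch tissue
foreground are discarded (densities are "per tissue area"), switchable.

## Statistics

Per-slide totals are sums over tiles, and density = total count / total
tissue area — the tissue-weighted estimate, not a mean of per-tile ratios.
Densities are compared across runs on the log(0.0001 + x) scale (natural
log; the offset keeps empty slides finite and damps log-noise at very low
counts). ICC is the two-way ANOVA consistency form
ICC(3,1) = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err); "two-way mixed,
single measures" is ambiguous between consistency and absolute agreement, so
both are implemented (consistency is the default, matching the single-
measures consistency line of the usual R implementation). Bland–Altman bias
is the mean difference, limits of agreement bias ± 1.96 sd, and pairs with
|difference| > 0.50 on the log scale are flagged for manual mask review.

## Synthetic slides

The renderer is the package's ground-truth instrument. Tissue is a smoothed
Gaussian random field thresholded at a coverage quantile (default 35%),
keeping the largest blobs (default 2, length scale 40 px). Hematoxylin
(0.3 OD) covers tissue; each nucleus is a disk with diameter drawn from
8–24 px carrying DAB with a mild radial profile, 0.8 OD at the rim rising to
1.3x at the center — the central peak is what makes touching nuclei
separable by intensity. Nuclei composite by pointwise maximum (cells exclude
each other spatially; additive composition would make clump overlaps the
intensity maxima and defeat intensity declumping by construction). Clumped
pairs share a diameter and sit at 0.7x the sum of radii: overlapping but
bimodal. With very unequal members that placement would bury the small
nucleus inside the large one, which is why members are equal-sized. Pixels
follow I_c = I0_c * 10^(-sum_s c_s v_s,c) with Gaussian sensor noise added
after, and the pyramid holds exact 2x and 32x block means of the top layer.

The canvas is rendered at the analysis magnification (top layer 20x, pyramid
20x/10x/0.625x): nucleus diameters are thereby specified in the same pixels
the 8–26 px detection gate sees. Re-scans (`render_replicate`) keep geometry
and truth fixed and redraw sensor noise plus a global illumination scale
uniform in ±1%.

What the renderer does *not* emulate: real chromatin texture, focus blur,
stain heterogeneity within a nucleus beyond the radial profile, section
thickness variation, or scanner stitching seams. Passing truth-recovery
tests therefore shows the pipeline's logic is correct under the stated
optical model, not that the default thresholds are optimal for any
particular real stain batch.

Artifacts are maskable insults stamped after staining: an air bubble (a
broken dark rim rendered as stain pooled at the bubble edge, placed at the
point farthest from tissue and nuclei), a coverslip shadow (15% darkening
along one edge) and a pen mark (saturated stroke). Their bounding boxes are
recorded in the ground truth; none of them alters nucleus pixels, so the
truth count is invariant.

## The replicate-agreement experiment

`scripts/acceptance.py` renders 40 slides (seeds `seed..seed+39`, 1024x1024
canvas, nucleus counts uniform in 0–400, 10% clumped, tissue coverage 50% so
the densest slides remain placeable at realistic packing), scans each twice
(noise sigma 2 intensity units, ±1% illumination, rescan seeds offset by
1000 and 2000), runs the full mask→tile→detect→combine pipeline (tile size
512 at this canvas) on all 80 renders, and computes ICC(3,1) of the
log-transformed densities. Problem sizes are desk-scale stand-ins for
archive-scale slides; the experiment is deterministic given `--seed`.

## Degenerate inputs and tie-breaks

- Three-class Otsu requires >= 3 distinct values; blank tiles fall back to
  the lower clamp bound.
- Zero tissue area flags the slide density as undefined rather than dividing
  by zero; the replicate experiment treats such runs as density 0.
- Argmin ties in the Otsu search resolve to the lowest (t_low, t_high) pair
  in lexicographic bin order; layer-selection ties resolve to the higher
  magnification; watershed label order follows seed raster order.
- `rename_slide` never overwrites: after any call, source XOR destination
  exists.

## Known limitations

- Only pyramid TIFF is read natively; proprietary scanner containers must be
  converted upstream.
- Counts across tile seams can differ by a few objects from a seam-free
  analysis (see Tiling).
- The ICC here has two raters (two runs) and no missing data; unbalanced or
  k>2 designs with missing cells are out of scope.
- Automatic artifact recognition is deliberately absent: bubbles, pen marks
  and control tissue are handled by manual mask edits, which the mask
  round-trip supports.
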