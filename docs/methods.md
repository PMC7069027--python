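# Methods

## The recognition model

The pipeline assumes a nadir RGB photograph of a wheat canopy at the
grain-filling stage, when spikes have yellowed while leaves remain green.
All color reasoning happens in chromatic coordinates
`r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B)`; dividing out total
intensity removes the first-order effect of illumination, and makes the
three indices bounded: `Eg = 2g − r − b = 3g − 1 ∈ [−1, 2]`,
`Dgr = (g − r)/(g + r) ∈ [−1, 1]`, `Dgb = (g − b)/(g + b) ∈ [−1, 1]`.
Pure-black pixels (deep shadow) carry the neutral chromatic value (⅓, ⅓, ⅓)
rather than failing; zero denominators in `Dgr`/`Dgb` yield 0, the
no-evidence value.

Feature usefulness is quantified as the overlap coefficient
`Σ_bins min(p₁, p₂)` between per-class histograms on shared bins (64 bins
by default); a feature is selected when its smaller overlap against either
confounder class falls below 0.3.  On scenes with the assumed color
structure this selects `{Eg, Dgr}` and rejects `Dgb`.

Classification operates on superpixels, not pixels: SLIC (via
scikit-image, CIELAB color space, 10 iterations, connectivity enforced)
partitions the image into locally homogeneous blocks; each is summarized
by the arithmetic mean of its index values.  The canonical segment count
is 10000 at 2592 × 1944 and scales with image area (`scale_n`, floored at
16).  Training labels come from a reference mask by the strict 0.8 rule: a
superpixel is positive when more than 80% of its pixels are spike pixels
(exactly 0.8 is negative).

Twelve classifier variants run over standardized `(mean_Eg, mean_Dgr)`:
SVMs with linear, quadratic (coef0 = 1), cubic and Gaussian kernels — the
Gaussian kernel scale s set to √P/4, √P or 4√P with P the number of
predictors, entering scikit-learn as `gamma = 1/s²` — and KNN with
k = 1/10/100, Euclidean, cosine or Minkowski-3 metrics, uniform or
distance weighting.  Standardization is fitted inside each training fold of
a stratified 5-fold cross-validation; the variant with the highest mean
accuracy wins, ties resolved by listing order.  SVM box constraint is the
scikit-learn default C = 1.  A resubstitution (apparent-accuracy)
diagnostic exists because some published tables report training-set
accuracy.  A pixel-wise control path thresholds `Eg` and `Dgr`
independently at their Otsu values and intersects the two masks
(intersection, because `Eg` alone cannot reject leaves; union is available
behind a flag).

## Counting

The predicted mask is opened with a disk and components below an area
floor are dropped.  Connected components (8-connectivity, so diagonal awn
contacts do not split a region) give `n_region`; component axes come from
the second central moment tensor (axis length 4√eigenvalue, the
normalization under which a solid ellipse recovers its own axes; the minor
axis is floored at the 1-px-strip value 4/√12 so elongation stays finite).

Overlap screening flags a region when its area exceeds 1.25 × the median
region area or its elongation exceeds 4.5.  The screen is deliberately
permissive: a straight single spike flagged by mistake contributes zero
inflections, while a fused pair that escapes screening is an
uncorrectable undercount.  With realistic spike-size spread (largest ≈ 2.5
× smallest by area) fused pairs of small spikes sit only ~1.4 × above the
median, which is why the area factor is 1.25 and not higher.  With a
single region the median equals its own area and only the elongation rule
can fire.

Each candidate's skeleton (`skeletonize`) is reduced to a pixel graph;
endpoint chains shorter than the spur length hanging off branch points are
deleted iteratively, and the backbone is the geodesic between the two most
distant remaining pixels (double BFS, lexicographic tie-breaks, so the
result is deterministic).  Along the backbone, incoming and outgoing
tangents are chords to points ±window steps away.  Three numerics choices
make the turning angle robust on masks assembled from superpixels, whose
boundaries carry segmentation-scale lobes: the chain is lightly
pre-smoothed (uniform filter, 3 samples) against single-pixel staircase;
the angle is also measured with chords of twice the window and the smaller
of the two values used, since a genuine fusion bend persists at the
coarser scale while boundary wiggle collapses; and bends closer than two
windows to a chain end are not counted at all — they cannot be
scale-validated there, and terminal hooks are segmentation artifacts (a
real fusion elbow sits at least one spike arm from the end).  Inflections
are local maxima of the scale-stable turning angle above the threshold,
kept greedily in descending order with a minimum chain-distance
separation.  `n_point` sums candidate inflection counts; non-candidates
contribute zero; the image total is `n_region + n_point`.

Two default parameter sets exist, both config keys throughout:

| parameter | function default | pipeline default | units |
|---|---|---|---|
| open_radius | 2 | 5 | px |
| min_area | 100 | 1200 | px |
| area_factor | 1.25 | 1.25 | — |
| elongation_limit | 4.5 | 4.5 | — |
| window | 7 | 12 | chain steps |
| angle_threshold | 35 | 40 | degrees |
| min_separation | 10 | 25 | chain steps |
| spur_length | 4 × open_radius | 24 | px |

The function defaults suit thin, smooth masks (and are the settings under
which the bend-recovery guarantees are tested); the pipeline defaults are
matched to the default synthetic geometry (spike width 24–38 px,
superpixel ≈ 11 px across): the opening radius is about a quarter spike
width, the area floor is below half the smallest spike, and the tangent
window and suppression distance span a junction smear (≈ one spike width).
Junction blur costs a measured bend 10–20°, so the 55–80° leaning elbows
arrive at the detector around 40–65°; the 40° threshold catches them while
the scale-validation rules above reject what boundary raggedness is left.
These values were calibrated on a development batch of scenes against
ground truth and then validated on disjoint seeds.

Evaluation: `A = (1 − |N_c − N_a|/N_a) × 100%` per image (negative when
the automatic count misses by more than the benchmark itself; reported
as-is), Pearson r and OLS of automatic on manual counts via
`scipy.stats.linregress`; r is NaN (without aborting the accuracies) when
either coordinate has zero variance.

## The synthetic canopy generator

No photographs ship with the package, so scenes are synthesized with full
ground truth (per-spike masks, class map, count, touching groups).  The
default frame is 972 × 1296 — a quarter (by area) of the 2592 × 1944
reference photograph — with 30 spikes and 40 leaves.  Spikes are capsules
(120–200 px long, 24–38 px wide) with ten 1-px awn strokes fanning from
the tip; leaves are quadratic-Bezier strips (180–380 × 10–20 px); soil is
textured background.  Non-overlapping spikes keep a guard gap of 8 px.
With probability 0.15 a new spike is instead leaned against an existing
spike's end at a relative angle of 55–80°, intersecting 5–50% of the
smaller mask; touching chains are capped at three.  The angle range
matters: junction blur reduces a measured bend by 10–20°, so leaning
angles much below ~50° are not resolvable by any threshold that still
rejects boundary wiggle — the generator models the clearly-leaning
overlaps the inflection rule is designed for.

Colors are Gaussian per class in 8-bit RGB with three variance components:
a per-pixel SD, a per-organ SD (a constant channel offset per rendered
instance), and a low-frequency multiplicative brightness texture shared by
all three channels (which cancels exactly in chromatic coordinates,
modelling illumination rather than hue).  The split matters: per-pixel
noise averages away inside a superpixel (≈ 126 px), while organ-to-organ
variation does not, so the per-organ share is what limits superpixel-level
separability — as plant heterogeneity does in nitrogen-starved stands.
Four named regimes emulate a fertilization gradient.  Class means are
designed in chromatic coordinates: soil always has r > g (mean Eg ≈ −0.10,
Dgr ≈ −0.32); spike and leaf Dgr means converge from (0.05, 0.25) at N4 to
(0.06, 0.10) at N1 while the organ-level variation grows; all classes
share a Dgb mean near 0.41.  Measured on 10⁵ sampled pixels, leaf-spike
Dgr separation is ≈ 6.4 / 4.4 / 2.0 / 0.63 pooled SDs along N4 → N1, and
all pairwise Dgb overlaps exceed 0.6 at N4.

The pipeline default `superpixel_n` is 10000 on this geometry (not the
area-scaled 2500): the scenes are half-linear-scale, and the method's
premise requires spikes to span 2–3 superpixels across, as they do at the
reference configuration.  `superpixel_n=None` restores area scaling for
full-size photographs.

What the generator does not model: perspective and mutual occlusion
ordering, specular highlights and shadows, wind blur, awn texture inside
spikes, soil debris, and real plant-architecture correlations.  Passing
tests therefore demonstrate the internal consistency and parameter
recovery of the pipeline under its own color assumptions, not performance
on field photographs.

## Problem sizes and determinism

Everything is seeded: scenes via PCG64 from `SceneConfig.seed`
(`generate_dataset` uses base_seed + index), cross-validation via
`StratifiedKFold(shuffle=True, random_state=seed)`; identical inputs give
bit-identical scenes and CSVs.  The test suite validates counting on 100
perfect-mask trials covering 1–50 spikes and runs the full pipeline on 20
scenes per treatment; `scripts/acceptance.py` uses 10 evaluation scenes
per treatment, 3 training scenes, a 40-trial counting oracle and a
2400-record classifier comparison — sizes chosen so the whole study re-runs
in minutes on one CPU.  The classifier-comparison record sets are
subsampled to a fixed 35% positive fraction at fixed n and seed, because at
raw scene frequencies (~10% positive) the weakest variants collapse to the
majority rule and treatment differences become invisible.

## Known limitations

- Counting accuracy degrades when fused groups exceed three spikes or lean
  at shallow angles; the backbone traverses one path through a clump, so
  star-shaped clusters under-count.
- The area-median screen assumes most regions are single spikes; images
  dominated by fusions shift the median and weaken the screen.
- The N1 regime deliberately breaks the color assumptions (that is its
  point); counts there are unreliable, mirroring the method's stated
  domain of validity.
- Indices are undefined-by-convention on black pixels; scenes with heavy
  shadow push those conventions harder than the generator does.
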