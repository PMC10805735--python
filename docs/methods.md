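# Methods

## The measurement

`nucleoshell` quantifies how a fluorescent signal distributes relative to a
core–shell nuclear condensate (the nucleolus: fibrillar core, granular
shell).  The central quantity is the boundary-normalized radial profile:
for each nucleolus, intensity is sampled along rays from the centroid of
the nucleolar outline, and each sample at radius *r* along a ray is
assigned the normalized distance

    d = r / r_b(θ),

where *r_b(θ)* is the distance from the centroid to the outline along that
ray.  Thus *d* = 1 is the boundary regardless of condensate size or shape,
*d* ∈ [0, 0.5] is the deep interior ("inside"), and *d* ∈ [1.5, 2] the
surrounding nucleoplasm ("outside").  Window means over those two bands,
one number per nucleolus per band, feed the hypothesis tests; profiles are
additionally binned (40 bins over [0, 2]), optionally smoothed by a
centered moving average, and aggregated across nucleoli (per-bin mean and
sample s.d., the nucleolus being the sampling unit, pooled across cells).

### Numerical choices

* **Outline and boundary radius.** The outline is the filled territory of
  the shell marker (ring plus enclosed core).  *r_b(θ)* is the first
  inside→outside crossing of the label along the ray, located to sub-pixel
  precision by linear interpolation of the bilinearly sampled mask
  membership; later re-entries are ignored for *r_b*, but samples beyond
  the first crossing that fall back inside the label stay valid with their
  *d*.  On pixelated disks the estimator is unbiased to < 0.15 px with
  excursions bounded by pixelation (≈ 0.5 px at radius 20 px).
* **Compartment-restricted interpolation.** Intensity samples use bilinear
  interpolation whose weights are renormalized over the pixels lying on
  the same side of the profiled outline as the sample (inside for
  *d* ≤ 1).  Plain bilinear interpolation smears intensity across a sharp
  boundary and biases the bins adjacent to *d* = 1 by order
  (1 px / bin width in px), which at realistic condensate radii
  (bin width 0.05 · r_b ≈ 1–3 px) is a 10–40 % error in those bins; the
  restricted scheme removes the bleed and is exact on constant images.
  Plain interpolation is available via `boundary_aware=False`.
* **Sample validity.** Discarded samples: outside the image; outside the
  parent nucleus; inside a different nucleolus label.  In addition, the
  default `neighbor_policy="partition"` attributes every nucleoplasm pixel
  to its *nearest* condensate (a Voronoi partition of the space between
  outlines) and keeps only samples whose nearest label is the profiled
  one.  This does two jobs at once.  First, it keeps the PSF halo of a
  bright neighbor out of the windows (a truncated Gaussian kernel of
  σ = 2 px reaches exactly 6 px beyond a neighbor's outline; a fixed guard
  band must exceed that reach plus ~1 px segmentation jitter, and the
  partition is at least as strict wherever halos matter).  Second, and
  more importantly for inference: it makes the sample sets of nucleoli in
  the same field *disjoint*.  Without it, overlapping d ≤ 2 annuli of
  neighboring nucleoli share noisy pixels, their window means become
  positively correlated within a field, and the downstream rank tests —
  which pool nucleoli as independent observations — over-reject (measured
  ≈ 8 % at nominal α = 5 % for identical-preset comparisons at 60 nucleoli
  per arm; exactly the pseudo-replication failure the pooling convention
  risks).  With the partition the identical-preset null is calibrated.  A
  fixed guard band (`neighbor_policy="margin"`, default 8 px) and no
  exclusion (`"none"`) remain available for sensitivity analysis.
* **Window means from raw samples.** Inside/outside means are computed
  from raw valid samples with inclusive edges, never from smoothed bins,
  so the smoothing choice cannot alter the hypothesis tests.
* **Defaults.** 180 rays, 0.25 px marching step, d_max = 2, 40 bins,
  5-bin smoothing window.  Doubling the ray count or halving the step
  changes bin means by < 1 % on default synthetic fields (tested), so the
  sampling density is not a sensitive parameter.
* **z-stacks.** Segmentation and centroids are 3D; profiling uses the 2D
  plane nearest the 3D centroid.  Full 3D spherical sampling is out of
  scope.
* **Degenerate inputs.** A constant image raises an explicit no-regions
  error; a concave region whose centroid falls outside itself raises a
  profiling error suggesting exclusion; a nucleolus whose boundary is
  undetectable on more than half of its rays, or with an empty window, is
  excluded with a machine-readable reason that ends up in the run
  manifest.

## Segmentation

Nuclei: global Otsu threshold on the nuclear marker, hole filling, minimum
area 2000 px²; border-touching nuclei are flagged, not dropped.  Nucleoli:
per-nucleus Otsu on the shell marker restricted to the nucleus interior,
hole filling (a hollow ring becomes the filled condensate), then a
half-maximum refinement: each detected blob's outline is re-drawn where
the signal crosses the midpoint between the blob's bright level (95th
percentile) and the nucleoplasm median.  For a symmetric PSF this midpoint
crossing sits at the true pre-blur boundary independent of object size,
removing the skew-histogram bias of Otsu.  Refined blobs are re-extracted
as connected components (so refinement may split what Otsu merged), then
filtered by minimum area (π·5² px²) and solidity (≥ 0.8).  Thresholds can
be overridden with fixed values.  No watershed splitting of touching
condensates is applied by default; the synthetic placement keeps
condensates resolvable (below), and genuinely fused objects are treated as
one, a documented limitation for real data.

## The statistical layer

Implemented directly (ranking and the normal/t distribution functions come
from scipy; the test logic does not):

* **Mann–Whitney U**, two-sided.  Mid-ranks; exact null by dynamic
  programming over rank sums when n₁+n₂ ≤ 14 and tie-free (used by the
  test oracles; validated against exhaustive enumeration for all equal-size
  datasets up to 5+5), otherwise normal approximation with tie-corrected
  variance and 0.5 continuity correction.  Identical constant samples give
  the defined degenerate result p = 1 (flagged).
* **Steel–Dwass all-pairs**, two-sided.  Per pair: mid-ranks within the
  pooled pair, tie-corrected variance, standardized statistic *t*;
  p = P(Q_{k,∞} ≥ √2·|t|) with the studentized-range survival function
  evaluated by Simpson integration of k·φ(z)·[Φ(z)−Φ(z−q)]^(k−1) on a
  fixed fine grid (absolute accuracy ≪ 1e−8; reproduces the tabulated
  q(k=3, ∞, 0.05) = 3.314 to three decimals).  At k = 2 this reduces
  exactly to the two-sided normal-approximation Mann–Whitney p (without
  continuity correction).  A finite-sample permutation variant
  (`method="permutation"`) refers each |t| to the permutation distribution
  of the maximum standardized pair statistic; at n = 5 per group the
  asymptotic and permutation p differ by up to ≈ 0.09, so the permutation
  mode is the reference for very small groups.
* **Paired t** and **one-sample t**, two-sided, df = n−1.  Zero-variance
  input raises an error (an undefined statistic is not p = 1).
* Two-sided p is min(1, 2·smaller tail) throughout.

`compare_conditions` applies Mann–Whitney for two conditions and
Steel–Dwass for three or more, separately to the inside and outside
windows, and refuses to compare window means computed with different
profiling parameters.  Nucleoli are pooled across cells as independent
observations, matching the field's reporting convention ("n nucleoli /
m cells"); cell-level correlation is not modeled, a known
pseudo-replication caveat, and the per-cell identifiers are carried in
every table so a per-cell sensitivity analysis can be run downstream.

## Assay helpers

* **Crosslink protection**: protected fraction = non-denatured band /
  total band per gel lane, clipped to [0, 1] with a flag when measurement
  noise pushes the ratio above 1.
* **ChIP-qPCR percent input**: %input = 100 · f · E^(Ct_input − Ct_IP)
  with input aliquot fraction f (default 0.02) and amplification
  efficiency E (default 2.0, config-exposed; the adjusted-input
  formulation is algebraically identical).  Values are normalized
  within-replicate to a control condition (controls become exactly 1) and
  the treated condition is tested against 1 with the one-sample t test
  across replicates.

## The synthetic generator

The generator emulates the study conditions end-to-end: 512×512 px fields
at 0.063 µm/px; one nucleus of radius 120 ± 10 px (draws truncated at
±2 s.d.); 3–5 nucleoli per nucleus of radius 25 ± 5 px (clipped to
15–35 px) with a shell occupying the outer 25 % of the radius; channel
laws — nucleus marker uniform 100, shell marker 200 in the shell / 60 in
the core / 20 outside, target signal core-enriched at ratio ρ = 3
(150 inside, nucleoplasm 50).  Optics and noise: Gaussian PSF σ = 2 px
(truncated at 3σ), Poisson photon noise at 1 photon per intensity unit,
Gaussian read noise σ = 2.  Intensity units are arbitrary camera units;
the implied SNR (core ≈ 150/√154 ≈ 12 per pixel) is a stated convention,
echoed into output metadata, chosen as typical of a good confocal/SIM
acquisition.

Condition presets change only the generating laws: `control` (ρ = 3);
`RNAPI_inhibited_like` and `G4_ligand_like` collapse the core contrast
(ρ → 1, nucleoplasm unchanged; the G4 preset additionally halves the
shell marker); `BLM_like` multiplies the whole target law by 0.5.

Placement is rejection sampling with a 10⁴-attempt cap and explicit
failure (never silent overlap).  Pairwise separation is
2·max(rᵢ, rⱼ) + 2 px — which keeps the d ≤ 2 annulus of one nucleolus off
every other body — plus 3·blur_sigma so neighboring condensates remain
*resolvable* under the PSF: two bodies with a gap smaller than the blur
support fuse into one apparent object, which the threshold segmentation
deliberately does not split, and such fused labels corrupt both windows.
The whole d ≤ 2 annulus is kept inside the nucleus so the outside window
is well populated.  Nucleolus outlines are circles by default; optional
low-order angular harmonics perturb the boundary so boundary-tracing code
is exercised on non-circular shapes while the per-ray ground truth stays
analytic.  Ground-truth masks are the pre-blur analytic disks; identical
(spec, seed) gives bit-identical output.

What the generator does **not** emulate: irregular (non-star-convex)
nucleolar shapes, sub-compartment structure within the core, chromatin
texture, per-cell staining variability, optical-reconstruction artifacts,
chromatic shift, or any mechanistic torsion model — the target signal *is*
its radial law.  Passing tests therefore demonstrate that the measurement
and inference chain recovers known radial redistributions under realistic
noise and geometry; they do not certify segmentation accuracy on real
images of irregular condensates.

Synthetic assay tables follow the same philosophy: gel bands with
multiplicative log-normal noise (CV 5 %) around true protected fractions;
qPCR Ct values from ideal doubling with 0.15-cycle measurement noise and a
0.3-cycle per-replicate chromatin offset, values typical of careful qPCR
replicates.

## Validation design

The acceptance layer (`scripts/acceptance.py`, `tests/test_acceptance.py`)
recomputes, from scratch: profiler agreement with an independent per-pixel
binning oracle on analytic laws (constant, linear, step); step-law
boundary localization across radii 10–60 px; segmentation recovery (count
error and IoU) over 20 seeded default fields; type-I error of all four
tests over 1000 null simulations; exact-test agreement with exhaustive
enumeration and with an independently coded 10⁵-resample permutation
reference; recovery of the core-depletion pattern (inside significant,
outside not) over 100 independent two-arm experiments of 60 nucleoli per
arm, with identical-preset pairings as a null control; the ChIP decision
pattern over 200 simulated experiments; and byte-identical pipeline
reruns.  Oracle fixtures use non-integer disk radii and centers: integer
geometry aligns Pythagorean-triple pixels at exactly d = 1, a measure-zero
configuration that turns half-open test binning into a spurious
boundary-convention disagreement.

Problem sizes (20 fields, 1000 null replicates, 100 two-arm runs of 60
nucleoli) were chosen so the whole validation runs on a laptop-class
single core in minutes while keeping Monte-Carlo error well inside each
check's tolerance.

## Known limitations

* Star-convex outlines are assumed by the ray tracer; strongly concave
  outlines give a centroid-outside error or a first-crossing boundary that
  underestimates the territory.
* Condensates closer than the PSF support are segmented as one object.
* The outside window requires the d ≤ 2 annulus to fit inside the nucleus;
  nucleoli hugging the nuclear envelope lose outside samples and are
  excluded when a window is empty.
* Pooling nucleoli across cells ignores within-cell correlation.
* The studentized-range reference is asymptotic; for groups of ≲ 8 use the
  permutation mode.
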