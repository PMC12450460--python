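# Methods

## Background correction

The correction is a two-step procedure on the raw scanner image
(non-negative float64 pixels on the original 8- or 16-bit integer
scale). First, a separable Gaussian blur (default σ = 2 px, reflective
borders) suppresses pixel noise. Second, the smooth local background of
the *blurred* image is estimated with the rolling-ball algorithm: the
surface traced by a ball of radius r (default 35 px) rolled beneath the
intensity landscape, which is exactly grayscale morphological opening
with a spherical-cap structuring element of height h(d) = √(r² − d²)
over the disc d ≤ r. The background is then subtracted from the
*original* image — not the blurred one — so spot amplitudes are not
attenuated by the blur, and the difference is clipped at zero (negative
densitometric intensities have no physical meaning).

Numerical choices:

- The opening is computed exactly (erosion then dilation with the full
  cap profile, both with reflective borders). No shrink/downsample
  optimization is applied: plate scans at the resolutions this tool
  targets are small enough that exactness is affordable, and the exact
  form is what the brute-force oracle in the test suite checks
  bit-for-bit.
- Erosion temporarily dips below zero (it subtracts the cap height);
  the composed opening is mathematically bounded by 0 ≤ opening ≤ input
  for non-negative input, and the implementation clamps into that range
  to guard against float round-off.
- Border handling is `reflect` for both stages, avoiding the dark-frame
  artifacts that zero padding would create at the plate edges. Keeping
  wells at least one ball radius away from the image edge makes border
  effects irrelevant in practice; the bundled simulator uses 60 px
  margins (at 30 px pitch) for this reason.
- The ball radius should comfortably exceed the spot radius; at the
  defaults (spot plateau ≈ 7 px, ball 35 px) spots are removed from the
  background estimate essentially exactly, and correcting an already
  flat image changes spot amplitudes by well under 1%.

One caveat worth stating: the opening's structuring element has a
fixed height in intensity units, so the background operator is *not*
gain-equivariant — opening(k·f) ≠ k·opening(f) in general (the
difference appears at the noise scale and near steep spot edges).
Downstream of background estimation the pipeline is exactly
homogeneous: per-well statistics scale linearly with the image, BCA
division and control subtraction commute with a common gain, ranks and
rank-sum p-values are gain-invariant. The gain-invariance checks in the
test suite and acceptance script therefore apply the gain to the
corrected image; an end-to-end gain through the rolling ball is
equivariant only up to the (small, noise-scale) background deviation.

## Grid model

Well centers are the bilinear span of three corner-well anchors (first
row/first column, first row/last column, last row/first column):
center(r, c) = A1 + f_c (A12 − A1) + f_r (H1 − A1) with
f_c = (c−1)/(n_cols−1), f_r = (r−1)/(n_rows−1). This is an affine model:
it absorbs translation, rotation, anisotropic scale and shear — the
distortions a flatbed membrane scan actually exhibits — but not lens
distortion, which is out of scope. The formula is evaluated in
barycentric form (1 − f_c − f_r)·A1 + f_c·A12 + f_r·H1 so the corner
anchors are reproduced bit-for-bit.

ROI membership is by pixel-center distance: pixel (row, col) — integer
coordinates at pixel centers, x = col, y = row — belongs to a well if
its distance to the well center is ≤ the well radius (inclusive).
Validation requires non-collinear anchors and a radius below half the
smaller inter-well spacing, which guarantees pairwise-disjoint ROIs.
Any disc that leaves the image bounds, even partially, is an error
naming the offending well. Anchor acquisition is non-interactive
(explicit coordinates on the CLI or a plain-text geometry file); the
fine-tuning that an interactive tool exposes as dragging is available
as explicit translate/rescale/radius parameters (`adjust_grid`).

## Per-well statistics

Statistics are computed over exactly the ROI pixel multiset: median
(midpoint convention for even counts), mean, *population* standard
deviation (divide by n — the ROI is the full population of interest,
and the choice is fixed so comparisons across images are stable), mode,
min, max, pixel count. The mode of a continuous-valued corrected image
is ill-defined, so it is computed after rounding to the nearest integer
of the original intensity scale, with ties broken toward the smallest
value — a deterministic rule rather than a statistical claim.

## Normalization and replicate statistics

Per-well median intensity is divided by the well's BCA protein
concentration (loading normalizer). The background is the pooled
per-well mean of the normalized intensities of *both* internal control
types — buffer-only wells (no cells) and untagged-strain wells (cells,
no epitope) — weighting each control well equally rather than averaging
the two control types separately; with balanced control counts the two
conventions coincide. Control wells have no BCA measurement of their
own, so they are normalized by the plate-median BCA of the sample
wells, keeping control and sample signals on a common scale; this is a
documented convention, not a measured quantity. Background-subtracted
values may be negative and are retained (clipping would bias replicate
means upward near zero).

A sample's integrated intensity is the mean of its background-
subtracted normalized medians across replicates. Both the sample sd
(n − 1) and the sem (sd/√n) are always reported, since either may be
wanted as an error bar; for a single replicate both are NaN. Samples
are ranked ascending by integrated intensity with lexicographic
tie-breaks on the sample id, so the output is permutation-invariant.

## Wilcoxon rank-sum test

The two-sample test is implemented from first principles. The statistic
is Mann–Whitney U of the first sample, computed from midranks. For
tie-free data with n + m ≤ 12 the p-value is exact: all C(n+m, n)
assignments of ranks to the first sample are enumerated, and the
p-value is the fraction of assignments at least as extreme as observed
(one-sided: U ≤ or ≥ observed; two-sided: |U − nm/2| ≥ |observed −
nm/2|, using the symmetry of the null distribution). Otherwise the
normal approximation is used with the tie-corrected variance
nm/12 · [(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction
(two-sided numerator clamped at zero, so identical samples give
p = 1). The exact path is verified against an independent enumeration
oracle and against an established reference implementation; the
approximation agrees with the exact distribution to well under 0.01 in
two-sided p at n = m = 12. No multiple-testing correction is applied
across sample pairs; callers screening many pairs should correct
downstream.

## Synthetic plates

The simulator renders: a linear illumination field (offset + gradient),
one spot per well at the true grid centers, additive Gaussian noise,
and quantization to the integer scanner scale with clipping at the bit
ceiling. Two spot profiles exist: `gaussian` (amplitude · exp(−d²/2σ²))
and `flat_top` (constant amplitude within 2σ of the center), the latter
so that a well ROI smaller than the plateau recovers the amplitude as
its median *exactly* in the noise-free case — separating grid/geometry
errors from point-spread effects. Noise is additive Gaussian rather
than Poisson: near-infrared scanner read noise at these intensities is
well approximated as additive, and it keeps the ground truth simple.
The same seed always yields a bitwise-identical image.

The default fixture models a realistic abundance-screening plate:
30 samples × 3 replicates plus 3 buffer-only (amplitude 0) and
3 untagged wells (small residual amplitude 2.0 from antibody
cross-reactivity), scattered over the 96 positions by a seeded
permutation to avoid spatial bias; true expression amplitudes log-
spaced over 10–1000 (two orders of magnitude) on the 16-bit scale;
per-well loading factors uniform in 0.8–1.25 multiplying the rendered
spot and reported as the BCA concentration (so BCA normalization is
genuinely exercised); illumination offset 20 with gradient
(0.02, 0.03)/px; noise sd 10 (1% of the maximum amplitude); 30 px well
pitch, 5 px ROI radius, 3.5 px spot sigma (flat-top plateau radius
7 px) on a 320×440 canvas with 60 px margins.

What the simulator does *not* model — and what passing tests therefore
do not demonstrate about real membranes: smear and bleed-through
between neighboring spots, missing or partial spots, spatially
correlated noise, saturation-shaped (non-Gaussian) spot profiles, and
membrane texture. The simulator validates the computational pipeline,
not the wet-lab assay.

At the fixture's conditions, the full pipeline recovers true expression
amplitudes with ≲3% relative error for wells at least ten times the
noise sd, and Spearman rank correlation ≥ 0.999 between integrated and
true intensities; the residual bias is dominated by the untagged
controls' contribution to the subtracted background (≈1 intensity
unit), which is the assay's own behavior, not an artifact.

## Fusion masses and shift calls

Peptide masses are average (isotope-abundance-weighted) chain masses:
the sum of standard average residue masses (the ExPASy-style table of
amino acid minus water, embedded as data) plus one water, 18.0153 Da —
the quantity relevant to SDS-PAGE mobility. Monoisotopic masses,
charges and post-translational modifications are out of scope. Mass
additivity holds by construction: mass(AB) = mass(A) + mass(B) −
18.0153 Da. The test suite cross-checks the table against an
independent elemental-composition summation (per-residue CHNOS counts ×
IUPAC standard atomic weights), which agrees to <0.01 Da even on the
full 45-residue tag + linker appendage.

The 3xHA + L2 appendage (MYPYDVPDYAGYPYDVPDYAGSYPYDVPDYA +
GGSSGGGGATENSS) computes to 4708.9 Da ≈ 4.7 kDa by this table. The
appendage is sometimes quoted as 4.9 kDa; that figure is not confirmed
by residue-mass summation of the printed sequence, and the computed
4.7 kDa is reported as-is rather than forced to match.

A PNGase glycosylation-shift call is a simple threshold on the apparent
mass drop after treatment: shifted iff (untreated − treated) ≥
min_shift, default 1.0 kDa. The threshold is an explicit, overridable
operational definition of a "clear" shift, not a fitted constant.

## Library summaries

Validation pass rates are 100·passed/total rounded half-up to one
decimal. The compound strain bound is floor(total × survival rate ×
in-frame rate) — a lower bound because it treats the two failure modes
as independent attritions.

Cross-library compartment agreement: among proteins assigned to a
compartment in the reference table, the percentage also assigned to it
in the query table. By default, proteins entirely absent from the query
are excluded from the denominator (absence usually means the protein
was not screened or gave no scorable signal, not that it disagrees);
`include_missing=True` switches to the stricter convention that counts
them as disagreements. The novel-assignment fraction is the share of
(protein, compartment) pairs in the query absent from the reference.

## Problem sizes

The bundled verification runs use the 96-well fixture at 320×440 px
(one rolling-ball opening ≈ 3–4 s at radius 35), 200 random ≤32×32
images for the morphology oracle sweep, full enumeration up to
C(24,12) ≈ 2.7M rank splits for the Wilcoxon checks, and 1000 random
sequence pairs for mass additivity — sizes chosen so the whole suite
and the acceptance script each complete in well under a minute while
still exercising every code path at realistic scale.
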