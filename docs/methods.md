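# Methods

This note records the models, conventions and numerical choices behind
`contourqa`, and what the synthetic phantoms do and do not establish.

## Geometry conventions

All arrays are ordered (x, y, z) matching the on-disk NIfTI layout, indices
are 0-based, and the physical position of voxel (i, j, k) is
`origin + index · spacing` (voxel-center convention). Images and masks must
share a grid exactly; no resampling is ever performed, because a contour is
always evaluated on the CT it was drawn on. NIfTI affines are written as
`diag(spacing)` plus the origin translation and read back without
reorientation — cohorts produced by this package or by any pipeline that
keeps one grid per patient round-trip losslessly.

## Overlap metrics and the bounding-box correction

TP/FP/FN/TN are voxel counts of the four membership combinations, evaluated
inside the smallest axis-aligned box containing every positive voxel of
either mask. The box cannot change TP, FP or FN (all positives lie inside
it); it only removes the enormous background TN count of a whole CT, which
would otherwise pin TNR and RI at ≈1 regardless of contour quality. The box
is tight, with no padding. Ratios with zero denominator (e.g. TNR of a
perfect match evaluated on its own tight box, where TN = FP = 0) are
reported as NaN, never forced to 0 or 1, and NaNs are skipped in all cohort
averages with contributing counts reported. Two empty masks are an error —
there is nothing to evaluate and no clinically meaningful score.

## Surface distances

A mask's surface is the set of centers of its boundary voxels: positive
voxels with a face-adjacent (6-connectivity) negative or out-of-grid
neighbour. This voxel-center dialect, rather than a marching-cubes mesh,
keeps every distance exactly reproducible by an exhaustive all-pairs oracle;
it shifts distances by at most one voxel relative to mesh surfaces, and the
tests therefore use a one-voxel-diagonal tolerance against analytic values.
Distances are Euclidean in mm with anisotropic spacing (CT slice thickness
commonly differs from in-plane pixel size). Nearest neighbours come from a
k-d tree, contractually identical to brute force.

The seven statistics are computed on the pooled vector of both directed
nearest-neighbour vectors, except MDA, which is directed. Pinned choices the
source material leaves open:

* `HD_std` uses the population (ddof = 0) formula — the pooled vector is the
  complete set of nearest-neighbour distances, not a sample;
* `HD_95` uses the linear-interpolation percentile;
* MDA runs from the ground-truth surface to the test surface.

## HU-density QA

**Model.** Each organ's HU values on CT follow a tissue-characteristic,
approximately unimodal distribution. A contour that includes the wrong
tissue changes the *shape* of the HU density sampled inside it, regardless
of organ size, because the KDE is normalized to unit area.

**Estimator.** Gaussian kernel, bandwidth by Scott's rule
`h = n^(−1/5) · sd(sample, ddof=1)`, overridable; a zero-variance sample
falls back to `max(1 HU, grid step)` with a warning. Densities are evaluated
on a shared uniform HU grid (default −1024 to 1600 HU, step 2 HU — the full
clinical CT range; narrower support-covering grids are used where the organ
range is known, e.g. in the validation simulations). The implementation is
cross-checked in the tests against an independent library KDE and against
the closed form for Gaussian samples (a Gaussian smoothed with a Gaussian
kernel is N(μ, σ² + h²)).

**Baseline.** Pointwise mean of the reference curves, with pointwise sample
SD (ddof = 1 — the reference cohort is a sample of the patient population).
Bounds are mean ± 2 SD, the lower bound clipped at 0. With ~80+ reference
patients and approximately normal pointwise fluctuation, a same-population
curve lies inside the envelope at ≈95% of grid points (two-sigma rule; the
exact normal-theory value for a new observation against an 80-sample
mean ± 2 SD band is 0.9497). The package's matched-population simulation
reproduces 0.95 ± 0.03, which is what the acceptance script recomputes.

**Agreement value.** The fraction of grid points (inclusive at both bounds)
where the test density lies inside the envelope. Two modes:

* *full-grid* (default, the faithful formula): every grid point counts,
  including zero-density tails where mean, SD and test density are all ~0
  and agree trivially — this inflates agreement on wide grids;
* *support-restricted*: the denominator keeps only points with baseline mean
  density > 10⁻⁶, a stricter and grid-extent-independent variant.

**Known limitation — non-monotonicity under extreme contamination.** The
indicator only records *whether* the density is inside the envelope, not how
far outside it is. Diluting the organ's own mode strongly enough (e.g. an
80% contaminant admixture shifted 10 SD away) can push flank densities
*below* the upper bound in regions where the clipped lower bound is 0,
letting a few points re-enter the envelope; full-grid agreement is therefore
guaranteed monotone only for moderate contamination (the tests exercise a
5 SD contaminant, where degradation is strictly monotone). Verdicts are
unaffected in practice: any such contour scores far below every sensible
threshold.

**Thresholding.** Default 1.0 (a contour must agree everywhere — the strict
clinical rule for flagging gross errors); configurable, since the right
tolerance depends on cohort size, contouring consistency and the organ set.
Small reference cohorts deserve looser thresholds: with n = 6 reference
patients a legitimate member curve can be the ~2σ outlier of the envelope
over many correlated grid points, so 100% agreement is unattainable even for
perfect contours (observed directly in the CLI smoke cohort).

## Cohort analysis

Per-organ and per-patient summaries are NaN-skipping means/SDs with counts.
Difference matrices are mean(method2) − mean(method1) per organ × metric;
positive overlap differences and negative distance differences favour
method2. Paired t-tests are two-sided on per-patient differences at
α = 0.05 with no multiple-testing correction by default (Holm adjustment is
an opt-in flag); degenerate cases follow fixed conventions — fewer than two
complete pairs gives p = NaN and no winner, constant nonzero differences
give p = 0 with the winner by sign.

## Synthetic phantoms

Phantoms are geometric primitives (spheres, ellipsoids, z-axis tubes) filled
with i.i.d. Gaussian HU draws at tissue-typical means (lung ≈ −700 HU, soft
tissue ≈ 30–40 HU) on a Gaussian background (−50 ± 20 HU), rasterized by the
voxel-center-inside test. Segmentation errors are injected as morphological
dilation/erosion (ball structuring element), integer-voxel translation,
boundary-voxel flips, or translation in a seeded random direction —
emulating the size over/under-estimation and misplacement modes of atlas and
network segmenters. Patient-size variation is a single uniform radius scale
per patient (default ±15%), standing in for a pediatric size range. All
randomness derives from one integer seed, with per-patient streams seeded as
`seed + patient_index`.

What the phantoms deliberately do **not** emulate: anatomical shape,
non-Gaussian or multimodal organ HU distributions (real cochlea or
esophagus densities are not Gaussian), partial-volume effects at organ
boundaries, imaging artifacts, and inter-observer ground-truth variability.
A green phantom test therefore establishes the correctness of the
*machinery* — metric formulas, envelope construction, monotone response to
known error types — not clinical performance on real CTs; clinical
reference values must be rebuilt per institution from real approved
contours.

## Numerical notes

* Distance-metric ordering invariants are enforced with a 1e-9 relative
  tolerance: `np.mean` of a constant vector can exceed its max by 1 ulp.
* KDE evaluation is chunked to bound memory at ~160 MB regardless of sample
  size; trapezoidal integrals over the grid are required to be within
  [0.98, 1.02] of 1 whenever the grid covers the sample ± 4 bandwidths.
* Baseline JSON serialization stores densities at full float precision
  (`repr` round-trip), so save/load is bit-identical.
* The 16-organ vocabulary is closed at the CLI boundary but advisory
  (warning only) programmatically, so the QA machinery generalizes to other
  structures.
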