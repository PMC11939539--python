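# Methods

## Measurement model

The quantity of interest is the alveolar ridge width — the distance between
the vestibular and oral cortical plates — and its change between a
post-extraction CBCT and a follow-up CBCT of the same site.

A CBCT cross-section of the ridge shows two dense cortical plates bounding
lower-intensity trabecular bone (and, centrally, the healing socket). Along a
line drawn across the ridge, the plates appear as the two outermost local
maxima of the grey-value profile. The width at a position is defined as the
difference of the x-coordinates (mm) of those outer maxima. This definition
needs no absolute grey calibration — CBCT grey values are relative, and peak
*locations* are order statistics, invariant under any strictly increasing
grey map (a property the test suite asserts on whole volumes).

Change is reported as `loss = width(t0) − width(t1)`, positive for
resorption. A position with fewer than two detected maxima at either
timepoint is reported as an explicit unmeasurable record, never dropped or
imputed.

## Coordinates and conventions

- Volumes are (axial slice, row, column); slice 0 is the most crestal slice
  retained and the index increases apically. In-plane points are (x, y) =
  (column mm, row mm) measured from the centre of voxel (0, 0, 0).
- 8-bit normalization uses one global min–max window per stack. Per-slice
  windows would change relative peak heights between slices; a single
  monotone map cannot move any peak. Values round half-up so results are
  bit-reproducible; a constant stack maps to zero by convention (degenerate
  inputs occur in padded phantom corners).
- Rounding of grey values after interpolation is also half-up, and a positive
  rotation angle turns image content counter-clockwise (rows displayed
  top-down); 90° rotations of square regions reduce exactly to index
  permutations.

## The measurement grid

One manually drawn line — through the socket centre, perpendicular to the
ridge, extending beyond it — defines everything else:

- 4 copies shifted ±1 and ±2 mm along the in-plane perpendicular
  (mesio-distal axis; positive offsets are distal);
- all 5 lines copied verbatim onto two deeper axial planes targeted at
  2.5 mm and 5.0 mm apical to the crestal slice.

The deeper planes use `k = round(target / slice_thickness)` slices, with an
exact tie between two equally distant slice counts broken toward the more
crestal slice (deterministic, and biased toward *excluding* less-resorbed
anatomy rather than including it). The achieved depth must lie within a
tolerance (default ±0.25 mm) or the operation fails, naming the achievable
depths. At the 0.15 mm slice thickness typical of high-resolution CBCT the
achieved depths are 2.55 mm (17 slices) and 4.95 mm (33 slices); at 1.0 mm
thickness the 2.5 mm target is unreachable within tolerance and errors out.

Grid invariants (enforced and property-tested): 15 lines, all parallel and
equal length, exactly 3 per offset and 5 per depth, adjacent offsets exactly
1 mm apart along the perpendicular.

## Profile extraction and peak detection

Profiles are sampled at steps of the in-plane voxel pitch (no oversampling,
keeping peak x-coordinates commensurate with the image grid). Each sample is
the arithmetic mean of `sampling_width_px` bilinear samples spaced one pixel
apart along the perpendicular, centred on the line — the behaviour of a plot
profile over a wide line selection. The default width is 10 pixels,
interpreted as pixels (image-analysis line-width semantics), configurable.

Maxima and minima are filtered by topographic prominence with threshold
`prominence_fraction × (profile max − min)`, default 10 % of the dynamic
range. The fraction is a free parameter of any peak-based method; it is
recorded in the output for audit and exposed everywhere. Plateaus report
their centre sample (lower index for even plateaus). On profiles of ≤200
samples the detector is tested equal to an exhaustive brute-force
extremum-plus-prominence scan.

When more than two maxima survive the filter, the *outermost* pair defines
the width — anatomically, the cortical plates bound the ridge — and the
measurement is flagged `EXTRA_PEAKS` for review. An outer maximum within one
sampling step of the profile end is flagged `BOUNDARY_PEAK` (the line may not
extend beyond the ridge there). Sub-sample (parabolic) peak refinement is
deliberately off: peak coordinates are read directly from the sample list, so
widths are exact multiples of the pitch and bit-reproducible.

## Registration

Both stacks are reduced by the *same* `RoiSpec` (crop + in-plane rotation
defined once on the baseline). Residual misalignment is removed by the
integer-voxel translation maximizing normalized cross-correlation, searched
exhaustively within a radius (default ±3 axial, ±10 in-plane voxels) — the
cropped volumes are small, so brute force is cheap and exactly reproducible.
The NCC for all candidate placements is computed at once via a normalized
matched filter on the zero-padded moving volume, which is algebraically the
same quantity as scoring each zero-filled shift; a literal Pearson-correlation
loop serves as the independent oracle in the tests, and recovery of noiseless
integer shifts is exact. Score ties resolve to the smallest shift (L1, then
lexicographic), so self-alignment returns (0, 0, 0). Rotation refinement
between timepoints is intentionally omitted — two scans of the same rigid jaw
region differ by a small rotation at most — and the NCC score is reported so
users can judge alignment quality (scores under 0.5 set a `low_score` flag).
Sub-voxel refinement is excluded for determinism. Differing voxel sizes are a
hard error; resampling is out of scope.

## Statistics

- **Summaries**: per-position mean and SD (n−1 denominator) of loss across
  subjects; single observations report SD as undefined, empty cells are not
  fabricated.
- **ANOVA/Tukey**: one-way ANOVA (scipy) with Tukey HSD at 95 % CI
  (statsmodels), validated against a hand-computed example (three groups
  {1,2,3}, {1,2,3}, {11,12,13} give F = 100 exactly).
- **ICC**: Shrout–Fleiss forms computed via pingouin from the two-way ANOVA
  mean squares. "Single random" raters map to ICC(2,1) (two-way random,
  absolute agreement), "single fixed" to ICC(3,1) (two-way mixed,
  consistency), with ICC(2,k)/ICC(3,k) as the averaged counterparts, labelled
  explicitly in the output. Inter-rater forms use each rater's mean across
  repeats; intra-rater reliability is the two-way consistency ICC of each
  rater's own repeats. Degenerate variance decompositions (ICC ≤ 0) are
  reported as computed. All forms are tested against direct mean-squares
  formulas on random balanced arrays.
- **Bland–Altman**: differences are rater1 − rater2; limits of agreement are
  mean ± 1.96 SD (n−1), exact identities by construction. Outliers are points
  strictly outside the limits; points within epsilon of a limit are flagged
  separately so borderline cases stay visible. The default pairing is
  per-position-per-scan (every measured position contributes one pair);
  averaging per scan first is a caller choice.
- **Sample size**: smallest integer n per group whose two-sample t-test power
  (noncentral t, df = 2n−2, noncentrality d·√(n/2)) reaches the target. For
  d = 1.019, α = 0.05, power 0.80, two-tailed, this gives n = 17 per group
  (achieved power 0.821); cross-checked against statsmodels' continuous
  solver.

## The synthetic phantom

The phantom emulates exactly the features the measurement reads, and no more:
per axial slice, two cortical rim bands (default 0.6 mm thick, intensity 220)
separated by the position-specific true width, trabecular fill (100), a
2 mm socket channel (60) at the central millimetre, background 40. The
follow-up volume renders the same geometry minus a programmed per-position
loss. Rendering applies box partial-volume averaging along the profile axis
and across lateral bin boundaries, then a Gaussian PSF (default σ = 0.15 mm =
1 voxel), then seeded additive Gaussian noise (default 0). Default volume:
45 × 60 × 90 voxels at 0.15 mm isotropic — the in-plane footprint of a
premolar site at high-resolution CBCT settings.

True widths and losses are piecewise constant in 1 mm lateral bins centred on
the measurement offsets and in three axial zones around the measurement
planes, so every grid position has one unambiguous truth value. Defaults:
baseline widths 7.2 / 7.8 / 8.4 mm (crestal → −5.0 mm; ridges flare slightly
apically) and losses

| zone | −2 mm | −1 mm | centre | +1 mm | +2 mm |
|------|------|------|------|------|------|
| crestal | 1.5 | 1.8 | 2.1 | 1.8 | 1.5 |
| −2.5 mm | 0.6 | 0.9 | 1.2 | 0.9 | 0.6 |
| −5.0 mm | 0.0 | 0.3 | 0.6 | 0.3 | 0.0 |

— maximal centrally and crestally, tapering laterally and apically, the
qualitative pattern of unassisted socket healing, with magnitudes in the
range reported for premolar sites over ~6 months.

Three deliberate geometric choices make the ground truth exactly recoverable,
so that measurement error isolates pipeline defects rather than artefacts of
the phantom itself:

- **Rim centres sit on voxel centres** (widths and losses are multiples of
  twice the 0.15 mm pitch, and the supplied central line starts on a voxel
  centre), so the noiseless expected peak falls exactly on a sample.
- **Shoulder asymmetry is bounded.** A rim band between unequal shoulders
  (background outside, trabecular inside) has its PSF-smoothed maximum pulled
  toward the brighter shoulder by approximately
  σ²·ln((rim−bg)/(rim−trab))/t; with σ = 0.15 mm, t = 0.6 mm and the default
  intensities this is ≈ 0.02 mm, far below half a voxel. (A wider PSF or
  darker trabecular fill pushes the smoothed argmax a full voxel inward — the
  reason these defaults are what they are.)
- **Lateral loss steps are uniform (0.3 mm)** between adjacent offsets. The
  10-pixel sampling band of an offset unavoidably overlaps the neighbouring
  bins; uniform small steps keep the contaminant rim displacement to one
  voxel with symmetric weights, which cannot move the sampled argmax.

What the phantom does *not* model: real anatomy (curved ridges, roots,
adjacent teeth), scatter, beam hardening, metal artefacts, rotational
misalignment between timepoints, or grey-value drift. Passing the phantom
suite therefore demonstrates the correctness of the measurement chain on
well-formed ridge images, not robustness to every clinical artefact; scans
with severe artefacts require the same qualitative exclusion review as any
grey-value method.

## Verified behaviour (computed by the test suite)

- Noiseless default phantoms: all 15 widths at both timepoints recovered
  within half an in-plane voxel (0.075 mm); the programmed loss gradient
  within one voxel per position; identical inputs give exactly zero loss.
- Noise σ = 10 grey levels with a 1-voxel PSF: ≥ 90 % of positions within one
  voxel of truth across 20 seeded phantoms.
- Rotating a phantom +17° and back −17° (two bilinear resamplings) leaves all
  measured widths within half a voxel of truth.
- Measured widths are invariant under strictly increasing grey maps and under
  joint integer translation of volume and grid.

## Problem sizes

Default phantom volumes (45 × 60 × 90 voxels) and the oracle-comparison sizes
(1,000 random profiles of ≤ 200 samples; 100 alignment trials on 8 × 12 × 12
volumes with a (2, 3, 3)-voxel search radius; 20 noisy phantoms) were chosen
so the full suite completes in well under a minute while still exercising
every code path at realistic CBCT sampling density.

## Known limitations

- Only integer-voxel translation alignment; no rotation or deformable
  registration between timepoints.
- Depth planes are whole slices: the achieved depth is quantized by the slice
  thickness, and coarse scans (≥ 0.6 mm slices) cannot honour the ±0.25 mm
  tolerance.
- The width definition assumes both cortical plates produce detectable
  maxima; a completely resorbed or fenestrated plate yields an unmeasurable
  (flagged) position rather than a width.
- Profile extraction requires isotropic in-plane spacing (true of CBCT
  reconstructions).
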