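# ridgewidth

Semi-automated measurement of alveolar-ridge-width change from CBCT scans.

After a tooth is extracted the alveolar ridge resorbs, most strongly at the
crest and at the centre of the socket. Quantifying that change — e.g. to
compare socket-preservation biomaterials against natural healing — requires a
reproducible, multi-position measurement rather than a single hand-picked
slice. `ridgewidth` implements such a workflow for paired CBCT scans (one
taken post-extraction, one pre-implantation):

1. **Volume I/O** — read a single-frame DICOM series, standardize the grey
   range to 8 bit (global min–max, half-up rounding), exchange stacks as
   multi-page TIFF with a JSON voxel-size sidecar.
2. **Preprocessing** — crop/rotate the baseline scan to the socket region
   (`RoiSpec`), re-apply the identical ROI to the follow-up, and remove
   residual misalignment with an exhaustive integer-voxel translation search
   maximizing normalized cross-correlation.
3. **Measurement grid** — the only manual inputs are the ROI and one central
   line drawn across the ridge on the crestal slice. The grid module expands
   it to 5 horizontal positions (central, ±1 mm, ±2 mm mesio-distally) × 3
   depth planes (crestal, 2.5 mm and 5.0 mm apical, each within ±0.25 mm given
   the slice thickness) — 15 positions in total.
4. **Width measurement** — at each position a wide-line grey-value profile
   (mean over a 10-pixel perpendicular band) is sampled across the ridge. The
   two bright cortical plates appear as the outermost local maxima above a
   prominence threshold (default 10 % of the profile's dynamic range); the
   ridge width at that position is

   `w = x(right outer maximum) − x(left outer maximum)` (mm),

   with QC flags for extra maxima, boundary peaks and unmeasurable profiles.
5. **Statistics** — per-position loss `Δw = w(t0) − w(t1)` (positive =
   resorption), per-position mean ± SD across subjects, one-way ANOVA with
   Tukey HSD, inter-/intra-rater ICC (Shrout–Fleiss ICC(2,1), ICC(3,1) and
   averaged forms), Bland–Altman limits of agreement (mean ± 1.96 SD of the
   paired differences), and a-priori two-sample *t*-test sample size from the
   noncentral-*t* power function.
6. **Phantom** — a synthetic CBCT generator renders baseline/follow-up ridge
   volumes with two cortical rim bands, trabecular fill, a low-intensity
   socket channel, partial-volume averaging, Gaussian PSF and seeded noise,
   plus a ground-truth width table — so the entire chain is testable with no
   patient data.

## Worked example

Generate a synthetic scan pair and run the full pipeline:

```sh
ridgewidth phantom --out fx --seed 42
cat > config.yaml <<EOF
t0: fx/t0
t1: fx/t1
out: out
central_line: fx/central_line.json
scan_pair_id: phantom-42
EOF
ridgewidth run --config config.yaml
```

`out/change.csv` then contains one row per measurement position:

```
scan_pair_id,offset_mm,depth_level,depth_mm,width_t0_mm,width_t1_mm,loss_mm
phantom-42,-2.0,crestal,0.0,7.199999999999999,5.699999999999999,1.5
phantom-42,-1.0,crestal,0.0,7.199999999999999,5.399999999999999,1.8000000000000007
phantom-42,0.0,crestal,0.0,7.199999999999999,5.1000000000000005,2.0999999999999988
phantom-42,1.0,crestal,0.0,7.199999999999999,5.399999999999999,1.8000000000000007
phantom-42,2.0,crestal,0.0,7.199999999999999,5.699999999999999,1.5
phantom-42,0.0,-2.5,2.5,7.8,6.6000000000000005,1.1999999999999993
...
```

Reading the central-crestal row: the ridge measured 7.2 mm wide right after
extraction and 5.1 mm at follow-up, a loss of 2.1 mm — exactly the resorption
this phantom programs at that position. The loss tapers laterally (1.8 mm at
±1 mm, 1.5 mm at ±2 mm) and apically (1.2 mm centrally at −2.5 mm, 0.6 mm at
−5.0 mm), the crestally- and centrally-weighted pattern typical of unassisted
socket healing. The run report (`out/report.json`) records the alignment
shift and NCC score, the chosen depth slices (22 and 38, achieved depths 2.55
and 4.95 mm for 0.15 mm slices) and any QC flags.

The power subcommand reproduces a standard a-priori sample size:

```sh
$ ridgewidth power --d 1.019
n = 17 per group (achieved power 0.821)
```

## Layout

```
src/ridgewidth/
  volume_io.py    DICOM in, 8-bit normalization, TIFF interchange
  preprocess.py   RoiSpec crop/rotation, NCC translation alignment
  grid.py         central line -> 15-position measurement grid
  width.py        wide-line profiles, peak detection, ridge width
  stats.py        change tables, ANOVA/Tukey, ICC, Bland-Altman, power
  phantom.py      synthetic ridge phantom with ground truth
  pipeline.py     end-to-end orchestration (RunConfig -> reports)
  cli.py          `ridgewidth` command-line interface
docs/methods.md   model, parameters, numerical choices, limitations
```
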